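"""Quadratic association engine: transforms, fits, model comparison,
multiplicity and binned summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ucurve._linalg import SingularDesignError
from ucurve.assoc import (binned_summary, compare_models, correct_multiplicity,
                          default_bin_edges, fit_quadratic, log_transform)
from ucurve.synth import SynthConfig, generate_cohort


@pytest.mark.parametrize("count,expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
def test_log_transform_round_numbers(count, expected):
    assert log_transform(count) == pytest.approx(expected)


def test_log_transform_rejects_negative_counts():
    with pytest.raises(ValueError):
        log_transform(-1)
    with pytest.raises(ValueError):
        log_transform(np.array([3, -2]))


def test_pure_linear_outcome_has_zero_quadratic_term(rng):
    x = rng.uniform(0, 2, 500)
    y = 3.0 + 1.7 * (x - x.mean())
    fit = fit_quadratic(y, x)
    assert fit.b == pytest.approx(0.0, abs=1e-10)
    assert fit.a == pytest.approx(1.7, abs=1e-10)


def test_pure_parabola_recovered_exactly(rng):
    x = rng.uniform(-1, 3, 500)
    y = -((x - x.mean()) ** 2)
    fit = fit_quadratic(y, x)
    assert fit.a == pytest.approx(0.0, abs=1e-9)
    assert fit.b == pytest.approx(-1.0, abs=1e-9)
    assert fit.p_F < 1e-300


def _rss_partial_f(y, x, cov):
    """Independent oracle: partial F from residual sums of squares of the
    two nested designs, via raw numpy least squares."""
    z = x - x.mean()
    C = cov.to_numpy(dtype=float) if cov is not None else np.empty((len(y), 0))
    X0 = np.column_stack([np.ones(len(y)), C])
    X2 = np.column_stack([X0, z, z**2])
    r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
    r2 = y - X2 @ np.linalg.lstsq(X2, y, rcond=None)[0]
    rss0, rss2 = r0 @ r0, r2 @ r2
    df2 = len(y) - X2.shape[1]
    return ((rss0 - rss2) / 2) / (rss2 / df2)


@pytest.mark.parametrize("seed", [0, 7, 23])
def test_joint_f_matches_rss_oracle(seed):
    cfg = SynthConfig(seed=seed, n_subjects=2000)
    tab, _ = generate_cohort(cfg)
    cov = tab[["sex", "age", "income"]]
    fit = fit_quadratic(tab["outcome"], tab["count_log"], cov)
    oracle = _rss_partial_f(tab["outcome"].to_numpy(),
                            tab["count_log"].to_numpy(), cov)
    assert fit.F_joint == pytest.approx(oracle, rel=1e-8)


def test_anova_f_equals_squared_quadratic_t(small_cohort):
    _, tab, _ = small_cohort
    fit = fit_quadratic(tab["outcome"], tab["count_log"],
                        tab[["sex", "age", "income"]])
    assert fit.anova_F == pytest.approx(fit.t_b**2, rel=1e-6)


def test_centering_makes_fit_shift_invariant(small_cohort):
    _, tab, _ = small_cohort
    cov = tab[["sex", "age"]]
    f1 = fit_quadratic(tab["outcome"], tab["count_log"], cov)
    f2 = fit_quadratic(tab["outcome"], tab["count_log"] + 11.3, cov)
    for attr in ("a", "b", "t_a", "t_b", "F_joint"):
        assert getattr(f1, attr) == pytest.approx(getattr(f2, attr), rel=1e-8)


def test_dr2_invariant_to_covariate_rescaling(small_cohort):
    _, tab, _ = small_cohort
    cov = tab[["age", "income"]]
    f1 = fit_quadratic(tab["outcome"], tab["count_log"], cov)
    f2 = fit_quadratic(tab["outcome"], tab["count_log"],
                       cov * 7.0 + 3.0)
    assert f1.dR2_quad == pytest.approx(f2.dR2_quad, abs=1e-12)
    assert f1.dR2_lin == pytest.approx(f2.dR2_lin, abs=1e-12)


def test_rank_deficient_design_names_columns(rng):
    x = rng.uniform(0, 2, 100)
    cov = pd.DataFrame({"c1": rng.normal(size=100)})
    cov["c2"] = 2.0 * cov["c1"]
    with pytest.raises(SingularDesignError) as err:
        fit_quadratic(rng.normal(size=100), x, cov)
    assert "c2" in err.value.columns or "c1" in err.value.columns


def test_constant_outcome_rejected(rng):
    with pytest.raises(ValueError, match="constant"):
        fit_quadratic(np.ones(100), rng.uniform(0, 2, 100))


def test_compare_models_identical_fits_give_f_zero(small_cohort):
    _, tab, _ = small_cohort
    fit = fit_quadratic(tab["outcome"], tab["count_log"])
    F, p = compare_models(fit, fit)
    assert F == 0.0 and p == 1.0


def test_compare_models_rejects_different_sample_sizes(small_cohort):
    _, tab, _ = small_cohort
    f1 = fit_quadratic(tab["outcome"], tab["count_log"])
    f2 = fit_quadratic(tab["outcome"][:1000], tab["count_log"][:1000])
    with pytest.raises(ValueError):
        compare_models(f1, f2)


def test_bonferroni_with_family_size_override():
    res = correct_multiplicity([0.001, 0.02, 0.04], "bonferroni",
                               alpha=0.05, m_override=30)
    assert res.threshold == pytest.approx(0.05 / 30)
    assert list(res.significant) == [True, False, False]


def test_bh_all_equal_small_p_all_significant():
    res = correct_multiplicity([0.01] * 10, "bh_fdr", alpha=0.05)
    assert res.significant.all()


def _bh_bruteforce(p, alpha):
    """Exhaustive step-up: largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(p)
    order = np.argsort(p, kind="mergesort")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / len(p):
            k = i
    sig = np.zeros(len(p), bool)
    sig[order[:k]] = True
    return sig


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
def test_bh_matches_exhaustive_step_up(pvals):
    res = correct_multiplicity(pvals, "bh_fdr", alpha=0.05)
    assert np.array_equal(res.significant, _bh_bruteforce(pvals, 0.05))


def test_bh_family_cannot_shrink():
    with pytest.raises(ValueError):
        correct_multiplicity([0.01, 0.02], "bh_fdr", m_override=1)


def test_p_values_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        correct_multiplicity([0.5, 1.2], "bonferroni")


def test_null_pf_is_uniform():
    """Under a zero-effect generator, the joint-F p-value is U(0,1)."""
    rng = np.random.default_rng(99)
    pvals = []
    for _ in range(400):
        x = rng.uniform(0, 1.5, 120)
        y = rng.standard_normal(120)
        pvals.append(fit_quadratic(y, x).p_F)
    d, _ = stats.kstest(pvals, "uniform")
    assert d < 0.07


def test_binned_summary_single_bin_equals_global_mean(rng):
    counts = rng.integers(0, 20, 300)
    y = rng.normal(size=300)
    out = binned_summary(counts, y, bin_edges=[-0.5, 25.0])
    assert len(out) == 1
    assert out.loc[0, "mean"] == pytest.approx(y.mean())
    assert out.loc[0, "n"] == 300


def test_binned_summary_constant_outcome_zero_se(rng):
    counts = rng.integers(0, 12, 500)
    out = binned_summary(counts, np.full(500, 2.5))
    nonempty = out[~out["empty"]]
    assert (nonempty["se"] == 0).all()


def test_binned_summary_flags_empty_bins():
    counts = np.array([0, 0, 5, 5])
    y = np.ones(4)
    out = binned_summary(counts, y, bin_edges=[-0.5, 0.5, 2.5, 5.5])
    assert out.loc[1, "empty"] and out.loc[1, "n"] == 0
    assert np.isnan(out.loc[1, "mean"])


def test_default_bins_cover_counts_and_pool_tail():
    edges = default_bin_edges(np.array([0, 3, 40]))
    assert len(edges) == 13          # 12 bins
    assert edges[-1] > 40


def test_binned_means_track_generating_curve(small_cohort):
    """Bin means should sit within 2 SE of the piecewise truth at the bin
    medians for nearly all bins."""
    cfg, tab, truth = small_cohort
    out = binned_summary(tab["count"], tab["outcome"])
    slope_low, slope_high = truth.true_segment_slopes
    zb = np.log10(cfg.true_breakpoint + 1)
    ok = total = 0
    for _, row in out[~out["empty"]].iterrows():
        if row["n"] < 10:
            continue
        z = np.log10(row["median_count"] + 1)
        g = slope_low * min(z, zb) + slope_high * max(z - zb, 0)
        # covariates are centered on average; compare to curve + overall offset
        resid = row["mean"] - g
        total += 1
        ok += abs(resid) <= 2 * row["se"] + 0.05
    assert ok / total >= 0.9
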