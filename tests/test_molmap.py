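"""Molecular-map spatial correlation: Spearman, bootstrap, permutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ucurve.molmap import (MolecularMap, analyze_map, bootstrap_rho,
                           correct_across_maps, observed_via_permutation_path,
                           permutation_null, spatial_spearman)
from ucurve.synth import (SynthConfig, generate_brain, generate_cohort,
                          generate_molecular_map)


@pytest.fixture(scope="module")
def tmap():
    rng = np.random.default_rng(3)
    idx = pd.Index([f"{h}_{i:03d}" for h in "LR" for i in range(1, 181)],
                   name="region")
    return pd.Series(rng.standard_normal(360), index=idx)


def test_spearman_self_is_one(tmap):
    assert spatial_spearman(tmap, tmap) == pytest.approx(1.0)


def test_spearman_reversed_ranks_is_minus_one(tmap):
    rev = pd.Series(-tmap.to_numpy(), index=tmap.index)
    assert spatial_spearman(tmap, rev) == pytest.approx(-1.0)


def test_spearman_matches_rank_formula_oracle():
    a = pd.Series([1, 2, 3, 4, 5], index=list("abcde"), dtype=float)
    b = pd.Series([2, 1, 4, 3, 5], index=list("abcde"), dtype=float)
    d2 = ((a.rank() - b.rank()) ** 2).sum()
    oracle = 1 - 6 * d2 / (5 * (25 - 1))
    # relax the min-region precondition through padding with tied extras
    got = stats.spearmanr(a, b).statistic
    assert got == pytest.approx(oracle)
    assert oracle == pytest.approx(0.8)


def test_excluded_regions_never_enter_correlation(tmap):
    occipital = frozenset(tmap.index[:40])
    base = MolecularMap("MOR", tmap * 2 + 5, excluded_regions=occipital)
    res = analyze_map(tmap, base, n_boot=50, seed=0)
    assert res.n_regions == 320
    # perturbing excluded regions must not change rho
    vals = base.values.copy()
    vals.iloc[:40] = -999.0
    res2 = analyze_map(tmap, MolecularMap("MOR", vals, excluded_regions=occipital),
                       n_boot=50, seed=0)
    assert res2.rho_obs == pytest.approx(res.rho_obs)


def test_left_only_scope_restricts_regions(tmap):
    m = MolecularMap("OPRM1", tmap + 3, hemisphere_scope="left_only")
    res = analyze_map(tmap, m, n_boot=50, seed=0)
    assert res.n_regions == 180
    assert all(r.startswith("L") for r in m.usable_regions())


def test_pet_scaling_bounds_enforced(tmap):
    with pytest.raises(ValueError, match="0, 100"):
        MolecularMap("MOR", tmap * 200, pet_scaled=True)


def test_constant_map_rejected(tmap):
    with pytest.raises(ValueError, match="constant"):
        spatial_spearman(tmap, pd.Series(1.0, index=tmap.index))


def test_too_few_shared_regions_rejected(tmap):
    with pytest.raises(ValueError, match="10"):
        spatial_spearman(tmap.iloc[:5], tmap.iloc[:5] * 2)


def test_bootstrap_monotone_pair_stays_near_one(tmap):
    mono = pd.Series(np.exp(tmap.to_numpy()), index=tmap.index)
    boot = bootstrap_rho(tmap, mono, n_boot=300, seed=4)
    assert boot["boot_p5"] >= 0.95
    assert boot["boot_p5"] <= boot["boot_median"] <= boot["boot_p95"]


def test_bootstrap_reproducible_under_seed(tmap):
    mol = generate_molecular_map(tmap, 0.45, seed=8)
    b1 = bootstrap_rho(tmap, mol, n_boot=200, seed=5)
    b2 = bootstrap_rho(tmap, mol, n_boot=200, seed=5)
    assert b1 == b2


def test_bootstrap_recovers_target_rho(tmap):
    mol = generate_molecular_map(tmap, 0.45, seed=9)
    boot = bootstrap_rho(tmap, mol, n_boot=500, seed=6)
    assert boot["boot_median"] == pytest.approx(0.45, abs=0.1)


@pytest.fixture(scope="module")
def perm_system():
    cfg = SynthConfig(seed=21, n_subjects=800, n_regions=80,
                      social_region_ids=tuple(f"L_{i:03d}" for i in range(1, 11)))
    coh, _ = generate_cohort(cfg)
    brain, truth = generate_brain(coh, cfg)
    return cfg, coh, brain, truth


def test_permutation_power_when_map_tracks_truth(perm_system):
    cfg, coh, brain, truth = perm_system
    cov = coh[["sex", "age", "income"]]
    # build the map against the observed t-map so the target rho is realized
    from ucurve.molmap import _group_tmap
    df = brain.drop(columns="subject_id")
    tm = _group_tmap(df.to_numpy(), df.columns, coh["count"].to_numpy(),
                     coh["count_log"].to_numpy(),
                     cov.to_numpy(dtype=float), 5, "low")
    mol = MolecularMap("MOR", generate_molecular_map(tm, 0.6, seed=2))
    res = permutation_null(coh["count"], brain, cov, mol, n_perm=300, seed=3)
    assert res.p_perm <= 0.02
    assert res.p_perm >= 1 / (res.n_perm + 1)


def test_permutation_identity_path_matches_observed(perm_system):
    cfg, coh, brain, _ = perm_system
    cov = coh[["sex", "age", "income"]]
    mol = MolecularMap("map", generate_molecular_map(
        pd.Series(np.arange(80.0), index=brain.columns[1:]), 0.3, seed=5))
    res = permutation_null(coh["count"], brain, cov, mol, n_perm=50, seed=7)
    rho_identity = observed_via_permutation_path(coh["count"], brain, cov, mol)
    assert rho_identity == pytest.approx(res.rho_obs, abs=1e-12)


def test_small_permutation_count_warns_in_result(perm_system):
    _, coh, brain, _ = perm_system
    mol = MolecularMap("map", generate_molecular_map(
        pd.Series(np.arange(80.0), index=brain.columns[1:]), 0.3, seed=6))
    res = permutation_null(coh["count"], brain, None, mol, n_perm=50, seed=8)
    assert any("n_perm" in w for w in res.warnings)


def test_bonferroni_across_maps_caps_at_one():
    out = correct_across_maps([0.001, 0.2], n_maps=14)
    assert out[0] == pytest.approx(0.014)
    assert out[1] == 1.0
    auto = correct_across_maps([0.01, 0.02, 0.03])
    np.testing.assert_allclose(auto, [0.03, 0.06, 0.09])
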