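"""Region-wise application of the association engines over a cortical atlas.

The same centered quadratic model used at the behavioral level is applied to
every region of a subjects x regions morphometry table (area, volume,
thickness or subcortical volume), with a two-stage FDR scheme: stage 1 is a
Benjamini-Hochberg correction of the joint-F p-values across all testable
regions; stage 2 corrects the per-term (linear, quadratic) p-values only
within the stage-1 survivors.  Group-split linear t-maps (participants at or
below vs. above the breakpoint) and map-to-map pattern correlation complete
the module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import linear_tmap, multi_ols, partial_f, term_tstats
from .assoc import QuadraticFit, correct_multiplicity, encode_covariates, fit_quadratic


def _region_matrix(region_table: pd.DataFrame):
    df = region_table.drop(columns=["subject_id"], errors="ignore")
    return df.to_numpy(dtype=float), list(df.columns)


def _covariate_matrix(covariates, n):
    cov = encode_covariates(covariates)
    if cov.shape[1] == 0:
        return np.empty((n, 0))
    return cov.to_numpy(dtype=float)


def _adjusted_r2(rss, tss, n, p):
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def regionwise_quadratic(region_table: pd.DataFrame, count_log, covariates=None,
                         q: float = 0.05, fdr_method: str = "bh_fdr") -> pd.DataFrame:
    """Per-region quadratic fits with two-stage FDR.

    Returns a DataFrame indexed by region label with per-region joint F,
    term t statistics and p-values, q-values (stage 1 on p_F across
    regions, stage 2 on term p-values within stage-1 survivors), adjusted
    dR2 of the quadratic term, and flags for constant (untestable) regions.
    """
    Y, labels = _region_matrix(region_table)
    n = Y.shape[0]
    x = np.asarray(count_log, dtype=float)
    C = _covariate_matrix(covariates, n)
    z = x - x.mean()
    ones = np.ones((n, 1))
    X0 = np.column_stack([ones, C])
    X1 = np.column_stack([X0, z])
    X2 = np.column_stack([X1, z**2])

    constant = np.ptp(Y, axis=0) == 0
    _, rss0, _, _ = multi_ols(X0, Y)
    _, rss1, _, _ = multi_ols(X1, Y)
    beta2, t2, p2, rss2, df2 = term_tstats(X2, Y)
    F, pF = partial_f(rss0, rss2, 2, df2)

    tss = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        dR2 = (_adjusted_r2(rss2, tss, n, X2.shape[1])
               - _adjusted_r2(rss1, tss, n, X1.shape[1]))

    out = pd.DataFrame({
        "F_joint": F, "p_F": pF,
        "t_lin": t2[-2], "p_lin": p2[-2],
        "t_quad": t2[-1], "p_quad": p2[-1],
        "dR2_quad": dR2, "constant": constant,
    }, index=pd.Index(labels, name="region"))

    testable = ~constant
    out["q_F"] = np.nan
    out["stage1_significant"] = False
    res1 = correct_multiplicity(out.loc[testable, "p_F"].to_numpy(),
                                fdr_method, alpha=q)
    out.loc[testable, "q_F"] = res1.adjusted_p
    out.loc[testable, "stage1_significant"] = res1.significant

    out["q_lin"] = np.nan
    out["q_quad"] = np.nan
    surv = out.index[out["stage1_significant"]]
    if len(surv):
        for term in ("lin", "quad"):
            res = correct_multiplicity(out.loc[surv, f"p_{term}"].to_numpy(),
                                       fdr_method, alpha=q)
            out.loc[surv, f"q_{term}"] = res.adjusted_p
    return out


def global_measures(totals_table: pd.DataFrame, count_log,
                    covariates=None) -> dict[str, QuadraticFit]:
    """Quadratic fits for global morphometry (total area/volume, mean
    thickness, total subcortical volume): the totals are just more outcomes."""
    out = {}
    for col in totals_table.columns:
        if col == "subject_id":
            continue
        out[col] = fit_quadratic(totals_table[col], count_log, covariates)
    return out


def groupwise_linear(region_table: pd.DataFrame, count_log, covariates=None,
                     *, counts=None, breakpoint=5, q: float = 0.05,
                     fdr_method: str = "bh_fdr") -> dict[str, pd.DataFrame]:
    """Per-group per-region linear t-maps with within-group FDR.

    Groups are defined on raw counts (``<= breakpoint`` vs ``>``, ties to
    the low group, matching the behavioral grouping).  When ``counts`` is
    omitted the split is applied to ``count_log`` directly.
    """
    Y, labels = _region_matrix(region_table)
    n = Y.shape[0]
    x = np.asarray(count_log, dtype=float)
    g = np.asarray(counts, dtype=float) if counts is not None else x
    C = _covariate_matrix(covariates, n)
    out = {}
    for name, mask in (("low", g <= breakpoint), ("high", g > breakpoint)):
        if not mask.any():
            raise ValueError(f"{name} group is empty at breakpoint {breakpoint}")
        t, p, _ = linear_tmap(Y[mask], x[mask], C[mask] if C.size else None)
        df = pd.DataFrame({"t": t, "p": p},
                          index=pd.Index(labels, name="region"))
        res = correct_multiplicity(p, fdr_method, alpha=q)
        df["q"] = res.adjusted_p
        df["significant"] = res.significant
        out[name] = df
    return out


def map_correlation(map_a: pd.Series, map_b: pd.Series):
    """Pearson correlation of two region-keyed statistic maps over their
    shared regions."""
    shared = map_a.index.intersection(map_b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared regions")
    r, p = stats.pearsonr(map_a.loc[shared], map_b.loc[shared])
    return float(r), float(p)
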