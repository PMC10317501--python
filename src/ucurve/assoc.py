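"""Behavioral-level nonlinear association engine.

The dose variable (number of close friends) is log-transformed as
``log10(x + 1)`` and mean-centered; each outcome is regressed on the centered
predictor, its square and a set of covariates.  The quantities of interest
are the joint (partial) F of the linear+quadratic block against the
covariates-only model, the per-term t statistics, and adjusted-R^2 effect
sizes for each added term; the quadratic and linear models are additionally
compared by a one-added-regressor ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._linalg import SingularDesignError, check_full_rank


def log_transform(count):
    """log10(count + 1) for a nonnegative friend count (scalar or array)."""
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValueError("friend counts must be nonnegative")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(count) else out


def encode_covariates(covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Dummy-encode categorical covariates with a first-level reference."""
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=None if covariates is None else covariates.index)
    cat = covariates.select_dtypes(include=["object", "category", "bool"]).columns
    enc = pd.get_dummies(covariates, columns=list(cat), drop_first=True, dtype=float)
    return enc.astype(float)


@dataclass
class QuadraticFit:
    """Results of the centered quadratic regression for one outcome.

    ``a``/``b`` are the linear and quadratic coefficients, ``F_joint`` the
    partial F of the (linear, quadratic) block vs. the covariates-only model,
    ``dR2_quad``/``dR2_lin`` the adjusted-R^2 increments of each added term,
    and ``anova_F``/``anova_p`` the quadratic-vs-linear model comparison.
    """

    a: float
    b: float
    c: float
    t_a: float
    t_b: float
    p_a: float
    p_b: float
    F_joint: float
    p_F: float
    df: tuple
    dR2_quad: float
    dR2_lin: float
    anova_F: float
    anova_p: float
    n: int
    rss: float = field(repr=False, default=np.nan)       # quadratic model RSS
    rss_lin: float = field(repr=False, default=np.nan)
    rss_cov: float = field(repr=False, default=np.nan)
    df_resid: int = field(repr=False, default=0)
    outcome: str = ""

    def summary(self) -> str:
        lines = [
            f"Quadratic dose-response fit{': ' + self.outcome if self.outcome else ''}",
            f"  n = {self.n}",
            f"  linear    a = {self.a: .5g}  t = {self.t_a: .3f}  p = {self.p_a:.3g}",
            f"  quadratic b = {self.b: .5g}  t = {self.t_b: .3f}  p = {self.p_b:.3g}",
            f"  joint F({self.df[0]}, {self.df[1]}) = {self.F_joint:.3f}  p = {self.p_F:.3g}",
            f"  dR2 (quad vs lin) = {100 * self.dR2_quad:.3f}%   "
            f"dR2 (lin vs cov) = {100 * self.dR2_lin:.3f}%",
            f"  quad-vs-lin ANOVA F = {self.anova_F:.3f}  p = {self.anova_p:.3g}",
        ]
        return "\n".join(lines)


class QuadraticModel:
    """Centered quadratic regression of one outcome on log-count + covariates.

    Parameters
    ----------
    outcome : array-like
        Response vector.
    count_log : array-like
        log10(count+1)-scale predictor (centered internally).
    covariates : DataFrame, optional
        Mixed categorical/continuous covariates, dummy-encoded internally.
    """

    def __init__(self, outcome, count_log, covariates: pd.DataFrame | None = None):
        self.outcome_name = getattr(outcome, "name", "") or ""
        y = np.asarray(outcome, dtype=float)
        x = np.asarray(count_log, dtype=float)
        if y.shape != x.shape:
            raise ValueError("outcome and predictor lengths differ")
        if np.ptp(y) == 0:
            raise ValueError("outcome is constant")
        self.y = y
        self.x = x
        cov = encode_covariates(covariates)
        if len(cov) not in (0, len(y)):
            raise ValueError("covariate rows do not match outcome length")
        self.cov = cov
        self.cov_names = list(cov.columns)
        p = len(self.cov_names)
        if len(y) <= p + 3:
            raise ValueError("too few observations for the quadratic design")

    def _designs(self):
        z = self.x - self.x.mean()
        C = self.cov.to_numpy(dtype=float) if self.cov_names else np.empty((len(z), 0))
        ones = np.ones_like(z)
        X0 = np.column_stack([ones, C])
        X1 = np.column_stack([ones, C, z])
        X2 = np.column_stack([ones, C, z, z**2])
        names = ["const", *self.cov_names, "count_log_c", "count_log_c_sq"]
        check_full_rank(X2, names)
        return X0, X1, X2

    def fit(self) -> QuadraticFit:
        X0, X1, X2 = self._designs()
        m0 = sm.OLS(self.y, X0).fit()
        m1 = sm.OLS(self.y, X1).fit()
        m2 = sm.OLS(self.y, X2).fit()
        k = X2.shape[1]
        # Wald F on the (linear, quadratic) block of the full model; an
        # RSS-based partial F against m0 is the algebraic identity checked
        # by the oracle tests.
        R = np.zeros((2, k))
        R[0, k - 2] = 1.0
        R[1, k - 1] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ftest = m2.f_test(R)
        F_joint = float(np.squeeze(ftest.fvalue))
        p_F = float(ftest.pvalue)
        anova_F, anova_p = compare_models(m2, m1)
        return QuadraticFit(
            a=float(m2.params[k - 2]),
            b=float(m2.params[k - 1]),
            c=float(m2.params[0]),
            t_a=float(m2.tvalues[k - 2]),
            t_b=float(m2.tvalues[k - 1]),
            p_a=float(m2.pvalues[k - 2]),
            p_b=float(m2.pvalues[k - 1]),
            F_joint=F_joint,
            p_F=p_F,
            df=(2, int(m2.df_resid)),
            dR2_quad=float(m2.rsquared_adj - m1.rsquared_adj),
            dR2_lin=float(m1.rsquared_adj - m0.rsquared_adj),
            anova_F=anova_F,
            anova_p=anova_p,
            n=len(self.y),
            rss=float(m2.ssr),
            rss_lin=float(m1.ssr),
            rss_cov=float(m0.ssr),
            df_resid=int(m2.df_resid),
            outcome=self.outcome_name,
        )


def fit_quadratic(outcome, count_log, covariates=None) -> QuadraticFit:
    """Fit the centered quadratic model; see :class:`QuadraticModel`."""
    return QuadraticModel(outcome, count_log, covariates).fit()


def _rss_df_n(fit):
    """Extract (rss, df_resid, n) from a statsmodels fit or a QuadraticFit."""
    if hasattr(fit, "ssr"):
        return float(fit.ssr), float(fit.df_resid), int(fit.nobs)
    return float(fit.rss), float(fit.df_resid), int(fit.n)


def compare_models(fit_full, fit_restricted):
    """One-added-regressor ANOVA F between nested fits (full vs restricted).

    ``F = ((RSS_r - RSS_f) / df_diff) / (RSS_f / df_resid_f)``; for a single
    added regressor this equals the squared t of that regressor.
    """
    rss_f, df_f, n_f = _rss_df_n(fit_full)
    rss_r, df_r, n_r = _rss_df_n(fit_restricted)
    if n_f != n_r:
        raise ValueError("models were fit on different sample sizes")
    df_diff = df_r - df_f
    if df_diff < 0 or rss_f > rss_r * (1 + 1e-10) + 1e-10:
        raise ValueError("models are not nested (restricted must be the smaller fit)")
    if df_diff == 0:
        return 0.0, 1.0
    F = ((rss_r - rss_f) / df_diff) / (rss_f / df_f)
    F = max(F, 0.0)
    return float(F), float(stats.f.sf(F, df_diff, df_f))


@dataclass
class MultiplicityResult:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    significant: np.ndarray
    method: str
    m: int
    alpha: float
    threshold: float | None = None  # Bonferroni per-test threshold

    def __len__(self):
        return len(self.raw_p)


def correct_multiplicity(p_values, method="bonferroni", alpha=0.05,
                         m_override: int | None = None) -> MultiplicityResult:
    """Bonferroni or Benjamini-Hochberg multiplicity correction.

    ``m_override`` lets the Bonferroni family size differ from the vector
    length (30 outcome F tests vs. 60 term t tests share one family in the
    behavioral analyses).  For BH, ``m_override`` may only enlarge the
    family (tests not in the vector are treated as nonsignificant).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        m = int(m_override) if m_override is not None else len(p)
        thr = alpha / m
        adj = np.minimum(p * m, 1.0)
        return MultiplicityResult(p, adj, p < thr, "bonferroni", m, alpha, thr)
    if method in ("bh_fdr", "fdr_bh", "bh"):
        m = int(m_override) if m_override is not None else len(p)
        if m < len(p):
            raise ValueError("BH family size cannot be smaller than the p-value vector")
        # step-up over the full family of size m
        order = np.argsort(p, kind="mergesort")
        ranked = p[order]
        crit = alpha * (np.arange(1, len(p) + 1)) / m
        passed = ranked <= crit
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        sig = np.zeros(len(p), dtype=bool)
        sig[order[:k]] = True
        adj = np.minimum.accumulate((ranked * m / np.arange(1, len(p) + 1))[::-1])[::-1]
        adjusted = np.empty_like(p)
        adjusted[order] = np.minimum(adj, 1.0)
        return MultiplicityResult(p, adjusted, sig, "bh_fdr", m, alpha)
    raise ValueError(f"unknown method {method!r}")


def default_bin_edges(counts) -> np.ndarray:
    """Integer bins 0..10 plus a pooled 11+ tail (12 bins)."""
    hi = max(float(np.max(counts)) + 0.5, 11.5)
    return np.array([-0.5] + [i + 0.5 for i in range(11)] + [hi])


def binned_summary(count, outcome, bin_edges=None) -> pd.DataFrame:
    """Per-bin median count, outcome mean, standard error and n.

    Empty bins are reported with ``n = 0`` and NaN mean and flagged via the
    ``empty`` column rather than dropped.
    """
    count = np.asarray(count, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    edges = default_bin_edges(count) if bin_edges is None else np.asarray(bin_edges, float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if count.min() < edges[0] or count.max() > edges[-1]:
        raise ValueError("bin edges do not cover the observed count range")
    idx = np.digitize(count, edges[1:-1], right=True)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            rows.append((b, np.nan, np.nan, np.nan, 0, True))
            continue
        vals = outcome[sel]
        se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        rows.append((b, float(np.median(count[sel])), float(vals.mean()), float(se), n, False))
    return pd.DataFrame(rows, columns=["bin", "median_count", "mean", "se", "n", "empty"])
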