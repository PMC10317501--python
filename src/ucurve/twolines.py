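"""Two-lines (interrupted regression) test for U-shaped relations.

A significant quadratic term is a notoriously weak certificate of a
U-shape: any convex monotone trend can produce one.  The two-lines
procedure instead (1) locates a candidate extremum from a flexible
covariate-adjusted fit, (2) fits an interrupted regression with separate
slopes below and above the candidate, (3) reallocates boundary
observations from the stronger segment (larger |z|) to the weaker one and
refits once, and (4) declares a U only when the two final segment slopes
are individually significant with opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import encode_covariates


@dataclass
class TwoLinesResult:
    """Breakpoint, per-segment slopes with inference, and the verdict.

    ``breakpoint`` is in predictor units; ``breakpoint_count`` carries the
    raw-count back-transform ``10^b - 1`` when the predictor is on the
    log10(count+1) scale.
    """

    breakpoint: float
    slope_low: float
    slope_high: float
    ci_low: tuple
    ci_high: tuple
    p_low: float
    p_high: float
    n_low: int
    n_high: int
    verdict: str
    breakpoint_count: float | None = None
    diagnostic: str = ""

    def summary(self) -> str:
        bp = f"{self.breakpoint:.4g}"
        if self.breakpoint_count is not None:
            bp += f" (raw count {self.breakpoint_count:.3g})"
        return "\n".join([
            "Two-lines interrupted regression",
            f"  breakpoint = {bp}",
            f"  low  segment: slope = {self.slope_low: .4g} "
            f"[{self.ci_low[0]:.4g}, {self.ci_low[1]:.4g}]  p = {self.p_low:.3g}  n = {self.n_low}",
            f"  high segment: slope = {self.slope_high: .4g} "
            f"[{self.ci_high[0]:.4g}, {self.ci_high[1]:.4g}]  p = {self.p_high:.3g}  n = {self.n_high}",
            f"  verdict: {self.verdict}" + (f"  ({self.diagnostic})" if self.diagnostic else ""),
        ])


def _verdict(slope_low, slope_high, p_low, p_high, alpha=0.05):
    both_sig = p_low < alpha and p_high < alpha
    if both_sig and np.sign(slope_low) == -np.sign(slope_high) != 0:
        return "inverted_u" if slope_low > 0 else "u_shape"
    if p_low < alpha or p_high < alpha:
        return "monotone"
    return "flat"


class TwoLinesModel:
    """Two-lines test of ``outcome`` against ``predictor`` with covariates.

    Parameters
    ----------
    min_segment : int
        Minimum observations per segment; an interior candidate that
        violates it yields verdict ``indeterminate``.
    log_count_scale : bool
        When True the predictor is log10(count+1) and the breakpoint is
        also reported as a raw count via ``10^b - 1``.
    residualize : bool
        Remove covariates from the outcome first instead of entering them
        in the interrupted regression.
    """

    def __init__(self, outcome, predictor, covariates=None, *, min_segment=10,
                 log_count_scale=False, residualize=False, alpha=0.05):
        self.y = np.asarray(outcome, dtype=float)
        self.x = np.asarray(predictor, dtype=float)
        if self.y.shape != self.x.shape:
            raise ValueError("outcome and predictor lengths differ")
        if len(np.unique(self.x)) < 4:
            raise ValueError("predictor needs at least 4 distinct values")
        if len(self.x) < 2 * min_segment:
            raise ValueError("too few observations for two segments")
        cov = encode_covariates(covariates)
        self.C = cov.to_numpy(dtype=float) if cov.shape[1] else np.empty((len(self.y), 0))
        self.min_segment = min_segment
        self.log_count_scale = log_count_scale
        self.residualize = residualize
        self.alpha = alpha
        if residualize and self.C.shape[1]:
            Z = np.column_stack([np.ones(len(self.y)), self.C])
            self.y = self.y - Z @ np.linalg.lstsq(Z, self.y, rcond=None)[0]
            self.C = np.empty((len(self.y), 0))

    # -- first stage: candidate extremum and its flat region ---------------
    def _candidate(self):
        z = self.x - self.x.mean()
        X = np.column_stack([np.ones(len(z)), self.C, z, z**2])
        fit = sm.OLS(self.y, X).fit()
        b_lin, b_quad = fit.params[-2], fit.params[-1]
        se_quad = fit.bse[-1]
        lo, hi = self.x.min(), self.x.max()
        if abs(b_quad) < 1e-12 or abs(b_quad) < 0.1 * se_quad:
            return None, None, None  # no usable curvature
        x_star = self.x.mean() - b_lin / (2 * b_quad)
        if not (lo < x_star < hi):
            return None, None, None
        # flat region: x where the fitted curve is within one pointwise SE
        # of its extremum value
        V = fit.cov_params()[-2:, -2:]
        zs = x_star - self.x.mean()
        g = lambda zz: b_lin * zz + b_quad * zz**2
        se_star = np.sqrt(np.array([zs, zs**2]) @ V @ np.array([zs, zs**2]))
        zz = np.sort(np.append(z, zs))   # the extremum itself is always inside
        curve = g(zz)
        peak = g(zs)
        inside = (curve >= peak - se_star) if b_quad < 0 else (curve <= peak + se_star)
        # keep the contiguous run containing the extremum
        idx = np.flatnonzero(inside)
        pos = np.searchsorted(zz, zs)
        pos = min(pos, len(zz) - 1)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            if run[0] <= pos <= run[-1]:
                idx = run
                break
        xs = zz[idx] + self.x.mean()
        return x_star, float(xs.min()), float(xs.max())

    # -- interrupted regression at a given break ---------------------------
    def _interrupted(self, c):
        """Segmented fit with a level-jump dummy at the cutoff.

        The jump term makes the two segment slopes within-segment
        estimates (equivalent to fitting the split halves separately up to
        the shared covariates).  Without it, cutting at a chance peak of
        the outcome converts the level difference into a spurious negative
        high-segment slope, inflating the false U-shape rate severalfold.
        """
        x_low = np.minimum(self.x - c, 0.0)    # ties at c go to the low segment
        x_high = np.maximum(self.x - c, 0.0)
        high = (self.x > c).astype(float)
        n_high = int(high.sum())
        n_low = len(self.x) - n_high
        X = np.column_stack([np.ones(len(self.x)), self.C, high, x_low, x_high])
        fit = sm.OLS(self.y, X).fit()
        return fit, n_low, n_high

    def _global_linear(self):
        X = np.column_stack([np.ones(len(self.x)), self.C, self.x])
        fit = sm.OLS(self.y, X).fit()
        slope, p = float(fit.params[-1]), float(fit.pvalues[-1])
        ci = tuple(fit.conf_int()[-1])
        verdict = "monotone" if p < self.alpha else "flat"
        return TwoLinesResult(
            breakpoint=float(self.x.max()), slope_low=slope, slope_high=slope,
            ci_low=ci, ci_high=ci, p_low=p, p_high=p,
            n_low=len(self.x), n_high=0, verdict=verdict,
            breakpoint_count=(10 ** self.x.max() - 1) if self.log_count_scale else None,
            diagnostic="no interior extremum; global linear fit reported")

    def fit(self) -> TwoLinesResult:
        x_star, flat_lo, flat_hi = self._candidate()
        if x_star is None:
            return self._global_linear()
        fit0, n_lo0, n_hi0 = self._interrupted(x_star)
        if min(n_lo0, n_hi0) < self.min_segment:
            return self._indeterminate(x_star, "candidate split leaves a segment "
                                               f"below {self.min_segment} observations")
        z_low = abs(fit0.tvalues[-2])
        z_high = abs(fit0.tvalues[-1])
        # Robin Hood reallocation: the weaker segment receives the larger
        # share of the flat region; one adjustment pass.
        w = 0.5 if z_low + z_high == 0 else z_high / (z_low + z_high)
        c = flat_lo + w * (flat_hi - flat_lo)
        fit1, n_low, n_high = self._interrupted(c)
        if min(n_low, n_high) < self.min_segment:
            return self._indeterminate(c, "adjusted split leaves a segment "
                                          f"below {self.min_segment} observations")
        slope_low, slope_high = float(fit1.params[-2]), float(fit1.params[-1])
        p_low, p_high = float(fit1.pvalues[-2]), float(fit1.pvalues[-1])
        ci = fit1.conf_int()
        return TwoLinesResult(
            breakpoint=float(c),
            slope_low=slope_low, slope_high=slope_high,
            ci_low=tuple(ci[-2]), ci_high=tuple(ci[-1]),
            p_low=p_low, p_high=p_high, n_low=n_low, n_high=n_high,
            verdict=_verdict(slope_low, slope_high, p_low, p_high, self.alpha),
            breakpoint_count=(10 ** c - 1) if self.log_count_scale else None)

    def _indeterminate(self, c, why) -> TwoLinesResult:
        n_low = int((self.x <= c).sum())
        return TwoLinesResult(
            breakpoint=float(c), slope_low=np.nan, slope_high=np.nan,
            ci_low=(np.nan, np.nan), ci_high=(np.nan, np.nan),
            p_low=np.nan, p_high=np.nan, n_low=n_low, n_high=len(self.x) - n_low,
            verdict="indeterminate",
            breakpoint_count=(10 ** c - 1) if self.log_count_scale else None,
            diagnostic=why)


def two_lines_test(outcome, predictor, covariates=None, **kwargs) -> TwoLinesResult:
    """Run the two-lines test; see :class:`TwoLinesModel`."""
    return TwoLinesModel(outcome, predictor, covariates, **kwargs).fit()


def split_and_fit(outcome, predictor, covariates=None, breakpoint=None):
    """Independent covariate-adjusted linear fits on the two groups split at
    the breakpoint (ties to the low group).

    Returns two statsmodels OLS results ``(fit_low, fit_high)`` whose last
    coefficient is the predictor slope.
    """
    if breakpoint is None:
        raise ValueError("breakpoint is required")
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    cov = encode_covariates(covariates)
    C = cov.to_numpy(dtype=float) if cov.shape[1] else np.empty((len(y), 0))
    fits = []
    for mask in (x <= breakpoint, x > breakpoint):
        if not mask.any():
            raise ValueError("empty group at this breakpoint")
        X = np.column_stack([np.ones(mask.sum()), C[mask], x[mask]])
        fits.append(sm.OLS(y[mask], X).fit())
    return tuple(fits)


def breakpoint_summary(results) -> dict:
    """Mean +/- SD of raw-count breakpoints across a set of outcomes."""
    bps = [r.breakpoint_count if r.breakpoint_count is not None else r.breakpoint
           for r in results if r.verdict in ("u_shape", "inverted_u")]
    if not bps:
        return {"n": 0, "mean": np.nan, "sd": np.nan}
    return {"n": len(bps), "mean": float(np.mean(bps)),
            "sd": float(np.std(bps, ddof=1)) if len(bps) > 1 else 0.0}
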