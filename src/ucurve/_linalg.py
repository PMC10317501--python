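"""Vectorised least-squares helpers shared by the region-wise engines.

All region-wise statistics (joint F maps, linear t-maps, permutation nulls)
go through the two routines here so that observed and null maps are computed
by literally the same code path.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


def check_full_rank(X: np.ndarray, names) -> None:
    """Raise :class:`SingularDesignError` naming collinear columns, if any."""
    r = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(r))
    bad = d < max(X.shape) * np.finfo(float).eps * (d.max() if d.size else 1.0)
    if bad.any():
        raise SingularDesignError([n for n, b in zip(names, bad) if b])


def multi_ols(X: np.ndarray, Y: np.ndarray):
    """OLS of every column of ``Y`` on the common design ``X``.

    Returns ``(beta, rss, df_resid, xtx_inv)`` where ``beta`` is (p, k) for
    k responses and ``rss`` the per-response residual sum of squares.
    """
    n, p = X.shape
    q, r = np.linalg.qr(X)
    beta = np.linalg.solve(r, q.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    rinv = np.linalg.inv(r)
    xtx_inv = rinv @ rinv.T
    return beta, rss, n - p, xtx_inv


def term_tstats(X: np.ndarray, Y: np.ndarray):
    """Per-response t statistics for every coefficient of the common design.

    Returns ``(beta, t, p, rss, df_resid)`` with ``beta``/``t``/``p`` of
    shape (p, k).
    """
    beta, rss, df, xtx_inv = multi_ols(X, Y)
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, t, p, rss, df


def partial_f(rss_restricted, rss_full, df_num, df_resid_full):
    """Nested-model partial F and its p-value (vectorised over responses)."""
    rss_restricted = np.asarray(rss_restricted, dtype=float)
    rss_full = np.asarray(rss_full, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_restricted - rss_full) / df_num) / (rss_full / df_resid_full)
    F = np.clip(F, 0.0, None)
    p = stats.f.sf(F, df_num, df_resid_full)
    return F, p


def linear_tmap(Y: np.ndarray, x: np.ndarray, Z: np.ndarray | None):
    """t statistic of ``x`` in ``y ~ 1 + Z + x`` for every column of ``Y``.

    Computed by the Frisch-Waugh route (residualise both sides against the
    nuisance block, then a single partial correlation per response), which is
    algebraically identical to the full-regression t but costs O(n k) per
    call — the permutation engine depends on this.
    """
    n = len(x)
    ones = np.ones((n, 1))
    Zfull = ones if Z is None or Z.size == 0 else np.column_stack([ones, Z])
    qz, _ = np.linalg.qr(Zfull)
    xr = x - qz @ (qz.T @ x)
    Yr = Y - qz @ (qz.T @ Y)
    df = n - Zfull.shape[1] - 1
    sx = np.sqrt(xr @ xr)
    sy = np.sqrt(np.einsum("ij,ij->j", Yr, Yr))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yr.T @ xr) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, df
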