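"""Two-wave cross-lagged panel models with full-information ML.

The panel relates the distance of the friend count from the breakpoint,
|count - breakpoint|, to an outcome across two waves.  The model is the
classic observed-variable CLPM: two autoregressive paths, two cross-lagged
paths, freely correlated wave-1 variables and covariates, covariate effects
on both wave-2 variables, and a wave-2 residual covariance.  Because every
wave-2 variable is regressed on the full exogenous block, the model is
covariance-saturated, so the FIML estimates are a deterministic function of
the full-information mean/covariance estimate, which is obtained by an EM
algorithm over missingness patterns (casewise likelihood on observed
entries).  Fit indices (CFI, TLI, RMSEA, SRMR) are computed from the ML
discrepancy against the saturated and independence models; formulas are
documented inline since variants exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ConvergenceError(RuntimeError):
    pass


def distance_transform(count, breakpoint: float = 5):
    """|count - breakpoint|: distance of the friend count from the optimum."""
    return np.abs(np.asarray(count, dtype=float) - breakpoint)


@dataclass
class CLPMSpec:
    """Column bindings for the two-wave panel."""

    x_t1: str = "x1"
    y_t1: str = "y1"
    x_t2: str = "x2"
    y_t2: str = "y2"
    stable_covariates: tuple = ()
    timevarying_covariates: tuple = ()   # wave-1 measurements; enter at their wave
    estimator: str = "fiml"              # "fiml" or "listwise"

    @property
    def covariates(self) -> tuple:
        return tuple(self.stable_covariates) + tuple(self.timevarying_covariates)

    def variables(self) -> list[str]:
        return [self.x_t1, self.y_t1, *self.covariates, self.x_t2, self.y_t2]


@dataclass
class CLPMResult:
    beta_ar_x: float
    beta_ar_y: float
    beta_cl_xy: float          # x_t1 -> y_t2
    beta_cl_yx: float          # y_t1 -> x_t2
    se: dict
    pvalues: dict
    fit: dict                  # CFI, TLI, RMSEA, SRMR, chi2, df
    n: int
    n_effective: dict
    estimator: str = "fiml"
    loglik: float = np.nan
    covariate_betas: dict = field(default_factory=dict)

    def paths(self) -> dict:
        return {"ar_x": self.beta_ar_x, "ar_y": self.beta_ar_y,
                "cl_xy": self.beta_cl_xy, "cl_yx": self.beta_cl_yx}

    def summary(self) -> str:
        lines = [f"Two-wave CLPM ({self.estimator}), n = {self.n}"]
        for k, v in self.paths().items():
            lines.append(f"  {k:6s} = {v: .4f}  (se {self.se[k]:.4f}, p {self.pvalues[k]:.3g})")
        f = self.fit
        lines.append(f"  CFI = {f['CFI']:.3f}  TLI = {f['TLI']:.3f}  "
                     f"RMSEA = {f['RMSEA']:.3f}  SRMR = {f['SRMR']:.4f}")
        return "\n".join(lines)


def _pattern_groups(mask: np.ndarray):
    """Group row indices by missingness pattern (order-independent)."""
    keys = [tuple(row) for row in mask]
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return {k: np.array(v) for k, v in sorted(groups.items())}


def _mvn_loglik(data: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                groups) -> float:
    ll = 0.0
    for key, rows in groups.items():
        obs = ~np.array(key)
        if not obs.any():
            continue
        x = data[np.ix_(rows, np.flatnonzero(obs))]
        m = mu[obs]
        s = sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0:
            raise np.linalg.LinAlgError("implied covariance not positive definite")
        sinv = np.linalg.inv(s)
        d = x - m
        quad = np.einsum("ij,jk,ik->i", d, sinv, d)
        ll += -0.5 * (len(rows) * (obs.sum() * np.log(2 * np.pi) + logdet) + quad.sum())
    return float(ll)


def em_mvnorm(data: np.ndarray, max_iter: int = 1000, tol: float = 1e-10):
    """EM for the MVN mean/covariance under arbitrary missingness.

    Returns ``(mu, sigma, loglik, n_iter)``; the likelihood is the casewise
    (full-information) likelihood over observed entries.
    """
    n, k = data.shape
    mask = np.isnan(data)
    if mask.all(axis=0).any():
        raise ValueError("a variable is entirely missing")
    groups = _pattern_groups(mask)
    col_means = np.nanmean(data, axis=0)
    filled = np.where(mask, col_means, data)
    mu = filled.mean(axis=0)
    sigma = np.cov(filled, rowvar=False, bias=True)
    sigma += 1e-8 * np.eye(k)
    last = -np.inf
    for it in range(max_iter):
        sx = np.zeros(k)
        sxx = np.zeros((k, k))
        for key, rows in groups.items():
            miss = np.array(key)
            obs = ~miss
            x = data[np.ix_(rows, np.flatnonzero(obs))]
            if miss.any():
                soo = sigma[np.ix_(obs, obs)]
                smo = sigma[np.ix_(miss, obs)]
                smm = sigma[np.ix_(miss, miss)]
                w = np.linalg.solve(soo, smo.T).T          # S_mo S_oo^-1
                cond_cov = smm - w @ smo.T
                xm = mu[miss] + (x - mu[obs]) @ w.T
                full = np.empty((len(rows), k))
                full[:, obs] = x
                full[:, miss] = xm
                sx += full.sum(axis=0)
                cross = full.T @ full
                cross[np.ix_(miss, miss)] += len(rows) * cond_cov
                sxx += cross
            else:
                sx += x.sum(axis=0)
                sxx += x.T @ x
        mu = sx / n
        sigma = sxx / n - np.outer(mu, mu)
        ll = _mvn_loglik(data, mu, sigma, groups)
        if abs(ll - last) < tol * (abs(ll) + 1.0):
            return mu, sigma, ll, it + 1
        last = ll
    raise ConvergenceError(
        f"EM did not converge in {max_iter} iterations (last change "
        f"{ll - last:.3e})")


def _fit_indices(chi2, df, chi2_base, df_base, n, s_sample, s_implied):
    """Standard ML chi-square fit indices with the independence baseline.

    CFI  = 1 - max(chi2 - df, 0) / max(chi2_base - df_base, chi2 - df, eps)
    TLI  = ((chi2_base/df_base) - (chi2/df)) / ((chi2_base/df_base) - 1)
    RMSEA = sqrt(max(chi2 - df, 0) / (df * n))
    SRMR = RMS of the standardized covariance residuals (lower triangle
           plus diagonal).
    A saturated model (df = 0) has CFI = TLI = 1 and RMSEA = 0 by
    convention.
    """
    d = np.sqrt(np.diag(s_sample))
    std_resid = (s_sample - s_implied) / np.outer(d, d)
    tri = np.tril_indices_from(std_resid)
    srmr = float(np.sqrt(np.mean(std_resid[tri] ** 2)))
    if df <= 0:
        return {"CFI": 1.0, "TLI": 1.0, "RMSEA": 0.0, "SRMR": srmr,
                "chi2": float(max(chi2, 0.0)), "df": int(df),
                "chi2_baseline": float(chi2_base), "df_baseline": int(df_base)}
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, num, np.finfo(float).eps)
    cfi = 1.0 - num / den
    ratio_b = chi2_base / df_base
    tli = (ratio_b - chi2 / df) / (ratio_b - 1.0) if ratio_b > 1 else 1.0
    rmsea = float(np.sqrt(num / (df * n)))
    return {"CFI": float(min(cfi, 1.0)), "TLI": float(min(tli, 1.0)),
            "RMSEA": rmsea, "SRMR": srmr, "chi2": float(chi2), "df": int(df),
            "chi2_baseline": float(chi2_base), "df_baseline": int(df_base)}


class CLPM:
    """Classic two-wave cross-lagged panel model on a wide table.

    Parameters
    ----------
    data : DataFrame
        One row per subject; wave-2 entries may be NaN.
    spec : CLPMSpec
        Column bindings, covariate sets and estimator.
    """

    def __init__(self, data: pd.DataFrame, spec: CLPMSpec | None = None, **kwargs):
        self.spec = spec if spec is not None else CLPMSpec(**kwargs)
        missing_cols = [c for c in self.spec.variables() if c not in data.columns]
        if missing_cols:
            raise KeyError(f"columns not in table: {missing_cols}")
        self.data = data
        self._vars = self.spec.variables()
        self._exo = [self.spec.x_t1, self.spec.y_t1, *self.spec.covariates]
        self._endo = [self.spec.x_t2, self.spec.y_t2]

    def fit(self, estimator: str | None = None) -> CLPMResult:
        est = estimator or self.spec.estimator
        raw = self.data[self._vars].to_numpy(dtype=float)
        n_all = raw.shape[0]
        if est == "listwise":
            raw = raw[~np.isnan(raw).any(axis=1)]
            if len(raw) < len(self._vars) + 2:
                raise ValueError("too few complete rows for listwise estimation")
        elif est != "fiml":
            raise ValueError("estimator must be 'fiml' or 'listwise'")
        n = raw.shape[0]
        groups = _pattern_groups(np.isnan(raw))
        mu, sigma, ll_sat, _ = em_mvnorm(raw)
        k = len(self._vars)
        ke = len(self._exo)
        idx_e = np.arange(ke)
        idx_d = np.arange(ke, k)

        s_ee = sigma[np.ix_(idx_e, idx_e)]
        s_de = sigma[np.ix_(idx_d, idx_e)]
        s_dd = sigma[np.ix_(idx_d, idx_d)]
        sign, _ = np.linalg.slogdet(s_ee)
        if sign <= 0:
            raise np.linalg.LinAlgError("exogenous covariance not positive definite")
        B = np.linalg.solve(s_ee, s_de.T).T           # (2, ke) raw-scale paths
        resid_cov = s_dd - B @ s_de.T

        sd = np.sqrt(np.diag(sigma))
        sd_e, sd_d = sd[idx_e], sd[idx_d]
        B_std = B * sd_e[None, :] / sd_d[:, None]

        # per-equation SEs on the standardized scale; effective n = rows
        # with that wave-2 variable observed
        corr_ee = s_ee / np.outer(sd_e, sd_e)
        corr_ee_inv = np.linalg.inv(corr_ee)
        se_map, p_map, n_eff = {}, {}, {}
        names = [("ar_x", 0, 0), ("cl_yx", 0, 1), ("cl_xy", 1, 0), ("ar_y", 1, 1)]
        obs_count = (~np.isnan(raw[:, idx_d])).sum(axis=0)
        resid_var_std = np.diag(resid_cov) / sd_d**2
        for key, i, j in names:
            m = int(obs_count[i])
            se = float(np.sqrt(resid_var_std[i] * corr_ee_inv[j, j] / m))
            t = B_std[i, j] / se if se > 0 else np.nan
            dfree = max(m - ke - 1, 1)
            se_map[key] = se
            p_map[key] = float(2 * stats.t.sf(abs(t), dfree))
            n_eff[key] = m
        cov_betas = {f"{self._endo[i]}~{self._exo[j]}": float(B_std[i, j])
                     for i in range(2) for j in range(2, ke)}

        # chi-square machinery: the structural model reproduces (mu, sigma)
        # exactly (saturated), so chi2 ~ 0; formulas kept general.
        sigma_implied = sigma.copy()
        ll_model = _mvn_loglik(raw, mu, sigma_implied, groups)
        chi2 = max(0.0, 2.0 * (ll_sat - ll_model))
        p_star = k * (k + 3) // 2
        q = (ke + ke * (ke + 1) // 2        # exogenous means + covariance
             + 2 + 2 * ke + 3)              # intercepts, paths, residual (co)variances
        df_model = p_star - q

        mu_b = np.array([np.nanmean(raw[:, j]) for j in range(k)])
        var_b = np.array([np.nanvar(raw[:, j]) for j in range(k)])
        ll_base = _mvn_loglik(raw, mu_b, np.diag(var_b), groups)
        chi2_base = max(0.0, 2.0 * (ll_sat - ll_base))
        df_base = k * (k + 1) // 2 - k

        fitstats = _fit_indices(chi2, df_model, chi2_base, df_base, n,
                                sigma, sigma_implied)
        return CLPMResult(
            beta_ar_x=float(B_std[0, 0]), beta_ar_y=float(B_std[1, 1]),
            beta_cl_xy=float(B_std[1, 0]), beta_cl_yx=float(B_std[0, 1]),
            se=se_map, pvalues=p_map, fit=fitstats, n=n_all,
            n_effective=n_eff, estimator=est, loglik=ll_sat,
            covariate_betas=cov_betas)


def fit_clpm(data: pd.DataFrame, spec: CLPMSpec | None = None, **kwargs) -> CLPMResult:
    return CLPM(data, spec, **kwargs).fit()


def fit_group_clpms(data: pd.DataFrame, baseline_count, breakpoint: float = 5,
                    spec: CLPMSpec | None = None, min_group: int = 50,
                    **kwargs) -> dict[str, CLPMResult]:
    """Separate CLPMs for the <=breakpoint and >breakpoint baseline groups.

    Group membership is fixed by the baseline friend count; both groups use
    the same model.
    """
    cnt = np.asarray(baseline_count, dtype=float)
    if len(cnt) != len(data):
        raise ValueError("baseline_count length does not match table")
    out = {}
    for name, mask in (("low", cnt <= breakpoint), ("high", cnt > breakpoint)):
        if mask.sum() < min_group:
            raise ValueError(f"{name} group has fewer than {min_group} rows")
        out[name] = CLPM(data.loc[mask], spec, **kwargs).fit()
    return out
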