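"""Synthetic cohorts with known ground truth.

Every downstream stage (quadratic testing, two-lines breakpoints, region-wise
brain maps, molecular-map correlation, cross-lagged panels, mediation) is
exercised against data from this module, because the cohorts the real
analyses run on are access-restricted.  The generator emulates the observed
regimes: a right-skewed friend-count distribution, outcomes with a small
inverted-U (or U) relation to log10(count+1) peaking near 5 friends,
covariate confounding, a "social brain" subset of cortical regions whose
area rises with friend count only below the breakpoint, molecular maps with
a controllable expected rank correlation to an effect map, two-wave panels
with known autoregressive/cross-lagged paths and MCAR missingness, and a
mediation triplet with known proportion mediated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .assoc import log_transform


def atlas_labels(n_regions: int = 360) -> list[str]:
    """HCP-MMP-style bilateral labels: L_001..L_k, R_001..R_k."""
    per_hemi = n_regions // 2
    labels = [f"L_{i:03d}" for i in range(1, per_hemi + 1)]
    labels += [f"R_{i:03d}" for i in range(1, n_regions - per_hemi + 1)]
    return labels


def _default_social_regions() -> tuple[str, ...]:
    # 10 bilateral pairs standing in for OFC/ACC/insula/temporal/TPJ areas
    return tuple(f"{h}_{i:03d}" for h in ("L", "R") for i in range(11, 21))


@dataclass
class SynthConfig:
    """Generator settings; defaults are the study regime being emulated.

    ``peak_effect`` is the outcome elevation (in outcome-SD units) at the
    breakpoint relative to zero friends; when None it is calibrated so the
    realized quadratic adjusted-R^2 increment is ``target_dr2`` (default
    0.4%, the scale of the strongest behavioral effects).
    """

    n_subjects: int = 7512
    count_mean: float = 6.0
    count_dispersion: float = 1.0
    zero_truncated: bool = True
    true_breakpoint: float = 5.0
    peak_effect: float | None = None
    target_dr2: float = 0.004
    post_shape: str = "decline"           # "decline" or "plateau" past the peak
    decline_rate: float = 1.0             # |slope_high| / slope_low when declining
    noise_sd: float = 1.0
    covariate_specs: tuple = (("sex", "binary", 0.2),
                              ("age", "normal", 0.15),
                              ("income", "normal", 0.10))
    n_regions: int = 360
    social_region_ids: tuple = field(default_factory=_default_social_regions)
    region_peak_effect: float = 0.5       # area elevation at breakpoint, noise-SD units
    region_slope: float | None = None     # mm^2 per log10 unit; overrides the above
    region_noise_sd: float = 50.0         # mm^2
    region_baseline: float = 500.0        # mm^2
    target_rho: float = 0.45
    clpm_paths: tuple = (0.6, 0.6, 0.3, 0.1)   # (ar_x, ar_y, cl_xy, cl_yx)
    clpm_wave1_corr: float = 0.3
    missing_rate: float = 0.3
    med_paths: tuple = (0.3, 0.3, 0.09)   # (a, b, c_prime)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 50:
            raise ValueError("n_subjects must be >= 50")
        if self.true_breakpoint <= 0:
            raise ValueError("true_breakpoint must be positive")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if abs(self.target_rho) > 1:
            raise ValueError("target_rho must lie in [-1, 1]")
        if any(abs(p) >= 1 for p in self.clpm_paths):
            raise ValueError("standardized CLPM paths must have |coef| < 1")
        if any(abs(p) >= 1 for p in self.med_paths):
            raise ValueError("standardized mediation paths must have |coef| < 1")
        if self.count_mean <= 0 or self.count_dispersion <= 0:
            raise ValueError("count distribution parameters must be positive")
        if self.post_shape not in ("decline", "plateau"):
            raise ValueError("post_shape must be 'decline' or 'plateau'")


@dataclass(eq=False)
class SynthTruth:
    """Ground truth recorded exactly as the generator used it."""

    true_breakpoint: float = np.nan
    true_segment_slopes: tuple = (np.nan, np.nan)   # per log10(count+1) unit
    true_peak_effect: float = np.nan
    true_region_effects: dict = field(default_factory=dict)
    true_rho: float = np.nan
    true_clpm_paths: tuple = ()
    true_prop_mediated: float = np.nan

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["true_segment_slopes"] = list(self.true_segment_slopes)
        payload["true_clpm_paths"] = list(self.true_clpm_paths)
        payload["true_region_effects"] = {k: float(v)
                                          for k, v in self.true_region_effects.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    def __eq__(self, other):
        if not isinstance(other, SynthTruth):
            return NotImplemented

        def same(a, b):
            if isinstance(a, float) and isinstance(b, float):
                return a == b or (np.isnan(a) and np.isnan(b))
            if isinstance(a, (tuple, list)) and isinstance(b, (tuple, list)):
                return len(a) == len(b) and all(same(x, y) for x, y in zip(a, b))
            return a == b

        return all(same(getattr(self, f), getattr(other, f))
                   for f in self.__dataclass_fields__)

    @classmethod
    def from_yaml(cls, path) -> "SynthTruth":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["true_segment_slopes"] = tuple(payload["true_segment_slopes"])
        payload["true_clpm_paths"] = tuple(payload["true_clpm_paths"])
        return cls(**payload)


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def draw_counts(config: SynthConfig, rng: np.random.Generator,
                n: int | None = None) -> np.ndarray:
    """Right-skewed friend counts: (zero-truncated) negative binomial.

    Gamma-Poisson mixture with mean ``count_mean`` and dispersion
    ``count_dispersion`` (variance = mean + mean^2/dispersion); zeros are
    redrawn when ``zero_truncated``.
    """
    n = config.n_subjects if n is None else n
    r = config.count_dispersion
    p = r / (r + config.count_mean)
    counts = rng.negative_binomial(r, p, size=n)
    if config.zero_truncated:
        while True:
            zero = counts == 0
            if not zero.any():
                break
            counts[zero] = rng.negative_binomial(r, p, size=int(zero.sum()))
    return counts.astype(int)


def _dose_curve(z: np.ndarray, config: SynthConfig, peak_effect: float) -> np.ndarray:
    """Piecewise-linear dose-response in z = log10(count+1), peaking at the
    log-transformed breakpoint and then flat or declining."""
    zb = log_transform(config.true_breakpoint)
    slope_low = peak_effect / zb
    slope_high = (-config.decline_rate * slope_low
                  if config.post_shape == "decline" else 0.0)
    return slope_low * np.minimum(z, zb) + slope_high * np.maximum(z - zb, 0.0)


def _segment_slopes(config: SynthConfig, peak_effect: float) -> tuple[float, float]:
    zb = log_transform(config.true_breakpoint)
    slope_low = peak_effect / zb
    slope_high = (-config.decline_rate * slope_low
                  if config.post_shape == "decline" else 0.0)
    return (slope_low, slope_high)


def calibrate_peak_effect(config: SynthConfig, target_dr2: float | None = None,
                          n_pilot: int = 200_000) -> float:
    """Peak effect (outcome-SD units) whose population quadratic-term
    R^2 increment equals ``target_dr2``.

    Projects the unit-peak dose curve onto {1, z} and {1, z, z^2} under a
    large fixed draw of the count distribution and solves the resulting
    scalar equation; deterministic given the config's distribution settings.
    """
    target = config.target_dr2 if target_dr2 is None else target_dr2
    rng = np.random.default_rng(20_240_501)  # internal, fixed: calibration only
    counts = draw_counts(config, rng, n=n_pilot)
    z = log_transform(counts)
    g = _dose_curve(z, config, peak_effect=1.0)
    zc = z - z.mean()
    X1 = np.column_stack([np.ones_like(zc), zc])
    X2 = np.column_stack([np.ones_like(zc), zc, zc**2])
    fit1 = X1 @ np.linalg.lstsq(X1, g, rcond=None)[0]
    fit2 = X2 @ np.linalg.lstsq(X2, g, rcond=None)[0]
    delta = fit2.var() - fit1.var()            # extra variance per unit peak^2
    v_g = g.var()
    v_other = sum(e**2 for _, _, e in config.covariate_specs) + config.noise_sd**2
    denom = delta - target * v_g
    if denom <= 0:
        raise ValueError("target_dr2 unattainable for this dose-curve shape")
    return float(np.sqrt(target * v_other / denom))


def _covariates(config: SynthConfig, rng: np.random.Generator,
                n: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw covariates and their summed standardized effect on outcomes."""
    cols, effect = {}, np.zeros(n)
    for name, dist, eff in config.covariate_specs:
        if dist == "binary":
            v = rng.integers(0, 2, size=n).astype(float)
            std = (v - 0.5) / 0.5
        elif dist == "normal":
            v = rng.standard_normal(n)
            std = v
        else:
            raise ValueError(f"unknown covariate distribution {dist!r}")
        cols[name] = v
        effect += eff * std
    return pd.DataFrame(cols), effect


def resolved_peak_effect(config: SynthConfig) -> float:
    return (config.peak_effect if config.peak_effect is not None
            else calibrate_peak_effect(config))


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Cohort table: counts, log counts, covariates and one outcome.

    The outcome is covariate effects + a piecewise-linear function of
    log10(count+1) rising to ``peak_effect`` at the breakpoint (then flat or
    declining) + Gaussian noise.
    """
    rng = _rng(config, 1)
    n = config.n_subjects
    counts = draw_counts(config, rng)
    z = log_transform(counts)
    cov, cov_effect = _covariates(config, rng, n)
    peak = resolved_peak_effect(config)
    signal = _dose_curve(z, config, peak)
    outcome = cov_effect + signal + config.noise_sd * rng.standard_normal(n)
    table = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)],
                          "count": counts, "count_log": z})
    table = pd.concat([table, cov], axis=1)
    table["outcome"] = outcome
    truth = SynthTruth(true_breakpoint=config.true_breakpoint,
                       true_segment_slopes=_segment_slopes(config, peak),
                       true_peak_effect=peak)
    return table, truth


def generate_brain(cohort: pd.DataFrame, config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Region table (subjects x regions, mm^2 area) over the atlas.

    Social regions follow baseline + slope * min(log-count, log-breakpoint)
    + covariate effects + noise (rise-then-plateau); all other regions are
    covariates + noise only.
    """
    labels = atlas_labels(config.n_regions)
    unknown = set(config.social_region_ids) - set(labels)
    if unknown:
        raise ValueError(f"social_region_ids not in atlas: {sorted(unknown)}")
    rng = _rng(config, 2)
    n = len(cohort)
    z = cohort["count_log"].to_numpy()
    zb = log_transform(config.true_breakpoint)
    # shared anatomy covariate effect: sex-like column if present
    cov_effect = np.zeros(n)
    if "sex" in cohort:
        cov_effect = 0.3 * config.region_noise_sd * (cohort["sex"].to_numpy() - 0.5) * 2
    baselines = config.region_baseline * rng.lognormal(0.0, 0.3, size=config.n_regions)
    noise = config.region_noise_sd * rng.standard_normal((n, config.n_regions))
    area = baselines[None, :] + cov_effect[:, None] + noise
    effects = {lab: 0.0 for lab in labels}
    social_idx = [labels.index(lab) for lab in config.social_region_ids]
    rise = np.minimum(z, zb)
    base_slope = (config.region_slope if config.region_slope is not None
                  else config.region_peak_effect * config.region_noise_sd / zb)
    for j in social_idx:
        slope = base_slope * rng.uniform(0.8, 1.2)
        area[:, j] += slope * rise
        effects[labels[j]] = slope
    table = pd.DataFrame(area, columns=labels)
    table.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    truth = SynthTruth(true_breakpoint=config.true_breakpoint,
                       true_region_effects=effects)
    return table, truth


def generate_molecular_map(true_region_effects, target_rho: float,
                           seed: int) -> pd.Series:
    """Region density vector with expected Spearman ``target_rho`` against
    the supplied effect vector, linearly rescaled to [0, 100].

    Uses a Gaussian-copula construction on normal scores of the effect
    ranks with latent Pearson ``2 sin(pi * rho / 6)`` so the expected rank
    correlation equals the request for continuous effect vectors.
    """
    if abs(target_rho) > 1:
        raise ValueError("target_rho must lie in [-1, 1]")
    eff = pd.Series(true_region_effects, dtype=float)
    if eff.nunique() <= 1:
        raise ValueError("effect vector is constant; rank correlation undefined")
    rng = np.random.default_rng(seed)
    ranks = eff.rank(method="average").to_numpy()
    nscores = (ranks - ranks.mean()) / ranks.std()
    latent = 2.0 * np.sin(np.pi * target_rho / 6.0)
    vals = latent * nscores + np.sqrt(max(0.0, 1.0 - latent**2)) * rng.standard_normal(len(eff))
    lo, hi = vals.min(), vals.max()
    scaled = 100.0 * (vals - lo) / (hi - lo)
    return pd.Series(scaled, index=eff.index, name="density")


def generate_longitudinal(config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Two-wave panel with known standardized AR/cross-lagged paths.

    Wave-1 (x1, y1) are standard normal with correlation
    ``clpm_wave1_corr``; wave-2 variables are the stated paths plus small
    covariate effects, with residual variances chosen so each wave-2
    variable has unit variance.  MCAR missingness is applied to wave-2
    entries so a fraction ``missing_rate`` of rows has at least one missing
    wave-2 value.
    """
    ar_x, ar_y, cl_xy, cl_yx = config.clpm_paths
    rho = config.clpm_wave1_corr
    rng = _rng(config, 3)
    n = config.n_subjects
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x1 = z1
    y1 = rho * z1 + np.sqrt(1 - rho**2) * z2
    cov = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float),
                        "age": rng.standard_normal(n)})
    gamma = 0.1
    cov_std = np.column_stack([(cov["sex"] - 0.5) * 2, cov["age"]])
    cov_part = gamma * cov_std.sum(axis=1)
    v_cov = 2 * gamma**2

    def _wave2(ar, cl, own, other):
        v_struct = ar**2 + cl**2 + 2 * ar * cl * rho + v_cov
        if v_struct >= 1:
            raise ValueError("implied wave-2 variance exceeds 1; covariance not PD")
        resid = np.sqrt(1 - v_struct)
        return ar * own + cl * other + cov_part + resid * rng.standard_normal(n)

    x2 = _wave2(ar_x, cl_yx, x1, y1)
    y2 = _wave2(ar_y, cl_xy, y1, x1)
    if config.missing_rate > 0:
        r_each = 1.0 - np.sqrt(1.0 - config.missing_rate)
        x2 = np.where(rng.random(n) < r_each, np.nan, x2)
        y2 = np.where(rng.random(n) < r_each, np.nan, y2)
    table = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)],
                          "x1": x1, "y1": y1, "x2": x2, "y2": y2})
    table = pd.concat([table, cov], axis=1)
    truth = SynthTruth(true_clpm_paths=(ar_x, ar_y, cl_xy, cl_yx))
    return table, truth


def generate_mediation(config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Standardized mediation triplet m = a x + e1, y = c' x + b m + e2.

    True proportion mediated is a*b / (a*b + c').
    """
    a, b, c_prime = config.med_paths
    rng = _rng(config, 4)
    n = config.n_subjects
    x = rng.standard_normal(n)
    v_m = 1 - a**2
    m = a * x + np.sqrt(v_m) * rng.standard_normal(n)
    v_y = 1 - (c_prime**2 + b**2 + 2 * a * b * c_prime)
    if v_m <= 0 or v_y <= 0:
        raise ValueError("mediation paths imply non-positive residual variance")
    y = c_prime * x + b * m + np.sqrt(v_y) * rng.standard_normal(n)
    table = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)],
                          "x": x, "m": m, "y": y})
    total = a * b + c_prime
    truth = SynthTruth(true_prop_mediated=(a * b / total) if total != 0 else np.nan)
    return table, truth
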