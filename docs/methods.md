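# Methods

This note documents the models implemented in `ucurve`, the choices made
where the design was genuinely open, what the synthetic-data generator
does and does not emulate, and the problem sizes used by the test suite.

## Dose variable and quadratic screen

Friend counts are transformed as `x = log10(count + 1)` (counts are
right-skewed, and the +1 keeps zero counts defined) and mean-centered
before squaring.  For each outcome the quadratic model

    y = b·x² + a·x + c + γ'z + ε

is fit by OLS alongside the nested linear and covariates-only models.
Reported quantities:

- **Joint F** — the partial F comparing the quadratic model to the
  covariates-only model (2 numerator df).  Implemented as a Wald test on
  the `(a, b)` block; this is algebraically identical to the RSS-based
  nested-model F, and the test suite asserts the identity to 1e-8 relative
  tolerance against an independent least-squares oracle.
- **ΔR² (adjusted)** — `dR2_quad` is adjusted-R²(quadratic) −
  adjusted-R²(linear); `dR2_lin` is adjusted-R²(linear) −
  adjusted-R²(covariates-only).
- **ANOVA comparison** — `F = ((RSS_lin − RSS_quad)/1)/(RSS_quad/df)`,
  which equals `t_b²` for the single added regressor.

A caveat worth recording: mean-centering makes the linear and quadratic
terms exactly orthogonal only when the predictor distribution is
symmetric.  For the skewed log-count it merely reduces their correlation;
the implementation centers as specified and does not residual-orthogonalize.

Categorical covariates are dummy-encoded against a first-level reference.
Rank-deficient designs raise an error naming the collinear columns.

Multiplicity: Bonferroni for behavioral outcome families (the family size
`m` is settable independently of the p-value vector length, since outcome-
level F tests and term-level t tests form different families), and
Benjamini–Hochberg step-up FDR for region-wise maps (swappable method
flag).  The BH significant set is tested against exhaustive step-up
enumeration, including a hypothesis-driven property test.

Binned summaries default to integer bins 0..10 plus a pooled 11+ tail
(12 bins), with per-bin median count, mean, and SE = sd/√n; empty bins are
reported with n = 0 and flagged, never dropped.

## Two-lines breakpoint test

The quadratic term has a well-known false-positive problem for monotone
non-parabolic trends, so U-shape claims rest on the two-lines procedure:

1. **Candidate extremum** from the covariate-adjusted quadratic fit,
   clipped to the observed range.  If the curvature is negligible or the
   extremum falls outside the data, there is no interior candidate: the
   model reports a global linear fit with verdict `monotone`/`flat` and a
   diagnostic.
2. **Flat region**: the set of observed predictor values whose fitted
   quadratic value lies within one pointwise SE of the extremum value
   (contiguous run containing the extremum).
3. **Reallocation (one pass)**: a preliminary interrupted regression at
   the extremum yields segment z statistics; the final cutoff is placed at
   the fraction `|z_high| / (|z_low| + |z_high|)` across the flat region,
   so the weaker segment receives the larger share of the ambiguous
   boundary observations.
4. **Final interrupted regression** `y = β0 + δ·1[x > c] + β1·x_low +
   β2·x_high + γ'z`, where `x_low = min(x − c, 0)`, `x_high = max(x − c, 0)`.
   The level-jump term δ is essential: without it, a cutoff placed at a
   chance peak of the outcome converts the level difference into a
   spurious negative high-segment slope.  In our plateau-null simulations
   the false U-shape rate was 15–19% without the jump term and ~3% with
   it, at ~95% detection power under the study-scale inverted-U regime.
   With the jump term the segment slopes are within-segment estimates,
   equivalent (up to shared covariates) to fitting the two split halves
   separately.

Verdicts: `u_shape`/`inverted_u` require both slopes individually
significant (p < 0.05) with opposite signs; both-significant same-sign or
one-significant patterns give `monotone`; neither significant gives
`flat`; an interior candidate whose split leaves a segment below the
minimum size (default 10) gives `indeterminate` with a diagnostic.  Ties
at the cutoff go to the low segment, matching the ≤5 / >5 grouping used
downstream.  Breakpoints are equivariant under affine transforms of the
predictor and are reported on both the log and raw-count scales.

## Region-wise brain maps

All regions of the subjects × regions table share one design, so the maps
are computed by multi-response least squares (QR once per design); the
per-region joint F, term t statistics and adjusted-ΔR² agree with the
single-outcome engine by construction.  Two-stage FDR follows the map
logic: stage 1 is BH across all testable regions on the joint-F p-values;
stage 2 applies BH to the term p-values only within stage-1 survivors.
Constant region columns are flagged and excluded from the FDR family.
Group-split linear t-maps (counts ≤ vs. > breakpoint) use the
Frisch–Waugh partial-correlation route, which is exact and fast enough to
re-estimate the full model inside every permutation.  Neuroimaging runs
add handedness-, head-motion- and scanner-like covariates to the
behavioral set via the config.

## Molecular-map correlation

Spearman rank correlation (average-rank ties) over the regions shared by
the t-map and the molecular map after exclusions: PET-derived maps are
validated to the 0–100 rescaled range, the μ-opioid receptor map excludes
the occipital reference-region list (supplied as config, not hard-coded),
and expression maps can be restricted to the left hemisphere (177 regions).
Robustness: bootstrap over region pairs (default 10,000; median and
5th–95th percentiles).  Significance: label-shuffling permutation null —
each shuffle permutes the friend-count column across subjects (outcomes
and covariates stay attached), recomputes group membership, re-estimates
the full region-wise model through the identical code path as the observed
map, and re-correlates; `p = (1 + #{|ρ_null| ≥ |ρ_obs|})/(n_perm + 1)`,
two-sided by absolute value (sidedness was a free choice; documented
here).  A spin-type spatial-autocorrelation-preserving null is an
extension point, not implemented.  Bonferroni across the 14-map panel
multiplies by the panel size and caps at 1.

The synthetic molecular-map generator uses a Gaussian copula on normal
scores of the effect ranks with latent Pearson `2·sin(π·ρ/6)`, so the
expected Spearman correlation equals the requested target for continuous
effect vectors; outputs are rescaled to [0, 100].

## Cross-lagged panel model

Classic two-wave observed-variable CLPM on `|count − breakpoint|` (raw
counts; breakpoint default 5) and an outcome: two autoregressive and two
cross-lagged paths, freely correlated wave-1 variables and covariates,
covariate effects on both wave-2 variables, and a wave-2 residual
covariance.  Stationarity is not constrained (two waves cannot identify
it).  Covariates point at wave-2 only; time-varying covariates enter at
their own wave.

Because both wave-2 variables are regressed on the full exogenous block,
the model is covariance-saturated; the FIML estimates are therefore the
path functions of the full-information mean/covariance, which is computed
by an EM algorithm over missingness patterns (the casewise likelihood over
observed entries).  Consequences checked by tests: estimates are invariant
to row/pattern order, and with no missing data FIML coincides with
listwise estimates exactly.  Path standardization uses the FIML standard
deviations; per-path SEs use the per-equation residual variance and the
exogenous correlation inverse with the per-equation observed count (an
MCAR-appropriate approximation).  Fit indices use the standard ML
chi-square formulas against the saturated and independence baselines
(formulas in the code docstring); for a saturated structure chi² ≈ 0 and
CFI = TLI = 1, RMSEA = 0 by convention.  Non-positive-definite implied or
exogenous covariances raise; EM non-convergence raises with the last
likelihood change.

## Mediation

Standardized variables; paths from three OLS fits (`a`: m ~ x + z;
`b`, `c'`: y ~ x + m + z; `c`: y ~ x + z); indirect = a·b (which equals
c − c' identically for nested OLS), proportion mediated = a·b/c, reported
with its own interval.  Inference: subject-level (row) resampling —
standard for observational mediation — with BCa intervals: bias-correction
z0 from the bootstrap position of the point estimate, acceleration from
jackknife skewness via the exact leave-one-out OLS update.  The bootstrap
is vectorised through per-resample Gram matrices.  The indirect-effect
p-value is the +1-corrected doubled tail fraction of resamples crossing
zero; region-wise runs BH-correct these p-values across regions, with a
pooled run using the summed area of the selected regions (the pooled run
is its own family — region-wise FDR covers regions only).  A total effect
smaller than twice its bootstrap SE flags the proportion mediated as
unstable rather than suppressing it.

## Synthetic-data generator

Defaults are the study regime: n = 7512 subjects; zero-truncated negative
binomial counts (mean 6, dispersion 1 — right-skewed with a long tail;
the real count distribution is published only as means/SDs, so this is a
stand-in, not a calibration); outcome = covariate effects (binary sex-like
0.2 SD, continuous age-/income-like 0.15/0.10 SD) + a piecewise-linear
function of log10(count+1) peaking at the breakpoint (5 friends) and then
declining (behavioral regime) or plateauing (brain regime) + unit Gaussian
noise.  The peak height defaults to the value whose population quadratic
ΔR² equals 0.4% — the scale of the strongest behavioral effects — solved
from a deterministic projection of the unit dose curve onto the quadratic
span under a large fixed count draw.  The piecewise (tent) shape rather
than a literal parabola keeps breakpoint recovery well-defined.

Brain tables: 360 atlas-labelled regions, log-normal baselines around
500 mm², 50 mm² noise; 20 social regions (10 bilateral pairs) rise with
log-count up to the breakpoint at heterogeneous slopes (peak ≈ 0.5 noise
SD) and plateau; all other regions are covariates + noise only.
Longitudinal: standardized wave-1 pair (correlation 0.3), wave-2 from the
stated standardized AR/cross-lagged paths plus small covariate effects,
residual variances solved for unit wave-2 variance (non-PD requests
raise); MCAR missingness masks each wave-2 entry independently at a rate
chosen so the requested fraction of rows has at least one missing entry.
Mediation: standardized linear-Gaussian triplet with recorded
`prop = a·b/(a·b + c')`.

What the generator does **not** emulate: family/sibling clustering, site
effects and scanner batch structure, non-Gaussian outcome tails (CBCL raw
scores are themselves skewed counts), measurement error in the friend
count, MAR/MNAR missingness (an MAR hook exists but the default is MCAR),
and spatial autocorrelation between atlas regions.  Passing tests
therefore certify the statistical machinery — estimator correctness,
calibration, error control — under clean conditions, not robustness to
those real-data complications.

## Problem sizes and numerical choices

The acceptance-grade tests run at: 50 datasets (n = 2000) for the oracle
equivalences; 500 plateau-null replicates (n = 2000) and 200 inverted-U
replicates (n = 7512) for two-lines calibration; 2000 null replicates
(n = 150) for quadratic-p uniformity and 200 permutation runs (n = 400,
60 regions, 200 shuffles each) for permutation-p uniformity; 100 seeds
for spatial-correlation recovery (360 regions, 1000 bootstraps each);
100 seeds of CLPM recovery (n = 5000, 30% MCAR); 500 mediation coverage
replicates (n = 500, 2000 bootstraps each); 100 seeds of FDR control
(20 true regions among 360, n = 2000); and exhaustive degree enumeration
over all labeled digraphs with ≤ 4 nodes.  These sizes are the package's
own choices, large enough that the pass bands (e.g. false-U rate ≤ 0.08,
coverage in [0.92, 0.98], mean FDP ≤ 0.08) are well-resolved.

Numerical details: EM convergence at 1e-10 relative log-likelihood change
(max 1000 iterations); permutation p-values use the +1 correction and are
never 0; bootstrap BCa guards z0 against 0/1 tail proportions; Spearman
resamples that are degenerate (all-tied) are dropped from the bootstrap
summary; region q-values for constant regions are NaN, and the FDR family
size excludes them.
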