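# Methods

## Model and estimands

The package works with study-level summary data: K independent studies,
each reporting an effect estimate β̂_j with standard error σ_j on an
additive scale (mean difference, log odds ratio or log risk ratio; ratio
measures are log-transformed on ingest and only exponentiated for
reporting). The working model for a study's estimate is

    β̂_j = β + b_j + σ_j ε_j,

where β is the common true effect, b_j a fixed per-study bias, and ε_j
standard normal, possibly truncated to (l_j, u_j). The estimators assume
effect homogeneity: any systematic spread between studies is treated as
bias, not as a random effect. Small-study effects correspond to b_j or
the truncation limits depending on the study size n_j.

### Pooled estimators

* **Weighted mean** (fixed effect): β̂_FE = Σβ̂_jσ_j⁻²/Σσ_j⁻², analytic
  SE (Σσ_j⁻²)^(−1/2), Wald CI. Efficient, but biased if any single b_j ≠ 0.
* **Weighted median**: sort the β̂_j; with standardized weights w_j and
  cumulative sums s_j, study j sits at percentile q_j = s_j − w_j/2 (as a
  fraction). The estimate interpolates linearly between the studies
  bracketing q = 0.5; a study exactly at 0.5 (tolerance 1e−12) is
  returned as-is. Because q₁ = w₁/2 ≤ ½ ≤ 1 − w_K/2 = q_K always, the
  defensive boundary branches (return the extreme study) can only
  trigger in degenerate one-study cases. Exact ties in β̂_j are ordered
  by ascending weight — a deterministic tie-break chosen so the
  estimator is invariant to permuting the input rows (a plain stable
  sort is not, when tied estimates carry unequal weights).
* **Mode-based estimate (MBE)**: the maximizer of the weighted normal
  kernel density with bandwidth h = 0.9·min(sd, 1.4826·mad)·K^(−1/5)
  (mad = median absolute deviation from the median). The K^(−1/5) rate
  is the standard Silverman exponent with the number of studies as the
  sample size. When mad = 0 (a majority of identical estimates) the sd
  is used alone; all-identical input short-circuits to the common value.
  The consistency factor is fixed at 1.4826 rather than the exact
  1/Φ⁻¹(3/4). A `bandwidth_multiplier` (default 1) is exposed for
  sensitivity analysis.

### Maximization of the kernel density

The headline MBE evaluates f on a uniform grid of 10,000 points over
[min β̂ − 3h, max β̂ + 3h], then refines the best cell by golden-section
search to an interval of 1e−8; grid ties break toward the smaller x.
A dedicated test checks agreement with a 10⁶-point grid argmax.

### Bootstrap inference

SEs for the median and MBE come from a parametric bootstrap: R resamples
(default 10,000) with β̂_j^r ~ N(β̂_j, σ_j²); the replicate estimates are
summarised by the normal-consistent MAD (1.4826 × MAD), and the CI is
the normal approximation around the original-data point estimate (not a
percentile interval). The bandwidth is recomputed on every resample, so
each resample is a full application of the estimator. Inside the
bootstrap the MBE uses a 1024-point grid with vectorised golden-section
refinement: the coarser grid changes individual replicate modes by far
less than the Monte-Carlo error of the MAD summary while making the
bootstrap an order of magnitude faster. Resampling leaves the σ_j — and
hence the weights — unchanged, which the vectorised paths exploit.
Identical seeds give bit-identical results. With K = 1 every estimator
returns the single study's estimate with its σ as SE.

## Diagnostics and comparators

* **Heterogeneity**: Q = Σσ_j⁻²(β̂_j − β̂_FE)²,
  I² = max(0, (Q − (K−1))/Q)·100, and the DerSimonian–Laird
  τ² = max(0, (Q − (K−1))/(Σw − Σw²/Σw)). DL is used for every
  random-effects weighting in the package.
* **Egger test**: weighted least squares of β̂_j on (1, σ_j) with weights
  σ_j⁻²; γ is the slope, tested two-sided against t with K−2 df. The
  default SE includes the multiplicative dispersion φ = weighted
  RSS/(K−2) (the classical test); `dispersion=False` gives the
  fixed-effect variant (φ = 1), which coincides exactly with the slope
  test of the extrapolation model at φ := 1. The regression needs K ≥ 3
  and at least two distinct σ_j.
* **Regression-based extrapolation**: the same WLS fit read at σ = 0:
  the pooled effect is the intercept with SE scaled by √φ and a t_{K−2}
  CI (honest for small K). φ is deliberately *not* floored at 1 —
  publication selection truncates the error distribution and genuinely
  under-disperses the estimates — but `truncate_phi=True` restores the
  conventional floor.
* **Trim-and-fill** (Duval–Tweedie, L0, random-random effects): iterate
  {DL-pool the trimmed set → centre all K studies → rank |deviations|
  (average-rank ties) → L0 = (4S − K(K+1))/(2K−1) with S the rank sum of
  the excess side's positive deviations → k0 = max(0, ⌊L0 + 0.5⌋)} until
  k0 stabilises (50-iteration cap, k0 capped at K−2 so pooling stays
  defined), then mirror the k0 extreme studies about the final mean
  (copying their σ) and DL-pool the augmented set. `side` names where
  the *missing* studies are imputed; `auto` takes the side opposite the
  Egger slope's sign, falling back to the mean-median skew when all σ_j
  are equal and the slope is undefined. Trim-and-fill is known to be
  implementation-sensitive (rounding of L0, choice of side, weighting
  scheme), so small differences from other software are expected.

## Simulation framework

The generator mimics meta-analyses of a continuous outcome with a
balanced binary intervention: n_j ~ Uniform(n1, n2) participants (drawn
continuously, rounded to integers) give σ_j = √(4/n_j); defaults
n1 = 100, n2 = 5000. True effect β defaults to 0 (0.02 in the power
scenario). Two bias mechanisms:

* **Type (a) — study quality**: each study is independently flagged with
  probability δ (Bernoulli flags keep replicates exchangeable; a
  `fixed_count` option flags exactly round(δK)); flagged studies receive
  b_j = b_max·max(0, (N − n_j)/(N − n1)) — b_max at the smallest size,
  linearly falling to zero at the threshold N.
* **Type (b) — publication selection**: studies below N are published
  only if their one-sided p-value (against H0: effect ≤ 0) is below a
  size-dependent ceiling p_j, implemented as a lower truncation limit
  l_j = z_{1−p_j} − β/σ_j on ε_j (u_j = +∞; selection is one-sided).
  The severity profile maps [n1, N] onto [p_min, 1] linearly, by square
  root, quadratically, or as a step; p_j = 1 for n_j ≥ N.

Truncated normals are drawn by inverse-CDF transformation of a uniform
on (Φ(l), Φ(u)), valid for arbitrarily extreme limits. Defaults where a
single value had to be fixed: δ = 1.0 with b_max = 0.5 and N = n2 for
the type (a) scenario, p_min = 0.05 and N = 4500 for type (b) — all
exposed in `SimulationConfig` so alternative severities (e.g.
N ∈ {1500, 3000, 4500, 6000}, δ ∈ {0.3, 0.6}) can be swept.

Seven standard scenarios: 1 no bias β=0; 2 type (a); 3–6 type (b) with
the linear/sqrt/quadratic/step profiles; 7 no bias β=0.02. The runner
spawns one RNG substream per replicate from a single SeedSequence, so a
(scenario, config, seed) triple is bit-reproducible and independent of
which estimators are requested; bootstrap seeds derive from the same
substream. Per-estimator summaries report mean estimate, bias, empirical
SD, mean model SE, coverage of β and rejection of 0, plus mean I² and
mean Egger γ across replicates.

### What the generator does and does not emulate

It reproduces size-dependent bias, selection-induced under-dispersion,
and the funnel-plot asymmetry these create. It does **not** include true
between-study heterogeneity (τ² > 0 in the data-generating process),
two-sided selection, correlated studies, or non-normal sampling error.
Passing tests therefore demonstrate robustness to the modelled
mechanisms, not to every way a real meta-analysis can be distorted.

## Verification strategy and problem sizes

The test suite checks hand-computed oracles (exact weighted-mean and
heterogeneity values, a manually executed trim-and-fill iteration,
closed-form truncated-normal moments), cross-checks heterogeneity
against `statsmodels.stats.meta_analysis.combine_effects`, and verifies
the median against an explicit weighted-CDF inversion and the MBE
against a dense-grid argmax. Property tests cover permutation
invariance, location/scale equivariance, range bounds and the
equal-weight reduction of the median to the sample median.

Statistical validity is checked at reduced but informative scales chosen
to keep a full run on one CPU comfortable: null-scenario coverage with
5000 replicates (analytic CI) and 500 bootstrap resamples; breakdown
sweeps at K = 1000 over contamination fractions 0.40–0.60 in steps of
0.01 (both robust estimators locate their threshold at 49%: with exactly
half the weight contaminated neither the median nor the mode identifies
the truth, so the last safe fraction on a 1% grid is 0.49); and the
scenario-2 bias ordering at 2000 replicates, K = 50. The acceptance
script (`scripts/acceptance.py`) re-runs these same experiments from a
single seed.

## Known limitations

* Bootstrap CIs for the median and MBE are conservative under the null
  (coverage above the nominal 95%), the price of the robust MAD summary.
* The MBE is sensitive to the bandwidth rule when study estimates form
  closely spaced clusters; the multiplier is exposed for that reason.
* Trim-and-fill coverage degrades with K even without bias, and its k0
  depends on rounding and side conventions.
* The regression-extrapolation CI can be very wide for small K; with
  K = 3 the fit is saturated up to one residual degree of freedom.
* None of the estimators "corrects" heterogeneity: under genuine effect
  heterogeneity uncorrelated with bias they estimate the weighted
  median/modal effect, not the mean effect.
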