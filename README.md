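# robustmeta

Robust pooled estimators for meta-analysis in the presence of
small-study effects and outlying studies.

## The problem

A fixed-effect meta-analysis pools K study-level effect estimates
β̂₁, …, β̂_K (mean differences, or log odds/risk ratios) with standard
errors σ_j by the inverse-variance weighted mean

    β̂_FE = Σ β̂_j σ_j⁻² / Σ σ_j⁻².

A single biased study biases this mean — it has a 0% breakdown level. In
practice, smaller studies often report systematically different effects
than larger ones ("small-study effects"), whether through study-quality
problems correlated with size or through selective publication of
significant results, and the weighted mean inherits that bias in full.

`robustmeta` implements two pooled estimators that are robust to such
mechanisms without modelling them explicitly:

* **Weighted median** — the 50th percentile of the inverse-variance
  weighted empirical distribution of the β̂_j, obtained by linear
  interpolation on the percentiles q_j = 100·(s_j − w_j/2), where
  w_j are standardized weights and s_j their cumulative sums. It is
  consistent as long as under 50% of the total weight comes from biased
  studies (a 50% breakdown level).
* **Mode-based estimate (MBE)** — the argmax of the weighted
  normal-kernel density f(x) = (h√2π)⁻¹ Σ_j w_j exp(−½((x−β̂_j)/h)²)
  with the outlier-resistant modified Silverman bandwidth
  h = 0.9·min(sd, 1.4826·mad)·K^(−1/5). Under the zero-modal-bias
  assumption (ZEMBA — the largest group of identically biased studies is
  the unbiased one) its breakdown level ranges from 50% up to 100%.

Standard errors for both come from a parametric bootstrap (resampling
β̂_j^r ~ N(β̂_j, σ_j²)) summarised by a MAD-based robust SD, with
normal-approximation confidence intervals.

For comparison the package also provides the classical diagnostics
(Cochran Q, I², DerSimonian–Laird τ², the Egger asymmetry coefficient γ)
and two established bias-adjusting estimators: regression-based
extrapolation to an infinitely large study (the intercept of the
weighted regression of β̂_j on σ_j under a multiplicative-dispersion
model) and Duval–Tweedie trim-and-fill (L0 estimator, random-effects at
both stages). A simulation framework generates study-level data under
configurable small-study-effect mechanisms — size-dependent fixed bias,
or publication selection via truncated-normal errors — to benchmark all
five estimators.

## Worked example

Simulate a meta-analysis of 15 studies with a true effect of **zero**
where 80% of studies carry a positive quality bias that shrinks with
study size, then pool it with all five estimators:

```python
import numpy as np
from robustmeta import MetaAnalysis, SimulationConfig, simulate_meta

cfg = SimulationConfig(K=15, beta=0.0, bias_type="type_a",
                       delta=0.8, b_max=0.6, N=5000)
data, truth = simulate_meta(cfg, np.random.default_rng(42))

res = MetaAnalysis.from_study_set(data).fit(seed=1, n_boot=10_000)
print(res.summary())
```

```
Meta-analysis of K = 15 studies (md)
----------------------------------------------------------------
estimator                     estimate                95% CI
weighted_mean                    0.135        (0.116; 0.153)
regression_extrapolation        -0.178       (-0.471; 0.115)
trim_and_fill                    0.175        (0.098; 0.252)
weighted_median                  0.087        (0.052; 0.123)
mbe                              0.062        (0.032; 0.091)
----------------------------------------------------------------
Q = 241.50   I^2 = 94.2%   tau^2 = 0.0213
Egger gamma = 8.98 (SE 3.77, p = 0.0333)
```

The true effect is 0. The weighted mean (0.135) absorbs the small-study
bias; trim-and-fill (0.175) overshoots it, and regression-based
extrapolation overcorrects to the other side (−0.178). The weighted
median (0.087) and especially the MBE (0.062) sit closest to the truth.
The diagnostics flag the problem: I² = 94% and a positive Egger slope
(γ = 8.98, p = 0.03) indicate funnel-plot asymmetry.

The same analysis is available from a shell for a CSV with columns
`study,estimate,se`:

```sh
robustmeta analyze --input studies.csv --measure md --seed 1 --out results.csv
robustmeta simulate --scenario 2 --k 10 --reps 1000 --seed 1 --outdir out/
robustmeta funnel --input studies.csv --out funnel.png
```

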