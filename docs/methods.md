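# Methods

## Study design being modelled

The package reimplements the analysis of a case-control school-scoliosis
screening comparison: 884 adolescents with radiographically confirmed
AIS (Cobb angle ≥ 10°) against 895 screened controls (Cobb < 10°),
N = 1779. Each subject carries gender, age, school category and nine
postural signs from visual inspection, Adam's forward-bending test and
scoliometer measurement of the angle of trunk rotation (ATR, abnormal
beyond 5°). Twelve covariates X₁…X₁₂ (everything except school category,
which is descriptive only) enter the prediction models.

## Synthetic cohort generator

Only marginal-by-status summaries of the original data are public, so
the generator samples each categorical variable from its published
per-level frequency conditional on AIS status, and age from a normal
with the published group mean and SD. Modelling choices:

- **Conditional independence given AIS status** is the baseline joint
  model — the weakest assumption consistent with the published
  marginals. Under it the implied true logistic model is the
  naive-Bayes posterior: the dummy coefficient of level *l* versus the
  reference is log(p₁ₗ/p₀ₗ) − log(p₁ᵣ/p₀ᵣ). An optional Gaussian-copula
  latent correlation matrix (symmetric, unit diagonal, PSD; one row per
  variable, age included) induces within-group dependence for
  stress-testing.
- **Age is truncated to [6, 19] years** (1st–12th graders). At the
  published parameters the truncation is almost inactive (< 0.1% of the
  mass), so group means/SDs are preserved to ~0.01.
- **Group sizes are exact**, not multinomial, and **one integer seed**
  drives the whole draw through `numpy.random.default_rng`; no global
  state is touched. The pipeline derives one child seed per stage from
  its config seed via `SeedSequence([seed, stage_index])`.

What passing tests on these cohorts do *not* show: the real signs are
correlated within subjects (a right thoracic curve produces several
signs at once). Conditional independence makes the combined twelve-sign
model somewhat *more* discriminative than reality — simulated test
accuracy runs in the high 80s versus the published low 80s, and
simulated specificity (~88.5% ± 2.2) sits above the published 82.6%.
Properties asserted on synthetic cohorts (coverage, scheme agreement,
operating-point bands) are therefore statements about the method under
a plausible data-generating process, not forecasts of field accuracy.

## Descriptive statistics

Pearson χ² with expected counts from the margins; the Yates continuity
correction ∑(|O−E|−0.5)²/E is applied exactly where the published table
flags it (lumbar kyphosis, a sparse 2×2), exposed as an explicit flag
rather than auto-triggering — reproducibility of the printed column
beats automatic small-sample rules here. A zero expected cell is an
error, not a silent zero. The age comparison defaults to Welch's
unequal-variance *t* (the pooled form is available); the sign convention
is control minus case, so the older case group yields a negative
statistic. The Welch statistic recomputed from the published summary
moments is −5.17; the published −4.63 is not recoverable from those
moments and is not targeted.

## Association models

Univariate odds ratios are closed-form 2×2 quantities with Wald
intervals (z fixed at 1.959964) and the Haldane–Anscombe +0.5 correction
(flagged on the estimate) when a cell is zero. The multivariate model
maximizes the Bernoulli likelihood by IRLS (≤ 100 iterations, tolerance
1e-8; statsmodels GLM is the workhorse). Two encodings are supported:
`dummy_expanded` (two indicators per three-level variable against the
"normal" reference — the form behind per-level AORs) and `single_score`
(0/1/2 per variable, raw years for age — the form of the published
equations). Numerical edge policy:

- a term constant in the sample (a level absent from a split) is
  inestimable: it is dropped from the fit, reported with coefficient 0
  and a warning — rank-deficiency errors are reserved for genuine
  collinearity;
- |coefficient| > 15 is treated as (quasi-)complete separation and
  reported via a warning and a flag on the model, keeping the last
  iterate, so replicate simulations with rare levels (flat back, lumbar
  kyphosis: expected abnormal counts ≈ 2–9) do not abort;
- fewer than 20 records per parameter warns.

Published multivariate AORs cannot be re-derived exactly (they require
the real joint data); the package's claim is parameter *recovery*:
refitting default synthetic cohorts recovers the generating log-odds
with pooled Wald-CI coverage ≈ 95% (measured 94.8% over 500
replicates). Coverage is evaluated on categorical coefficients whose
published cells are all ≥ 5 — Wald intervals are unreliable below that,
and age's generating effect is quadratic (unequal group SDs), so its
linear coefficient has no single true value.

## ROC analysis

For grouped categorical predictors the rank AUC is computed in closed
form from level counts (ties one-half), equivalent to enumerating all
case-control pairs; the default score coding collapses each sign to
binary (normal vs any abnormality), which reproduces five of the
published AUCs exactly at two decimals (shoulder-height 0.70, pelvic
tilt 0.59, thoracic ATR 0.66, thoracolumbar ATR 0.54, lumbar ATR 0.67);
ordinal 0/1/2 coding is available. Gender (0.64 vs printed 0.65),
lumbar concave (0.70 vs 0.71) and scapular tilt (0.775 vs printed 0.77)
differ in the last digit — plausibly computed on the original 70%
training split — and are not exact-checked. Age uses the binormal form
Φ(Δμ/√(σ₁²+σ₀²)). Intervals are Hanley–McNeil with
Q₁ = A/(2−A), Q₂ = 2A²/(1+A), clipped to [0,1]; a boundary AUC
degenerates to a point interval with a warning. The AUC = 0.5 test uses
the normal approximation z = (A−0.5)/SE.

## Coefficient weighting

The source analysis never defines its weighting transform, so the
package fixes one concrete, documented contract. For weights wⱼ > 0
covering all twelve variables:

    βⱼ → βⱼ · wⱼ / mean(w),

followed by re-calibration of the intercept (1-d root find) so the mean
predicted probability on the training data equals the observed case
fraction. Uniform weights are exactly a no-op and rescaling all raw
weights changes nothing.

Weight vectors per scheme: the AUC scheme uses each predictor's
training-split AUC (binormal for age). The AOR scheme uses each
variable's adjusted odds ratio from a dummy-encoded training fit (mean
of the two level-AORs for three-level variables), **mapped to its
AUC-equivalent** Φ(ln OR·√3/π/√2) — the standard log-odds →
common-language-effect-size conversion. Raw AORs span orders of
magnitude (age ≈ 1.1 vs trunk rotation ≈ 7.5) and multiplying
coefficients by weights on that scale distorts the fitted balance enough
to cost ~3 accuracy points, contradicting the documented near-
equivalence of the four models; on the bounded scale both ingredients
are commensurable (which the combined product scheme needs anyway) and
the near-equivalence emerges: across 200 simulated runs the four
schemes' total accuracies stay within 2 points of each other in ~98% of
runs, mean spread ≈ 0.8 points. A separation-flagged variable's AOR
weight falls back to its Haldane-corrected univariate OR; a fully
inestimable variable weights 1.

The four published equations are packaged as bit-stable fixtures
(`printed_equation`), tagged by scheme; their coefficients come from the
original (unavailable) training split and are inputs, never targets.
Classification defaults to threshold 0.5 with ties classifying positive.

## Evaluation protocol

Stratified-by-label 7:3 random split (per-stratum sizes round(f·n);
at N = 1779 this gives 1245/534), seed-reproducible; stratification is
the default because it stabilizes the prevalence-dependent PPV/NPV.
Metrics are exact ratios from the 2×2 prediction table, kept on the
proportion scale internally and formatted as percentages at 2 d.p.;
zero-denominator ratios are NaN, never 0. Published Table-3-style values
are not desk-reproducible (real data, unrecorded split seed); the
package asserts distributional properties instead: positive mean
training-optimism (~0.6 points, needing ~60 seeds to resolve), test
sensitivity in (75%, 90%) in ≥ 80% of runs, and the scheme-agreement
property above.

## Problem sizes and runtimes

Simulation-backed checks use: 500 replicates at n = 1779 for coverage,
200 seeded runs for scheme agreement, 60 for operating-point and
optimism properties, 30 for AUC-band checks — sizes at which each
Monte-Carlo assertion has a comfortable noise margin while the whole
suite stays interactive (≈ half a minute). The acceptance script scales
the same computations to 50–300 runs.

## Known limitations

- Conditional independence given status overstates multi-sign
  discrimination relative to correlated real signs (see above); the
  copula option exists precisely to probe this.
- Wald inference throughout (matching the published intervals); no
  profile-likelihood or exact small-sample intervals.
- No curve-progression modelling, no inter-rater measurement error, no
  genetic/hormonal covariates, no graphical ROC rendering — numeric
  reports only.
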