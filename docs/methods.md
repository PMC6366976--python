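# Methods notes

This note records the modeling assumptions, parameter defaults, and
numerical choices behind grimclock, and what the simulation-based tests do
and do not establish about behavior on real methylation data.

## The two-stage model

The clock is a composition of linear models. Stage 1 estimates each target
biomarker y (plasma protein level or smoking pack-years) as

  ŷ = b₀ + b_age·age + b_sex·sex + Σⱼ wⱼ·βⱼ

where βⱼ are CpG beta values and the wⱼ are sparse (elastic net). Stage 2
fits an elastic-net Cox proportional-hazards model of time-to-death on the
retained surrogates together with age and sex; its linear predictor X'β is
the log hazard ratio relative to baseline. The affine calibration

  estimate = slope·X'β + intercept,
  slope = sd(age)/sd(X'β), intercept = mean(age) − slope·mean(X'β)

is exact by construction: calibrated training outputs match the mean and
variance of training age to machine precision, and because slope > 0 the
calibration preserves the sample ranking of mortality risk. Age
acceleration is the OLS residual of the estimate on age; residualization is
performed within the dataset being analyzed by default (an
`apply_clock(..., reference=(slope, intercept))` option applies a stored
regression instead, for scoring new data against a training-set reference).
Sample statistics use the n−1 denominator throughout; the convention
matters less than its consistency between calibration and its tests.

## Stage-1 fitting choices

- **Elastic-net mixing** defaults to 0.5 (equal L1/L2 share) and is
  configurable; nothing in the two-stage design depends on the exact value.
- **Age and sex are unpenalized by default.** They are adjustment
  covariates, not candidate features. The partially-penalized problem is
  solved exactly by residualizing both the target and the (standardized)
  CpG matrix on [1, age, sex], fitting the elastic net on the residuals,
  and recovering the covariate weights by least squares given the fitted
  CpG block. `penalize_covariates=True` puts age and sex into the
  penalized design instead.
- **λ at the CV minimum** of the 10-fold mean squared prediction error,
  with folds assigned by seeded sample-level shuffling.
- **Internal standardization**: CpGs are standardized for fitting;
  coefficients are returned on the original beta scale, so models are
  scale-equivariant and serialized tables apply directly to beta values.
- **Path resolution**: 30 penalty values down to 1/20 of the critical
  (all-zero) penalty, coordinate-descent tolerance 1e-3. On the simulated
  design (600 training samples, 2,000 CpGs) this reproduces the selection
  and held-out correlation of a much finer path at a fraction of the cost;
  both knobs are exposed (`n_alphas`, `path_eps`, `tol`).
- **Selection** requires Pearson r strictly above 0.35 against the
  observed target in both the training and the test split. Zero-variance
  predictions are flagged as undefined correlations and never selected.
- The CpG *sets* chosen by the penalized fit are not stable across seeds
  or cohorts — near-equivalent estimators exist on different supports — so
  tests assert recovery of predictive performance and of which targets are
  estimable, never of particular CpG identities.
- An optional CpG whitelist restricts the feature universe (the analogue
  of intersecting array platforms for cross-platform portability).

## Stage-2 fitting choices

- All components (including age and sex) are penalized by default,
  mirroring a design in which the model "automatically selects" even the
  demographic covariates. `unpenalized=("Age", "Female")` force-includes
  them with zero penalty factor.
- **Penalty selection uses the one-standard-error rule** on the
  cross-validated held-out Breslow log partial likelihood: the largest
  penalty whose mean held-out likelihood is within one SE of the best.
  The CV-minimum rule is a poor fit for this stage: the held-out curve is
  nearly flat at small penalties, so the minimum lands at a penalty small
  enough to retain every noise component with a tiny coefficient. Even
  under the 1-SE rule, when a strong *penalized* age effect anchors the
  fit the chosen penalty must stay small enough to estimate it, and noise
  components can ride along; with age and sex force-included the penalty
  is free to stay large and pure-noise surrogates are dropped exactly.
  The null-recovery tests therefore exercise the force-include option. If
  the parsimonious choice zeroes *every* coefficient (no usable linear
  predictor), the fit falls back to the CV optimum.
- Tie handling is Breslow (the coordinate-descent Cox implementation's
  convention, and the likelihood the CV scorer evaluates).
- Constant component columns are dropped with a warning rather than an
  error; a fit with fewer than two observed events is refused.
- The single-stage comparator (`train_single_stage_clock`) runs the
  identical machinery with the raw CpG matrix plus age and sex as
  components, so two-stage vs single-stage comparisons differ only in the
  feature layer. The test harness asserts that both beat age alone on
  held-out concordance when mortality acts through the CpG layer — it
  deliberately does not assert a winner between them.
- Published clock weights are inputs, never bundled: any external clock is
  a coefficient table (`feature_id`, `weight`, with reserved rows
  `Intercept`, `Age`, `Female`) applied by `apply_coefficient_table`,
  which median-imputes missing CpGs on request (reference medians, or the
  in-matrix median for partially observed columns).

## Validation statistics

- `cox_association` delegates to a proportional-hazards fit with the Huber
  sandwich variance (cluster-aggregated when labels are supplied; with
  all-distinct labels it reduces to the unclustered sandwich). The
  underlying fitter uses Efron tie handling, which coincides with Breslow
  on tie-free data; the brute-force likelihood oracle in the tests uses
  distinct event times for that reason. Newton convergence is tightened to
  1e-9 so estimates match brute-force maximization to 1e-6.
- `fixed_effect_meta` pools on the log-hazard scale (inverse-variance
  weights); Q is tested against χ²(k−1), and I² = max(0, (Q−df)/Q) is
  reported as a labeled extra. The Q null is asymptotic: with robust SEs
  and strata of only a couple of hundred samples it is measurably
  anti-conservative, and its calibration test runs at 400 samples per
  stratum where the χ² approximation holds.
- `stouffer_meta` pools *signed* z-scores weighted by √n (direction-aware
  pooling; the alternative of pooling unsigned evidence is not offered).
- `mortality_deviance_residual` is the covariate-free excess-mortality
  score: martingale residuals event − H₀(t) with the Nelson–Aalen d/n
  estimator, transformed to deviance residuals; residual signs equal
  martingale signs and the martingale residuals sum to zero.
- `bicor` scales deviations by 9·MAD with Tukey biweights. A zero MAD
  makes the statistic undefined and raises by default; the Pearson
  fallback used by the reference implementation of this statistic is
  available behind a flag, off by default so pathological inputs stay
  visible.
- `extreme_group_contrast` excludes the middle 1−2q of the sample;
  at q=0.5 the median point (if any) goes to the bottom group so a median
  split excludes no one. Tails flooded by ties raise rather than silently
  overlap.

## The synthetic-cohort generator

What it emulates: bounded beta values with CpG-specific baselines
(logit-normal sample noise, SD 0.35 on the logit scale, so per-CpG sample
means track baselines to within ~0.01); sparse CpG→biomarker maps (default
30 CpGs per signal biomarker) plus age and sex effects (drawn per
biomarker with SD 0.3 and 0.15 in signal-SD units — moderate,
non-dominant covariate structure); noise scaled so the realized signal R²
equals the configured value; a zero-floored pack-years analogue (mean 10,
SD 15, matching typical cohort distributions); exponential
proportional-hazards mortality (default baseline hazard 0.02/year, log HR
0.09 per year of age and 0.25 per SD of each signal biomarker — hazard
ratios of ~1.09 and ~1.28, the order observed for strong mortality
biomarkers in elderly cohorts); independent exponential censoring with the
rate solved numerically for a target censored fraction (default 30%);
round-robin strata with small multiplicative hazard offsets (±10% spread)
so meta-analysis sees heterogeneous-but-poolable strata.

What it does not emulate: array artifacts (probe chemistry, batches,
detection failures), cell-composition confounding, pedigree/family
correlation (samples are independent — consistent with the robust/clustered
estimators implemented, which independent data also satisfy), non-linear
CpG–biomarker relationships, and informative censoring (the generator's
independent-censoring mechanism is a modeling assumption, not an empirical
claim about any cohort). Passing recovery tests therefore demonstrates
that the estimators recover the structure they assume, at realistic sizes
and noise levels — not that real methylation data satisfy those
assumptions.

## Problem sizes in the test suite

The recovery studies run at the design sizes of the simulated experiments:
stage-1 selection at 600 training/300 test samples, 2,000 CpGs, 20
candidate biomarkers (6 with R²=0.5 signal), 10 seeds; stage-2 support
recovery at 1,500 training/700 held-out samples, 8 candidate components (3
informative), 10 seeds; Q-calibration at 3×400 samples × 100 replicates;
the end-to-end CLI demo at 260 samples × 220 CpGs. Monte-Carlo assertions
use fixed seeds (derandomized) with explicit success-count margins chosen
from the binomial sampling error of the check itself.

## Known limitations

- Elastic-net CpG selection is not reproducible across near-equivalent
  fits; only target-level selection and predictive performance are stable.
- The 1-SE Cox rule is conservative by design; with very weak signals it
  can shrink everything and trigger the CV-minimum fallback, whose
  component set is then dense.
- Sandwich standard errors assume many independent clusters; few-cluster
  corrections are not implemented.
- No random-effects meta-analysis, and no multiple-testing framework:
  statistics are reported per analysis, as in the validation design the
  package mirrors.
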