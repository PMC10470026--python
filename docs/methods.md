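# Methods

## The model

`tmtme` builds a combined prognostic classifier for right-censored cohorts
with two feature blocks: a samples × genes expression matrix on the
log2(TPM+1) scale (telomere-maintenance candidate genes) and a samples ×
cell-types immune-fraction matrix on the probability simplex (the shape of
a CIBERSORT deconvolution output).

Construction proceeds in five stages on a training cohort:

1. **Univariate Cox screen.** Each candidate gene is fitted alone in a Cox
   proportional-hazards model; genes with Wald p < `screen_alpha` (default
   0.05) are kept. Zero-variance and non-converging genes are skipped with
   a warning.
2. **Lasso-Cox selection.** The screened genes enter an L1-penalized Cox
   model solved along a descending penalty path by cyclical coordinate
   descent. The penalty is chosen by K-fold (default 5) cross-validated
   partial-likelihood deviance, `-2·[llₐ(β₍₋ₖ₎) − ll₋ₖ(β₍₋ₖ₎)]`
   (Verweij–van Houwelingen), at the deviance minimum (`lambda_rule="min"`;
   a one-standard-error rule and a bootstrap stability-selection mode are
   available). Genes with nonzero coefficients form the signature; the
   signature size is data-determined, never forced.
3. **Bootstrap-stabilized weights.** For the signature genes (and,
   separately, the signature cells) a multivariate Cox fit on the full
   cohort gives the coefficient vector *Coef*. `B` bootstrap resamples
   with replacement of size n (default B = 1000) are each refitted;
   resamples with no events, a constant feature, or a non-converged fit
   are dropped and counted, and fewer than 0.9·B usable refits aborts with
   an error. *SD* is the per-feature standard deviation of the resampled
   coefficients, and the weight of feature *i* is *Coefᵢ / SDᵢ* — a
   signal-to-noise-scaled log hazard ratio. Subsampling without
   replacement and a bootstrap-mean *Coef* are exposed as alternatives but
   are off by default.
4. **Scores.**
   `TM = Σᵢ (Coefᵢ/SDᵢ)·expressionᵢ` and
   `TME = −Σⱼ (Coefⱼ/SDⱼ)·fractionⱼ`.
   No centering or rescaling is applied; the TME minus sign lives in the
   score function, not in the stored weights, so a stored weight object is
   always the plain Coef/SD ratio. With favorable (negative-coefficient)
   cells, higher TME means better prognosis; higher TM means worse.
5. **Median-split subgroups.** Each cohort is split at its *own* sample
   medians of the two scores — medians are never transferred from the
   training cohort — and crossed into TM_L+TME_H, TM_L+TME_L, TM_H+TME_H,
   TM_H+TME_L. The two concordant cells are merged into "Mixed", giving
   the three-level classifier TM_L+TME_H / Mixed / TM_H+TME_L. Scores
   exactly at the median go to "low" (configurable). Labels depend on the
   scores only through ranks, so any strictly monotone transform of a
   score leaves the subgroups unchanged.

Evaluation reports per-subgroup Kaplan–Meier curves, the k-sample log-rank
test, Cox hazard ratios of the subgroup labels against the favorable
reference TM_L+TME_H (optionally adjusted for clinical covariates), and
time-dependent AUC at 3/5/7 years for a continuous risk score, by default
z(TM) − z(TME) standardized within the evaluated cohort (per-score AUCs
are reported alongside).

## Survival machinery and numerical choices

All survival primitives are implemented in the package and validated
against brute-force oracles and reference libraries in the test suite.

* **Cox fits** maximize the partial likelihood with the Efron tie
  correction by default (Breslow behind a flag) by damped Newton iteration:
  step-halving on any likelihood decrease, at most 100 iterations,
  convergence when max|gradient| < 1e-8. Standard errors come from the
  inverse observed information. Risk-set sums use reverse cumulative sums
  over time-sorted samples; the Efron correction is applied through a
  flattened (event time × within-tie index) expansion, so no Python loop
  runs over event times. A constant covariate raises a non-identifiability
  error naming it; a cohort with no events is rejected.
* **The gene screen** runs all single-gene fits as one vectorized batch of
  1-D Newton problems with per-gene step capping (|Δβ| ≤ 1; the 1-D partial
  likelihood is concave, so capped Newton is safe). This is what makes
  bootstrap weighting and many-seed calibration studies cheap on one CPU.
* **Kaplan–Meier** is the product-limit estimator over distinct event
  times; censored-only tails leave the curve flat, and the reported median
  survival is the smallest event time with S(t) ≤ 0.5 (+∞ if never
  reached).
* **Log-rank** is the standard k-sample chi-square with df = k−1, using
  the hypergeometric variance with the (n−d)/(n−1) tie factor.
* **Time-dependent ROC** uses the cumulative-cases / dynamic-controls
  definition with inverse-probability-of-censoring weights from the
  Kaplan–Meier estimate of the censoring distribution (cases weighted by
  1/G(T⁻), controls by 1/G(t)). The AUC is the trapezoidal area over the
  threshold sweep, which equals the censoring-weighted Mann–Whitney
  statistic with half credit for ties. Horizons are given in years and
  converted with 365.25 days/year.
* **p-values** are asymptotic throughout (Wald for Cox, chi-square for
  log-rank); no small-sample corrections.

Tie handling, the confidence-interval method, and the ROC estimator are
conventions of this package; other choices (e.g. Breslow ties) are exposed
where reasonable.

## The synthetic-cohort generator

`generate_cohort` emulates the statistical structure the analysis assumes,
so that every stage is testable without any data download.

* Expression: i.i.d. normal per gene with mean 3.0 and SD 1.2 on the
  log2(TPM+1) scale (typical magnitudes for moderately expressed genes),
  truncated at 0.
* Fractions: symmetric Dirichlet (concentration 1.0) over `n_cell_types`
  cell types, so rows live on the simplex like a deconvolution output.
* Survival: exponential baseline hazard (default median survival five
  years, in days) scaled by `exp(linear predictor)`, where the linear
  predictor is Σ signal_effects·z(expression) + Σ cell_effects·fractions.
  Signal effects act on standardized expression so planted effect sizes
  are per-SD and scale-free. Censoring is independent exponential with its
  rate solved by root-finding so the expected censored fraction equals
  `censoring_target` (default 0.30).
* The default planted design — the study condition used by the heavier
  tests and by `scripts/acceptance.py` — is n = 600 samples, 200 genes of
  which 10 carry effects ±0.5 per expression SD (5 positive, 5 negative),
  and 10 cell types of which 5 favorable cells carry log-hazard −3 per
  unit fraction. Returned cohorts carry a `truth` record of every planted
  parameter.

Because fractions sum to one, cell effects are only identified relative to
the remaining composition: a design where five cells share a negative
effect makes each *null* cell carry an equal-magnitude positive marginal
association. A univariate screen therefore has limited power to pick out
the favorable cells individually, while the multivariate fit on the
designated favorable cells recovers all signs reliably. Mirroring the
setting in which the favorable cell types are known in advance, the
pipeline accepts an explicit cell signature (`cells=...`); when none is
given it falls back to a univariate screen keeping favorable
(negative-coefficient) cells at `cell_alpha`, and to all cells with a
warning if none pass.

What the generator does **not** emulate: RNA-seq count noise,
gene–gene correlation, batch effects, tumor purity, non-proportional
hazards, or informative censoring. Passing tests demonstrate correctness
of the estimators and recoverability of planted structure under the
model's own assumptions, not performance on real cohorts.

## Calibration checks and problem sizes

The acceptance tests run at fixed problem sizes chosen to finish quickly
on one CPU while leaving the statistical checks well powered: 20
train/validate seed pairs at n = 600 with B = 200 for sign recovery,
directionality, subgroup ordering and transfer; 200 null cohorts at
n = 300 for calibration. For the null screen, 50 genes per cohort are
tested (10 000 tests) so that binomial sampling noise dominates the small
finite-sample excess of the asymptotic Wald test (measured at ≈ 0.051 for
nominal 0.05 at n = 300); the acceptance band is the exact binomial 99%
interval. Because a training-cohort split is fit to its own outcome,
log-rank calibration is assessed on *independent* null cohorts labelled
with trained weights and their own medians — the transfer protocol —
where the type-I level is exact by construction.

`scripts/acceptance.py` runs the default planted design end to end
(training cohort seeded by `--seed`, validation cohort by `--seed`+1000,
B = 1000) and reports screen/signature sizes, the percentage of planted
features whose weight sign is recovered, the training log-rank
chi-square, validation AUC at 3/5/7 years, the validation hazard ratio of
TM_H+TME_L versus TM_L+TME_H, whether the three-level median-survival
ordering holds on validation, and the realized censoring percentage.

## Known limitations

* The exponential-baseline generator yields proportional hazards by
  construction; model misspecification is out of scope.
* Gene/sample identifiers are matched by exact case-sensitive string
  equality; no symbol aliasing or harmonization across annotation
  versions.
* The lasso path solver uses Breslow ties internally (glmnet convention),
  while the unpenalized fits default to Efron; with continuous survival
  times the two coincide.
* Stability-selection mode resamples at the cross-validated penalty
  rather than re-tuning the penalty per resample.
* No time-varying covariates, stratified Cox, competing risks, or frailty
  terms.
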