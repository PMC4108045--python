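# Methods

## The problem

A logistic prediction model fitted to a small dataset and evaluated on that
same dataset reports an apparent ("naive") C statistic — the area under the
ROC curve, equivalently the probability that a randomly chosen case receives
a higher predicted risk than a randomly chosen control — that overstates the
discrimination the model would achieve in new data. The excess is the
*optimism*, and it grows as the events-per-variable ratio (EPV = number of
cases / number of candidate predictors) falls. `optimcv` implements six
internal-validation procedures that estimate an optimism-corrected C from the
small dataset alone, plus the machinery to study how well they do it.

## The C statistic

For scores s and binary outcome y, C is computed over all n1 x n0
case-control pairs as

    C = (#{s_case > s_control} + 0.5 * #{s_case = s_control}) / (n1 * n0),

the Mann-Whitney form. Ties count one half — the definition in terms of
"higher predicted probability" alone does not fix a tie convention, and one
half is the standard choice that keeps C = 0.5 for uninformative scores.
Equality is exact on the computed floats (no epsilon): this makes results
bit-reproducible, at the cost of treating scores differing in the last bit
as distinct — which is the desired behaviour for ranking-based statistics.
C depends only on the score ordering, so the linear predictor and the
predicted probability give identical values.

## Logistic fitting under separation

The validators refit logistic models hundreds of thousands of times on tiny
training subsets. At EPV <= 5 an appreciable fraction of those subsets is
completely or quasi-completely separated, where the MLE diverges. The fitter
is Newton-Raphson with step-halving, capped at 25 iterations (gradient
tolerance 1e-8). On separation the iterates stop at large but finite
coefficients; the fit is flagged (`separation_detected`, triggered when any
training linear predictor exceeds 15 in magnitude, i.e. fitted probabilities
beyond ~1-3e-7) and the diverged linear predictor is used for ranking anyway.
Rationale: C consumes only the ordering, which the diverged direction
defines perfectly well, and this mirrors what naive refitting inside each
resample does — excluding or shrinking those fits would silently change the
estimand. Degenerate fits are counted and reported per estimate.

Covariate columns constant within a training subset (an inevitable byproduct
of resampling) are dropped for that fit and contribute zero to the linear
predictor. A rank-deficient design after that drop raises an error naming
the offending columns rather than guessing.

## The six procedures

All procedures share a `MethodConfig` (defaults: k = 10 folds, r = 20
replications, b = 200 bootstrap resamples, split fraction 2/3, stratified
sampling, one master seed).

- **Sample splitting** — one random 2/3 : 1/3 split; fit on the larger part,
  C on the smaller.
- **k-fold CV** — stratified random partition into k groups; each held out
  in turn; the k fold-level C values are averaged.
- **Replicated k-fold CV** — r independent partitions; the mean of all r*k
  fold-level C values (200 models at the defaults, matching the common
  recommendation to average at least 200 model evaluations). With r = 1 it
  reduces exactly — same stream, same folds — to single k-fold CV.
- **Leave-one-out CV** — each row's out-of-sample probability from a model
  fitted to the other n-1 rows; one C pooled from the n probabilities.
  Pooling probabilities from n different models biases C downward; the
  procedure is included because it remains in common use.
- **Leave-pair-out CV** — every (case, control) pair held out in turn; the
  model fitted on the remaining n-2 rows scores both members; C is the
  fraction of pairs ranked correctly (ties one half). Exhaustive, hence
  deterministic, at the cost of n1*n0 fits.
- **Harrell bootstrap** — b resamples with replacement of size n; the mean
  of (C of the resample model on the resample − C of that model on the
  original data) estimates the optimism, which is subtracted from the naive
  C.

Design choices where the procedure definitions are genuinely open:

- *Stratification.* Folds and splits are stratified by outcome by default.
  With 15 cases and k = 10, unstratified folds can contain zero cases,
  leaving the fold C undefined; stratification guarantees computability.
  The unstratified variant is kept behind a flag for sensitivity analysis.
  A fold or split that still ends up single-class aborts with a specific
  error rather than being silently skipped, so method comparisons are never
  computed over different replicate sets.
- *Degenerate bootstrap resamples.* A resample lacking a class is redrawn
  (and counted in diagnostics) rather than skipped, keeping exactly b
  differences in the average.
- *Seed policy.* Each stochastic method derives an independent stream from
  (master seed, fixed method tag), so adding or reordering methods never
  perturbs another method's results. The replicated-CV stream is further
  keyed by replication index.
- *Range.* The bootstrap-corrected C is clipped to [0, 1] (the subtraction
  can otherwise escape the range); optimism is then recomputed as
  naive − corrected so the two stay consistent.

## Synthetic populations

Two parametric populations emulate the clinical settings that motivate the
methods. The published descriptions specify the distributional *forms* but
not the numeric parameters (those came from exploratory analyses of
registries that are not deposited); the defaults below are plausible
clinical values chosen once, and correctness is defined by the calibration
step hitting the target C, not by the defaults themselves.

**Down-like** (3 predictors): maternal age ~ Triangular(15, 31, 47);
log10 MoM alpha-fetoprotein and log10 MoM hCG bivariate normal given age,
with means linear in age (slopes −0.002 and +0.003 per year around age 31),
SDs 0.20 and 0.25, correlation 0.10. Outcome logistic with base coefficients
(+0.09 per year age, −4.0 per log10 AFP, +3.5 per log10 hCG) and intercept
−10, giving ~1.5% prevalence at the scale constant that reaches C = 0.90.
The registry prevalence in this setting is far lower (~0.2%); the simulator
uses a higher prevalence so that desk-scale Monte-Carlo samples contain
enough events for stable C estimation. Prevalence does not enter the
estimand — the case-control draw conditions on class, and the population C
is calibrated after the intercept is fixed.

**Cesarean-like** (5 predictors): gestational age ~ Triangular(37, 39.5, 42)
weeks; maternal age ~ Uniform(16, 37); birthweight centile ~ Uniform(0, 100);
maternal height normal (SD 6.5 cm) with mean 164 cm plus small linear terms
in age, gestational age and centile; infant sex Bernoulli through a logistic
link on the other four covariates (male fraction ~0.51). Outcome logistic
with base coefficients (+0.06 age, −0.06 height, +0.15 gestational age,
+0.25 male sex, +0.008 centile) and intercept 0.4, ~15% prevalence at the
scale reaching C = 0.71 (the clinical rate in this setting is ~20%).

Triangular draws use the closed-form inverse CDF. All generators draw from a
`numpy.random.Generator` in a fixed order, so an entire simulated experiment
is bit-reproducible from its master seed.

**What the generators do not emulate:** real gestational-age-specific
median normalisation of the biomarkers (the MoM scale is assumed, not
recomputed), measurement error and digit preference, non-linear covariate
effects, interactions, and secular trends. Tests passing on these
populations therefore demonstrate the *procedural* properties of the
correction methods (bias direction, relative variability, exactness of the
exhaustive procedures) under a well-specified logistic truth — not
performance on any particular clinical registry.

## Calibrating the population C

The generating model's discrimination is controlled by multiplying all
non-intercept coefficients by one scale constant. `population_c` estimates
the model's C by Monte-Carlo (default 500,000 individuals, requiring at
least 1,000 events). `calibrate_scale_constant` bisects the constant on a
single common-random-numbers sample — covariates and outcome uniforms drawn
once — which makes the empirical C an exactly non-decreasing step function
of the constant, so bisection is well posed; the bracket [0, 50] is doubled
geometrically if too small. Stopping tolerance is 0.002 on the C scale
(below the 2-decimal reporting precision). The returned spec is verified on
an independent sample within tol plus a 3-standard-error Monte-Carlo
allowance (Hanley-McNeil SE; at n = 500,000 the estimator's own noise is
~0.002, the same order as the tolerance, so a literal tol-only check would
reject perfectly calibrated specs about half the time).

## Evaluation harness

For a simulated small dataset, the *true* C of its fitted model is the
concordance on a large gold standard: a fresh population of 100,000
individuals per simulation cell. (For a real large dataset the same
`true_c` operation scores the pooled complement of a partition produced by
`partition_small_datasets`, which splits each class into near-equal disjoint
groups.) Each method's signed error is corrected − true; summaries report
mean and median signed error, mean and median absolute error, IQRs, MSE and
a Wilcoxon signed-rank p-value against zero. Pairwise method contrasts take
per-dataset differences in absolute error (column method minus row method),
with raw (unadjusted) Wilcoxon p-values, since each contrast is reported as
its own comparison.

The Wilcoxon test drops exact zeros, uses the exact sign-flip null
distribution (dynamic programming over doubled midranks) for up to 25
non-zero differences, and a normal approximation with tie correction and
continuity correction beyond; an all-zero vector yields p = 1.

Simulation grids run cells of (population spec x design) with independent
derived seeds per cell and per replicate; a cell failure is recorded and
does not abort the grid. The default study size is 200 replicates per cell —
large enough to resolve the documented bias directions (naive optimistic;
leave-one-out pessimistic; bootstrap optimistic at low EPV and low C;
cross-validation mildly pessimistic) with one-sided Wilcoxon tests — with
larger runs available by flag.

## Known limitations

- Leave-pair-out cost grows as n1 * n0 model fits; it is practical for the
  small datasets it is designed for (hundreds of rows), not for large ones.
- The corrected-C procedures assume a fixed model specification: variable
  selection, interactions and non-linear transforms inside the resampling
  loop are out of scope.
- Calibration and population-C values carry Monte-Carlo error of order
  0.002 at the default sample size; targets closer to 1 than ~0.98 leave
  little headroom for the bisection bracket.
- The unstratified fold option can abort on datasets with very few cases;
  this is by design (see stratification above).
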