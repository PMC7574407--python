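# Methods

This note documents the statistical procedures implemented in
`pathsurv`, the choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Survival models

**Penalized fit.** `CoxLasso` maximizes the Cox partial likelihood with
an L1 penalty. The path is solved by glmnet-style coordinate descent
(scikit-survival's `CoxnetSurvivalAnalysis`) over a grid of 100
log-spaced penalty values from the smallest λ that produces the empty
model down to 10⁻³ of it. Predictors are standardized internally
(configurable) and coefficients are reported on the original scale. λ
is chosen to minimize the mean cross-validated partial-likelihood
deviance over 10 event-stratified inner folds, using the
Verweij–van Houwelingen form `dev_k(λ) = −2 [ℓ_full(β̂_{−k}(λ)) −
ℓ_{−k}(β̂_{−k}(λ))]`, which remains stable when a fold has few events.
The deviance uses a Breslow-tie partial likelihood; with continuous
synthetic times, ties do not arise. When the solver truncates a path
early (deviance saturation), missing grid points reuse the nearest
fitted penalty; refits at a single requested λ (the final model) are
solved directly at that λ with tolerance 1e-9.

**Unpenalized fit.** `CoxPH` fits by Newton iteration with Efron tie
handling (lifelines). Before fitting, columns are scanned in order by
incremental Gram–Schmidt on the centered design: a column whose
residual against the span of previously accepted columns has norm
≤ 1e-9 (relative) is flagged *aliased* — exactly collinear — and gets
no estimate (NaN hazard ratio, SE, p-value), the way standard survival
software reports NA for such terms; constant columns are aliased by
the same rule. Wald standard errors and p-values are reported,
matching the convention of presenting se(coef) next to p-values.
Non-convergence (e.g. monotone likelihood when a predictor is positive
only in censored samples) is recorded on the results object as
`converged=False` with a diagnostic, never raised.

**Concordance.** Harrell's C counts, over comparable pairs (the earlier
time is an observed event), the fraction where the earlier-event
sample has the higher risk, ties in risk scoring 0.5 (computed via
lifelines; an independent pair-enumeration oracle covers it in the
tests). Zero comparable pairs is an error at the metric level; inside
the harness such folds are recorded as unavailable and excluded from
means rather than imputed at 0.5, which would bias permutation nulls
toward the center.

## Evaluation harness

The outer scheme defaults to 20 repetitions of 5-fold CV (100 trained
models). Outer folds are stratified by event status so that
low-event-rate cohorts cannot produce event-free test folds. All fold
assignments derive from `numpy.random.SeedSequence` of (scheme seed,
repetition, fold), so a run is a pure function of its inputs.

Optional predictor screening (`PreSplitFilter`) runs inside each outer
training fold only: a univariable-Cox Wald filter (p ≤ α, default
0.05) and/or a minimum-positive-count rule for binary predictors
(strictly more than k positives, default k = 2 — the recurrence filter
that removes most perfectly collinear near-private mutations). Because
filters see only training rows, the evaluation is leak-free; the tests
verify fold-by-fold that candidate sets equal what the filter computes
from training rows alone.

**Stability.** Each trained model is a rater assigning
selected/not-selected to every candidate variable; Fleiss' κ
(statsmodels) measures chance-corrected agreement across the 100
raters. The subject universe is the union of per-model candidate sets
(post-filter, pre-selection): a variable a fold-specific filter never
offered to some rater counts as "not selected" by that rater, which
makes "never selected" an informative form of agreement. κ is
undefined (returned as NaN) when every assignment lands in one
category. **Parsimony** is the mean selected-set size over the models.
Reported concordance is mean ± SD over the per-model test-fold values.

**Final model.** The whole cohort is refitted at the arithmetic mean of
the per-model selected λ's (a geometric mean is available by flag);
variables with nonzero coefficients are then given unpenalized
multivariable and univariable Cox estimates, with aliasing flags — on
sparse mutation data the multivariable refit routinely aliases
duplicated-profile genes, and the report keeps them visible rather
than silently dropping them.

**Null models.** Permutations shuffle (time, event) pairs jointly
across samples, preserving the outcome multiset and the censoring
distribution while breaking every predictor–outcome association;
predictor correlations are untouched. Concordance under permutation
should sit near 0.5, and the acceptance script measures exactly this.

## Single-sample enrichment

**Binary score** and **log-odds-ratio score** operate on binary SPM
matrices. For the log-OR, the 2×2 table's gene universe is *all genes
present in the (possibly filtered) matrix*, so upstream gene filters
change the denominator — deliberate, documented, and covered by tests.
Set membership is always intersected with matrix genes first; sets
with no genes in the matrix are dropped with a warning. Zero cells are
the common case under 99.9% sparsity, so the Haldane–Anscombe
correction adds 0.5 to all four cells whenever any cell is zero (and
never otherwise); the correction is a parameter so alternatives can be
audited, and a zero correction with a zero cell raises rather than
emitting ±inf.

**GSVA-style score** (continuous CNV data): for gene *i* and sample
*j*, the expression-level statistic is the Gaussian-kernel CDF estimate
`z_ij = Σ_k Φ((x_ij − x_ik)/h_i)` with per-gene bandwidth `h_i = sd_i/4`
(the reference rule); within each sample, genes are ranked by `z` and
assigned the symmetric rank statistic `r = |p/2 − rank|`; walking down
the ranked list, in-set steps add `r^τ` (normalized by the in-set sum)
and out-of-set steps subtract `1/(p − m)`. With `es_mode =
max_deviation_diff` (default) the score is the largest positive plus
the largest negative walk deviation; `two_sided_max` returns the
signed deviation of largest magnitude. Defaults τ = 1, bandwidth rule
sd/4. The score is invariant to per-gene shifts (only within-gene
differences and between-gene ranks enter) and to gene reordering;
ranking ties are broken by row order for determinism. Sets covering
every matrix gene have an empty complement and are dropped. At least 3
samples are required for the kernel CDF to be meaningful. The
implementation is validated against an independent step-by-step naive
trace in the tests.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical obstacles* of somatic
alteration data, not its biology:

* **SPM**: per-gene mutation rates drawn from a Beta distribution with
  mean `1 − sparsity_target` and concentration `rate_dispersion`
  (default 0.5, giving a heavy-tailed handful of recurrently mutated
  genes over a long near-silent tail); entries are independent
  Bernoulli given the gene rate. Optional duplicate groups force
  identical rows — the perfect-collinearity structure of genes mutated
  in the same patients. Defaults (2 000 genes × 500 samples, sparsity
  0.999) match the sparsity regime of a real lower-grade-glioma-sized
  cohort. Realized zero fraction concentrates within ±2% of target at
  these sizes.
* **CNV**: genes partitioned into contiguous segments; one Gaussian
  value per (segment, sample) shared by all genes of the segment, plus
  optional per-gene noise — the genes-called-together-in-one-region
  structure. No chromosome coordinates, GISTIC thresholds or purity.
* **Gene sets**: uniform sizes within a range, with strict
  superset/subset nested pairs on request (real collections contain
  such nestings, e.g. a mitotic-cell-cycle set containing a
  DNA-replication set).
* **Survival**: exponential baseline hazard `exp(x'β)/scale`;
  independent exponential censoring whose scale is found by bisection
  (200 iterations) against the target censoring rate, realized event
  rate within ±5% of target at n ≥ 500. Times are clipped strictly
  positive.

Consequently, passing tests demonstrate the *machinery* — calibration,
leak-freedom, metric correctness, collinearity handling — under a
proportional-hazards world with independent censoring. They do not
certify predictive performance on real tumor cohorts, where
proportionality, censoring independence and the mutation-rate model
all fail in their own ways.

## Collinearity simulation

Each replicate draws independent noise predictors plus signal columns
duplicated exactly, with outcome either Gaussian linear (default; also
the faster family) or exponential-hazard survival with ~30%
censoring. The Lasso path is solved on a common penalty grid fixed
from a reference replicate, and the report records, per λ, the
fraction of replicates in which ≥2 members of some duplicate group are
simultaneously selected (nonzero). With the Gaussian coordinate-descent
path the both-selected fraction is substantially positive over a broad
λ range — duplicated variables are *not* reliably discarded — while
the survival-path solver resolves exact duplicates to one member at
the tolerances used; both findings are reported as measured. When both
copies are selected their coefficients share a sign (the penalty makes
opposite signs strictly worse). The literal `any_lambda_all_exclusive`
flag is trivially true at the null end of the path, so the per-λ
fraction table carries the substantive content. Standardization is a
toggle because duplicate handling can depend on it.

## Numerical conventions and limitations

* Continuous matrices serialize at 6 significant digits; binary
  matrices round-trip bit-exactly.
* Samples present in only one of matrix/clinical inputs are dropped
  with a logged warning (plain inner join).
* Zero-variance predictors are dropped with a warning before penalized
  fits and contribute zero coefficients.
* Problem sizes in the test-suite and the acceptance script (cohorts of
  300–400 samples, 20–300 predictors, 5×5 schemes with 3 permutations)
  are chosen so the full pipeline, including its end-to-end pattern
  checks, completes quickly on a single CPU while keeping the Monte
  Carlo error of the calibration quantities well inside their stated
  tolerances.
* Ridge and elastic-net penalties, time-varying covariates, competing
  risks, and variant-level (sub-gene) features are out of scope.
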