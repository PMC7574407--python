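# pathsurv

Gene-level versus pathway-level survival prediction from somatic alterations.

Tumor genomes carry two broad classes of somatic alteration: point
mutations (SPM), recorded here as binary gene-level non-silent mutation
calls, and copy-number variation (CNV), recorded as continuous
gene-level estimates. Both are candidate predictors of patient
prognosis, but gene-level mutation matrices are extremely sparse (real
cohorts are ~99.9% zeros) and riddled with perfect collinearity —
distinct genes mutated in exactly the same one or two patients, or
genes called together inside one copy-number segment. `pathsurv` is a
pipeline for asking, on such data, whether aggregating genes into
pathways buys predictive power, stability or parsimony, and for
quantifying what collinearity does to penalized gene-level models.

It is written for biostatisticians and computational biologists who
work with gene-by-sample alteration matrices, MSigDB-style gene-set
collections (GMT), and right-censored survival tables.

## The model

For a sample with predictor vector $x$, the Cox proportional hazards
model sets $h(t \mid x) = h_0(t)\,e^{x^\top\beta}$. With many more
predictors than events, $\beta$ is estimated by maximizing the L1
(Lasso) penalized partial likelihood

$$\hat\beta(\lambda) = \arg\max_\beta\; \ell(\beta) - \lambda \lVert\beta\rVert_1 ,$$

which sets most coefficients exactly to zero. The pipeline evaluates a
model by nested cross-validation: in each of `n_reps` repetitions the
cohort is split into `n_outer_folds` event-stratified folds; on every
outer training fold a Cox Lasso is fitted with $\lambda$ chosen by an
inner 10-fold CV of the partial-likelihood deviance, and the penalized
linear predictor is scored on the held-out fold by Harrell's
concordance index (C = 1 perfect ranking, C = 0.5 random). The default
20 × 5 scheme yields 100 trained models, which are reused as 100
"raters" for a Fleiss-kappa statistic of selection stability, and whose
mean selected-set size measures parsimony. A final model refits the
whole cohort at the arithmetic mean of the 100 selected $\lambda$'s and
reports unpenalized multivariable and univariable Cox estimates
(hazard ratios, standard errors, Wald p-values) for the retained
predictors, flagging exactly collinear ("aliased") predictors, which
have no estimate.

Pathway-level predictors come from three single-sample enrichment
scores:

* **binary** (SPM): 1 if any member gene of the pathway is mutated in
  the sample;
* **log-odds ratio** (SPM): the log odds ratio of the 2×2 table
  cross-classifying all matrix genes by pathway membership × mutation
  status in that sample (Haldane–Anscombe 0.5 correction when a cell is
  zero);
* **GSVA-style** (CNV): per-gene Gaussian-kernel CDF estimates across
  samples, per-sample gene ranking, and a weighted Kolmogorov–Smirnov-
  like random walk giving one enrichment score per (pathway, sample).

Permutation null models — jointly shuffling (time, event) pairs across
samples — verify that reported concordance is not a pipeline artifact,
and a dedicated simulation measures how often the Lasso retains both
copies of an exactly duplicated predictor (it is not guaranteed to
discard them, at any $\lambda$).

## Worked example

Synthetic cohort whose survival is driven by the mutation burden of one
pathway, evaluated gene-level versus pathway-level:

```python
from pathsurv.simulate import (SpmSimConfig, GeneSetSimConfig, SurvivalSimConfig,
                               generate_spm, generate_gene_sets, generate_survival)
from pathsurv.features import log_odds_pathway_score, gene_level_features
from pathsurv.evaluation import CvScheme, NestedCVEvaluation, build_final_model

spm = generate_spm(SpmSimConfig(n_genes=300, n_samples=300, sparsity_target=0.97,
                                rate_dispersion=2.0, seed=10))
sets = generate_gene_sets(GeneSetSimConfig(n_sets=10, set_size_range=(20, 40),
                                           gene_universe=list(spm.gene_ids), seed=11))
pathway_X = log_odds_pathway_score(spm, sets)
y = generate_survival(pathway_X, SurvivalSimConfig(betas={"SET001": 1.2},
                                                   censoring_rate_target=0.3, seed=12))

scheme = CvScheme(n_reps=5, n_outer_folds=5, seed=0)
print(NestedCVEvaluation(pathway_X, y, scheme, workflow_id="spm_pathway_logor").run().summary())
print(NestedCVEvaluation(gene_level_features(spm), y, scheme,
                         workflow_id="spm_gene_all").run().summary())
```

prints

```
workflow_id       spm_pathway_logor        workflow_id       spm_gene_all
n_models                         25        n_models                    25
ci_mean                     0.68967        ci_mean               0.653804
ci_sd                       0.03399        ci_sd                 0.035663
fleiss_kappa               0.608196        fleiss_kappa          0.596167
avg_model_size                 2.92        avg_model_size            11.6
```

Both representations rank survival well above chance (mean test-fold
concordance 0.69 and 0.65), but the pathway-level model needs fewer
than 3 predictors per trained model where the gene-level model spreads
the same signal over ~12 weakly mutated genes. The final refit
recovers the generating pathway with a strongly significant hazard
ratio:

```python
final = build_final_model(pathway_X, y,
                          NestedCVEvaluation(pathway_X, y, scheme).run())
print(final.summary().round(4))
```

```
        hazard_ratio  se_coef  p_value  aliased  uni_hazard_ratio  uni_se_coef  uni_p_value
SET001        3.3732   0.1266   0.0000    False            3.2898       0.1260       0.0000
SET004        1.2669   0.0997   0.0176    False            1.1636       0.0989       0.1255
```

A one-unit increase in the SET001 log-odds enrichment multiplies the
hazard by 3.37 (the generating coefficient was 1.2 on the log scale,
$e^{1.2} = 3.3$); SET004 is a weakly correlated passenger.

The same stages are scriptable from the shell (`pathsurv simulate`,
`validate`, `features`, `fit`, `evaluate`, `simulate-collinearity`);
see `pathsurv --help`.

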