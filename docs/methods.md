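# Methods

This note documents the models, numerical choices and study conditions behind
`rcdml`, and what the test suite does and does not establish.

## Data model and labelling

Inputs are a genes × samples CPM matrix and a long or wide (sample, inhibitor) →
response-AUC table.  Responses are sparse by design — each inhibitor was assayed on
its own sample subset — so blank wide-table cells are absent records, never zeros.
Cohorts are the intersection of expression samples and samples with a response for the
inhibitor; inhibitors can be filtered to those with at least `min_n` observations
(inclusive bound, default 300).  ic50 is parsed and stored but unused; every analysis
runs on the response AUC.

Labels are cohort-level quantiles (defaults 0.25/0.75, linear interpolation between
order statistics, configurable via any `numpy.quantile` method).  Inequalities are
strict on both sides, so threshold ties are excluded; a constant response vector
labels everything excluded with a warning rather than an error.  Which tail is
"responder" is a mandatory `direction` flag: for *ex vivo* viability assays low drug
AUC usually means drug-sensitive, but the opposite convention also appears, and
silently guessing would flip every downstream confusion matrix.  Labels are computed
on the full cohort before splitting — a mild information-sharing choice (the quantile
thresholds see all subjects) that mirrors how such screens are labelled in practice;
Phase-2 *expression* is never touched before holdout scoring, and the test suite
asserts that perturbing it leaves every Phase-1 result bit-identical.

## Tree-Shapley feature selection

The `shap` strategy ranks genes by the mean absolute Shapley attribution of a
gradient-boosted tree model over the training samples.  Attributions are computed by
the exact polynomial-time path algorithm (EXTEND/UNWIND recursion) under the
path-dependent expectation convention: features outside the coalition split the walk
proportionally to per-node training cover.  The implementation is checked against an
exhaustive-coalition oracle (enumerate all 2^M feature subsets with the tree's
path-conditional expectation) to < 1e-10 on small trees, and satisfies local accuracy
(Σφᵢ = margin − cover-weighted expectation) on every converted ensemble.

The base model is an XGBoost classifier configured for attribution rather than raw
accuracy: 300 rounds, depth 4, learning rate 0.05, row subsampling 0.63 and per-node
column subsampling 0.1.  The rationale: a deterministic greedy booster re-uses the few
best splitters among a group of correlated informative genes, and TreeSHAP then
assigns exact zeros to the unused members, so a redundant signature is only partially
recovered.  Per-node column subsampling forces splits to rotate through the correlated
group (the random-forest trick inside boosting), spreading Shapley credit over all of
its members; with it, 9–10 of 10 planted genes are recovered across generator seeds
versus 6–8 with stock greedy settings.  The configuration is exposed via
`base_model_params` for users who prefer the tuned-classifier defaults.

Scores are tied-broken lexicographically by gene id, as in every other strategy, so
rankings are deterministic.

## Moderated-t differential expression

The `dge` strategy works on log₂(CPM + 0.5) (offset configurable).  Genes below 1 CPM
group-mean in both classes are removed first; the within-group aggregation is the
group mean (a filterByExpr-like reading), with an "all samples" mode available.  Per
gene, the pooled two-sample variance s²_g with d = n₁ + n₀ − 2 degrees of freedom is
shrunk toward a prior: the scaled-F prior (d₀, s₀²) is fitted by method of moments on
e_g = log s²_g − ψ(d/2) + log(d/2), solving ψ′(d₀/2) = var(e) − ψ′(d/2) by Newton
iteration on the trigamma inverse; the posterior variance is
s̃² = (d₀s₀² + d s²)/(d₀ + d) and the moderated t uses d₀ + d degrees of freedom
(capped at the experiment-wide pooled df; when the observed variances are no more
dispersed than χ² sampling explains, d₀ = ∞ and every gene is shrunk to the mean
variance).  Sample variances are floored at 1e-5 × median to keep the log-scale
moment fit finite for near-constant genes.  The implementation agrees with
Bioconductor limma to ~1e-8 on t, p, d₀ and s₀² in both the finite and the
complete-shrinkage branch (one test runs limma through Rscript as an independent
oracle), and its null type-I rate at p < 0.05 is calibrated to [0.04, 0.06] on 2,000
simulated null genes.

Selection ranks by p-value (score −log₁₀ p) and always returns k genes — the pipeline
needs a fixed-size signature — while reporting how many of them pass BH-FDR < 0.05.
Whether the original workflow restricted the signature to FDR-significant genes when
fewer than k passed is unknown; reporting rather than enforcing keeps every cell
comparable.

## PCA and random baselines

`pca` fits principal components on the training split only (training mean, full SVD)
and projects both splits; signature entries are component labels scored by explained
variance.  Component signatures are intentionally non-transferable across cohorts and
are rejected by the swap experiment.  `random` draws k genes without replacement from
a seeded generator — the no-information baseline that any informative strategy must
beat.

## Classifiers and tuning

Three tree ensembles share one train/predict contract: scikit-learn's random forest
(`rf`), an XGBoost-style booster with per-level column subsampling and min-split-loss
(`gb_a`), and a LightGBM-style booster without those knobs (`gb_b`).  The full
reference search grids live in `DEFAULT_GRIDS`; mapping details: `max_features`
tokens 'auto' and 'sqrt' both mean √p for classification; `max_depth: None` maps to
each library's no-limit token (0 for XGBoost under hist, −1 for LightGBM); LightGBM
row subsampling activates `subsample_freq = 1`, since bagging is otherwise off.

Random search samples each grid entry uniformly and independently (`n_iter` draws,
de-duplicated), scores every configuration by mean ROC-AUC over the same stratified
folds, and keeps the first-sampled best.  A single-class validation fold scores 0.5
(the uninformative value) with a warning, keeping the search ordering total.
`n_iter` defaults to 60; the full grids with up to 1,000 trees are expensive,
so the package also ships `DESK_GRIDS` — value-subsets of the full grids with
small ensembles — which the test suite and the acceptance script search with
`n_iter` 2–4.  Everything is seeded: a master `SeedSequence` spawns per-repeat, then
per-split/selection/cell seeds, and re-running with the same seed reproduces reports
bit-for-bit (single-threaded fits, `tree_method="hist"`, `deterministic=True`).

## Protocol details

Splits are stratified by class (the cohort sizes after quartile labelling make
single-class folds a real risk under unstratified shuffling).  Within a repeat one
5-fold partition of Phase 1 is shared by all hyperparameter configurations, so their
CV scores are comparable; feature selection runs inside each training fold.  "Best
model" means: best hyperparameter configuration by mean CV AUC, refit on all of
Phase 1 with the signature re-selected on all of Phase 1 — a refit rather than fold
-model reuse, the standard reading.  Each of the `repeats` runs re-draws the holdout
split and the folds from its own derived seed.

The feature-swap experiment keeps B's split, labels, tuned hyperparameters and fit
seed, replacing only the Phase-1 signature with the donor's; swapping a report with
itself therefore reproduces the native holdout AUC exactly, making the identity case a
sharp correctness check rather than an approximate one.

## Evaluation

ROC-AUC uses the Mann-Whitney rank formulation with half-credit for ties, which is
identical (to 1e-12, property-tested on 1,000 fixtures) to trapezoidal integration of
the ROC curve.  Confusion matrices threshold the class-1 probability at 0.5.
Divergence AUC excludes missing cells from the row mean and requires two observed
cells per drug.  The conservation index CI = (Σcᵢ²/Σcᵢ)/(R/2) was chosen so that its
range reproduces the conventional low/mid/high bins (full conservation 2.0, full
uniqueness 2/R); the verbal description it formalises ("product of the feature counts
divided by the sum squared") is not computable as written at realistic scale, so the
numeric values are this package's convention and only the binning behaviour is
comparable.  One-way ANOVA on divergence scores is exposed as a thin convenience
wrapper over standard routines and is not part of the method core.

## Synthetic cohorts and study conditions

Each sample draws a latent response z from a standardised skew-normal (shape
`response_skew`; sign controls the skew of the resulting drug-AUC histogram).  The
drug AUC is 150 + 40·z plus Gaussian noise (sd 10, clipped at 0) — an affine transform
centred in the range typical of *ex vivo* viability AUCs.  Expression is log-normal:
per-gene log₂-CPM baseline N(3, 2), per-sample noise sd `dispersion` (default 1);
each informative gene's log₂-CPM is shifted by `effect_size · z`.  Informative genes
sit on well-expressed baselines (N(4, 1)): a planted gene below the 1-CPM filter would
be undetectable by construction rather than by method failure, which is not the regime
the pipeline probes.  The default gene pool is 20,000 — transcriptome scale — because
the random-baseline property (AUC ≈ 0.5) presumes that 30 random genes rarely hit a
planted one; in a small pool the baseline becomes spuriously predictive and the
comparison meaningless.

The generator's defaults are the study conditions of the recovery experiments:
n = 300 samples, 10 informative genes, effect size 2.  Multi-inhibitor generation
shares one expression matrix, draws disjoint informative sets by default (specific or
shared sets can be passed explicitly), and subsamples each inhibitor's cohort.

What the generator does **not** emulate: count-level (negative-binomial) noise —
inputs are already CPM; gene-gene correlation beyond the planted latent structure;
batch effects; library-size artefacts.  Passing tests therefore show that the
pipeline's machinery is correct and recovers planted monotone expression-response
signal at realistic dimensions; they do not certify performance on real cohorts,
where correlated backgrounds and weaker, polygenic effects make both selection and
classification harder.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full protocol at desk scale:
planted-signal recovery with n = 300 / 20,000 genes, 3 repeats, `DESK_GRIDS`,
`n_iter = 4`, one classifier; null-effect calibration over 60 single-configuration
repeats at 500 genes; the swap experiment with two 200-sample inhibitors over 2,000
genes.  These sizes keep a full run in minutes on one CPU while leaving every
qualitative property (recovery, baseline nullity, isolation, specificity) intact.

## Known limitations

- The conservation index's numeric values are package-specific (see above); only the
  binning is comparable across implementations.
- The moderated-t runs on log-CPM without precision weights; very small counts are
  handled by the +0.5 offset, not by a mean-variance trend fit.
- The confusion threshold is fixed at 0.5 rather than calibrated.
- TreeSHAP is implemented in pure Python; it is exact and fast enough for the
  pipeline's sample sizes (tens of milliseconds per 100-tree model), but not tuned
  for very deep ensembles.
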