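# rcdml

Responder classification from transcriptomic signatures and *ex vivo* drug-response
data.

`rcdml` is a benchmarking pipeline for a recurring precision-oncology question: given
bulk RNA-seq expression (CPM) of patient samples and *ex vivo* drug-response AUC values
(area under the dose-response viability curve — not to be confused with classifier
ROC-AUC), can a transcriptomic signature measured at diagnosis predict whether a
patient's cells respond to a given inhibitor?  It is aimed at computational biologists
evaluating feature-selection strategies for p ≫ n expression classifiers, and at
method developers who need a fully synthetic, ground-truthed test bed for such
pipelines.

## The method

For each inhibitor the workflow is:

1. **Quantile labelling.**  Samples with response AUC strictly above the 0.75 quantile
   of the cohort distribution form one class, strictly below the 0.25 quantile the
   other; the middle half is excluded.  Which tail is called *responder* is an explicit
   `direction` parameter.
2. **Phase 1 / Phase 2 split.**  The labeled cohort is shuffled and split 80/20
   (stratified).  Phase 1 carries model optimisation under 5-fold CV; Phase 2 is a
   holdout scored exactly once.
3. **Feature selection** (inside each training fold), one of four strategies, each
   returning a fixed signature of k = 30 features:
   - `shap` — rank genes by mean |φᵢ|, where φᵢ are exact per-sample Shapley
     attributions of a gradient-boosted tree model, computed by the polynomial-time
     path algorithm with path-dependent (training-cover) expectations;
   - `dge` — rank genes by moderated-t p-value on log₂(CPM + 0.5), with empirical-Bayes
     variance shrinkage s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d), the prior (d₀, s₀²) fitted by
     method of moments on log variances, after removing genes below 1 CPM group mean in
     both classes; BH-FDR is reported;
   - `pca` — first k principal components fitted on the training split only;
   - `random` — k genes drawn uniformly, the no-information baseline.
4. **Classifier tuning.**  Random-search over fixed hyperparameter grids for three
   tree ensembles — random forest (`rf`) and two gradient-boosting variants (`gb_a`,
   XGBoost-style with per-level column subsampling and min-split-loss; `gb_b`,
   LightGBM-style without) — every sampled configuration scored by mean CV ROC-AUC on
   shared folds.
5. **Validation.**  The winning configuration is refit on all of Phase 1 with a
   re-selected signature and scored on the holdout: ROC-AUC (Mann-Whitney rank
   formulation), confusion matrix, sensitivity, specificity.  The whole procedure runs
   10 times (configurable) and results are averaged.

Two bespoke statistics summarise the grid of (strategy × classifier) cells:

- **Divergence AUC** — within-drug normalised deviation D = (a − m)/m of a cell's
  ROC-AUC from the drug's mean over cells; removes between-drug variance so cells are
  comparable across drugs (per-drug divergences sum to zero by construction).
- **Conservation index** — for the R = folds × repeats selection rounds of a cell with
  feature occurrence counts cᵢ, CI = (Σcᵢ²/Σcᵢ)/(R/2), i.e. the count-weighted mean
  occurrence normalised so identical rounds give 2.0 and fully disjoint rounds 2/R;
  binned low (< 0.5), mid (0.5–1.5), high (> 1.5).

A cross-inhibitor **feature swap** probes signature specificity: inhibitor B's Phase-2
refit is repeated with its tuned hyperparameters and split unchanged but with inhibitor
A's signature, and the swapped holdout AUC is compared with the native one.

A synthetic-data module generates fully ground-truthed cohorts (skew-normal latent
response, log-normal CPM, planted response-associated genes), so every stage is
testable without any external download.

## Worked example

Generate a synthetic cohort with 10 planted response-associated genes, label it, and
run the pipeline at desk scale:

```bash
rcdml simulate --out demo/sim --n-genes 2000 --n-samples 300 --seed 42
rcdml label --resp demo/sim/response.csv --inhibitor SYN-1
rcdml run --expr demo/sim/expression.csv --resp demo/sim/response.csv \
      --inhibitor SYN-1 --strategies shap,dge,random --classifiers rf \
      --repeats 2 --n-iter 4 --desk-scale --seed 7 --out demo/run
```

which prints

```
SYN-1: 75 responders, 75 non-responders, 150 excluded (thresholds 120.3 / 177.9)
SYN-1: shap+rf=1.000, dge+rf=1.000, random+rf=0.433
```

The first line is the quartile labelling of the 300-sample cohort (the middle half is
excluded by design).  The second line gives mean holdout ROC-AUC per strategy: the
Shapley and differential-expression signatures find the planted genes and separate the
classes perfectly, while 30 random genes carry no signal (AUC ≈ 0.5).  Per-cell
metrics, per-fold signatures, a divergence table and a manifest with all seeds land
under `demo/run/`.

The same API is available in Python:

```python
from rcdml.synthetic import SyntheticSpec, generate_cohort
from rcdml.dataio import match_cohort
from rcdml.pipeline import run_inhibitor

expr, resp, truth = generate_cohort(SyntheticSpec(seed=42))
report = run_inhibitor(match_cohort(expr, resp, "SYN-1"),
                       strategies=["shap"], classifiers=["rf"], repeats=3, seed=7)
print(report.mean_holdout_auc("shap", "rf"))
```

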