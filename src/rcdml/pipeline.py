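"""Orchestration of the full per-inhibitor protocol.

For one inhibitor the workflow is, per repeat:

1. label the whole cohort by response quantiles (labels are a property of the
   cohort, computed before any split);
2. stratified split of the labeled samples into Phase 1 (80%, model
   optimisation) and Phase 2 (20%, holdout — untouched until the end);
3. 5-fold stratified CV over Phase 1; inside every fold the feature signature
   is re-selected on the training folds only;
4. random-search hyperparameter tuning, every configuration scored on the
   same folds; the best configuration's per-fold AUCs form the CV result;
5. the signature is re-selected on all of Phase 1, the winning configuration
   is refit on Phase 1, and the holdout is scored exactly once.

The whole procedure runs ``repeats`` times with seeds derived from a single
master seed via a splittable seed tree, and the report keeps every per-repeat
cell so that aggregates, conservation indices and swap experiments can be
recomputed from it.

Classifiers and PCA consume log2(CPM + 0.5); the differential-expression and
expression-filter steps take raw CPM and transform internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .dataio import MatchedCohort
from .evaluation import ConfusionMatrix, confusion, roc_auc
from .feature_selection import (
    FeatureRanking,
    dge_select,
    pca_select,
    random_select,
    shap_rank,
)
from .labeling import Direction, ResponseLabels, assign_labels
from .modeling import (
    ClassifierSpec,
    CvResult,
    DESK_GRIDS,
    fit,
    predict_scores,
    search_over_folds,
)

__all__ = [
    "SplitPlan",
    "SearchSettings",
    "RepeatResult",
    "ExperimentReport",
    "make_split",
    "run_inhibitor",
    "run_feature_swap",
]

GENE_STRATEGIES = ("shap", "dge", "random")
ALL_STRATEGIES = ("shap", "dge", "pca", "random")
LOG_OFFSET = 0.5


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SplitPlan:
    """Phase-1 / Phase-2 partition plus fold assignments over Phase 1."""

    phase1_ids: list[str]
    phase2_ids: list[str]
    fold_of: dict[str, int]
    holdout_frac: float
    folds: int
    seed: int
    repeat_index: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.phase1_ids) & set(self.phase2_ids)
        if overlap:
            raise ValueError(f"phase-1/phase-2 overlap: {sorted(overlap)[:5]}")
        if set(self.fold_of) != set(self.phase1_ids):
            raise ValueError("folds do not partition phase-1")

    def fold_members(self, fold: int) -> list[str]:
        return [s for s in self.phase1_ids if self.fold_of[s] == fold]


def make_split(
    sample_ids: Sequence[str],
    y: Sequence[int] | np.ndarray,
    holdout_frac: float = 0.2,
    folds: int = 5,
    seed: int = 0,
    repeat_index: int = 0,
    inhibitor: str = "?",
) -> SplitPlan:
    """Seeded, class-stratified Phase-1/Phase-2 split with CV folds.

    Operates on labeled (non-excluded) samples only; stratification keeps the
    two classes balanced in every fold, which at quartile-labelling cohort
    sizes prevents single-class folds.
    """
    ids = list(sample_ids)
    y = np.asarray(y)
    if len(ids) != len(y):
        raise ValueError("sample_ids and labels differ in length")
    n = len(ids)
    if n * (1 - holdout_frac) < folds:
        raise ValueError(
            f"inhibitor {inhibitor!r}: {n} labeled samples leave fewer than "
            f"{folds} per phase-1 fold"
        )
    idx = np.arange(n)
    p1, p2 = train_test_split(
        idx, test_size=holdout_frac, random_state=seed, shuffle=True, stratify=y
    )
    p1 = np.sort(p1)
    p2 = np.sort(p2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for f, (_, val) in enumerate(skf.split(p1.reshape(-1, 1), y[p1])):
        for j in val:
            fold_of[ids[p1[j]]] = f
    return SplitPlan(
        phase1_ids=[ids[i] for i in p1],
        phase2_ids=[ids[i] for i in p2],
        fold_of=fold_of,
        holdout_frac=holdout_frac,
        folds=folds,
        seed=seed,
        repeat_index=repeat_index,
    )


@dataclass
class SearchSettings:
    """Random-search scale: iterations and the grid family to sample from."""

    n_iter: int = 60
    grids: Mapping[str, dict] | None = None  # None -> full default grids
    folds: int = 5


@dataclass
class RepeatResult:
    strategy: str
    classifier: str
    repeat_index: int
    cv: CvResult
    fold_rankings: list[FeatureRanking]
    phase1_ranking: FeatureRanking
    best_params: dict
    holdout_auc: float
    confusion: ConfusionMatrix
    fit_seed: int
    search_seed: int

    @property
    def sensitivity(self) -> float | None:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> float | None:
        return self.confusion.specificity


@dataclass
class ExperimentReport:
    inhibitor: str
    strategies: list[str]
    classifiers: list[str]
    k: int
    repeats: int
    master_seed: int
    labels: ResponseLabels
    splits: list[SplitPlan]
    cells: dict[tuple[str, str], list[RepeatResult]]

    def mean_holdout_auc(self, strategy: str, classifier: str) -> float:
        return float(np.mean([r.holdout_auc for r in self.cells[(strategy, classifier)]]))

    def mean_cv_auc(self, strategy: str, classifier: str) -> float:
        return float(np.mean([r.cv.mean_auc for r in self.cells[(strategy, classifier)]]))

    def selections(self, strategy: str, classifier: str) -> list[list[str]]:
        """All per-fold signatures of a cell (folds x repeats selection rounds)."""
        out: list[list[str]] = []
        for r in self.cells[(strategy, classifier)]:
            out.extend(rk.feature_ids for rk in r.fold_rankings)
        return out

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for (s, c), results in self.cells.items():
            for r in results:
                cm = r.confusion
                rows.append(
                    {
                        "inhibitor": self.inhibitor,
                        "strategy": s,
                        "classifier": c,
                        "repeat": r.repeat_index,
                        "cv_auc": r.cv.mean_auc,
                        "holdout_auc": r.holdout_auc,
                        "sensitivity": cm.sensitivity,
                        "specificity": cm.specificity,
                        "tp": cm.tp,
                        "fp": cm.fp,
                        "tn": cm.tn,
                        "fn": cm.fn,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class _StrategyFolds:
    """Model-ready matrices for one strategy in one repeat."""

    fold_data: list[tuple[pd.DataFrame, np.ndarray, pd.DataFrame, np.ndarray]]
    fold_rankings: list[FeatureRanking]
    phase1_ranking: FeatureRanking
    X_phase1: pd.DataFrame
    X_holdout: pd.DataFrame


def _select_and_transform(
    strategy: str,
    cpm_train: pd.DataFrame,
    log_train: pd.DataFrame,
    log_test: pd.DataFrame,
    y_train: np.ndarray,
    k: int,
    seed: int,
) -> tuple[FeatureRanking, pd.DataFrame, pd.DataFrame]:
    """Run one selection strategy on a training split; transform both splits."""
    if strategy == "shap":
        ranking = shap_rank(log_train, y_train, k, seed=seed)
    elif strategy == "dge":
        ranking = dge_select(cpm_train, y_train, k, log_offset=LOG_OFFSET)
    elif strategy == "random":
        ranking = random_select(list(log_train.columns), k, seed=seed)
    elif strategy == "pca":
        ranking, proj = pca_select(log_train, log_test, k)
        return ranking, proj.train_transformed, proj.test_transformed
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    genes = ranking.feature_ids
    return ranking, log_train[genes], log_test[genes]


def _prepare_strategy(
    strategy: str,
    split: SplitPlan,
    cpm: pd.DataFrame,  # samples x genes, CPM
    log: pd.DataFrame,  # samples x genes, log2(CPM + offset)
    y: pd.Series,  # sample -> 0/1 over labeled samples
    k: int,
    seeds: list[int],
) -> _StrategyFolds:
    p1 = split.phase1_ids
    p2 = split.phase2_ids
    fold_data = []
    fold_rankings = []
    for f in range(split.folds):
        val_ids = split.fold_members(f)
        tr_ids = [s for s in p1 if split.fold_of[s] != f]
        ranking, X_tr, X_val = _select_and_transform(
            strategy,
            cpm.loc[tr_ids],
            log.loc[tr_ids],
            log.loc[val_ids],
            y.loc[tr_ids].to_numpy(),
            k,
            seeds[f],
        )
        fold_rankings.append(ranking)
        fold_data.append((X_tr, y.loc[tr_ids].to_numpy(), X_val, y.loc[val_ids].to_numpy()))
    phase1_ranking, X_phase1, X_holdout = _select_and_transform(
        strategy,
        cpm.loc[p1],
        log.loc[p1],
        log.loc[p2],
        y.loc[p1].to_numpy(),
        k,
        seeds[split.folds],
    )
    return _StrategyFolds(
        fold_data=fold_data,
        fold_rankings=fold_rankings,
        phase1_ranking=phase1_ranking,
        X_phase1=X_phase1,
        X_holdout=X_holdout,
    )


def run_inhibitor(
    cohort: MatchedCohort,
    strategies: Sequence[str] = ALL_STRATEGIES,
    classifiers: Sequence[str] = ("rf", "gb_a", "gb_b"),
    k: int = 30,
    repeats: int = 10,
    seed: int = 0,
    low_q: float = 0.25,
    high_q: float = 0.75,
    direction: Direction = Direction.HIGH_AUC_IS_RESPONDER,
    search: SearchSettings | None = None,
    holdout_frac: float = 0.2,
) -> ExperimentReport:
    """Full protocol for one inhibitor across strategies x classifiers x repeats."""
    search = search or SearchSettings()
    unknown = set(strategies) - set(ALL_STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}")

    labels = assign_labels(
        cohort.response_auc, cohort.sample_ids, low_q=low_q, high_q=high_q,
        direction=direction,
    )
    y = labels.binary()
    labeled_ids = list(y.index)
    cpm = cohort.expression.samples_by_genes().loc[labeled_ids]
    log = np.log2(cpm + LOG_OFFSET)

    master = np.random.SeedSequence(seed)
    repeat_ss = master.spawn(repeats)
    cells: dict[tuple[str, str], list[RepeatResult]] = {
        (s, c): [] for s in strategies for c in classifiers
    }
    splits: list[SplitPlan] = []

    for r in range(repeats):
        split_ss, select_ss, model_ss = repeat_ss[r].spawn(3)
        split = make_split(
            labeled_ids,
            y.to_numpy(),
            holdout_frac=holdout_frac,
            folds=search.folds,
            seed=_seed_int(split_ss),
            repeat_index=r,
            inhibitor=cohort.inhibitor,
        )
        splits.append(split)

        strat_ss = select_ss.spawn(len(strategies))
        prepared: dict[str, _StrategyFolds] = {}
        for si, s in enumerate(strategies):
            sel_seeds = [_seed_int(ch) for ch in strat_ss[si].spawn(search.folds + 1)]
            prepared[s] = _prepare_strategy(s, split, cpm, log, y, k, sel_seeds)

        cell_ss = model_ss.spawn(len(strategies) * len(classifiers))
        ci = 0
        for s in strategies:
            sf = prepared[s]
            for c in classifiers:
                search_seed = _seed_int(cell_ss[ci])
                fit_seed = (search_seed + 1) % (2**31)
                ci += 1
                grid = None if search.grids is None else dict(search.grids[c])
                spec = ClassifierSpec(
                    algorithm=c, param_grid=grid, n_iter=search.n_iter, seed=search_seed
                )
                best_params, cv = search_over_folds(spec, sf.fold_data)
                model = fit(c, best_params, sf.X_phase1, y.loc[split.phase1_ids], fit_seed)
                scores = predict_scores(model, sf.X_holdout)
                y_hold = y.loc[split.phase2_ids].to_numpy()
                cells[(s, c)].append(
                    RepeatResult(
                        strategy=s,
                        classifier=c,
                        repeat_index=r,
                        cv=cv,
                        fold_rankings=sf.fold_rankings,
                        phase1_ranking=sf.phase1_ranking,
                        best_params=best_params,
                        holdout_auc=roc_auc(scores, y_hold),
                        confusion=confusion(scores, y_hold),
                        fit_seed=fit_seed,
                        search_seed=search_seed,
                    )
                )

    return ExperimentReport(
        inhibitor=cohort.inhibitor,
        strategies=list(strategies),
        classifiers=list(classifiers),
        k=k,
        repeats=repeats,
        master_seed=seed,
        labels=labels,
        splits=splits,
        cells=cells,
    )


def run_feature_swap(
    report_a: ExperimentReport,
    cohort_b: MatchedCohort,
    report_b: ExperimentReport,
    classifiers: Sequence[str] | None = None,
    strategies: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cross-inhibitor specificity control: refit B with A's signatures.

    For every (gene-based strategy, classifier, repeat) cell, inhibitor B's
    Phase-2 refit is repeated with its split, labels, tuned hyperparameters
    and fit seed unchanged, but with the Phase-1 signature replaced by the one
    inhibitor A selected on its own Phase 1.  Swapping a report with itself
    therefore reproduces the native holdout AUC exactly.  PCA signatures are
    rejected: component labels are not transferable across cohorts.

    Returns a tidy frame with native and swapped holdout AUC per cell and an
    ``underperformed`` flag (swapped < native).
    """
    strategies = list(strategies or [s for s in report_b.strategies if s in GENE_STRATEGIES])
    if "pca" in strategies:
        raise ValueError("pca signatures are not transferable between cohorts")
    classifiers = list(classifiers or report_b.classifiers)
    for s in strategies:
        if s not in report_a.strategies:
            raise ValueError(f"strategy {s!r} missing from the donor report")

    y = report_b.labels.binary()
    cpm = cohort_b.expression.samples_by_genes().loc[list(y.index)]
    log = np.log2(cpm + LOG_OFFSET)
    gene_pool = set(log.columns)

    rows = []
    for s in strategies:
        for c in classifiers:
            native_cells = report_b.cells[(s, c)]
            donor_cells = report_a.cells[(s, c)]
            n_rep = min(len(native_cells), len(donor_cells))
            for r in range(n_rep):
                native = native_cells[r]
                donor_sig = donor_cells[r].phase1_ranking.feature_ids
                missing = [g for g in donor_sig if g not in gene_pool]
                if missing:
                    raise ValueError(
                        f"donor signature genes absent from {cohort_b.inhibitor!r}: "
                        f"{missing[:5]}"
                    )
                split = report_b.splits[r]
                X_p1 = log.loc[split.phase1_ids, donor_sig]
                X_hold = log.loc[split.phase2_ids, donor_sig]
                model = fit(c, native.best_params, X_p1, y.loc[split.phase1_ids],
                            native.fit_seed)
                swapped_auc = roc_auc(
                    predict_scores(model, X_hold), y.loc[split.phase2_ids].to_numpy()
                )
                rows.append(
                    {
                        "strategy": s,
                        "classifier": c,
                        "repeat": r,
                        "native_auc": native.holdout_auc,
                        "swapped_auc": swapped_auc,
                        "underperformed": swapped_auc < native.holdout_auc,
                    }
                )
    return pd.DataFrame(rows)
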