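"""Signature selection: tree-Shapley ranking, moderated-t DGE, PCA, random baseline.

Every strategy maps a training split (samples x genes, CPM) plus binary labels
to an ordered list of exactly ``k`` features.  Gene-based strategies return
gene ids; the PCA strategy returns component labels together with the fitted
projection (fit on the training split only, then applied to the test split).

The moderated t-statistic shrinks each gene's pooled variance toward a prior
variance s0^2 with prior degrees of freedom d0, both estimated from the
ensemble of gene variances by the method of moments on log variances:
log s_g^2 given sigma_g^2 is a scaled-F / log-chi^2 variable, so

    e_g = log s_g^2 - digamma(d/2) + log(d/2)

has mean log sigma^2-ish and excess variance trigamma(d0/2); solving
trigamma(d0/2) = var(e) - trigamma(d/2) by Newton iteration gives d0, and the
mean equation gives s0^2.  The posterior variance is

    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d),

and the moderated t uses d0 + d degrees of freedom.  When the observed
variances are no more dispersed than sampling alone explains, d0 = +inf and
every gene is shrunk completely to s0^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureRanking",
    "ModeratedTResult",
    "PcaProjection",
    "cpm_filter",
    "moderated_t_test",
    "dge_select",
    "shap_rank",
    "pca_select",
    "random_select",
    "DEFAULT_SHAP_BASE_PARAMS",
]


@dataclass
class FeatureRanking:
    strategy: str  # {shap, dge, pca, random, fixed}
    entries: list[tuple[str, float]]  # (feature_id, score), score descending
    k: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.entries) != self.k:
            raise ValueError(f"expected {self.k} entries, got {len(self.entries)}")
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("entries not sorted by score descending")

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.entries]


def _sort_ranked(ids: Sequence[str], scores: np.ndarray, k: int) -> list[tuple[str, float]]:
    """Top-k by score descending, ties broken lexicographically by id."""
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return [(ids[i], float(scores[i])) for i in order[:k]]


# ----------------------------------------------------------------------
# expression filter
# ----------------------------------------------------------------------
def cpm_filter(
    train_X: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    min_cpm: float = 1.0,
    within_group: str = "mean",
) -> tuple[list[str], int]:
    """Keep genes with at least ``min_cpm`` CPM in either label group.

    ``within_group="mean"`` keeps gene g when its group-mean CPM reaches the
    cutoff in at least one group (the filterByExpr-like reading);
    ``"all"`` requires every sample of one group to reach it.
    Returns (kept gene ids, number removed).
    """
    y = np.asarray(labels)
    if len(y) != len(train_X):
        raise ValueError("labels do not align with samples")
    groups = [train_X.loc[y == cls] for cls in (0, 1)]
    if within_group == "mean":
        ok = [g.mean(axis=0) >= min_cpm for g in groups]
    elif within_group == "all":
        ok = [(g >= min_cpm).all(axis=0) for g in groups]
    else:
        raise ValueError("within_group must be 'mean' or 'all'")
    keep = ok[0] | ok[1]
    kept = list(train_X.columns[keep])
    return kept, int((~keep).sum())


# ----------------------------------------------------------------------
# moderated t / differential expression
# ----------------------------------------------------------------------
@dataclass
class ModeratedTResult:
    table: pd.DataFrame  # per gene: mean_diff, s2, s2_post, t, p, fdr
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    df_residual: int
    df_total: float

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.s0_sq <= 0:
            raise ValueError("prior d0 and s0^2 must be positive")


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) to gene variances."""
    s2 = np.maximum(np.asarray(s2, dtype=float), 0.0)
    if s2.size < 2:
        return np.inf, float(s2[0]) if s2.size else 1.0
    med = np.median(s2)
    if med == 0:
        warnings.warn("more than half of residual variances are exactly zero")
        med = 1.0
    s2 = np.maximum(s2, 1e-5 * med)  # keep log finite for near-constant genes
    z = np.log(s2)
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # variances no more dispersed than chi^2 sampling: complete shrinkage
        return np.inf, float(s2.mean())
    half_d0 = _trigamma_inverse(excess)
    if not np.isfinite(half_d0):
        return np.inf, float(s2.mean())
    d0 = 2.0 * half_d0
    s0_sq = np.exp(e_mean + special.polygamma(0, half_d0) - np.log(half_d0))
    return float(d0), float(s0_sq)


def moderated_t_test(
    train_X: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    log_offset: float = 0.5,
    log_transform: bool = True,
) -> ModeratedTResult:
    """Empirical-Bayes two-group test per gene on log2(CPM + offset).

    ``train_X`` is samples x genes in CPM; ``labels`` is 0/1.  The reported
    mean difference is group1 - group0 on the log2 scale.
    """
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per class")
    X = train_X.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + log_offset)
    g1 = X[y == 1]
    g0 = X[y == 0]
    m1 = g1.mean(axis=0)
    m0 = g0.mean(axis=0)
    d = n1 + n0 - 2
    ss = ((g1 - m1) ** 2).sum(axis=0) + ((g0 - m0) ** 2).sum(axis=0)
    s2 = ss / d

    d0, s0_sq = fit_f_dist(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    # total df capped at the pooled residual df of the whole experiment
    df_total = min(d0 + d, s2.size * d)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    fdr = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "mean_diff": diff,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "fdr": fdr,
        },
        index=train_X.columns,
    )
    return ModeratedTResult(
        table=table, d0=float(d0), s0_sq=float(s0_sq), df_residual=d, df_total=float(df_total)
    )


def dge_select(
    train_X: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    k: int,
    fdr_alpha: float = 0.05,
    min_cpm: float = 1.0,
    log_offset: float = 0.5,
) -> FeatureRanking:
    """Differential-expression signature: top-k genes by moderated-t p-value.

    Always returns k genes (the pipeline needs a fixed-size signature); the
    number of them passing FDR < ``fdr_alpha`` is reported in ``extra``.
    """
    kept, n_removed = cpm_filter(train_X, labels, min_cpm=min_cpm)
    if k > len(kept):
        raise ValueError(
            f"k={k} exceeds the {len(kept)} genes surviving the expression filter"
        )
    res = moderated_t_test(train_X[kept], labels, log_offset=log_offset)
    with np.errstate(divide="ignore"):
        score = -np.log10(np.maximum(res.table["p"].to_numpy(), 1e-300))
    entries = _sort_ranked(kept, score, k)
    chosen = [f for f, _ in entries]
    n_pass = int((res.table.loc[chosen, "fdr"] < fdr_alpha).sum())
    return FeatureRanking(
        strategy="dge",
        entries=entries,
        k=k,
        extra={
            "n_fdr_pass": n_pass,
            "n_filtered_out": n_removed,
            "d0": res.d0,
            "s0_sq": res.s0_sq,
        },
    )


# ----------------------------------------------------------------------
# tree-Shapley ranking
# ----------------------------------------------------------------------
# Attribution-oriented booster: heavy per-node column subsampling plus row
# bagging diversify splits across correlated predictors, so Shapley credit is
# shared by all members of a redundant signature instead of concentrating on
# the few genes a deterministic greedy booster happens to reuse.
DEFAULT_SHAP_BASE_PARAMS: dict = {
    "n_estimators": 300,
    "max_depth": 4,
    "learning_rate": 0.05,
    "subsample": 0.63,
    "colsample_bynode": 0.1,
    "tree_method": "hist",
    "n_jobs": 1,
}


def shap_rank(
    train_X: pd.DataFrame,
    train_y: Sequence[int] | np.ndarray,
    k: int,
    base_model_params: dict | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Rank genes by mean |Shapley attribution| of a boosted-tree model.

    A gradient-boosted tree ensemble (XGBoost with its stock settings, not the
    tuned Phase-1 parameters) is fitted on the training split; per-sample,
    per-gene Shapley values are computed by the exact path algorithm in
    :mod:`rcdml.treeshap`; the global score of a gene is the mean absolute
    attribution over the training samples.
    """
    from xgboost import XGBClassifier

    from .treeshap import TreeEnsemble, mean_abs_attribution, tree_shap

    y = np.asarray(train_y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    ids = list(train_X.columns)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} genes")
    params = dict(DEFAULT_SHAP_BASE_PARAMS)
    if base_model_params:
        params.update(base_model_params)
    model = XGBClassifier(random_state=int(seed), **params)
    X = train_X.to_numpy(dtype=float)
    model.fit(X, y)
    phi = tree_shap(TreeEnsemble.from_xgboost(model), X)
    score = mean_abs_attribution(phi)[: len(ids)]
    return FeatureRanking(strategy="shap", entries=_sort_ranked(ids, score, k), k=k, seed=seed)


# ----------------------------------------------------------------------
# PCA projection
# ----------------------------------------------------------------------
@dataclass
class PcaProjection:
    loadings: pd.DataFrame  # genes x k
    mean: pd.Series  # training mean per gene
    train_transformed: pd.DataFrame  # samples x k
    test_transformed: pd.DataFrame  # samples x k
    explained_variance_ratio: np.ndarray

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        centered = X[self.mean.index] - self.mean
        out = centered.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(out, index=X.index, columns=self.loadings.columns)


def pca_select(
    train_X: pd.DataFrame, test_X: pd.DataFrame, k: int
) -> tuple[FeatureRanking, PcaProjection]:
    """First-k principal components fitted on the training split only.

    The test split is centred with the training mean and projected on the
    training loadings; it never influences the fit.
    """
    from sklearn.decomposition import PCA

    if k > min(len(train_X), train_X.shape[1]):
        raise ValueError(
            f"k={k} exceeds min(n_train_samples={len(train_X)}, n_genes={train_X.shape[1]})"
        )
    pca = PCA(n_components=k, svd_solver="full")
    train_t = pca.fit_transform(train_X.to_numpy(dtype=float))
    labels = [f"PC{i + 1}" for i in range(k)]
    proj = PcaProjection(
        loadings=pd.DataFrame(pca.components_.T, index=train_X.columns, columns=labels),
        mean=pd.Series(pca.mean_, index=train_X.columns),
        train_transformed=pd.DataFrame(train_t, index=train_X.index, columns=labels),
        test_transformed=pd.DataFrame(
            pca.transform(test_X.to_numpy(dtype=float)), index=test_X.index, columns=labels
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    entries = [(lab, float(r)) for lab, r in zip(labels, pca.explained_variance_ratio_)]
    ranking = FeatureRanking(strategy="pca", entries=entries, k=k)
    return ranking, proj


# ----------------------------------------------------------------------
# random baseline
# ----------------------------------------------------------------------
def random_select(gene_ids: Sequence[str], k: int, seed: int) -> FeatureRanking:
    """k genes drawn uniformly without replacement from a seeded generator."""
    ids = list(gene_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} genes")
    rng = np.random.default_rng(seed)
    chosen = [ids[i] for i in rng.choice(len(ids), size=k, replace=False)]
    entries = [(f, 1.0) for f in sorted(chosen)]
    return FeatureRanking(strategy="random", entries=entries, k=k, seed=seed)
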