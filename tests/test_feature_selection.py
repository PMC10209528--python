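"""Expression filter, moderated-t statistics and the four selection strategies."""

import subprocess
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rcdml.feature_selection import (
    FeatureRanking,
    cpm_filter,
    dge_select,
    moderated_t_test,
    pca_select,
    random_select,
    shap_rank,
)


def _frame(vals: np.ndarray, prefix: str = "g") -> pd.DataFrame:
    return pd.DataFrame(vals, columns=[f"{prefix}{i}" for i in range(vals.shape[1])])


# ----------------------------------------------------------------------
# cpm_filter
# ----------------------------------------------------------------------
def test_cpm_filter_requires_one_expressed_group():
    # gene 0: low in both groups -> removed; gene 1: high in one group -> kept
    X = _frame(np.array(
        [[0.4, 2.0], [0.6, 2.0],  # group 0
         [0.5, 0.0], [0.5, 0.0]]  # group 1
    ))
    kept, n_removed = cpm_filter(X, [0, 0, 1, 1])
    assert kept == ["g1"]
    assert n_removed == 1


def test_cpm_filter_matches_brute_force_on_random_fixture():
    rng = np.random.default_rng(11)
    X = _frame(rng.gamma(0.8, 2.0, size=(30, 100)))
    y = rng.integers(0, 2, 30)
    kept, _ = cpm_filter(X, y)
    expected = [
        c
        for c in X.columns
        if X.loc[y == 0, c].mean() >= 1.0 or X.loc[y == 1, c].mean() >= 1.0
    ]
    assert kept == expected


def test_cpm_filter_all_samples_mode_is_stricter():
    X = _frame(np.array([[5.0], [0.2], [5.0], [5.0]]))
    y = [0, 0, 1, 1]
    assert cpm_filter(X, y, within_group="mean")[0] == ["g0"]
    assert cpm_filter(X, y, within_group="all")[0] == ["g0"]  # group 1 all >= 1
    X2 = _frame(np.array([[5.0], [0.2], [5.0], [0.2]]))
    assert cpm_filter(X2, y, within_group="all")[0] == []


# ----------------------------------------------------------------------
# moderated t
# ----------------------------------------------------------------------
def test_equal_group_means_give_t_zero_p_one():
    rng = np.random.default_rng(0)
    base = rng.lognormal(2, 1, size=(6, 20))
    X = pd.DataFrame(np.vstack([base, base]), columns=[f"g{i}" for i in range(20)])
    y = [0] * 6 + [1] * 6
    res = moderated_t_test(X, y)
    np.testing.assert_allclose(res.table["t"], 0.0, atol=1e-12)
    np.testing.assert_allclose(res.table["p"], 1.0, atol=1e-12)


def test_equal_variances_reduce_to_pooled_t():
    """With identical gene variances the posterior equals the sample variance
    and the moderated t equals the ordinary pooled two-sample t."""
    rng = np.random.default_rng(1)
    n1 = n0 = 8
    G = 40
    logx = rng.normal(4, 1, size=(n1 + n0, G))
    # force every gene's pooled variance to the same value on the log scale
    y = np.array([0] * n0 + [1] * n1)
    for g in range(G):
        for cls in (0, 1):
            block = logx[y == cls, g]
            centred = block - block.mean()
            logx[y == cls, g] = block.mean() + centred / centred.std(ddof=1)
    X = pd.DataFrame(2.0 ** logx - 0.5, columns=[f"g{i}" for i in range(G)])
    res = moderated_t_test(X, y)
    np.testing.assert_allclose(res.table["s2_post"], res.table["s2"], rtol=1e-10)
    t_plain = np.array(
        [
            stats.ttest_ind(np.log2(X.iloc[:, g] + 0.5)[y == 1],
                            np.log2(X.iloc[:, g] + 0.5)[y == 0]).statistic
            for g in range(G)
        ]
    )
    np.testing.assert_allclose(res.table["t"], t_plain, rtol=1e-8)


def test_null_type_one_error_calibrated():
    rng = np.random.default_rng(42)
    n = 20
    cpm = 2.0 ** rng.normal(5, 1, size=(2 * n, 2000))
    X = pd.DataFrame(cpm, columns=[f"G{i}" for i in range(2000)])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    res = moderated_t_test(X, y)
    rate = float((res.table["p"] < 0.05).mean())
    assert 0.04 <= rate <= 0.06


def test_moderated_t_matches_limma_oracle():
    """Independent cross-check against Bioconductor limma on a tiny fixture."""
    rng = np.random.default_rng(8)
    G = 80
    logx = rng.normal(4, 1, G) + rng.normal(0, 1, size=(14, G)) * rng.uniform(
        0.3, 2.0, G
    )
    logx[7:, :6] += 1.2
    y = np.array([0] * 7 + [1] * 7)
    X = pd.DataFrame(2.0 ** logx - 0.5, columns=[f"g{i}" for i in range(G)])
    X[X < 0] = 0.0
    res = moderated_t_test(X, y)

    log_for_r = np.log2(X.to_numpy() + 0.5).T
    lines = ["\n".join(",".join(f"{v!r}" for v in row) for row in log_for_r)]
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        np.savetxt(os.path.join(td, "x.csv"), log_for_r, delimiter=",")
        rcode = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.csv(file.path('{td}', 'x.csv'), header=FALSE))
        design <- cbind(1, c(rep(0, 7), rep(1, 7)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                          d0=fit$df.prior, s0=fit$s2.prior)
        write.csv(out, file.path('{td}', 'out.csv'), row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(os.path.join(td, "out.csv"))
    np.testing.assert_allclose(res.table["t"], ref["t"], atol=1e-8)
    np.testing.assert_allclose(res.table["p"], ref["p"], atol=1e-8)
    assert res.d0 == pytest.approx(ref["d0"][0], rel=1e-6)
    assert res.s0_sq == pytest.approx(ref["s0"][0], rel=1e-6)


def test_fewer_than_two_per_class_rejected():
    X = _frame(np.ones((3, 5)))
    with pytest.raises(ValueError, match="2 samples per class"):
        moderated_t_test(X, [0, 1, 1])


# ----------------------------------------------------------------------
# dge_select
# ----------------------------------------------------------------------
def test_dge_recovers_planted_genes(labeled_training_split):
    cpm, y, truth = labeled_training_split
    ranking = dge_select(cpm, y, k=30)
    assert ranking.k == 30 and len(ranking.entries) == 30
    hits = set(ranking.feature_ids) & set(truth.informative_genes)
    assert len(hits) == len(truth.informative_genes)
    assert ranking.extra["n_fdr_pass"] >= len(truth.informative_genes)


def test_dge_on_pure_null_returns_k_but_nothing_passes_fdr():
    rng = np.random.default_rng(21)
    X = _frame(2.0 ** rng.normal(4, 1, size=(40, 300)))
    y = rng.permutation([0] * 20 + [1] * 20)
    ranking = dge_select(X, y, k=30)
    assert len(ranking.entries) == 30
    assert ranking.extra["n_fdr_pass"] == 0


def test_dge_k_larger_than_filtered_pool_is_error():
    rng = np.random.default_rng(3)
    X = _frame(2.0 ** rng.normal(4, 1, size=(12, 10)))
    y = [0] * 6 + [1] * 6
    with pytest.raises(ValueError, match="exceeds"):
        dge_select(X, y, k=11)


def test_dge_pvalues_invariant_to_gene_order(labeled_training_split):
    cpm, y, _ = labeled_training_split
    cols = list(cpm.columns)[::-1]
    a = dge_select(cpm, y, k=15)
    b = dge_select(cpm[cols], y, k=15)
    assert a.feature_ids == b.feature_ids


# ----------------------------------------------------------------------
# shap_rank
# ----------------------------------------------------------------------
def test_shap_rank_finds_planted_genes(labeled_training_split):
    cpm, y, truth = labeled_training_split
    log = np.log2(cpm + 0.5)
    ranking = shap_rank(log, y, k=30, seed=0)
    assert len(ranking.entries) == 30
    hits = set(ranking.feature_ids) & set(truth.informative_genes)
    assert len(hits) >= 8


def test_shap_rank_rejects_single_class_and_oversized_k():
    X = _frame(np.random.default_rng(0).normal(size=(10, 5)))
    with pytest.raises(ValueError, match="single class"):
        shap_rank(X, [1] * 10, k=3)
    with pytest.raises(ValueError, match="exceeds"):
        shap_rank(X, [0] * 5 + [1] * 5, k=6)


# ----------------------------------------------------------------------
# pca_select
# ----------------------------------------------------------------------
def test_pca_components_orthonormal_and_variance_ordered():
    rng = np.random.default_rng(9)
    X = _frame(rng.normal(size=(40, 20)))
    ranking, proj = pca_select(X, X.iloc[:5], k=6)
    L = proj.loadings.to_numpy()
    np.testing.assert_allclose(L.T @ L, np.eye(6), atol=1e-8)
    evr = proj.explained_variance_ratio
    assert all(a >= b - 1e-12 for a, b in zip(evr, evr[1:]))
    assert ranking.feature_ids == [f"PC{i}" for i in range(1, 7)]


def test_pca_variance_concentrated_on_one_gene():
    rng = np.random.default_rng(10)
    X = _frame(rng.normal(size=(50, 8)) * 0.01)
    X["g3"] = rng.normal(scale=10.0, size=50)
    ranking, proj = pca_select(X, X.iloc[:3], k=2)
    assert abs(proj.loadings.loc["g3", "PC1"]) > 0.99
    assert proj.explained_variance_ratio[0] > 0.99


def test_pca_eigenvalues_match_brute_force_eigendecomposition():
    rng = np.random.default_rng(12)
    X = _frame(rng.normal(size=(30, 10)))
    _, proj = pca_select(X, X.iloc[:2], k=10)
    centred = X.to_numpy() - X.to_numpy().mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(np.cov(centred.T)))[::-1]
    train_var = proj.train_transformed.to_numpy().var(axis=0, ddof=1)
    np.testing.assert_allclose(train_var, eig[:10], rtol=1e-8)


def test_pca_fit_never_touches_test_data():
    rng = np.random.default_rng(13)
    X = _frame(rng.normal(size=(30, 12)))
    test_a = _frame(rng.normal(size=(8, 12)))
    test_b = _frame(rng.normal(size=(8, 12)) * 100)
    _, proj_a = pca_select(X, test_a, k=4)
    _, proj_b = pca_select(X, test_b, k=4)
    np.testing.assert_array_equal(
        proj_a.loadings.to_numpy(), proj_b.loadings.to_numpy()
    )
    np.testing.assert_array_equal(proj_a.mean.to_numpy(), proj_b.mean.to_numpy())


def test_pca_k_too_large_is_error():
    X = _frame(np.random.default_rng(0).normal(size=(5, 10)))
    with pytest.raises(ValueError, match="exceeds"):
        pca_select(X, X, k=6)


# ----------------------------------------------------------------------
# random_select
# ----------------------------------------------------------------------
def test_random_select_deterministic_and_complete():
    ids = [f"g{i}" for i in range(50)]
    a = random_select(ids, 10, seed=99)
    b = random_select(ids, 10, seed=99)
    assert a.feature_ids == b.feature_ids
    assert random_select(ids, 50, seed=0).k == 50
    assert sorted(random_select(ids, 50, seed=0).feature_ids) == sorted(ids)


def test_random_select_uniform_over_seeds():
    ids = [f"g{i}" for i in range(200)]
    k, n_seeds = 30, 1000
    counts = {g: 0 for g in ids}
    for seed in range(n_seeds):
        for g in random_select(ids, k, seed=seed).feature_ids:
            counts[g] += 1
    p = k / len(ids)
    sigma = np.sqrt(n_seeds * p * (1 - p))
    lo, hi = n_seeds * p - 3 * sigma, n_seeds * p + 3 * sigma
    outside = sum(1 for c in counts.values() if not (lo <= c <= hi))
    # a few 3-sigma excursions among 200 genes are expected; gross bias is not
    assert outside <= 5


def test_rankings_are_sorted_with_lexicographic_tie_break():
    with pytest.raises(ValueError, match="sorted"):
        FeatureRanking(strategy="dge", entries=[("a", 1.0), ("b", 2.0)], k=2)
    r = random_select([f"g{i}" for i in range(40)], 5, seed=4)
    assert r.feature_ids == sorted(r.feature_ids)
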