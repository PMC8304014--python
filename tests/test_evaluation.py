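import numpy as np
import pandas as pd
import pytest

from truthseq.evaluation import (
    AccuracyReport,
    BenchmarkConfig,
    ClusterAssignment,
    NormalizationSpec,
    annotate_and_score,
    cluster_cells,
    dropout_ratio,
    filter_cluster_specific_genes,
    knee_curve,
    low_count_ratio,
    normalize,
    random_accuracy,
    run_benchmark,
    summarize_variance,
)


def _assignment(clusters, prefix="c"):
    cells = [f"{prefix}{i}" for i in range(len(clusters))]
    return ClusterAssignment(cells, np.asarray(clusters))


class TestAccuracy:
    def test_perfect_clustering_scores_one(self):
        labels = [("M1", "a"), ("M1", "a"), ("M2", "b"), ("M2", "b")]
        rep = annotate_and_score(_assignment([0, 0, 1, 1]), labels)
        assert rep.accuracy_sub == 1.0
        assert rep.accuracy_major == 1.0

    def test_modal_fraction(self):
        labels = [("M", "A")] * 6 + [("M", "B")] * 4
        rep = annotate_and_score(_assignment([0] * 10), labels)
        assert rep.annotation_sub[0] == "A"
        assert rep.accuracy_sub == pytest.approx(0.6)

    def test_two_cluster_hand_example(self):
        # c1 holds {A x3, B x1}, c2 holds {B x2} -> accuracy (3+2)/6
        labels = [("M", "A")] * 3 + [("M", "B")] + [("M", "B")] * 2
        rep = annotate_and_score(_assignment([0, 0, 0, 0, 1, 1]), labels)
        assert rep.annotation_sub == {0: "A", 1: "B"}
        assert rep.accuracy_sub == pytest.approx(5 / 6)

    def test_tie_breaks_to_globally_frequent_label(self):
        # cluster 0 is tied A/B; B is globally more frequent
        labels = [("M", "A"), ("M", "B"), ("M", "B"), ("M", "B")]
        rep = annotate_and_score(_assignment([0, 0, 1, 1]), labels)
        assert rep.annotation_sub[0] == "B"

    def test_major_never_below_sub_for_nested_labels(self):
        rng = np.random.default_rng(0)
        labels = [(f"M{i % 3}", f"M{i % 3}.s{i % 6}") for i in range(60)]
        for _ in range(10):
            clusters = rng.integers(0, 8, size=60)
            rep = annotate_and_score(_assignment(clusters), labels)
            assert rep.accuracy_major >= rep.accuracy_sub

    def test_disjoint_cell_sets_rejected(self):
        with pytest.raises(ValueError, match="truth"):
            annotate_and_score(
                ClusterAssignment(["x1"], np.array([0])), {"y1": ("M", "a")}
            )


class TestRandomAccuracy:
    def test_single_cluster_is_permutation_invariant(self):
        labels = [("M", "A")] * 6 + [("M", "B")] * 4
        assign = _assignment([0] * 10)
        rm, rs = random_accuracy(assign, labels, n_perm=5, seed=0)
        assert rs == pytest.approx(0.6)

    def test_baseline_below_good_clustering(self):
        labels = [("M1", "a")] * 10 + [("M2", "b")] * 10
        assign = _assignment([0] * 10 + [1] * 10)
        rep = annotate_and_score(assign, labels)
        rm, rs = random_accuracy(assign, labels, n_perm=200, seed=1)
        assert rs < rep.accuracy_sub
        assert rm < rep.accuracy_major

    def test_matches_exhaustive_permutation_on_tiny_input(self):
        import itertools

        labels = [("M", "A"), ("M", "A"), ("M", "B"), ("M", "B")]
        clusters = np.array([0, 0, 1, 2])
        assign = _assignment(clusters)
        accs = []
        for perm in set(itertools.permutations(clusters)):
            rep = annotate_and_score(_assignment(list(perm)), labels)
            accs.append(rep.accuracy_sub)
        # Monte-Carlo over uniform permutations converges to the same mean
        exhaustive = []
        for perm in itertools.permutations(range(4)):
            rep = annotate_and_score(
                _assignment([clusters[i] for i in perm]), labels
            )
            exhaustive.append(rep.accuracy_sub)
        _, rs = random_accuracy(assign, labels, n_perm=4000, seed=2)
        assert rs == pytest.approx(np.mean(exhaustive), abs=0.02)


class TestMatrixQC:
    def test_dropout_examples(self):
        assert dropout_ratio(np.zeros((3, 3))) == 1.0
        assert dropout_ratio(np.array([[0, 1], [2, 0]])) == 0.5
        assert dropout_ratio(np.ones((2, 2))) == 0.0

    def test_low_count_examples(self):
        assert low_count_ratio(np.array([[0, 1], [2, 5]]), 1) == 0.25
        assert low_count_ratio(np.zeros((2, 2)), 3) == 0.0

    def test_dropout_low_count_complementarity(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.5, size=(20, 30))
        assert dropout_ratio(X) + low_count_ratio(X, X.max()) == pytest.approx(1.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            dropout_ratio(np.empty((0, 0)))

    def test_knee_curve_sorted_descending(self):
        curve = knee_curve({"a": 5, "b": 1, "c": 3})
        assert list(curve["count"]) == [5, 3, 1]
        assert list(curve["rank"]) == [1, 2, 3]
        flat = knee_curve([2, 2, 2])
        assert (flat["count"] == 2).all()


class TestMarkerFilter:
    def test_gene_in_five_clusters_removed_everywhere(self):
        lists = {k: ["ubiquitous", f"own_{k}"] for k in range(5)}
        out = filter_cluster_specific_genes(lists)
        for k in range(5):
            assert "ubiquitous" not in out[k]
            assert f"own_{k}" in out[k]

    def test_gene_in_exactly_four_clusters_retained(self):
        lists = {k: ["borderline"] for k in range(4)}
        out = filter_cluster_specific_genes(lists)
        assert all("borderline" in v for v in out.values())

    def test_empty_input(self):
        assert filter_cluster_specific_genes({}) == {}


class TestNormalization:
    def test_quantile_columns_share_sorted_vector(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(3, size=(15, 8)).astype(float)
        Q = normalize(X, "quantile")
        ref = np.sort(Q[:, 0])
        for c in range(1, Q.shape[1]):
            assert np.allclose(np.sort(Q[:, c]), ref)

    def test_scale_gives_gene_zscores(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(5, size=(10, 20)).astype(float)
        Z = normalize(X, "scale")
        nonconst = X.std(axis=1) > 0
        assert np.allclose(Z[nonconst].mean(axis=1), 0, atol=1e-12)
        assert np.allclose(Z[nonconst].std(axis=1, ddof=1), 1, atol=1e-12)

    def test_tpm_columns_sum_to_a_million(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(2, size=(12, 6)).astype(float)
        X[:, 0] = np.maximum(X[:, 0], 1)
        lengths = rng.integers(200, 2000, size=12).astype(float)
        T = normalize(X, NormalizationSpec("tpm", lengths=lengths))
        nonzero = X.sum(axis=0) > 0
        assert np.allclose(T[:, nonzero].sum(axis=0), 1e6)

    def test_tpm_single_expressed_gene_takes_everything(self):
        X = np.array([[5.0], [0.0]])
        T = normalize(X, NormalizationSpec("tpm", lengths=[100.0, 100.0]))
        assert T[0, 0] == pytest.approx(1e6)

    def test_tpm_length_weighting(self):
        # equal counts, lengths l and 2l -> 2/3 and 1/3 of a million
        X = np.array([[4.0], [4.0]])
        T = normalize(X, NormalizationSpec("tpm", lengths=[100.0, 200.0]))
        assert T[0, 0] == pytest.approx(2e6 / 3)
        assert T[1, 0] == pytest.approx(1e6 / 3)

    def test_log_rank_library_size_hand_fixtures(self):
        X = np.array([[0.0, 9.0, 4.0],
                      [3.0, 0.0, 4.0],
                      [1.0, 3.0, 2.0]])
        L = normalize(X, "log")
        assert np.allclose(L, np.log10(X + 1))
        R = normalize(X, "rank")
        assert np.allclose(R[:, 0], [1, 3, 2])
        assert np.allclose(R[:, 2], [2.5, 2.5, 1])  # average ties
        S = normalize(X, "library_size")
        totals = X.sum(axis=0)  # 4, 12, 10; median 10
        assert np.allclose(S.sum(axis=0), 10.0)
        assert np.allclose(S, X * (10.0 / totals))

    def test_count_is_identity(self):
        X = np.arange(6, dtype=float).reshape(2, 3)
        assert np.array_equal(normalize(X, "count"), X)

    def test_tpm_requires_lengths(self):
        with pytest.raises(ValueError, match="lengths"):
            normalize(np.ones((2, 2)), "tpm")


def _separable_data(n_per=20, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, 5)) + np.array([30, 10, 10, 10, 10])
    b = rng.normal(0, 1, size=(n_per, 5)) + np.array([10, 30, 10, 10, 10])
    X = np.vstack([a, b]).T  # genes x cells
    labels = [("M1", "M1.a")] * n_per + [("M2", "M2.b")] * n_per
    cells = [f"c{i}" for i in range(2 * n_per)]
    return X, cells, labels


class TestBenchmark:
    def test_separable_majors_score_one_for_kmeans(self):
        X, cells, labels = _separable_data()
        config = BenchmarkConfig(
            normalizations=("count",), reductions=("none",), feature_counts=(5,),
            clusterings=("kmeans",), seeds=(0,), n_clusters=2,
        )
        table = run_benchmark(X, cells, labels, config)
        assert (table["status"] == "ok").all()
        assert table["accuracy_major"].iloc[0] == 1.0

    def test_grid_is_deterministic(self):
        X, cells, labels = _separable_data(seed=3)
        config = BenchmarkConfig(
            normalizations=("count", "log"), reductions=("pca",),
            feature_counts=(3,), clusterings=("kmeans", "hierarchical"),
            seeds=(1,), n_clusters=2,
        )
        t1 = run_benchmark(X, cells, labels, config)
        t2 = run_benchmark(X, cells, labels, config)
        pd.testing.assert_frame_equal(t1, t2)

    def test_major_accuracy_dominates_sub_across_grid(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(3, size=(30, 40)).astype(float)
        labels = [(f"M{i % 2}", f"M{i % 2}.s{i % 4}") for i in range(40)]
        cells = [f"c{i}" for i in range(40)]
        config = BenchmarkConfig(
            normalizations=("log", "scale"), reductions=("pca",),
            feature_counts=(5,), clusterings=("kmeans", "som", "density"),
            seeds=(0,), n_clusters=4,
        )
        table = run_benchmark(X, cells, labels, config)
        ok = table[table["status"] == "ok"]
        assert len(ok) == len(table)
        assert (ok["accuracy_major"] >= ok["accuracy_sub"]).all()
        var = summarize_variance(table)
        assert {"clustering", "accuracy_sub_variance"} <= set(var.columns)

    @pytest.mark.parametrize("method", ["kmeans", "hierarchical", "som",
                                        "density", "kmeans_louvain"])
    def test_each_clustering_method_separates_clean_blobs(self, method):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.2, size=(25, 3)) + [5, 0, 0]
        b = rng.normal(0, 0.2, size=(25, 3)) - [5, 0, 0]
        Y = np.vstack([a, b])
        clusters = cluster_cells(Y, method, n_clusters=2, knn=10, seed=0)
        labels = [("A", "A")] * 25 + [("B", "B")] * 25
        rep = annotate_and_score(
            ClusterAssignment([f"c{i}" for i in range(50)], clusters), labels
        )
        assert rep.accuracy_major == 1.0
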