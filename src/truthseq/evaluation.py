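"""Normalization, clustering, and accuracy scoring against known cell labels.

Clusters are annotated by the true label that occupies the largest
proportion of them; accuracy is the fraction of cells whose cluster
annotation equals their own label, computed independently at the major-
and sub-category level. A chance baseline repeats the scoring after
uniformly permuting the cluster-index vector.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA, FastICA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("count", "quantile", "scale", "library_size", "log", "rank", "tpm")
CLUSTERING_METHODS = ("density", "hierarchical", "som", "kmeans", "kmeans_louvain")
REDUCTION_METHODS = ("none", "pca", "ica")


# ---------------------------------------------------------------------------
# Accuracy scoring


@dataclass
class ClusterAssignment:
    cell_ids: list[str]
    clusters: np.ndarray  # one integer cluster index per cell
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clusters = np.asarray(self.clusters)
        if len(self.clusters) != len(self.cell_ids):
            raise ValueError("every cell needs exactly one cluster index")


@dataclass
class AccuracyReport:
    accuracy_major: float
    accuracy_sub: float
    annotation_major: dict[int, str]
    annotation_sub: dict[int, str]
    confusion_sub: pd.DataFrame
    random_accuracy_major: float | None = None
    random_accuracy_sub: float | None = None


def _annotate_level(
    clusters: np.ndarray, labels: Sequence[str]
) -> tuple[dict[int, str], float]:
    """Majority-label annotation and per-cell agreement for one label level.

    Modal-label ties break toward the globally more frequent label, then
    lexicographically.
    """
    labels = np.asarray(labels, dtype=object)
    global_freq = Counter(labels)
    annotation: dict[int, str] = {}
    for k in np.unique(clusters):
        members = labels[clusters == k]
        counts = Counter(members)
        top = max(counts.values())
        modal = [lab for lab, n in counts.items() if n == top]
        modal.sort(key=lambda lab: (-global_freq[lab], lab))
        annotation[int(k)] = modal[0]
    hits = sum(annotation[int(k)] == lab for k, lab in zip(clusters, labels))
    return annotation, hits / len(labels)


def annotate_and_score(
    assignment: ClusterAssignment,
    truth_labels: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str]],
) -> AccuracyReport:
    """Score a clustering against known (major, sub) labels."""
    if isinstance(truth_labels, Mapping):
        missing = [c for c in assignment.cell_ids if c not in truth_labels]
        if missing:
            raise ValueError(f"cells without truth labels: {missing[:5]}")
        pairs = [truth_labels[c] for c in assignment.cell_ids]
    else:
        pairs = list(truth_labels)
        if len(pairs) != len(assignment.cell_ids):
            raise ValueError("one (major, sub) label per cell required")
    majors = [m for m, _ in pairs]
    subs = [s for _, s in pairs]
    ann_major, acc_major = _annotate_level(assignment.clusters, majors)
    ann_sub, acc_sub = _annotate_level(assignment.clusters, subs)
    confusion = pd.crosstab(
        pd.Series(assignment.clusters, name="cluster"),
        pd.Series(subs, name="sub_label"),
    )
    return AccuracyReport(acc_major, acc_sub, ann_major, ann_sub, confusion)


def random_accuracy(
    assignment: ClusterAssignment,
    truth_labels,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Chance baseline: mean accuracy over uniform permutations of the
    cluster-index vector."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    total_major = total_sub = 0.0
    for _ in range(n_perm):
        perm = rng.permutation(assignment.clusters)
        rep = annotate_and_score(
            ClusterAssignment(assignment.cell_ids, perm), truth_labels
        )
        total_major += rep.accuracy_major
        total_sub += rep.accuracy_sub
    return total_major / n_perm, total_sub / n_perm


# ---------------------------------------------------------------------------
# Matrix QC metrics


def dropout_ratio(X: np.ndarray) -> float:
    """Fraction of zero entries in the matrix."""
    X = np.asarray(X)
    if X.size == 0:
        raise ValueError("empty matrix")
    return float((X == 0).sum() / X.size)


def low_count_ratio(X: np.ndarray, threshold: float = 1) -> float:
    """Fraction of entries with 0 < value <= threshold."""
    X = np.asarray(X)
    if X.size == 0:
        raise ValueError("empty matrix")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return float(((X > 0) & (X <= threshold)).sum() / X.size)


def knee_curve(counts: Mapping[str, int] | Sequence[int] | np.ndarray) -> pd.DataFrame:
    """Barcode read counts ranked descending: columns rank (1-based), count."""
    if isinstance(counts, Mapping):
        values = np.asarray(list(counts.values()))
    else:
        values = np.asarray(counts)
    if values.size == 0:
        raise ValueError("at least one barcode required")
    ordered = np.sort(values)[::-1]
    return pd.DataFrame({"rank": np.arange(1, len(ordered) + 1), "count": ordered})


def filter_cluster_specific_genes(
    per_cluster_genes: Mapping[object, Iterable[str]],
    max_clusters: int = 4,
) -> dict[object, list[str]]:
    """Drop genes that are differential in more than ``max_clusters``
    clusters; genes in at most that many clusters stay cluster-specific."""
    membership: dict[str, int] = defaultdict(int)
    for genes in per_cluster_genes.values():
        for g in set(genes):
            membership[g] += 1
    return {
        k: [g for g in genes if membership[g] <= max_clusters]
        for k, genes in per_cluster_genes.items()
    }


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class NormalizationSpec:
    method: str = "library_size"
    pre_log: bool = False  # apply log10(x+1) before the method
    lengths: Mapping[str, float] | Sequence[float] | None = None  # for tpm

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATION_METHODS:
            raise ValueError(
                f"unknown normalization {self.method!r}; choose from {NORMALIZATION_METHODS}"
            )


def _quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Classic quantile normalization: each cell's sorted values are
    replaced by the across-cell means of the order statistics (ties broken
    by stable order, so every column ends up a permutation of the same
    reference vector)."""
    order = np.argsort(X, axis=0, kind="stable")
    means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty(X.shape, dtype=float)
    for c in range(X.shape[1]):
        out[order[:, c], c] = means
    return out


def normalize(
    X: np.ndarray,
    spec: NormalizationSpec | str,
    gene_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Normalize a genes x cells count matrix.

    Methods: ``count`` (identity), ``library_size`` (per-cell scaling to
    the median cell total), ``log`` (log10(x+1)), ``scale`` (per-gene
    z-score), ``rank`` (per-cell ranks, average ties), ``quantile``
    (classic sorted-mean substitution), ``tpm`` (length-normalized
    counts-per-million within each cell).
    """
    if isinstance(spec, str):
        spec = NormalizationSpec(method=spec)
    X = np.asarray(X, dtype=float)
    if spec.pre_log and spec.method != "log":
        X = np.log10(X + 1)
    m = spec.method
    if m == "count":
        return X.copy()
    if m == "log":
        return np.log10(X + 1)
    if m == "library_size":
        totals = X.sum(axis=0)
        target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
        safe = np.where(totals > 0, totals, 1.0)
        return X * (target / safe)
    if m == "scale":
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return (X - mean) / sd
    if m == "rank":
        return np.apply_along_axis(scipy.stats.rankdata, 0, X)
    if m == "quantile":
        return _quantile_normalize(X)
    if m == "tpm":
        if spec.lengths is None:
            raise ValueError("tpm normalization requires transcript lengths")
        if isinstance(spec.lengths, Mapping):
            if gene_ids is None:
                raise ValueError("tpm with a length mapping requires gene_ids")
            missing = [g for g in gene_ids if g not in spec.lengths]
            if missing:
                raise ValueError(f"missing transcript lengths for genes: {missing[:5]}")
            lengths = np.array([spec.lengths[g] for g in gene_ids], dtype=float)
        else:
            lengths = np.asarray(spec.lengths, dtype=float)
        if len(lengths) != X.shape[0] or np.any(lengths <= 0):
            raise ValueError("one positive length per gene required")
        rate = X / lengths[:, None]
        denom = rate.sum(axis=0)
        empty = denom == 0
        if empty.any():
            logger.warning("%d all-zero cells left at zero under TPM", int(empty.sum()))
        safe = np.where(empty, 1.0, denom)
        return rate / safe * 1e6
    raise AssertionError(m)


# ---------------------------------------------------------------------------
# Clustering algorithms (standard methods, invoked as plumbing)


def _knn_louvain(Y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Phenograph-style clustering: k-nearest-neighbour graph + Louvain."""
    import random

    import igraph

    k = min(k, len(Y) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Y)
    _, idx = nn.kneighbors(Y)
    edges = sorted(
        {(min(i, int(j)), max(i, int(j))) for i in range(len(Y)) for j in idx[i, 1:]}
    )
    g = igraph.Graph(n=len(Y), edges=edges)
    # igraph draws from Python's global random module; pin it for determinism
    state = random.getstate()
    try:
        random.seed(seed)
        part = g.community_multilevel()
    finally:
        random.setstate(state)
    return np.asarray(part.membership)


def _som_cluster(Y: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    """Minimal batch self-organizing map on a near-square grid.

    Units are initialized from random data points and trained with a
    shrinking Gaussian neighbourhood; cells map to their best unit.
    """
    rng = np.random.default_rng(seed)
    gx = max(1, int(np.round(np.sqrt(n_clusters))))
    gy = max(1, int(np.ceil(n_clusters / gx)))
    n_units = gx * gy
    grid = np.array([(i, j) for i in range(gx) for j in range(gy)], dtype=float)
    W = Y[rng.choice(len(Y), size=n_units, replace=len(Y) < n_units)].astype(float)
    n_epochs = 20
    sigma0 = max(gx, gy) / 2.0
    for epoch in range(n_epochs):
        sigma = max(0.5, sigma0 * (1 - epoch / n_epochs))
        d2 = ((Y[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)
        gdist2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)
        H = np.exp(-gdist2 / (2 * sigma**2))  # (units, units)
        weights = H[:, bmu]  # (units, cells)
        denom = weights.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        W = (weights @ Y) / denom
    d2 = ((Y[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _density_peak_cluster(Y: np.ndarray, n_clusters: int) -> np.ndarray:
    """Density-peak clustering (local density x separation ranking).

    Cutoff distance is the 2% quantile of pairwise distances; densities
    use a Gaussian kernel; the top ``n_clusters`` points by
    density x delta become centres and the rest follow their nearest
    denser neighbour.
    """
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(Y))
    n = len(Y)
    tri = D[np.triu_indices(n, k=1)]
    dc = np.quantile(tri, 0.02) if len(tri) else 1.0
    dc = max(dc, 1e-12)
    rho = np.exp(-((D / dc) ** 2)).sum(axis=1) - 1
    order = np.argsort(-rho)
    delta = np.empty(n)
    nearest_denser = np.full(n, -1)
    delta[order[0]] = D[order[0]].max()
    for pos in range(1, n):
        i = order[pos]
        denser = order[:pos]
        j = denser[D[i, denser].argmin()]
        delta[i] = D[i, j]
        nearest_denser[i] = j
    gamma = rho * delta
    centers = np.argsort(-gamma)[:n_clusters]
    labels = np.full(n, -1)
    for c, i in enumerate(centers):
        labels[i] = c
    for i in order:
        if labels[i] == -1:
            labels[i] = labels[nearest_denser[i]]
    return labels


def cluster_cells(
    Y: np.ndarray,
    method: str,
    n_clusters: int = 12,
    knn: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Run one of the five supported clustering algorithms on cells x
    features coordinates."""
    if method == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        return km.fit_predict(Y)
    if method == "hierarchical":
        return AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(Y)
    if method == "kmeans_louvain":
        return _knn_louvain(Y, knn, seed)
    if method == "som":
        return _som_cluster(Y, n_clusters, seed)
    if method == "density":
        return _density_peak_cluster(Y, n_clusters)
    raise ValueError(f"unknown clustering method {method!r}; choose from {CLUSTERING_METHODS}")


def reduce_dimensions(
    X_norm: np.ndarray, method: str = "pca", n_features: int = 30, seed: int = 0
) -> np.ndarray:
    """cells x features coordinates from a normalized genes x cells matrix."""
    Y = X_norm.T
    if method == "none":
        return Y
    n_features = min(n_features, min(Y.shape))
    if method == "pca":
        return PCA(n_components=n_features, random_state=seed).fit_transform(Y)
    if method == "ica":
        ica = FastICA(n_components=n_features, random_state=seed, max_iter=500, tol=1e-3)
        return ica.fit_transform(Y)
    raise ValueError(f"unknown reduction {method!r}; choose from {REDUCTION_METHODS}")


# ---------------------------------------------------------------------------
# Default workflow and benchmark grid


def default_workflow(
    X: np.ndarray,
    cell_ids: Sequence[str],
    truth_labels,
    n_pcs: int = 30,
    clustering: str = "kmeans_louvain",
    n_clusters: int | None = None,
    knn: int = 30,
    seed: int = 0,
    with_random_baseline: bool = False,
    n_perm: int = 100,
) -> AccuracyReport:
    """Library-size normalization, PCA to the top components, graph (or
    other) clustering, then majority-label scoring."""
    if isinstance(truth_labels, Mapping):
        pairs = [truth_labels[c] for c in cell_ids]
    else:
        pairs = list(truth_labels)
    if n_clusters is None:
        n_clusters = len(set(s for _, s in pairs))
    norm = normalize(X, NormalizationSpec("library_size"))
    norm = np.log10(norm + 1)
    Y = reduce_dimensions(norm, "pca", n_pcs, seed=seed)
    clusters = cluster_cells(Y, clustering, n_clusters=n_clusters, knn=knn, seed=seed)
    assignment = ClusterAssignment(list(cell_ids), clusters, method=clustering)
    report = annotate_and_score(assignment, pairs)
    if with_random_baseline:
        rm, rs = random_accuracy(assignment, pairs, n_perm=n_perm, seed=seed)
        report.random_accuracy_major = rm
        report.random_accuracy_sub = rs
    return report


@dataclass
class BenchmarkConfig:
    normalizations: Sequence[str] = ("count", "quantile", "scale", "library_size", "log", "rank", "tpm")
    reductions: Sequence[str] = ("pca",)
    feature_counts: Sequence[int] = (100, 70, 40, 10)
    clusterings: Sequence[str] = ("kmeans", "kmeans_louvain")
    seeds: Sequence[int] = (0,)
    n_clusters: int | None = None
    knn: int = 30
    lengths: Mapping[str, float] | None = None  # needed when tpm is in the grid

    def __post_init__(self) -> None:
        if not (self.normalizations and self.reductions and self.feature_counts and self.clusterings and self.seeds):
            raise ValueError("benchmark grid must be non-empty")


def run_benchmark(
    X: np.ndarray,
    cell_ids: Sequence[str],
    truth_labels: Sequence[tuple[str, str]],
    config: BenchmarkConfig,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Execute the full (normalization x reduction x features x clustering
    x seed) grid; failures of individual cells are recorded, not fatal."""
    pairs = list(truth_labels)
    n_clusters = config.n_clusters or len(set(s for _, s in pairs))
    rows = []
    for nm in config.normalizations:
        spec = NormalizationSpec(nm, lengths=config.lengths if nm == "tpm" else None)
        try:
            Xn = normalize(X, spec, gene_ids=gene_ids)
        except Exception as exc:  # record and continue per grid contract
            for rd in config.reductions:
                for nf in config.feature_counts:
                    for cl in config.clusterings:
                        for sd in config.seeds:
                            rows.append(
                                dict(normalization=nm, reduction=rd, features=nf,
                                     clustering=cl, seed=sd, status=f"failed: {exc}",
                                     accuracy_major=np.nan, accuracy_sub=np.nan)
                            )
            continue
        for rd in config.reductions:
            for nf in config.feature_counts:
                try:
                    Y = reduce_dimensions(Xn, rd, nf, seed=config.seeds[0])
                except Exception as exc:
                    for cl in config.clusterings:
                        for sd in config.seeds:
                            rows.append(
                                dict(normalization=nm, reduction=rd, features=nf,
                                     clustering=cl, seed=sd, status=f"failed: {exc}",
                                     accuracy_major=np.nan, accuracy_sub=np.nan)
                            )
                    continue
                for cl in config.clusterings:
                    for sd in config.seeds:
                        try:
                            clusters = cluster_cells(
                                Y, cl, n_clusters=n_clusters, knn=config.knn, seed=sd
                            )
                            rep = annotate_and_score(
                                ClusterAssignment(list(cell_ids), clusters, cl), pairs
                            )
                            rows.append(
                                dict(normalization=nm, reduction=rd, features=nf,
                                     clustering=cl, seed=sd, status="ok",
                                     accuracy_major=rep.accuracy_major,
                                     accuracy_sub=rep.accuracy_sub)
                            )
                        except Exception as exc:
                            rows.append(
                                dict(normalization=nm, reduction=rd, features=nf,
                                     clustering=cl, seed=sd, status=f"failed: {exc}",
                                     accuracy_major=np.nan, accuracy_sub=np.nan)
                            )
    return pd.DataFrame(rows)


def summarize_variance(table: pd.DataFrame, vary: str = "normalization") -> pd.DataFrame:
    """Per-clustering-method accuracy variance across one grid axis
    (stability summaries)."""
    ok = table[table["status"] == "ok"]
    return (
        ok.groupby(["clustering", vary])["accuracy_sub"].mean().groupby("clustering").var()
        .rename("accuracy_sub_variance").reset_index()
    )
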