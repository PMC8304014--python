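"""Ground-truth construction: cell-type expression panel and true-count sampling.

The reference panel stores, for every gene and every (major, sub) cell
category, the parameters of an independent normal distribution of
expression. Panels can be fit from a labelled expression matrix (a
subcategory needs at least three samples, otherwise the gene's overall
mean/variance is used as a fallback) or synthesized hierarchically
(gene baselines + major-category effects + sub-category effects + marker
genes). The ground-truth matrix is sampled from the panel: a fixed number
of cells per subcategory, each gene drawn from Normal(mu, var), rounded to
the nearest integer and clipped at zero to yield true mRNA copy numbers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import write_matrix, read_matrix

SOURCE_FIT = "subcategory_fit"
SOURCE_FALLBACK = "overall_fallback"

MIN_SAMPLES_FOR_FIT = 3  # below this, the per-gene overall distribution is used


@dataclass
class ReferencePanel:
    """Per-gene, per-subcategory normal expression parameters."""

    genes: list[str]
    subcategories: list[tuple[str, str]]  # (major_label, sub_label)
    mu: np.ndarray  # (n_genes, n_subcategories)
    var: np.ndarray  # (n_genes, n_subcategories)
    fallback_mu: np.ndarray  # (n_genes,)
    fallback_var: np.ndarray  # (n_genes,)
    source: np.ndarray  # (n_genes, n_subcategories) of {subcategory_fit, overall_fallback}

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        self.validate()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_subcategories(self) -> int:
        return len(self.subcategories)

    def validate(self) -> None:
        if self.n_genes == 0 or self.n_subcategories == 0:
            raise ValueError("panel must have at least one gene and one subcategory")
        shape = (self.n_genes, self.n_subcategories)
        if self.mu.shape != shape or self.var.shape != shape:
            raise ValueError(f"mu/var must have shape {shape}")
        if not np.all(np.isfinite(self.mu)) or not np.all(np.isfinite(self.var)):
            raise ValueError("panel contains undefined (non-finite) entries")
        if np.any(self.var < 0):
            raise ValueError("variances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, (major, sub) in enumerate(self.subcategories):
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.genes,
                        "major": major,
                        "sub": sub,
                        "mu": self.mu[:, s],
                        "var": self.var[:, s],
                        "source": self.source[:, s],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_genes={self.n_genes}\tn_subcategories={self.n_subcategories}\n")
            fb = pd.DataFrame(
                {
                    "gene": self.genes,
                    "major": "__overall__",
                    "sub": "__overall__",
                    "mu": self.fallback_mu,
                    "var": self.fallback_var,
                    "source": SOURCE_FALLBACK,
                }
            )
            pd.concat([self.to_frame(), fb], ignore_index=True).to_csv(
                fh, sep="\t", index=False
            )

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t", comment="#")
        fb = df[df["sub"] == "__overall__"]
        body = df[df["sub"] != "__overall__"]
        genes = list(dict.fromkeys(body["gene"]))
        subcats = list(dict.fromkeys(zip(body["major"], body["sub"])))
        gidx = {g: i for i, g in enumerate(genes)}
        sidx = {s: i for i, s in enumerate(subcats)}
        mu = np.empty((len(genes), len(subcats)))
        var = np.empty_like(mu)
        source = np.empty(mu.shape, dtype=object)
        for row in body.itertuples(index=False):
            i, j = gidx[row.gene], sidx[(row.major, row.sub)]
            mu[i, j], var[i, j], source[i, j] = row.mu, getattr(row, "var"), row.source
        fallback_mu = np.array([fb.loc[fb["gene"] == g, "mu"].iloc[0] for g in genes])
        fallback_var = np.array([fb.loc[fb["gene"] == g, "var"].iloc[0] for g in genes])
        return cls(genes, subcats, mu, var, fallback_mu, fallback_var, source)


@dataclass
class GroundTruthMatrix:
    """True mRNA copy numbers (genes x cells) with known cell labels."""

    counts: np.ndarray  # (n_genes, n_cells) non-negative integers
    gene_ids: list[str]
    cell_ids: list[str]
    cell_labels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match id lists")
        if len(self.cell_labels) != len(self.cell_ids):
            raise ValueError("one label per cell required")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def major_labels(self) -> list[str]:
        return [m for m, _ in self.cell_labels]

    def sub_labels(self) -> list[str]:
        return [s for _, s in self.cell_labels]

    def write(self, out_dir: str | os.PathLike) -> None:
        write_matrix(self.counts, self.gene_ids, self.cell_ids, out_dir, self.cell_labels)

    @classmethod
    def read(cls, in_dir: str | os.PathLike) -> "GroundTruthMatrix":
        X, genes, cells, labels = read_matrix(in_dir)
        if labels is None:
            raise ValueError(f"{in_dir}/cells.tsv carries no cell labels")
        return cls(X.astype(np.int64), genes, cells, labels)


@dataclass
class PanelSynthesisSpec:
    """Parameters of the hierarchical synthetic expression panel.

    Gene baselines are drawn on the natural-log scale
    (``Normal(baseline_mean, baseline_sd)``) and perturbed by per-major and
    per-sub effects; marker genes are shifted up by ``marker_fold`` in their
    own subcategory. Per-subcategory variance is ``noise_var_scale * mu**2``
    (a constant coefficient of variation).
    """

    n_genes: int = 500
    n_major: int = 4
    subs_per_major: int = 3
    baseline_mean: float = 0.5
    baseline_sd: float = 0.8
    major_effect_sd: float = 0.6
    sub_effect_sd: float = 0.25
    markers_per_sub: int = 5
    marker_fold: float = 4.0
    noise_var_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_major, self.subs_per_major, self.markers_per_sub) < 1:
            raise ValueError("all count parameters must be >= 1")
        for name in ("baseline_sd", "major_effect_sd", "sub_effect_sd", "noise_var_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")


def fit_reference_panel(
    sample_matrix: np.ndarray | pd.DataFrame,
    sample_labels: Sequence[tuple[str, str]],
    gene_ids: Sequence[str] | None = None,
    subcategories: Sequence[tuple[str, str]] | None = None,
) -> ReferencePanel:
    """Fit per-subcategory normal distributions from labelled expression data.

    Subcategories with at least :data:`MIN_SAMPLES_FOR_FIT` samples get the
    per-gene sample mean and unbiased (n-1) variance; smaller subcategories
    fall back to the gene's overall mean/variance across all samples.

    Parameters
    ----------
    sample_matrix
        genes x samples expression values.
    sample_labels
        Per-sample (major, sub) label pairs.
    subcategories
        Optional explicit subcategory list; each entry must be represented
        by at least one sample.
    """
    if isinstance(sample_matrix, pd.DataFrame):
        if gene_ids is None:
            gene_ids = list(sample_matrix.index)
        sample_matrix = sample_matrix.to_numpy()
    X = np.asarray(sample_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("sample_matrix must be a non-empty genes x samples matrix")
    n_genes, n_samples = X.shape
    if len(sample_labels) != n_samples:
        raise ValueError("one (major, sub) label per sample required")
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)

    seen = list(dict.fromkeys(sample_labels))
    if subcategories is None:
        subcategories = seen
    else:
        subcategories = list(subcategories)
        missing = [s for s in subcategories if s not in seen]
        if missing:
            raise ValueError(f"subcategories with no samples: {missing}")

    fallback_mu = X.mean(axis=1)
    fallback_var = X.var(axis=1, ddof=1) if n_samples > 1 else np.zeros(n_genes)

    S = len(subcategories)
    mu = np.empty((n_genes, S))
    var = np.empty_like(mu)
    source = np.empty((n_genes, S), dtype=object)
    labels_arr = list(sample_labels)
    for j, sc in enumerate(subcategories):
        cols = [i for i, lab in enumerate(labels_arr) if lab == sc]
        if len(cols) >= MIN_SAMPLES_FOR_FIT:
            sub = X[:, cols]
            mu[:, j] = sub.mean(axis=1)
            var[:, j] = sub.var(axis=1, ddof=1)
            source[:, j] = SOURCE_FIT
        else:
            mu[:, j] = fallback_mu
            var[:, j] = fallback_var
            source[:, j] = SOURCE_FALLBACK
    return ReferencePanel(
        gene_ids, list(subcategories), mu, var, fallback_mu, fallback_var, source
    )


def synthesize_reference_panel(spec: PanelSynthesisSpec) -> ReferencePanel:
    """Build a hierarchical synthetic panel with marker genes.

    Each subcategory's markers are a disjoint slice of the gene list and
    their mean is ``marker_fold`` times the gene's largest non-marker
    subcategory mean, which guarantees marker dominance by construction.
    """
    n_sub_total = spec.n_major * spec.subs_per_major
    if spec.markers_per_sub * n_sub_total > spec.n_genes:
        raise ValueError(
            f"cannot allocate {spec.markers_per_sub} markers to each of "
            f"{n_sub_total} subcategories from {spec.n_genes} genes"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    genes = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    subcats = [
        (f"major_{m:02d}", f"major_{m:02d}.sub_{s:02d}")
        for m in range(spec.n_major)
        for s in range(spec.subs_per_major)
    ]

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    major_eff = rng.normal(0.0, spec.major_effect_sd, size=(spec.n_genes, spec.n_major))
    sub_eff = rng.normal(0.0, spec.sub_effect_sd, size=(spec.n_genes, n_sub_total))
    log_mu = baseline[:, None] + np.repeat(major_eff, spec.subs_per_major, axis=1) + sub_eff
    mu = np.exp(log_mu)

    # disjoint marker blocks, in gene order: subcategory j owns genes
    # [j*markers_per_sub, (j+1)*markers_per_sub)
    for j in range(n_sub_total):
        block = slice(j * spec.markers_per_sub, (j + 1) * spec.markers_per_sub)
        other = np.delete(mu[block], j, axis=1)
        mu[block, j] = spec.marker_fold * other.max(axis=1)

    var = spec.noise_var_scale * mu**2
    fallback_mu = mu.mean(axis=1)
    fallback_var = var.mean(axis=1)
    source = np.full(mu.shape, SOURCE_FIT, dtype=object)
    return ReferencePanel(genes, subcats, mu, var, fallback_mu, fallback_var, source)


def marker_genes(spec: PanelSynthesisSpec) -> dict[tuple[str, str], list[str]]:
    """Marker gene ids per subcategory for a panel built from ``spec``."""
    n_sub_total = spec.n_major * spec.subs_per_major
    subcats = [
        (f"major_{m:02d}", f"major_{m:02d}.sub_{s:02d}")
        for m in range(spec.n_major)
        for s in range(spec.subs_per_major)
    ]
    out = {}
    for j in range(n_sub_total):
        out[subcats[j]] = [
            f"gene_{i:05d}"
            for i in range(j * spec.markers_per_sub, (j + 1) * spec.markers_per_sub)
        ]
    return out


def sample_ground_truth(
    panel: ReferencePanel, cells_per_subcategory: int, seed: int = 0
) -> GroundTruthMatrix:
    """Sample true mRNA copy numbers: per subcategory, a fixed number of
    cells, each gene ~ Normal(mu, var), rounded and clipped at zero.

    Randomness is split into one independent stream per cell, so per-cell
    draws do not depend on evaluation order.
    """
    if cells_per_subcategory < 1:
        raise ValueError("cells_per_subcategory must be >= 1")
    panel.validate()
    S, G = panel.n_subcategories, panel.n_genes
    n_cells = cells_per_subcategory * S
    streams = np.random.SeedSequence(seed).spawn(n_cells)

    counts = np.empty((G, n_cells), dtype=np.int64)
    cell_ids: list[str] = []
    labels: list[tuple[str, str]] = []
    sd = np.sqrt(panel.var)
    c = 0
    for j, (major, sub) in enumerate(panel.subcategories):
        for k in range(cells_per_subcategory):
            rng = np.random.default_rng(streams[c])
            draw = rng.normal(panel.mu[:, j], sd[:, j])
            counts[:, c] = np.clip(np.rint(draw), 0, None).astype(np.int64)
            cell_ids.append(f"cell_{c:05d}")
            labels.append((major, sub))
            c += 1
    return GroundTruthMatrix(counts, list(panel.genes), cell_ids, labels)
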