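"""Reusable in-memory experiment harnesses built on the simulator.

These drive the headline analyses at desk scale: the saturation/oracle
round trip, the UMI-correction comparison, and the depth ladder that maps
sequencing depth to clustering accuracy and matrix sparsity. They are
shared by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import default_workflow, dropout_ratio
from .ground_truth import PanelSynthesisSpec, sample_ground_truth, synthesize_reference_panel
from .library_builder import PCRParams, TruncationParams, build_library, synthesize_transcripts
from .quantifier import quantify
from .sequencer import ErrorProfile, QualityProfile, RunConfig, iter_read_batches
from .quantifier import CountMatrix


def _zero_error_profiles(read_len: int) -> tuple[ErrorProfile, QualityProfile]:
    return ErrorProfile(np.zeros((read_len, 4, 4))), QualityProfile.uniform(read_len)


@dataclass
class OracleResult:
    truth: np.ndarray
    recovered: np.ndarray
    exact_fraction: float
    n_cells: int
    n_genes: int


def oracle_roundtrip(
    n_subcategories: int = 5,
    cells_per_sub: int = 20,
    n_genes: int = 50,
    umi_length: int = 14,
    seed: int = 0,
) -> OracleResult:
    """Noise-free saturation round trip: truth -> library -> reads ->
    UMI-deduplicated counts.

    PCR runs at efficiency 1 (every fragment at exactly 2^cycles
    molecules, uniform sampling weights) with zero mutation; sequencing
    errors are off; depth is set by a coupon-collector bound so every
    fragment is observed with overwhelming probability. The recovered
    matrix should equal the ground truth entry-for-entry; UMIs are long
    enough that random collisions within a (cell, gene) group are
    negligible at this scale.
    """
    spec = PanelSynthesisSpec(
        n_genes=n_genes,
        n_major=n_subcategories,
        subs_per_major=1,
        baseline_mean=1.0,
        baseline_sd=0.5,
        markers_per_sub=2,
        seed=seed,
    )
    panel = synthesize_reference_panel(spec)
    truth = sample_ground_truth(panel, cells_per_sub, seed=seed + 1)
    reference = synthesize_transcripts(truth.gene_ids, mean_length=300, seed=seed + 2)
    library = build_library(
        truth,
        reference,
        umi_length=umi_length,
        pcr_params=PCRParams(cycles=3, efficiency=1.0, mutation_rate=0.0, seed=seed + 3),
        seed=seed + 3,
    )
    F = len(library.fragments)
    depth = int(F * (np.log(F) + np.log(1e6)))  # P(any fragment missed) < ~1e-6
    config = RunConfig(depth=depth, read2_len=60, seed=seed + 4)
    profiles = _zero_error_profiles(max(60, library.barcode_bank.barcode_length + umi_length))
    batches = iter_read_batches(library, reference, config, profiles)
    matrix, stats = quantify(library, batches=batches, dedup=True)
    recovered = matrix.aligned_to(truth.gene_ids, truth.cell_ids)
    exact = float((recovered == truth.counts).mean())
    return OracleResult(truth.counts, recovered, exact, truth.n_cells, truth.n_genes)


@dataclass
class UMIComparisonResult:
    corr_dedup: list[float]
    corr_raw: list[float]

    @property
    def win_rate(self) -> float:
        wins = [d >= r for d, r in zip(self.corr_dedup, self.corr_raw)]
        return float(np.mean(wins))


def umi_correction_replicates(
    n_replicates: int = 20,
    efficiency: float = 0.7,
    cycles: int = 4,
    n_genes: int = 60,
    n_cells: int = 30,
    reads_per_molecule: float = 1.5,
    seed: int = 0,
) -> UMIComparisonResult:
    """Replicated comparison of UMI-deduplicated vs raw counts.

    Amplification at sub-unit efficiency makes per-fragment copy numbers
    disperse, which biases raw read counts; collapsing by UMI removes the
    bias. Per replicate the Pearson correlation of each quantification
    against the true counts is recorded.
    """
    corr_d: list[float] = []
    corr_r: list[float] = []
    for rep in range(n_replicates):
        s = seed + 1000 * rep
        spec = PanelSynthesisSpec(
            n_genes=n_genes,
            n_major=3,
            subs_per_major=1,
            baseline_mean=1.0,
            baseline_sd=0.7,
            markers_per_sub=2,
            seed=s,
        )
        panel = synthesize_reference_panel(spec)
        truth = sample_ground_truth(panel, max(1, n_cells // 3), seed=s + 1)
        reference = synthesize_transcripts(truth.gene_ids, mean_length=300, seed=s + 2)
        library = build_library(
            truth,
            reference,
            pcr_params=PCRParams(
                cycles=cycles, efficiency=efficiency, mutation_rate=1e-5, seed=s + 3
            ),
            seed=s + 3,
        )
        depth = max(1000, int(library.total_molecules() * reads_per_molecule))
        config = RunConfig(depth=depth, read2_len=60, seed=s + 4)
        batches = list(iter_read_batches(library, reference, config))
        dedup, _ = quantify(library, batches=iter(batches), dedup=True)
        raw, _ = quantify(library, batches=iter(batches), dedup=False)
        t = truth.counts.ravel().astype(float)
        d = dedup.aligned_to(truth.gene_ids, truth.cell_ids).ravel().astype(float)
        r = raw.aligned_to(truth.gene_ids, truth.cell_ids).ravel().astype(float)
        corr_d.append(float(np.corrcoef(t, d)[0, 1]))
        corr_r.append(float(np.corrcoef(t, r)[0, 1]))
    return UMIComparisonResult(corr_d, corr_r)


@dataclass
class DepthLadderResult:
    depths_per_cell: list[int]
    seeds: list[int]
    accuracy_major: np.ndarray  # (n_depths, n_seeds)
    accuracy_sub: np.ndarray
    dropout: np.ndarray

    def median_accuracy_major(self) -> np.ndarray:
        return np.median(self.accuracy_major, axis=1)

    def median_accuracy_sub(self) -> np.ndarray:
        return np.median(self.accuracy_sub, axis=1)

    def median_dropout(self) -> np.ndarray:
        return np.median(self.dropout, axis=1)


def depth_ladder(
    depths_per_cell: Sequence[int] = (30, 100, 300, 900),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    panel_spec: PanelSynthesisSpec | None = None,
    cells_per_sub: int = 30,
    read2_len: int = 60,
) -> DepthLadderResult:
    """Sequencing-depth ladder on the default synthetic panel.

    One library per seed is built once and re-sequenced at every depth
    (library reuse), then quantified with UMI dedup and pushed through the
    default workflow (library-size normalization, PCA, kNN+Louvain).
    Reports clustering accuracy at both label levels and the dropout ratio
    of each count matrix.
    """
    n_depths = len(depths_per_cell)
    acc_major = np.zeros((n_depths, len(seeds)))
    acc_sub = np.zeros((n_depths, len(seeds)))
    dropout = np.zeros((n_depths, len(seeds)))
    for j, s in enumerate(seeds):
        spec = panel_spec or PanelSynthesisSpec(seed=s)
        if panel_spec is not None:
            spec = PanelSynthesisSpec(**{**panel_spec.__dict__, "seed": s})
        panel = synthesize_reference_panel(spec)
        truth = sample_ground_truth(panel, cells_per_sub, seed=s + 1)
        reference = synthesize_transcripts(truth.gene_ids, mean_length=400, seed=s + 2)
        library = build_library(truth, reference, seed=s + 3)
        labels = {c: lab for c, lab in zip(truth.cell_ids, truth.cell_labels)}
        for i, dpc in enumerate(depths_per_cell):
            config = RunConfig(depth=dpc * truth.n_cells, read2_len=read2_len, seed=s + 5)
            batches = iter_read_batches(library, reference, config)
            matrix, _ = quantify(library, batches=batches, dedup=True)
            X = matrix.aligned_to(truth.gene_ids, truth.cell_ids)
            dropout[i, j] = dropout_ratio(X)
            report = default_workflow(
                X, truth.cell_ids, labels, n_pcs=30, clustering="kmeans_louvain",
                knn=15, seed=s,
            )
            acc_major[i, j] = report.accuracy_major
            acc_sub[i, j] = report.accuracy_sub
    return DepthLadderResult(list(depths_per_cell), list(seeds), acc_major, acc_sub, dropout)
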