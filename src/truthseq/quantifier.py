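"""Truth-aware quantification of simulated reads back into a count matrix.

Reads are demultiplexed by cell barcode (exact match, then unique
Hamming-1 correction), assigned to genes either from the truth tag the
simulator stores in the read header (oracle mapping) or by exact k-mer
voting against a small transcript reference, and collapsed per
(cell, gene) by UMI with the directional single-mismatch merging rule.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptReference, read_fastq, read_manifest, write_manifest, write_matrix, read_matrix
from .library_builder import BarcodeBank, SequencingLibrary
from .sequencer import ReadBatch

logger = logging.getLogger(__name__)

ALIGN_REFERENCE_CAP = 10_000_000  # total transcript bases the k-mer voter accepts
DEFAULT_KMER = 31


@dataclass
class CountMatrix:
    """Quantified genes x cells counts (``dedup_mode`` records whether UMI
    collapsing was applied)."""

    X: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    dedup_mode: str = "umi"  # or "raw"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if not np.issubdtype(self.X.dtype, np.integer):
            raise ValueError("counts must be integers")
        if np.any(self.X < 0):
            raise ValueError("counts must be non-negative")
        if self.X.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match id lists")

    def write(self, out_dir: str | os.PathLike) -> None:
        write_matrix(self.X, self.gene_ids, self.cell_ids, out_dir)
        write_manifest({"dedup_mode": self.dedup_mode}, Path(out_dir) / "quantify.txt")

    @classmethod
    def read(cls, in_dir: str | os.PathLike) -> "CountMatrix":
        X, genes, cells, _ = read_matrix(in_dir)
        meta = Path(in_dir) / "quantify.txt"
        mode = read_manifest(meta).get("dedup_mode", "umi") if meta.exists() else "umi"
        return cls(X.astype(np.int64), genes, cells, mode)

    def aligned_to(
        self, gene_ids: Sequence[str], cell_ids: Sequence[str]
    ) -> np.ndarray:
        """Counts reindexed onto the given gene/cell ordering (zeros where
        a gene or cell was not observed)."""
        out = np.zeros((len(gene_ids), len(cell_ids)), dtype=np.int64)
        gpos = {g: i for i, g in enumerate(self.gene_ids)}
        cpos = {c: i for i, c in enumerate(self.cell_ids)}
        for i, g in enumerate(gene_ids):
            gi = gpos.get(g)
            if gi is None:
                continue
            for j, c in enumerate(cell_ids):
                ci = cpos.get(c)
                if ci is not None:
                    out[i, j] = self.X[gi, ci]
        return out


@dataclass
class DemuxStats:
    reads_total: int = 0
    reads_assigned: int = 0
    reads_barcode_corrected: int = 0
    reads_discarded_barcode: int = 0
    reads_discarded_gene: int = 0

    def validate(self) -> None:
        if self.reads_total != (
            self.reads_assigned + self.reads_discarded_barcode + self.reads_discarded_gene
        ):
            raise AssertionError("demux accounting identity violated")

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_total": self.reads_total,
            "reads_assigned": self.reads_assigned,
            "reads_barcode_corrected": self.reads_barcode_corrected,
            "reads_discarded_barcode": self.reads_discarded_barcode,
            "reads_discarded_gene": self.reads_discarded_gene,
        }


# ---------------------------------------------------------------------------
# Barcode demultiplexing


class BarcodeMatcher:
    """Exact + unique-Hamming-1 barcode lookup against a bank.

    With a bank built at minimum pairwise distance >= 3 every single-error
    word has a unique neighbour; at distance 2 ties are possible and are
    conservatively discarded.
    """

    def __init__(self, bank: BarcodeBank):
        self.bank = bank
        self.exact = {bc: cid for cid, bc in zip(bank.cell_ids, bank.barcodes)}
        self.length = bank.barcode_length
        self._corrections: dict[str, str | None] = {}

    def _correct(self, barcode: str) -> str | None:
        hit: str | None = None
        arr = list(barcode)
        for i in range(self.length):
            orig = arr[i]
            for b in "ACGT":
                if b == orig:
                    continue
                arr[i] = b
                cand = "".join(arr)
                cid = self.exact.get(cand)
                if cid is not None:
                    if hit is not None and hit != cid:
                        return None  # ambiguous: two bank words within distance 1
                    hit = cid
            arr[i] = orig
        return hit

    def match(self, barcode: str) -> tuple[str | None, bool]:
        """Return (cell_id or None, was_corrected)."""
        cid = self.exact.get(barcode)
        if cid is not None:
            return cid, False
        if barcode not in self._corrections:
            self._corrections[barcode] = self._correct(barcode)
        cid = self._corrections[barcode]
        return cid, cid is not None


def demultiplex(read1_seq: str, barcode_bank: BarcodeBank | BarcodeMatcher) -> str | None:
    """Assign one read-1 sequence to a cell, or None if unassignable."""
    matcher = (
        barcode_bank
        if isinstance(barcode_bank, BarcodeMatcher)
        else BarcodeMatcher(barcode_bank)
    )
    if len(read1_seq) < matcher.length:
        return None
    cid, _ = matcher.match(read1_seq[: matcher.length])
    return cid


# ---------------------------------------------------------------------------
# Gene assignment


class KmerVoter:
    """Exact k-mer vote of a read against transcript sequences.

    Only k-mers unique to one gene vote; the read goes to the gene with a
    strict plurality, else nowhere. Intended for toy references only.
    """

    def __init__(self, reference: TranscriptReference, k: int = DEFAULT_KMER):
        total = reference.total_length()
        if total > ALIGN_REFERENCE_CAP:
            raise ValueError(
                f"reference of {total} bases exceeds the k-mer voter cap of "
                f"{ALIGN_REFERENCE_CAP}; use an external aligner for real data"
            )
        self.k = k
        index: dict[str, str | None] = {}
        for gene, seq in reference.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in index and index[kmer] != gene:
                    index[kmer] = None  # shared between genes: uninformative
                else:
                    index[kmer] = gene
        self.index = {km: g for km, g in index.items() if g is not None}

    def assign(self, read_seq: str) -> str | None:
        votes: dict[str, int] = defaultdict(int)
        for i in range(0, len(read_seq) - self.k + 1):
            g = self.index.get(read_seq[i : i + self.k])
            if g is not None:
                votes[g] += 1
        if not votes:
            return None
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return None
        return ranked[0][0]


def assign_gene(
    read,
    reference: TranscriptReference | None = None,
    mode: str = "truth_tag",
    voter: KmerVoter | None = None,
) -> str | None:
    """Assign a read to a gene.

    ``truth_tag`` reads the simulator's header tag
    (``cell|gene|copy|molecule``) — the oracle mapper. ``align`` does an
    exact k-mer vote against a (small) transcript reference.
    """
    if mode == "truth_tag":
        comment = read.comment if hasattr(read, "comment") else str(read)
        parts = comment.split("|")
        if len(parts) < 2:
            raise ValueError(f"read carries no truth tag: {comment!r}")
        return parts[1]
    if mode == "align":
        if voter is None:
            if reference is None:
                raise ValueError("align mode requires a reference")
            voter = KmerVoter(reference)
        seq = read.seq if hasattr(read, "seq") else str(read)
        return voter.assign(seq)
    raise ValueError(f"unknown gene assignment mode {mode!r}")


# ---------------------------------------------------------------------------
# UMI counting


def _directional_cluster_count(counts: dict[str, int]) -> int:
    """Number of distinct molecules under directional 1-mismatch merging.

    A UMI is absorbed into a Hamming-1 neighbour seen at least twice as
    often; absorption cascades through the already-merged representative.
    """
    if len(counts) <= 1:
        return len(counts)
    order = sorted(counts, key=lambda u: (-counts[u], u))
    root: dict[str, str] = {}
    for umi in order:
        best = None
        arr = list(umi)
        for i in range(len(arr)):
            orig = arr[i]
            for b in "ACGT":
                if b == orig:
                    continue
                arr[i] = b
                neigh = "".join(arr)
                c = counts.get(neigh)
                if c is not None and neigh in root and c >= 2 * counts[umi]:
                    if best is None or counts[neigh] > counts[best]:
                        best = neigh
            arr[i] = orig
        root[umi] = root[best] if best is not None else umi
    return len(set(root.values()))


def count_with_umi(
    assigned: pd.DataFrame,
    dedup: bool = True,
    directional: bool = True,
    gene_ids: Sequence[str] | None = None,
    cell_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Collapse assigned reads into a count matrix.

    ``assigned`` needs columns cell_id, gene_id, umi. With ``dedup`` the
    count is the number of UMI clusters per (cell, gene) (directional
    single-mismatch merging unless ``directional=False``, which counts
    exact distinct UMIs); without it, the raw read count.
    """
    for col in ("cell_id", "gene_id", "umi"):
        if col not in assigned.columns:
            raise ValueError(f"assigned reads need a {col!r} column")
    if gene_ids is None:
        gene_ids = sorted(assigned["gene_id"].unique())
    if cell_ids is None:
        cell_ids = sorted(assigned["cell_id"].unique())
    gpos = {g: i for i, g in enumerate(gene_ids)}
    cpos = {c: i for i, c in enumerate(cell_ids)}
    X = np.zeros((len(gene_ids), len(cell_ids)), dtype=np.int64)

    if not dedup:
        grouped = assigned.groupby(["gene_id", "cell_id"], sort=False).size()
        for (g, c), n in grouped.items():
            if g in gpos and c in cpos:
                X[gpos[g], cpos[c]] = n
        return CountMatrix(X, list(gene_ids), list(cell_ids), dedup_mode="raw")

    grouped = assigned.groupby(["gene_id", "cell_id"], sort=False)["umi"].value_counts()
    per_group: dict[tuple[str, str], dict[str, int]] = defaultdict(dict)
    for (g, c, umi), n in grouped.items():
        per_group[(g, c)][umi] = int(n)
    for (g, c), umi_counts in per_group.items():
        if g not in gpos or c not in cpos:
            continue
        if directional:
            X[gpos[g], cpos[c]] = _directional_cluster_count(umi_counts)
        else:
            X[gpos[g], cpos[c]] = len(umi_counts)
    return CountMatrix(X, list(gene_ids), list(cell_ids), dedup_mode="umi")


# ---------------------------------------------------------------------------
# Whitelist (knee) estimation


def estimate_whitelist(barcode_counts: dict[str, int] | pd.Series) -> list[str]:
    """Estimate real cell barcodes from the rank/count knee.

    Barcodes are sorted by read count; the cutoff is placed at the
    steepest drop of the log-count curve (the knee cliff), and everything
    above it is kept.
    """
    if isinstance(barcode_counts, dict):
        series = pd.Series(barcode_counts)
    else:
        series = barcode_counts
    series = series.sort_values(ascending=False)
    if len(series) <= 2:
        return list(series.index)
    logc = np.log10(series.to_numpy(dtype=float) + 1)
    cliff = int(np.argmin(np.diff(logc)))
    return list(series.index[: cliff + 1])


# ---------------------------------------------------------------------------
# End-to-end quantification


def _reads_dataframe_from_fastq(
    fastq1: str | os.PathLike,
    barcode_len: int,
    umi_len: int,
) -> pd.DataFrame:
    rows = {"barcode": [], "umi": [], "tag_gene": [], "seq2": []}
    for rec in read_fastq(fastq1):
        rows["barcode"].append(rec.seq[:barcode_len])
        rows["umi"].append(rec.seq[barcode_len : barcode_len + umi_len])
        parts = rec.comment.split("|")
        rows["tag_gene"].append(parts[1] if len(parts) > 1 else "")
        rows["seq2"].append("")
    return pd.DataFrame(rows)


def quantify(
    library: SequencingLibrary,
    fastq1: str | os.PathLike | None = None,
    fastq2: str | os.PathLike | None = None,
    batches: Iterable[ReadBatch] | None = None,
    reference: TranscriptReference | None = None,
    mode: str = "truth_tag",
    dedup: bool = True,
    directional: bool = True,
) -> tuple[CountMatrix, DemuxStats]:
    """Quantify simulated reads against the library's barcode bank.

    Reads come either from a FASTQ pair on disk or directly from in-memory
    :class:`ReadBatch` chunks (the two routes produce identical counts for
    the same reads). Cells are recovered by barcode demultiplexing; genes
    by the truth tag or k-mer alignment; molecules by UMI collapsing.
    """
    bank = library.barcode_bank
    matcher = BarcodeMatcher(bank)
    bl = bank.barcode_length
    ul = library.umi_bank.umi_length
    stats = DemuxStats()

    barcodes: list[str] = []
    umis: list[str] = []
    genes: list[str | None] = []

    voter = None
    if mode == "align":
        if reference is None:
            raise ValueError("align mode requires a reference")
        voter = KmerVoter(reference)

    if batches is not None:
        gene_ids_lib: list[str] = []
        for batch in batches:
            if not gene_ids_lib:
                # recover library gene ordering from the fragments table
                gene_ids_lib = list(dict.fromkeys(library.fragments.table["gene_id"]))
                frag_gene = (
                    library.fragments.table["gene_id"]
                    .map({g: i for i, g in enumerate(gene_ids_lib)})
                    .to_numpy()
                )
            n = len(batch)
            for row in range(n):
                s1 = batch.seq1[row].tobytes().decode()
                barcodes.append(s1[:bl])
                umis.append(s1[bl : bl + ul])
                if mode == "truth_tag":
                    genes.append(gene_ids_lib[frag_gene[batch.frag_idx[row]]])
                else:
                    genes.append(voter.assign(batch.seq2[row].tobytes().decode()))
    else:
        if fastq1 is None:
            raise ValueError("either fastq1 or batches must be given")
        reads2 = iter(read_fastq(fastq2)) if (fastq2 is not None and mode == "align") else None
        for rec in read_fastq(fastq1):
            barcodes.append(rec.seq[:bl])
            umis.append(rec.seq[bl : bl + ul])
            if mode == "truth_tag":
                parts = rec.comment.split("|")
                if len(parts) < 2:
                    raise ValueError(f"read {rec.read_id} carries no truth tag")
                genes.append(parts[1])
            else:
                rec2 = next(reads2)
                genes.append(voter.assign(rec2.seq))

    stats.reads_total = len(barcodes)

    # vector-ish demux: resolve unique barcodes once
    bc_series = pd.Series(barcodes, dtype=object)
    unique_bcs = bc_series.unique()
    resolution: dict[str, tuple[str | None, bool]] = {
        bc: matcher.match(bc) for bc in unique_bcs
    }
    cells = np.array([resolution[bc][0] for bc in barcodes], dtype=object)
    corrected = np.array([resolution[bc][1] for bc in barcodes], dtype=bool)
    genes_arr = np.array(genes, dtype=object)

    no_cell = np.array([c is None for c in cells], dtype=bool)
    no_gene = ~no_cell & np.array([g is None or g == "" for g in genes_arr], dtype=bool)
    keep = ~no_cell & ~no_gene
    stats.reads_discarded_barcode = int(no_cell.sum())
    stats.reads_discarded_gene = int(no_gene.sum())
    stats.reads_assigned = int(keep.sum())
    stats.reads_barcode_corrected = int((corrected & keep).sum())
    stats.validate()

    assigned = pd.DataFrame(
        {
            "cell_id": cells[keep],
            "gene_id": genes_arr[keep],
            "umi": np.array(umis, dtype=object)[keep],
        }
    )
    matrix = count_with_umi(
        assigned,
        dedup=dedup,
        directional=directional,
        cell_ids=bank.cell_ids,
    )
    return matrix, stats
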