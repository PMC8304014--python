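"""Shared file I/O: FASTA references, paired FASTQ, sparse count matrices, manifests.

All on-disk formats are plain text: FASTA in, gzip FASTQ (Phred+33) out,
MatrixMarket + TSV sidecars for matrices, flat ``key=value`` manifests.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.io
import scipy.sparse
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


@dataclass
class TranscriptReference:
    """Reference transcript sequences, one per gene.

    ``sequences`` maps gene id to an uppercase sequence over {A,C,G,T,N};
    ``lengths`` is kept in sync and feeds length normalization (TPM).
    """

    sequences: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    @property
    def lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.sequences.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def checksum(self) -> str:
        h = hashlib.md5()
        for g in sorted(self.sequences):
            h.update(g.encode())
            h.update(b"\x00")
            h.update(self.sequences[g].encode())
        return h.hexdigest()


def read_fasta(path: str | os.PathLike) -> TranscriptReference:
    """Read a FASTA file into a :class:`TranscriptReference`.

    The record id is the first whitespace-delimited header token
    (Gencode-style ``|``-separated ids are kept verbatim). Sequences are
    uppercased; characters outside {A,C,G,T,N} and duplicate ids are
    rejected.
    """
    ref = TranscriptReference()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if record.id in ref.sequences:
            raise ValueError(f"duplicate transcript id {record.id!r} in {path}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {record.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"transcript {record.id!r} has an empty sequence")
        ref.sequences[record.id] = seq
    if not ref.sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return ref


def write_fasta(reference: TranscriptReference, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in reference.sequences.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


@dataclass
class FastqRecord:
    read_id: str
    comment: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )


def _open_maybe_gzip(path: str | os.PathLike, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # level 1 (simulated reads compress well; speed matters more) and
            # a pinned mtime so identical runs give byte-identical files
            raw = gzip.GzipFile(
                filename="", fileobj=open(path, "wb"), mode="wb", compresslevel=1, mtime=0
            )
            return _io.TextIOWrapper(raw) if "t" in mode else raw
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(records: Iterable[FastqRecord], path: str | os.PathLike) -> int:
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            header = f"@{rec.read_id} {rec.comment}" if rec.comment else f"@{rec.read_id}"
            fh.write(f"{header}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


def read_fastq(path: str | os.PathLike) -> Iterator[FastqRecord]:
    with _open_maybe_gzip(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ header line: {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ separator for {header!r}")
            if any(ord(c) < 33 for c in qual):
                raise ValueError(f"quality character below '!' in record {header!r}")
            head = header[1:].rstrip("\n")
            read_id, _, comment = head.partition(" ")
            yield FastqRecord(read_id=read_id, comment=comment, seq=seq, qual=qual)


def write_fastq_pair(
    records: Iterable[tuple[FastqRecord, FastqRecord]], prefix: str | os.PathLike
) -> tuple[Path, Path]:
    """Write mate-paired records to ``<prefix>_R1.fastq.gz`` / ``_R2.fastq.gz``."""
    p1 = Path(f"{prefix}_R1.fastq.gz")
    p2 = Path(f"{prefix}_R2.fastq.gz")
    with _open_maybe_gzip(p1, "wt") as f1, _open_maybe_gzip(p2, "wt") as f2:
        for r1, r2 in records:
            f1.write(f"@{r1.read_id} {r1.comment}\n{r1.seq}\n+\n{r1.qual}\n")
            f2.write(f"@{r2.read_id} {r2.comment}\n{r2.seq}\n+\n{r2.qual}\n")
    return p1, p2


def read_fastq_pair(
    prefix: str | os.PathLike,
) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    p1 = Path(f"{prefix}_R1.fastq.gz")
    p2 = Path(f"{prefix}_R2.fastq.gz")
    for r1, r2 in zip(read_fastq(p1), read_fastq(p2), strict=True):
        yield r1, r2


# ---------------------------------------------------------------------------
# Count matrices (MTX + id sidecars)


def write_matrix(
    X: np.ndarray | scipy.sparse.spmatrix,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
    out_dir: str | os.PathLike,
    cell_labels: Sequence[tuple[str, str]] | None = None,
) -> None:
    """Write a genes x cells matrix as ``matrix.mtx`` plus id sidecars.

    ``genes.tsv`` holds one gene id per line; ``cells.tsv`` holds
    ``cell_id<TAB>major<TAB>sub`` (labels blank when unknown).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sp = scipy.sparse.csc_matrix(X)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), sp)
    with open(out_dir / "genes.tsv", "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")
    with open(out_dir / "cells.tsv", "w") as fh:
        for i, c in enumerate(cell_ids):
            if cell_labels is not None:
                major, sub = cell_labels[i]
            else:
                major = sub = ""
            fh.write(f"{c}\t{major}\t{sub}\n")


def read_matrix(
    in_dir: str | os.PathLike,
) -> tuple[np.ndarray, list[str], list[str], list[tuple[str, str]] | None]:
    """Read back what :func:`write_matrix` wrote. Lossless for integer input."""
    in_dir = Path(in_dir)
    X = scipy.io.mmread(str(in_dir / "matrix.mtx")).toarray()
    if np.allclose(X, np.round(X)):
        X = np.round(X).astype(np.int64)
    gene_ids = (in_dir / "genes.tsv").read_text().splitlines()
    cell_ids: list[str] = []
    labels: list[tuple[str, str]] = []
    have_labels = False
    for line in (in_dir / "cells.tsv").read_text().splitlines():
        parts = line.split("\t")
        cell_ids.append(parts[0])
        major = parts[1] if len(parts) > 1 else ""
        sub = parts[2] if len(parts) > 2 else ""
        if major or sub:
            have_labels = True
        labels.append((major, sub))
    return X, gene_ids, cell_ids, (labels if have_labels else None)


# ---------------------------------------------------------------------------
# Flat key=value manifests


def write_manifest(entries: dict[str, object], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}={value}\n")


def read_manifest(path: str | os.PathLike) -> dict[str, str]:
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    return entries


def file_checksum(path: str | os.PathLike) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
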