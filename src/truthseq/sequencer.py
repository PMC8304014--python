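"""On-machine sequencing simulation from a stored library.

Each requested read pair samples one molecule (with replacement, weighted
by its PCR copy number — modelling cluster sampling on a flow cell),
assembles read 1 as cell-barcode + UMI and read 2 as the 5' end of the
fragment with its PCR substitutions applied, then injects sequencing
errors and Phred qualities from position/base-indexed profile files.

Work is partitioned into fixed-size chunks of reads with one RNG stream
per chunk, so output is byte-identical regardless of the thread count.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .io import TranscriptReference, _open_maybe_gzip
from .library_builder import SequencingLibrary

logger = logging.getLogger(__name__)

ADAPTER = "AGATCGGAAGAGC"  # read-through padding for fragments shorter than read 2

QUAL_MIN = 2
QUAL_MAX = 41
DEFAULT_ERROR_RATE = 0.001  # total substitution probability per sequenced base
DEFAULT_Q_MEAN = 37.0
DEFAULT_Q_SD = 2.0
DEFAULT_ERROR_Q_MEAN = 25.0
DEFAULT_ERROR_Q_SD = 5.0

_TAG_CHUNK = 11
_CHUNK_SIZE = 65536

_CODE = np.full(256, 4, dtype=np.uint8)  # N and anything else -> 4
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i
_BASE_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Profiles


@dataclass
class ErrorProfile:
    """Per-base substitution probabilities ``p[position, ref, alt]``.

    Indexed by cycle position along the read and by the 4-letter codes
    A,C,G,T (diagonal is zero). For each (position, ref) the alt
    probabilities must sum to at most 1.
    """

    p: np.ndarray  # (read_len, 4, 4)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 3 or self.p.shape[1:] != (4, 4):
            raise ValueError("error profile must have shape (read_len, 4, 4)")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("error probabilities must lie in [0, 1]")
        if np.any(self.p.sum(axis=2) > 1 + 1e-9):
            raise ValueError("alt probabilities exceed 1 for some (position, base)")

    @property
    def read_len(self) -> int:
        return self.p.shape[0]

    @property
    def total(self) -> np.ndarray:
        """Total substitution probability per (position, ref)."""
        return self.p.sum(axis=2)

    @classmethod
    def uniform(cls, read_len: int, rate: float = DEFAULT_ERROR_RATE) -> "ErrorProfile":
        """Flat profile: total rate per base, split evenly over the 3 alts."""
        p = np.full((read_len, 4, 4), rate / 3.0)
        p[:, np.arange(4), np.arange(4)] = 0.0
        return cls(p)

    @classmethod
    def positional(cls, rates: Sequence[float]) -> "ErrorProfile":
        """Per-position total rates (e.g. a quality ramp), split evenly."""
        rates = np.asarray(rates, dtype=float)
        p = np.repeat(rates[:, None, None], 4, axis=1) * np.full((4, 4), 1 / 3.0)
        p[:, np.arange(4), np.arange(4)] = 0.0
        return cls(p)

    def extended(self, read_len: int) -> "ErrorProfile":
        if read_len <= self.read_len:
            return self
        logger.warning(
            "error profile covers %d positions, extending to %d with the uniform default",
            self.read_len,
            read_len,
        )
        ext = ErrorProfile.uniform(read_len).p
        ext[: self.read_len] = self.p
        return ErrorProfile(ext)

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("position\tref_base\talt_base\tprobability\n")
            for pos in range(self.read_len):
                for r, rb in enumerate("ACGT"):
                    for a, ab in enumerate("ACGT"):
                        if r == a:
                            continue
                        fh.write(f"{pos}\t{rb}\t{ab}\t{self.p[pos, r, a]:.8g}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike, read_len: int) -> "ErrorProfile":
        """Parse the tab-separated schema ``position ref_base alt_base
        probability`` (``*`` wildcards positions or bases); uncovered
        (position, base) cells fall back to the uniform default with a
        logged warning."""
        p = np.zeros((read_len, 4, 4))
        covered = np.zeros((read_len, 4), dtype=bool)
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            pos_s, ref_s, alt_s, prob_s = parts
            try:
                prob = float(prob_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad probability {prob_s!r}") from exc
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{path}:{lineno}: probability {prob} outside [0, 1]")
            positions = range(read_len) if pos_s == "*" else [int(pos_s)]
            refs = range(4) if ref_s == "*" else ["ACGT".index(ref_s)]
            for pos in positions:
                if pos >= read_len:
                    continue
                for r in refs:
                    if alt_s == "*":
                        for a in range(4):
                            if a != r:
                                p[pos, r, a] = prob / 3.0
                    else:
                        a = "ACGT".index(alt_s)
                        if a != r:
                            p[pos, r, a] = prob
                    covered[pos, r] = True
        if not covered.all():
            logger.warning(
                "%s: %d (position, base) cells missing, filled with uniform default",
                path,
                int((~covered).sum()),
            )
            default = DEFAULT_ERROR_RATE / 3.0
            for pos, r in zip(*np.nonzero(~covered)):
                p[pos, r] = default
                p[pos, r, r] = 0.0
        return cls(p)


@dataclass
class QualityProfile:
    """Phred-quality mean/spread per (position, base), with separate cells
    for bases that were substituted during sequencing. Drawn qualities are
    rounded and clamped to [2, 41]."""

    q_mean: np.ndarray  # (read_len, 4)
    q_sd: np.ndarray
    error_q_mean: np.ndarray
    error_q_sd: np.ndarray

    def __post_init__(self) -> None:
        shape = np.asarray(self.q_mean).shape
        for name in ("q_mean", "q_sd", "error_q_mean", "error_q_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape or arr.ndim != 2 or arr.shape[1] != 4:
                raise ValueError("quality profile arrays must share shape (read_len, 4)")
            setattr(self, name, arr)

    @property
    def read_len(self) -> int:
        return self.q_mean.shape[0]

    @classmethod
    def uniform(
        cls,
        read_len: int,
        mean: float = DEFAULT_Q_MEAN,
        sd: float = DEFAULT_Q_SD,
        error_mean: float = DEFAULT_ERROR_Q_MEAN,
        error_sd: float = DEFAULT_ERROR_Q_SD,
    ) -> "QualityProfile":
        full = np.full((read_len, 4), float(mean))
        return cls(full, np.full_like(full, sd), np.full_like(full, error_mean), np.full_like(full, error_sd))

    def extended(self, read_len: int) -> "QualityProfile":
        if read_len <= self.read_len:
            return self
        logger.warning(
            "quality profile covers %d positions, extending to %d with defaults",
            self.read_len,
            read_len,
        )
        base = QualityProfile.uniform(read_len)
        for name in ("q_mean", "q_sd", "error_q_mean", "error_q_sd"):
            arr = getattr(base, name)
            arr[: self.read_len] = getattr(self, name)
        return base

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("position\tbase\tmean_q\tsd_q\tis_error\n")
            for pos in range(self.read_len):
                for b, bb in enumerate("ACGT"):
                    fh.write(f"{pos}\t{bb}\t{self.q_mean[pos, b]:g}\t{self.q_sd[pos, b]:g}\t0\n")
                    fh.write(
                        f"{pos}\t{bb}\t{self.error_q_mean[pos, b]:g}\t{self.error_q_sd[pos, b]:g}\t1\n"
                    )

    @classmethod
    def from_file(cls, path: str | os.PathLike, read_len: int) -> "QualityProfile":
        """Parse ``position base mean_q sd_q is_error`` rows (``*`` wildcards
        allowed); missing cells fall back to defaults with a warning."""
        prof = cls.uniform(read_len)
        covered = np.zeros((read_len, 4, 2), dtype=bool)
        lines = Path(path).read_text().splitlines()
        for lineno, line in enumerate(lines, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            pos_s, base_s, mean_s, sd_s, err_s = parts
            mean, sd = float(mean_s), float(sd_s)
            if sd < 0:
                raise ValueError(f"{path}:{lineno}: negative quality spread")
            is_err = err_s.strip() in ("1", "true", "True")
            positions = range(read_len) if pos_s == "*" else [int(pos_s)]
            bases = range(4) if base_s == "*" else ["ACGT".index(base_s)]
            for pos in positions:
                if pos >= read_len:
                    continue
                for b in bases:
                    if is_err:
                        prof.error_q_mean[pos, b] = mean
                        prof.error_q_sd[pos, b] = sd
                    else:
                        prof.q_mean[pos, b] = mean
                        prof.q_sd[pos, b] = sd
                    covered[pos, b, int(is_err)] = True
        if not covered.all():
            logger.warning(
                "%s: %d quality cells missing, defaults used",
                path,
                int((~covered).sum()),
            )
        return prof


def load_profiles(
    error_path: str | os.PathLike | None,
    quality_path: str | os.PathLike | None,
    read_len: int,
) -> tuple[ErrorProfile, QualityProfile]:
    """Load profile files, falling back to uniform defaults when absent."""
    if error_path is None:
        err = ErrorProfile.uniform(read_len)
    else:
        err = ErrorProfile.from_file(error_path, read_len)
    if quality_path is None:
        qual = QualityProfile.uniform(read_len)
    else:
        qual = QualityProfile.from_file(quality_path, read_len)
    return err, qual


# ---------------------------------------------------------------------------
# Run configuration and read assembly


@dataclass
class RunConfig:
    depth: int  # total read pairs to emit
    read2_len: int = 75
    threads: int = 1
    seed: int = 0
    run_id: str = "run1"
    platform_rule: str = "droplet-v1"  # read1 = barcode||UMI, read2 = cDNA 5' end
    pad_mode: str = "adapter"  # or "N"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.read2_len < 1:
            raise ValueError("read2_len must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.platform_rule != "droplet-v1":
            raise ValueError(f"unknown platform rule {self.platform_rule!r}")
        if self.pad_mode not in ("adapter", "N"):
            raise ValueError("pad_mode must be 'adapter' or 'N'")


@dataclass
class ReadBatch:
    """A chunk of assembled, noise-injected read pairs as byte matrices."""

    start_index: int
    seq1: np.ndarray  # (n, read1_len) uint8
    qual1: np.ndarray
    seq2: np.ndarray  # (n, read2_len) uint8
    qual2: np.ndarray
    frag_idx: np.ndarray  # fragment row in the library
    mol_idx: np.ndarray  # molecule index within the fragment's PCR tree

    def __len__(self) -> int:
        return len(self.frag_idx)


class _LibraryIndex:
    """Flat numpy views over a library for fast per-chunk assembly."""

    def __init__(self, library: SequencingLibrary, reference: TranscriptReference):
        table = library.fragments.table
        self.cell_ids = library.barcode_bank.cell_ids
        cell_pos = {c: i for i, c in enumerate(self.cell_ids)}
        genes_in_lib = list(dict.fromkeys(table["gene_id"]))
        gene_pos = {g: i for i, g in enumerate(genes_in_lib)}
        self.gene_ids = genes_in_lib

        self.frag_cell = table["cell_id"].map(cell_pos).to_numpy(dtype=np.int64)
        self.frag_gene = table["gene_id"].map(gene_pos).to_numpy(dtype=np.int64)
        self.frag_copy = table["copy_index"].to_numpy(dtype=np.int64)
        self.start = table["start"].to_numpy(dtype=np.int64)
        self.end = table["end"].to_numpy(dtype=np.int64)

        seqs = [reference[g] for g in genes_in_lib]
        self.gene_offset = np.concatenate([[0], np.cumsum([len(s) for s in seqs])])[:-1]
        self.ref_concat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)

        bl = library.barcode_bank.barcode_length
        self.bc_bytes = np.frombuffer(
            "".join(library.barcode_bank.barcodes).encode(), dtype=np.uint8
        ).reshape(len(self.cell_ids), bl)
        ul = library.umi_bank.umi_length
        self.umi_bytes = np.frombuffer(
            "".join(library.umi_bank.umis).encode(), dtype=np.uint8
        ).reshape(len(library.umi_bank), ul)

        self.copy_number = library.pcr.copy_number.astype(np.float64)
        self.cum_weights = np.cumsum(self.copy_number)
        self.total_molecules = self.cum_weights[-1]
        # per-molecule substitution maps, resolved once per mutated fragment
        self.variants = {
            f: rec.molecule_variants() for f, rec in library.pcr.mutated.items()
        }
        self.read1_len = bl + ul
        self.barcode_len = bl


def _apply_noise_matrix(
    seq: np.ndarray,
    rng: np.random.Generator,
    error: ErrorProfile,
    quality: QualityProfile,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized substitution + quality draw over an (n, L) byte matrix.

    N bases are never substituted and always receive quality 2.
    """
    n, L = seq.shape
    codes = _CODE[seq]
    is_n = codes == 4
    safe = np.where(is_n, 0, codes)
    pos = np.broadcast_to(np.arange(L), (n, L))

    tot = error.total[pos, safe]
    u = rng.random((n, L))
    err = (u < tot) & ~is_n

    out = seq.copy()
    if err.any():
        e_pos = pos[err]
        e_ref = safe[err]
        probs = error.p[e_pos, e_ref]  # (k, 4)
        c = np.cumsum(probs, axis=1)
        c /= c[:, -1][:, None]
        u2 = rng.random(len(c))
        alt = (u2[:, None] > c).sum(axis=1)
        out[err] = _BASE_BYTES[alt]
    codes_after = _CODE[out]
    safe_after = np.where(is_n, 0, codes_after)

    q_mean = np.where(err, quality.error_q_mean[pos, safe_after], quality.q_mean[pos, safe_after])
    q_sd = np.where(err, quality.error_q_sd[pos, safe_after], quality.q_sd[pos, safe_after])
    q = np.rint(rng.normal(q_mean, q_sd)).astype(np.int64)
    q = np.clip(q, QUAL_MIN, QUAL_MAX)
    q[is_n] = QUAL_MIN
    return out, (q + 33).astype(np.uint8)


def apply_sequencing_noise(
    seq: str,
    profiles: tuple[ErrorProfile, QualityProfile],
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Substitute bases and draw Phred qualities for one read sequence."""
    error, quality = profiles
    error = error.extended(len(seq))
    quality = quality.extended(len(seq))
    mat = np.frombuffer(seq.encode(), dtype=np.uint8)[None, :].copy()
    out, qual = _apply_noise_matrix(mat, rng, error, quality)
    return out[0].tobytes().decode(), qual[0].tobytes().decode()


def _assemble_chunk(
    index: _LibraryIndex,
    config: RunConfig,
    err1: ErrorProfile,
    qual1: QualityProfile,
    err2: ErrorProfile,
    qual2: QualityProfile,
    chunk_idx: int,
    count: int,
) -> ReadBatch:
    rng = _stream(config.seed, _TAG_CHUNK, chunk_idx)
    u = rng.random(count) * index.total_molecules
    frag = np.searchsorted(index.cum_weights, u, side="right")
    mol = rng.integers(0, index.copy_number[frag].astype(np.int64))

    # read 1: barcode || UMI
    seq1 = np.concatenate(
        [index.bc_bytes[index.frag_cell[frag]], index.umi_bytes[frag]], axis=1
    )

    # read 2: fragment 5' end, padded with adapter read-through (or N)
    L2 = config.read2_len
    rel = np.arange(L2)
    frag_len = (index.end - index.start)[frag]
    pos = (index.gene_offset[index.frag_gene[frag]] + index.start[frag])[:, None] + rel
    valid = rel[None, :] < frag_len[:, None]
    gathered = index.ref_concat[np.minimum(pos, len(index.ref_concat) - 1)]
    if config.pad_mode == "adapter":
        adapter = np.frombuffer(ADAPTER.encode(), dtype=np.uint8)
        pad = adapter[(rel[None, :] - frag_len[:, None]) % len(adapter)]
    else:
        pad = np.full((count, L2), ord("N"), dtype=np.uint8)
    seq2 = np.where(valid, gathered, pad)

    # PCR substitutions carried by the sampled molecule
    if index.variants:
        for row in range(count):
            f = int(frag[row])
            var = index.variants.get(f)
            if var is None:
                continue
            for off, alt in var[int(mol[row])].items():
                if off < L2:
                    seq2[row, off] = ord(alt)

    noisy1, q1 = _apply_noise_matrix(seq1, rng, err1, qual1)
    noisy2, q2 = _apply_noise_matrix(seq2, rng, err2, qual2)
    return ReadBatch(
        start_index=chunk_idx * _CHUNK_SIZE,
        seq1=noisy1,
        qual1=q1,
        seq2=noisy2,
        qual2=q2,
        frag_idx=frag,
        mol_idx=mol,
    )


def iter_read_batches(
    library: SequencingLibrary,
    reference: TranscriptReference,
    config: RunConfig,
    profiles: tuple[ErrorProfile, QualityProfile] | None = None,
) -> Iterator[ReadBatch]:
    """Generate read batches in deterministic read-index order.

    The RNG stream of a batch depends only on (seed, chunk index), never on
    thread scheduling.
    """
    if library.total_molecules() == 0:
        raise ValueError("cannot sequence an empty library")
    ref_ck = library.manifest.get("reference_checksum")
    if ref_ck and ref_ck != reference.checksum():
        logger.warning(
            "reference checksum %s does not match the one recorded when the "
            "library was built (%s)",
            reference.checksum(),
            ref_ck,
        )
    index = _LibraryIndex(library, reference)
    if profiles is None:
        profiles = load_profiles(None, None, max(index.read1_len, config.read2_len))
    error, quality = profiles
    err1 = error.extended(index.read1_len)
    qu1 = quality.extended(index.read1_len)
    err2 = error.extended(config.read2_len)
    qu2 = quality.extended(config.read2_len)

    n_chunks = (config.depth + _CHUNK_SIZE - 1) // _CHUNK_SIZE
    sizes = [
        min(_CHUNK_SIZE, config.depth - i * _CHUNK_SIZE) for i in range(n_chunks)
    ]

    def work(i: int) -> ReadBatch:
        return _assemble_chunk(index, config, err1, qu1, err2, qu2, i, sizes[i])

    if config.threads == 1:
        for i in range(n_chunks):
            yield work(i)
    else:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            yield from pool.map(work, range(n_chunks))


def _batch_fastq_bytes(
    batch: ReadBatch, index: _LibraryIndex, config: RunConfig
) -> tuple[bytes, bytes]:
    buf1 = bytearray()
    buf2 = bytearray()
    cells = index.cell_ids
    genes = index.gene_ids
    for row in range(len(batch)):
        f = batch.frag_idx[row]
        header = (
            f"@SIM:{config.run_id}:{batch.start_index + row} "
            f"{cells[index.frag_cell[f]]}|{genes[index.frag_gene[f]]}|"
            f"{index.frag_copy[f]}|{batch.mol_idx[row]}\n"
        ).encode()
        buf1 += header
        buf1 += batch.seq1[row].tobytes()
        buf1 += b"\n+\n"
        buf1 += batch.qual1[row].tobytes()
        buf1 += b"\n"
        buf2 += header
        buf2 += batch.seq2[row].tobytes()
        buf2 += b"\n+\n"
        buf2 += batch.qual2[row].tobytes()
        buf2 += b"\n"
    return bytes(buf1), bytes(buf2)


def sequence_library(
    library: SequencingLibrary,
    reference: TranscriptReference,
    config: RunConfig,
    profiles: tuple[ErrorProfile, QualityProfile] | None = None,
    out_prefix: str | os.PathLike = "simulated",
) -> tuple[Path, Path]:
    """Run the sequencing simulation and write a gzip FASTQ pair.

    Returns the two mate file paths (``<prefix>_R1.fastq.gz`` and
    ``_R2.fastq.gz``). Identical (library, config, profiles, seed) produce
    byte-identical output at any thread count.
    """
    index = _LibraryIndex(library, reference)
    p1 = Path(f"{out_prefix}_R1.fastq.gz")
    p2 = Path(f"{out_prefix}_R2.fastq.gz")
    mode = "wt"
    with _open_maybe_gzip(p1, "wb") as f1, _open_maybe_gzip(p2, "wb") as f2:
        for batch in iter_read_batches(library, reference, config, profiles):
            b1, b2 = _batch_fastq_bytes(batch, index, config)
            f1.write(b1)
            f2.write(b2)
    return p1, p2
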