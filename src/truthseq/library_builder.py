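"""Persistent simulated sequencing library.

Four sub-libraries make up one library, mirroring a tag-based (UMI)
single-cell protocol:

* **fragment library** — one record per true mRNA copy, stored as (start,
  end) offsets on the gene's reference transcript after random head/tail
  truncation; one file per cell on disk;
* **UMI bank** — one random fixed-length UMI per original fragment (all PCR
  copies of a fragment share it);
* **barcode bank** — one fixed-length cell barcode per cell, generated by
  rejection sampling under a minimum pairwise Hamming distance;
* **PCR control library** — per fragment, the number of molecules after a
  set number of amplification cycles and the full provenance of every
  substitution PCR introduced.

The library is written to disk once and reused read-only by any number of
sequencing runs with different depths/seeds.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ground_truth import GroundTruthMatrix
from .io import TranscriptReference, read_manifest, write_manifest

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = {c: i for i, c in enumerate("ACGT")}

LIBRARY_FORMAT_VERSION = "1"

# RNG stream tags: keep per-purpose streams independent of each other
_TAG_FRAGMENT = 1
_TAG_PCR_GLOBAL = 2
_TAG_PCR_TREE = 3
_TAG_BARCODE = 4
_TAG_UMI = 5


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def random_sequences(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n random ACGT sequences as a (n, length) uint8 byte matrix."""
    return BASES[rng.integers(0, 4, size=(n, length))]


def decode_seq(row: np.ndarray) -> str:
    return row.tobytes().decode("ascii")


def synthesize_transcripts(
    gene_ids: Sequence[str],
    mean_length: int = 500,
    min_length: int = 100,
    seed: int = 0,
) -> TranscriptReference:
    """Random transcript sequences for testing (lognormal-ish length spread)."""
    rng = _stream(seed, 99)
    ref = TranscriptReference()
    for g in gene_ids:
        length = max(min_length, int(rng.lognormal(np.log(mean_length), 0.35)))
        ref.sequences[g] = decode_seq(random_sequences(rng, 1, length)[0])
    return ref


# ---------------------------------------------------------------------------
# Fragment library


@dataclass
class TruncationParams:
    """Head/tail truncation model for single mRNA copies.

    Missing lengths are independent Geometric draws (support starting at 0)
    whose means are the given fractions of the transcript length. Draws
    producing an empty fragment are redrawn up to ``max_redraws`` times,
    after which the copy is emitted full-length.
    """

    mean_head_fraction: float = 0.1
    mean_tail_fraction: float = 0.1
    max_redraws: int = 10

    def __post_init__(self) -> None:
        if self.mean_head_fraction < 0 or self.mean_tail_fraction < 0:
            raise ValueError("truncation fractions must be >= 0")


@dataclass
class FragmentLibrary:
    """All fragment records in canonical (cell, gene, copy) order.

    ``table`` columns: cell_id, gene_id, copy_index, start, end.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cell_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["cell_id"]))

    def keys(self) -> pd.DataFrame:
        return self.table[["cell_id", "gene_id", "copy_index"]]


def _geometric0(rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
    """Geometric with support {0, 1, ...} and the given per-element mean."""
    p = 1.0 / (mean + 1.0)
    return rng.geometric(p) - 1


def fragment_transcripts(
    truth: GroundTruthMatrix,
    reference: TranscriptReference,
    trunc_params: TruncationParams | None = None,
    seed: int = 0,
) -> FragmentLibrary:
    """Cut every true mRNA copy into one recorded fragment.

    For each cell c and gene g with count k, exactly k records are emitted;
    each copy independently loses a random head and tail stretch.
    """
    trunc = trunc_params or TruncationParams()
    lengths = reference.lengths
    # genes with nonzero counts must have a reference sequence
    nonzero = np.asarray(truth.counts).sum(axis=1) > 0
    for gi in np.nonzero(nonzero)[0]:
        g = truth.gene_ids[gi]
        if g not in lengths:
            raise KeyError(f"gene {g!r} has nonzero counts but no reference transcript")

    rng = _stream(seed, _TAG_FRAGMENT)
    counts = np.asarray(truth.counts)
    gene_len = np.array([lengths.get(g, 1) for g in truth.gene_ids], dtype=np.int64)

    # expand (gene, cell) pairs with counts into per-fragment rows, cell-major
    gi_idx, ci_idx = np.nonzero(counts.T > 0)  # transposed -> cell-major order
    ci_idx, gi_idx = gi_idx, ci_idx  # rename: first axis was cells
    k = counts[gi_idx, ci_idx]
    cell_rep = np.repeat(ci_idx, k)
    gene_rep = np.repeat(gi_idx, k)
    copy_index = np.concatenate([np.arange(n) for n in k]) if len(k) else np.empty(0, int)
    L = gene_len[gene_rep]

    head = _geometric0(rng, trunc.mean_head_fraction * L.astype(float))
    tail = _geometric0(rng, trunc.mean_tail_fraction * L.astype(float))
    start = head
    end = L - tail
    bad = start >= end
    for _ in range(trunc.max_redraws):
        if not bad.any():
            break
        nb = int(bad.sum())
        start[bad] = _geometric0(rng, trunc.mean_head_fraction * L[bad].astype(float))
        end[bad] = L[bad] - _geometric0(rng, trunc.mean_tail_fraction * L[bad].astype(float))
        bad = start >= end
    if bad.any():
        start[bad] = 0
        end[bad] = L[bad]

    cells = np.array(truth.cell_ids, dtype=object)
    genes = np.array(truth.gene_ids, dtype=object)
    table = pd.DataFrame(
        {
            "cell_id": cells[cell_rep],
            "gene_id": genes[gene_rep],
            "copy_index": copy_index.astype(np.int64),
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
        }
    )
    return FragmentLibrary(table)


# ---------------------------------------------------------------------------
# Barcode and UMI banks


@dataclass
class BarcodeBank:
    """cell_id -> fixed-length barcode, pairwise Hamming >= min_hamming."""

    cell_ids: list[str]
    barcodes: list[str]
    min_hamming: int = 2

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.barcodes):
            raise ValueError("one barcode per cell required")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be distinct")

    @property
    def barcode_length(self) -> int:
        return len(self.barcodes[0])

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.barcodes))

    def min_pairwise_hamming(self) -> int:
        """Exhaustive minimum pairwise Hamming distance over the bank."""
        arr = np.frombuffer("".join(self.barcodes).encode(), dtype=np.uint8).reshape(
            len(self.barcodes), -1
        )
        best = arr.shape[1]
        for i in range(len(arr) - 1):
            d = (arr[i + 1 :] != arr[i]).sum(axis=1).min()
            best = min(best, int(d))
        return best


_BARCODE_ATTEMPTS_PER_CELL = 10_000


def get_barcode_bank(
    cells: int | Sequence[str],
    barcode_length: int = 16,
    min_hamming: int = 2,
    seed: int = 0,
) -> BarcodeBank:
    """Random barcode bank under a minimum pairwise Hamming distance.

    Candidates are drawn uniformly and rejected if any accepted barcode is
    closer than ``min_hamming``; the attempt budget is bounded so an
    infeasible request (e.g. more barcodes than the alphabet supports)
    raises instead of looping forever.
    """
    if isinstance(cells, int):
        if cells < 1:
            raise ValueError("n_cells must be >= 1")
        cell_ids = [f"cell_{i:05d}" for i in range(cells)]
    else:
        cell_ids = list(cells)
    n = len(cell_ids)
    if barcode_length < 1:
        raise ValueError("barcode_length must be >= 1")

    rng = _stream(seed, _TAG_BARCODE)
    accepted = np.empty((n, barcode_length), dtype=np.uint8)
    count = 0
    while count < n:
        attempts = 0
        while True:
            cand = random_sequences(rng, 1, barcode_length)[0]
            if count == 0:
                break
            dist = (accepted[:count] != cand).sum(axis=1).min()
            if dist >= max(min_hamming, 1):
                break
            attempts += 1
            if attempts >= _BARCODE_ATTEMPTS_PER_CELL:
                raise RuntimeError(
                    f"could not place barcode {count + 1}/{n} of length "
                    f"{barcode_length} with min Hamming distance {min_hamming}: "
                    f"attempt budget exhausted (request infeasible or nearly so)"
                )
        accepted[count] = cand
        count += 1
    barcodes = [decode_seq(accepted[i]) for i in range(n)]
    return BarcodeBank(cell_ids, barcodes, min_hamming=min_hamming)


@dataclass
class UMIBank:
    """One UMI per fragment key, aligned with the fragment table rows.

    UMIs are drawn uniformly over the 4^length sequence space; collisions
    between different fragments are allowed (as random assignment implies).
    """

    keys: pd.DataFrame  # cell_id, gene_id, copy_index — same order as fragments
    umis: np.ndarray  # object array of strings

    def __post_init__(self) -> None:
        if len(self.keys) != len(self.umis):
            raise ValueError("one UMI per fragment key required")

    @property
    def umi_length(self) -> int:
        return len(self.umis[0]) if len(self.umis) else 0

    def __len__(self) -> int:
        return len(self.umis)


def get_umi_bank(
    fragment_keys: pd.DataFrame | FragmentLibrary, umi_length: int = 10, seed: int = 0
) -> UMIBank:
    """Attach one uniformly random UMI to every fragment."""
    if isinstance(fragment_keys, FragmentLibrary):
        keys = fragment_keys.keys().copy()
    else:
        keys = fragment_keys[["cell_id", "gene_id", "copy_index"]].copy()
    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")
    rng = _stream(seed, _TAG_UMI)
    mat = random_sequences(rng, len(keys), umi_length)
    umis = np.array([decode_seq(row) for row in mat], dtype=object)
    return UMIBank(keys.reset_index(drop=True), umis)


# ---------------------------------------------------------------------------
# PCR amplification


@dataclass
class PCRParams:
    cycles: int = 3
    efficiency: float = 0.9  # per-cycle duplication probability
    mutation_rate: float = 1e-5  # per-base per-duplication substitution probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class PCRMutationRecord:
    """Provenance of substitutions in one fragment's amplification tree.

    ``parents[i]`` is the parent molecule of molecule ``i`` (molecule 0 is
    the original; parents[0] == -1). ``events`` rows are
    (molecule_index, offset, ref_base, alt_base, cycle_introduced), where
    ref_base is the base the parent carried at that offset (so stacked
    mutations chain correctly) and offsets are relative to fragment start.
    """

    parents: np.ndarray  # (copy_number,) int
    events: list[tuple[int, int, str, str, int]] = field(default_factory=list)

    def molecule_variants(self) -> list[dict[int, str]]:
        """Final offset -> base map per molecule, by replaying inheritance."""
        states: list[dict[int, str]] = [dict() for _ in range(len(self.parents))]
        by_mol: dict[int, list[tuple[int, int, str, str, int]]] = {}
        for ev in self.events:
            by_mol.setdefault(ev[0], []).append(ev)
        for i in range(len(self.parents)):
            p = self.parents[i]
            if p >= 0:
                states[i] = dict(states[p])
            for _, off, _ref, alt, _cyc in by_mol.get(i, ()):
                states[i][off] = alt
        return states


@dataclass
class PCRControlLibrary:
    """Per-fragment molecule counts plus mutation provenance.

    ``copy_number`` aligns with the fragment table; only fragments whose
    tree acquired at least one substitution carry a full
    :class:`PCRMutationRecord` (mutation-free trees need no provenance:
    every molecule is identical to the template).
    """

    copy_number: np.ndarray  # (n_fragments,) int
    mutated: dict[int, PCRMutationRecord]  # fragment row index -> record
    params: PCRParams

    def __len__(self) -> int:
        return len(self.copy_number)

    def n_mutations(self) -> int:
        return sum(len(r.events) for r in self.mutated.values())


def pcr_amplify(
    fragments: FragmentLibrary,
    umi_bank: UMIBank,
    reference: TranscriptReference,
    params: PCRParams,
) -> PCRControlLibrary:
    """Simulate exponential PCR amplification of every fragment.

    Starting from one molecule, each cycle every existing molecule
    duplicates with probability ``efficiency``; every base of a newly
    synthesized strand substitutes with probability ``mutation_rate`` and
    daughters inherit all parental mutations. Molecule counts are drawn
    vectorized across fragments; the (rare) fragments that acquire
    substitutions get an exact per-molecule tree resolved from a dedicated
    per-fragment stream, so results are deterministic given the seed.
    """
    if len(umi_bank) != len(fragments):
        raise ValueError("umi_bank is not aligned with the fragment library")
    F = len(fragments)
    start = fragments.table["start"].to_numpy()
    end = fragments.table["end"].to_numpy()
    L = (end - start).astype(np.int64)

    rng = _stream(params.seed, _TAG_PCR_GLOBAL)
    n = np.ones(F, dtype=np.int64)
    D = np.zeros((F, params.cycles), dtype=np.int64)
    for t in range(params.cycles):
        d = rng.binomial(n, params.efficiency)
        D[:, t] = d
        n = n + d

    if params.mutation_rate > 0 and params.cycles > 0:
        K = rng.binomial(D * L[:, None], params.mutation_rate)
    else:
        K = np.zeros_like(D)

    mutated: dict[int, PCRMutationRecord] = {}
    hot = np.nonzero(K.sum(axis=1))[0]
    if len(hot):
        genes = fragments.table["gene_id"].to_numpy()
        for f in hot:
            seq = reference[genes[f]][start[f] : end[f]]
            frng = _stream(params.seed, _TAG_PCR_TREE, int(f))
            mutated[int(f)] = _resolve_tree(frng, D[f], K[f], seq)
    return PCRControlLibrary(copy_number=n, mutated=mutated, params=params)


def _resolve_tree(
    rng: np.random.Generator,
    daughters_per_cycle: np.ndarray,
    events_per_cycle: np.ndarray,
    fragment_seq: str,
) -> PCRMutationRecord:
    L = len(fragment_seq)
    parents = [-1]
    states: list[dict[int, str]] = [{}]
    events: list[tuple[int, int, str, str, int]] = []
    for t in range(len(daughters_per_cycle)):
        d = int(daughters_per_cycle[t])
        n_existing = len(parents)
        chosen = np.sort(rng.choice(n_existing, size=d, replace=False))
        first_new = n_existing
        for p in chosen:
            parents.append(int(p))
            states.append(states[p])
        placed: set[tuple[int, int]] = set()
        for _ in range(int(events_per_cycle[t])):
            while True:
                j = int(rng.integers(d))
                off = int(rng.integers(L))
                if (j, off) not in placed:
                    placed.add((j, off))
                    break
            mol = first_new + j
            state = dict(states[mol])
            ref = state.get(off, fragment_seq[off])
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            state[off] = alt
            states[mol] = state
            events.append((mol, off, ref, alt, t + 1))
    return PCRMutationRecord(parents=np.array(parents, dtype=np.int64), events=events)


# ---------------------------------------------------------------------------
# The assembled library and its on-disk form


@dataclass
class SequencingLibrary:
    """The four sub-libraries plus the run manifest, ready for sequencing."""

    barcode_bank: BarcodeBank
    umi_bank: UMIBank
    fragments: FragmentLibrary
    pcr: PCRControlLibrary
    manifest: dict[str, str]

    def validate(self) -> None:
        if len(self.umi_bank) != len(self.fragments):
            raise ValueError("umi bank not aligned with fragment library")
        if len(self.pcr.copy_number) != len(self.fragments):
            raise ValueError("pcr control not aligned with fragment library")
        cells = set(self.fragments.table["cell_id"])
        known = set(self.barcode_bank.cell_ids)
        missing = cells - known
        if missing:
            raise ValueError(f"cells without barcodes: {sorted(missing)[:5]}")

    def total_molecules(self) -> int:
        return int(self.pcr.copy_number.sum())


def build_library(
    truth: GroundTruthMatrix,
    reference: TranscriptReference,
    barcode_length: int = 16,
    umi_length: int = 10,
    min_hamming: int = 2,
    trunc_params: TruncationParams | None = None,
    pcr_params: PCRParams | None = None,
    seed: int = 0,
) -> SequencingLibrary:
    """Build all four sub-libraries from a ground-truth matrix.

    One top-level seed drives independent per-stage streams; every
    parameter lands in the manifest so a stored library is self-describing.
    """
    pcr_params = pcr_params or PCRParams(seed=seed)
    trunc = trunc_params or TruncationParams()
    fragments = fragment_transcripts(truth, reference, trunc, seed=seed)
    barcode_bank = get_barcode_bank(
        truth.cell_ids, barcode_length, min_hamming=min_hamming, seed=seed
    )
    umi_bank = get_umi_bank(fragments, umi_length, seed=seed)
    pcr = pcr_amplify(fragments, umi_bank, reference, pcr_params)
    manifest = {
        "format_version": LIBRARY_FORMAT_VERSION,
        "barcode_length": barcode_length,
        "umi_length": umi_length,
        "min_hamming": min_hamming,
        "cycles": pcr_params.cycles,
        "efficiency": pcr_params.efficiency,
        "mutation_rate": pcr_params.mutation_rate,
        "mean_head_fraction": trunc.mean_head_fraction,
        "mean_tail_fraction": trunc.mean_tail_fraction,
        "seed": seed,
        "pcr_seed": pcr_params.seed,
        "n_cells": len(truth.cell_ids),
        "n_fragments": len(fragments),
        "reference_checksum": reference.checksum(),
    }
    lib = SequencingLibrary(
        barcode_bank, umi_bank, fragments, pcr, {k: str(v) for k, v in manifest.items()}
    )
    lib.validate()
    return lib


def _encode_events(rec: PCRMutationRecord) -> str:
    return ";".join(f"{m}:{o}:{r}:{a}:{c}" for m, o, r, a, c in rec.events)


def _decode_events(text: str) -> list[tuple[int, int, str, str, int]]:
    out = []
    for part in text.split(";"):
        if not part:
            continue
        m, o, r, a, c = part.split(":")
        out.append((int(m), int(o), r, a, int(c)))
    return out


def write_library(library: SequencingLibrary, path: str | os.PathLike) -> Path:
    """Persist the library: manifest, banks, PCR control, per-cell fragments."""
    library.validate()
    root = Path(path)
    (root / "fragments").mkdir(parents=True, exist_ok=True)
    write_manifest(library.manifest, root / "manifest.txt")

    pd.DataFrame(
        {"cell_id": library.barcode_bank.cell_ids, "barcode": library.barcode_bank.barcodes}
    ).to_csv(root / "barcodes.tsv", sep="\t", index=False)

    umi_df = library.umi_bank.keys.copy()
    umi_df["umi"] = library.umi_bank.umis
    umi_df.to_csv(root / "umis.tsv", sep="\t", index=False)

    pcr_df = library.fragments.keys().copy()
    pcr_df["copy_number"] = library.pcr.copy_number
    parents = np.full(len(pcr_df), "", dtype=object)
    events = np.full(len(pcr_df), "", dtype=object)
    for f, rec in library.pcr.mutated.items():
        parents[f] = ",".join(str(p) for p in rec.parents)
        events[f] = _encode_events(rec)
    pcr_df["parents"] = parents
    pcr_df["mutations"] = events
    pcr_df.to_csv(root / "pcr_control.tsv", sep="\t", index=False)

    for cell_id, grp in library.fragments.table.groupby("cell_id", sort=False):
        grp[["gene_id", "copy_index", "start", "end"]].to_csv(
            root / "fragments" / f"{cell_id}.tsv", sep="\t", index=False
        )
    return root


def read_library(path: str | os.PathLike) -> SequencingLibrary:
    """Load a stored library; read-only with respect to the files."""
    root = Path(path)
    manifest_path = root / "manifest.txt"
    if not manifest_path.exists():
        raise FileNotFoundError(f"library manifest missing: {manifest_path}")
    manifest = read_manifest(manifest_path)

    for name in ("barcodes.tsv", "umis.tsv", "pcr_control.tsv"):
        if not (root / name).exists():
            raise FileNotFoundError(f"library sub-file missing: {root / name}")
    if not (root / "fragments").is_dir():
        raise FileNotFoundError(f"library sub-directory missing: {root / 'fragments'}")

    bc = pd.read_csv(root / "barcodes.tsv", sep="\t")
    barcode_bank = BarcodeBank(
        list(bc["cell_id"]), list(bc["barcode"]), int(manifest.get("min_hamming", 2))
    )

    frames = []
    for cell_id in barcode_bank.cell_ids:
        f = root / "fragments" / f"{cell_id}.tsv"
        if not f.exists():
            continue  # cells with zero fragments have no file
        df = pd.read_csv(f, sep="\t")
        df.insert(0, "cell_id", cell_id)
        frames.append(df)
    if not frames:
        raise FileNotFoundError(f"no fragment files under {root / 'fragments'}")
    fragments = FragmentLibrary(pd.concat(frames, ignore_index=True))

    umi_df = pd.read_csv(root / "umis.tsv", sep="\t")
    umi_bank = UMIBank(
        umi_df[["cell_id", "gene_id", "copy_index"]],
        umi_df["umi"].to_numpy(dtype=object),
    )

    pcr_df = pd.read_csv(
        root / "pcr_control.tsv", sep="\t", keep_default_na=False, dtype={"parents": str, "mutations": str}
    )
    params = PCRParams(
        cycles=int(manifest.get("cycles", 3)),
        efficiency=float(manifest.get("efficiency", 0.9)),
        mutation_rate=float(manifest.get("mutation_rate", 1e-5)),
        seed=int(manifest.get("pcr_seed", 0)),
    )
    mutated: dict[int, PCRMutationRecord] = {}
    for f in np.nonzero((pcr_df["mutations"] != "").to_numpy())[0]:
        row = pcr_df.iloc[int(f)]
        mutated[int(f)] = PCRMutationRecord(
            parents=np.array([int(x) for x in row["parents"].split(",")], dtype=np.int64),
            events=_decode_events(row["mutations"]),
        )
    pcr = PCRControlLibrary(
        copy_number=pcr_df["copy_number"].to_numpy(dtype=np.int64),
        mutated=mutated,
        params=params,
    )
    lib = SequencingLibrary(barcode_bank, umi_bank, fragments, pcr, manifest)
    lib.validate()
    return lib
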