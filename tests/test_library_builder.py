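import numpy as np
import pandas as pd
import pytest

from truthseq.ground_truth import GroundTruthMatrix
from truthseq.io import TranscriptReference
from truthseq.library_builder import (
    PCRParams,
    TruncationParams,
    build_library,
    fragment_transcripts,
    get_barcode_bank,
    get_umi_bank,
    pcr_amplify,
    read_library,
    synthesize_transcripts,
    write_library,
)


def _toy_truth(counts, gene_ids=None):
    counts = np.asarray(counts, dtype=np.int64)
    gene_ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    cells = [f"c{i}" for i in range(counts.shape[1])]
    return GroundTruthMatrix(counts, gene_ids, cells, [("m", "s")] * counts.shape[1])


class TestFragmentation:
    def test_copy_conservation(self, small_truth, small_reference):
        lib = fragment_transcripts(small_truth, small_reference, seed=0)
        per_pair = lib.table.groupby(["cell_id", "gene_id"]).size()
        for (cell, gene), n in per_pair.items():
            ci = small_truth.cell_ids.index(cell)
            gi = small_truth.gene_ids.index(gene)
            assert n == small_truth.counts[gi, ci]
        assert len(lib) == small_truth.counts.sum()

    def test_no_truncation_limit(self):
        truth = _toy_truth([[5], [3]])
        ref = TranscriptReference({"g0": "ACGT" * 25, "g1": "TTAACC" * 10})
        lib = fragment_transcripts(truth, ref, TruncationParams(0.0, 0.0), seed=1)
        lens = lib.table.apply(lambda r: len(ref[r["gene_id"]]), axis=1)
        assert (lib.table["start"] == 0).all()
        assert (lib.table["end"] == lens).all()

    def test_coordinates_inside_transcript(self, small_truth, small_reference):
        lib = fragment_transcripts(
            small_truth, small_reference, TruncationParams(0.4, 0.4), seed=2
        )
        lens = lib.table["gene_id"].map(small_reference.lengths)
        assert (lib.table["start"] >= 0).all()
        assert (lib.table["start"] < lib.table["end"]).all()
        assert (lib.table["end"] <= lens).all()

    def test_missing_gene_named_in_error(self):
        truth = _toy_truth([[2]], gene_ids=["lost_gene"])
        ref = TranscriptReference({"other": "ACGTACGT"})
        with pytest.raises(KeyError, match="lost_gene"):
            fragment_transcripts(truth, ref)


class TestBarcodeBank:
    def test_default_bank_meets_min_hamming(self):
        bank = get_barcode_bank(100, barcode_length=16, min_hamming=2, seed=0)
        assert bank.min_pairwise_hamming() >= 2

    def test_single_cell_is_vacuous(self):
        bank = get_barcode_bank(1, barcode_length=4, seed=0)
        assert len(bank.barcodes) == 1

    def test_infeasible_request_errors(self):
        # only 4 distinct length-1 barcodes exist
        with pytest.raises(RuntimeError, match="Hamming"):
            get_barcode_bank(5, barcode_length=1, min_hamming=1, seed=0)

    def test_deterministic(self):
        a = get_barcode_bank(20, seed=5)
        b = get_barcode_bank(20, seed=5)
        assert a.barcodes == b.barcodes


class TestUMIBank:
    def test_one_umi_per_fragment_with_length(self, small_truth, small_reference):
        frags = fragment_transcripts(small_truth, small_reference, seed=3)
        bank = get_umi_bank(frags, umi_length=10, seed=4)
        assert len(bank) == len(frags)
        assert all(len(u) == 10 for u in bank.umis)

    def test_deterministic(self, small_truth, small_reference):
        frags = fragment_transcripts(small_truth, small_reference, seed=3)
        a = get_umi_bank(frags, 8, seed=9)
        b = get_umi_bank(frags, 8, seed=9)
        assert list(a.umis) == list(b.umis)

    def test_collision_rate_matches_uniform_sampling(self):
        # umi_length=1 over many fragments: each of the 4 letters ~uniform,
        # so distinct count ~ 4 and per-pair collision probability ~ 1/4
        keys = pd.DataFrame(
            {"cell_id": ["c"] * 4000, "gene_id": ["g"] * 4000,
             "copy_index": range(4000)}
        )
        bank = get_umi_bank(keys, umi_length=1, seed=0)
        freqs = pd.Series(list(bank.umis)).value_counts(normalize=True)
        assert np.allclose(freqs, 0.25, atol=3 * np.sqrt(0.25 * 0.75 / 4000))


class TestPCR:
    def _frags(self, n=50, length=100, seed=0):
        truth = _toy_truth(np.full((1, n), 1))
        ref = TranscriptReference({"g0": "ACGT" * (length // 4)})
        frags = fragment_transcripts(truth, ref, TruncationParams(0, 0), seed=seed)
        bank = get_umi_bank(frags, 8, seed=seed)
        return frags, bank, ref

    def test_certain_duplication_doubles_every_cycle(self):
        frags, bank, ref = self._frags()
        pcr = pcr_amplify(frags, bank, ref, PCRParams(cycles=3, efficiency=1.0,
                                                      mutation_rate=0.0, seed=1))
        assert np.all(pcr.copy_number == 8)
        assert pcr.n_mutations() == 0

    def test_zero_cycles_leave_single_molecules(self):
        frags, bank, ref = self._frags()
        pcr = pcr_amplify(frags, bank, ref, PCRParams(cycles=0, seed=1))
        assert np.all(pcr.copy_number == 1)
        assert pcr.n_mutations() == 0

    def test_zero_mutation_rate_records_nothing(self):
        frags, bank, ref = self._frags()
        pcr = pcr_amplify(frags, bank, ref, PCRParams(cycles=5, efficiency=0.5,
                                                      mutation_rate=0.0, seed=2))
        assert pcr.n_mutations() == 0

    def test_copy_number_bounded_and_mean_matches_branching_process(self):
        frags, bank, ref = self._frags(n=10_000)
        params = PCRParams(cycles=3, efficiency=0.9, mutation_rate=0.0, seed=3)
        pcr = pcr_amplify(frags, bank, ref, params)
        assert pcr.copy_number.max() <= 2**params.cycles
        expected = (1 + params.efficiency) ** params.cycles
        se = pcr.copy_number.std(ddof=1) / np.sqrt(len(pcr.copy_number))
        assert abs(pcr.copy_number.mean() - expected) < 3 * se

    def test_dispersion_grows_with_cycles(self):
        frags, bank, ref = self._frags(n=5000)
        v = {}
        for cycles in (3, 6):
            pcr = pcr_amplify(frags, bank, ref,
                              PCRParams(cycles=cycles, efficiency=0.7,
                                        mutation_rate=0.0, seed=4))
            v[cycles] = pcr.copy_number.var(ddof=1)
        assert v[6] > v[3]

    def test_mutations_inside_fragment_with_valid_alleles(self):
        frags, bank, ref = self._frags(n=2000, length=200)
        pcr = pcr_amplify(frags, bank, ref,
                          PCRParams(cycles=4, efficiency=0.9,
                                    mutation_rate=2e-3, seed=5))
        assert pcr.n_mutations() > 0
        starts = frags.table["start"].to_numpy()
        ends = frags.table["end"].to_numpy()
        for f, rec in pcr.mutated.items():
            frag_len = ends[f] - starts[f]
            seq = ref["g0"][starts[f]:ends[f]]
            for mol, off, r, a, cycle in rec.events:
                assert 0 <= off < frag_len
                assert a != r
                assert 1 <= cycle <= 4
                assert 0 < mol < len(rec.parents)
            # inheritance: every molecule's variant map replays consistently
            variants = rec.molecule_variants()
            assert len(variants) == rec.parents.shape[0]


class TestPersistence:
    def test_round_trip_is_lossless(self, small_library, tmp_path):
        root = write_library(small_library, tmp_path / "lib")
        back = read_library(root)
        pd.testing.assert_frame_equal(
            back.fragments.table, small_library.fragments.table,
            check_dtype=False,
        )
        assert list(back.umi_bank.umis) == list(small_library.umi_bank.umis)
        assert back.barcode_bank.barcodes == small_library.barcode_bank.barcodes
        assert np.array_equal(back.pcr.copy_number, small_library.pcr.copy_number)
        assert set(back.pcr.mutated) == set(small_library.pcr.mutated)
        for f, rec in small_library.pcr.mutated.items():
            assert back.pcr.mutated[f].events == rec.events
            assert np.array_equal(back.pcr.mutated[f].parents, rec.parents)

    def test_missing_umi_file_named(self, small_library, tmp_path):
        root = write_library(small_library, tmp_path / "lib")
        (root / "umis.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="umi"):
            read_library(root)

    def test_sequencing_reuse_leaves_library_unchanged(self, small_library,
                                                       small_reference, tmp_path):
        from truthseq.io import file_checksum
        from truthseq.sequencer import RunConfig, sequence_library

        root = write_library(small_library, tmp_path / "lib")
        files = sorted(p for p in root.rglob("*") if p.is_file())
        before = {p: file_checksum(p) for p in files}
        lib = read_library(root)
        for depth, seed in ((500, 1), (1500, 2)):
            sequence_library(lib, small_reference,
                             RunConfig(depth=depth, read2_len=50, seed=seed),
                             None, tmp_path / f"run{seed}")
        after = {p: file_checksum(p) for p in files}
        assert before == after
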