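import gzip

import numpy as np
import pytest

from truthseq.library_builder import build_library, PCRParams
from truthseq.sequencer import (
    ADAPTER,
    ErrorProfile,
    QualityProfile,
    RunConfig,
    apply_sequencing_noise,
    iter_read_batches,
    load_profiles,
    sequence_library,
)


def _zero_profiles(L):
    return ErrorProfile(np.zeros((L, 4, 4))), QualityProfile.uniform(L)


class TestProfiles:
    def test_flat_file_splits_rate_over_alts(self, tmp_path):
        f = tmp_path / "err.tsv"
        f.write_text("position\tref_base\talt_base\tprobability\n*\t*\t*\t0.003\n")
        prof = ErrorProfile.from_file(f, read_len=10)
        assert np.allclose(prof.p[:, 0, 1:], 0.001)
        assert np.allclose(prof.total, 0.003)
        assert np.all(prof.p[:, np.arange(4), np.arange(4)] == 0)

    def test_empty_quality_file_uses_defaults(self, tmp_path, caplog):
        f = tmp_path / "qual.tsv"
        f.write_text("position\tbase\tmean_q\tsd_q\tis_error\n")
        with caplog.at_level("WARNING"):
            prof = QualityProfile.from_file(f, read_len=5)
        assert "missing" in caplog.text
        assert np.all(prof.q_mean == 37.0)

    def test_probability_above_one_rejected(self, tmp_path):
        f = tmp_path / "err.tsv"
        f.write_text("0\tA\tC\t1.5\n")
        with pytest.raises(ValueError, match="outside"):
            ErrorProfile.from_file(f, read_len=5)

    def test_malformed_row_reports_line_number(self, tmp_path):
        f = tmp_path / "err.tsv"
        f.write_text("position\tref_base\talt_base\tprobability\n0\tA\tC\n")
        with pytest.raises(ValueError, match=":2"):
            ErrorProfile.from_file(f, read_len=5)

    def test_error_profile_file_round_trip(self, tmp_path):
        prof = ErrorProfile.positional(np.linspace(0.001, 0.01, 12))
        prof.to_file(tmp_path / "err.tsv")
        back = ErrorProfile.from_file(tmp_path / "err.tsv", read_len=12)
        assert np.allclose(back.p, prof.p)


class TestNoise:
    def test_zero_profile_is_identity(self):
        rng = np.random.default_rng(0)
        seq = "ACGTACGTAC"
        out, qual = apply_sequencing_noise(seq, _zero_profiles(len(seq)), rng)
        assert out == seq
        assert len(qual) == len(seq)

    def test_certain_substitution_changes_every_base(self):
        L = 8
        p = np.zeros((L, 4, 4))
        # every base goes to the "next" base with certainty
        for b in range(4):
            p[:, b, (b + 1) % 4] = 1.0
        rng = np.random.default_rng(0)
        out, _ = apply_sequencing_noise("AAAACCCC", (ErrorProfile(p),
                                                     QualityProfile.uniform(L)), rng)
        assert out == "CCCCGGGG"

    def test_n_bases_untouched_with_floor_quality(self):
        rng = np.random.default_rng(0)
        prof = ErrorProfile.uniform(4, rate=0.9), QualityProfile.uniform(4)
        out, qual = apply_sequencing_noise("NNNN", prof, rng)
        assert out == "NNNN"
        assert qual == chr(2 + 33) * 4

    def test_empirical_rates_match_profile(self):
        # positional ramp, ~3e5 bases, per-(position, base) 3-sigma check
        L = 15
        rates = np.linspace(0.004, 0.04, L)
        error = ErrorProfile.positional(rates)
        quality = QualityProfile.uniform(L)
        rng = np.random.default_rng(1)
        from truthseq.library_builder import random_sequences
        from truthseq.sequencer import _apply_noise_matrix, _CODE

        n = 20_000
        seq = random_sequences(rng, n, L)
        out, _ = _apply_noise_matrix(seq, rng, error, quality)
        changed = out != seq
        codes = _CODE[seq]
        zs = []
        for pos in range(L):
            for b in range(4):
                mask = codes[:, pos] == b
                m = int(mask.sum())
                rate = changed[mask, pos].mean()
                se = np.sqrt(rates[pos] * (1 - rates[pos]) / m)
                zs.append(abs(rate - rates[pos]) / se)
        zs = np.asarray(zs)
        assert (zs < 3).mean() >= 0.95  # per-cell 3-sigma coverage
        assert zs.max() < 4.5  # outer bound over the 60 comparisons


class TestSequencing:
    def test_record_count_and_tag_traceability(self, small_library,
                                               small_reference, tmp_path):
        config = RunConfig(depth=2000, read2_len=50, seed=3)
        p1, p2 = sequence_library(small_library, small_reference, config,
                                  None, tmp_path / "run")
        from truthseq.io import read_fastq

        keys = set(
            zip(
                small_library.fragments.table["cell_id"],
                small_library.fragments.table["gene_id"],
                small_library.fragments.table["copy_index"],
            )
        )
        n1 = 0
        for rec in read_fastq(p1):
            cell, gene, copy, mol = rec.comment.split("|")
            assert (cell, gene, int(copy)) in keys
            n1 += 1
        n2 = sum(1 for _ in read_fastq(p2))
        assert n1 == n2 == config.depth

    def test_zero_noise_reads_are_reference_substrings(self, small_truth,
                                                       small_reference):
        lib = build_library(
            small_truth, small_reference,
            pcr_params=PCRParams(cycles=2, efficiency=0.8, mutation_rate=0.0, seed=5),
            seed=5,
        )
        L2 = 40
        profiles = _zero_profiles(max(L2, 26))
        config = RunConfig(depth=500, read2_len=L2, seed=6)
        table = lib.fragments.table
        adapter_pad = (ADAPTER * 10)
        for batch in iter_read_batches(lib, small_reference, config, profiles):
            for row in range(len(batch)):
                seq2 = batch.seq2[row].tobytes().decode()
                frag = table.iloc[int(batch.frag_idx[row])]
                ref_seq = small_reference[frag["gene_id"]]
                core = ref_seq[frag["start"]:frag["end"]][:L2]
                assert seq2.startswith(core)
                assert seq2[len(core):] == adapter_pad[: L2 - len(core)]

    def test_sampling_weights_proportional_to_copy_number(self, small_truth,
                                                          small_reference):
        lib = build_library(
            small_truth, small_reference,
            pcr_params=PCRParams(cycles=3, efficiency=0.5, mutation_rate=0.0, seed=7),
            seed=7,
        )
        depth = 200_000
        config = RunConfig(depth=depth, read2_len=30, seed=8)
        counts = np.zeros(len(lib.fragments))
        for batch in iter_read_batches(lib, small_reference, config,
                                       _zero_profiles(30)):
            np.add.at(counts, batch.frag_idx, 1)
        w = lib.pcr.copy_number / lib.pcr.copy_number.sum()
        expected = depth * w
        se = np.sqrt(depth * w * (1 - w))
        assert np.mean(np.abs(counts - expected) < 3 * se + 1e-9) > 0.99

    def test_byte_identical_across_thread_counts(self, small_library,
                                                 small_reference, tmp_path):
        outs = []
        for threads in (1, 4):
            config = RunConfig(depth=30_000, read2_len=60, threads=threads, seed=9)
            p1, p2 = sequence_library(small_library, small_reference, config,
                                      None, tmp_path / f"t{threads}")
            outs.append(p1.read_bytes() + p2.read_bytes())
        assert outs[0] == outs[1]

    def test_empty_library_rejected(self, small_library, small_reference):
        import copy

        lib = copy.copy(small_library)
        lib.pcr = copy.copy(small_library.pcr)
        lib.pcr.copy_number = np.zeros_like(small_library.pcr.copy_number)
        with pytest.raises(ValueError, match="empty"):
            next(iter_read_batches(lib, small_reference,
                                   RunConfig(depth=10, read2_len=30, seed=0)))
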