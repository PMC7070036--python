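"""Paired-end QC: expected error, anchoring, splicing, merging, dispositions."""

import random

import pytest

from amberphage.qc import (
    DISPOSITIONS,
    QcConfig,
    ReadPair,
    expected_error,
    find_anchor,
    merge_pair,
    process_pair,
    reverse_complement,
    run_qc_pairs,
    splice_library,
    truncate_and_filter,
)
from .conftest import perfect_pair
from ._oracles import reference_disposition


class TestExpectedError:
    @pytest.mark.parametrize(
        "qual,expected",
        [([20] * 100, 1.0), ([], 0.0), ([10, 20, 30], 0.111)],
    )
    def test_known_values(self, qual, expected):
        assert expected_error(qual) == pytest.approx(expected, abs=1e-9)

    def test_negative_phred_rejected(self):
        with pytest.raises(ValueError):
            expected_error([10, -1])


class TestTruncateAndFilter:
    def test_high_quality_pair_kept_and_truncated(self, qc_config):
        pair = ReadPair("a", "A" * 150, [40] * 150, "C" * 150, [40] * 150)
        trimmed, reason = truncate_and_filter(pair, qc_config)
        assert reason is None
        assert len(trimmed.fwd_seq) == 120 and len(trimmed.rev_seq) == 95
        assert len(trimmed.fwd_qual) == 120 and len(trimmed.rev_qual) == 95

    def test_short_forward_read_fails_length(self, qc_config):
        pair = ReadPair("a", "A" * 100, [40] * 100, "C" * 150, [40] * 150)
        assert truncate_and_filter(pair, qc_config) == (None, "fail_length")

    def test_low_quality_reverse_fails_expected_error(self, qc_config):
        # 95 bases at Q=15: E = 95 * 10^-1.5 ~= 3.0 > 1
        pair = ReadPair("a", "A" * 150, [40] * 150, "C" * 150, [15] * 150)
        assert truncate_and_filter(pair, qc_config) == (None, "fail_expected_error")

    def test_quality_beyond_truncation_is_ignored(self, qc_config):
        # terrible tail quality is cut away before the Emax filter
        qual = [40] * 120 + [2] * 30
        pair = ReadPair("a", "A" * 150, qual, "C" * 150, [40] * 150)
        _, reason = truncate_and_filter(pair, qc_config)
        assert reason is None


class TestFindAnchor:
    ANCHOR = "GATTACA"

    def test_exact_hit(self):
        seq = "CCCCC" + self.ANCHOR + "GGGG"
        assert find_anchor(seq, self.ANCHOR, 1) == (5, 0)

    def test_one_substitution_within_budget(self):
        seq = "CCCCC" + "GATTACC" + "GGGG"
        assert find_anchor(seq, self.ANCHOR, 1) == (5, 1)

    def test_two_substitutions_exceed_budget(self):
        seq = "CCCCC" + "GATCACC" + "GGGG"
        assert find_anchor(seq, self.ANCHOR, 1) is None

    def test_leftmost_wins_on_tie(self):
        seq = self.ANCHOR + "TT" + self.ANCHOR
        assert find_anchor(seq, self.ANCHOR, 0) == (0, 0)

    def test_anchor_longer_than_sequence(self):
        assert find_anchor("GAT", self.ANCHOR, 2) is None

    def test_n_bases_count_as_mismatches(self):
        seq = "CCCCC" + "GANTANA" + "GGGG"
        assert find_anchor(seq, self.ANCHOR, 1) is None
        assert find_anchor(seq, self.ANCHOR, 2) == (5, 2)


class TestSpliceLibrary:
    INSERT = "TGTACTGTTTAGGTTTCTACT"

    def seq(self, cfg, prefix="ACGT"):
        return prefix + cfg.composite_upstream + self.INSERT + cfg.downstream_anchor + "AC"

    def test_exact_amplicon(self, qc_config):
        got = splice_library(self.seq(qc_config), qc_config)
        assert got == (self.INSERT, 0, 0)

    def test_one_substitution_in_primer_tolerated(self, qc_config):
        seq = self.seq(qc_config)
        # mutate inside the upstream primer region (offset 4 is its start)
        seq = seq[:6] + ("A" if seq[6] != "A" else "G") + seq[7:]
        got = splice_library(seq, qc_config)
        assert got is not None and got[0] == self.INSERT and got[1] == 1

    def test_primer_plus_spacer_mismatches_share_one_budget(self, qc_config):
        seq = self.seq(qc_config)
        i_primer = 6                       # inside upstream primer
        i_spacer = 4 + len(qc_config.upstream_anchor) + 1  # inside GCC spacer
        for i in (i_primer, i_spacer):
            seq = seq[:i] + ("A" if seq[i] != "A" else "G") + seq[i + 1 :]
        assert splice_library(seq, qc_config) is None

    def test_clipped_downstream_anchor(self, qc_config):
        full = self.seq(qc_config, prefix="")
        clipped = full[: len(qc_config.composite_upstream) + 21 + 5]
        got = splice_library(clipped, qc_config)
        assert got == (self.INSERT, 0, 0)

    def test_missing_downstream_anchor_fails(self, qc_config):
        no_tail = qc_config.composite_upstream + self.INSERT
        assert splice_library(no_tail, qc_config) is None

    def test_read_too_short_for_library(self, qc_config):
        short = qc_config.composite_upstream + self.INSERT[:10]
        assert splice_library(short, qc_config) is None


class TestMergePair:
    def test_identical_inserts_merge(self):
        s = "TGTACTGTTTAGGTTTCTACT"
        assert merge_pair(s, s) == s

    def test_single_disagreement_rejected(self):
        s = "TGTACTGTTTAGGTTTCTACT"
        t = "A" + s[1:]
        assert merge_pair(s, t) is None

    def test_all_positions_disagreeing_rejected(self):
        s = "A" * 21
        assert merge_pair(s, "C" * 21) is None

    def test_n_disqualifies_even_if_equal(self):
        s = "N" + "A" * 20
        assert merge_pair(s, s) is None

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            merge_pair("AAA", "AAAA")


class TestRunQc:
    def test_error_free_pairs_all_kept(self, qc_config):
        inserts = ["TGTACTGTTTAGGTTTCTACT", "GCTGCTGCTGCTGCTGCTTAG"]
        pairs = [perfect_pair(ins, qc_config, f"p{i}") for i, ins in enumerate(inserts)]
        result = run_qc_pairs(pairs, qc_config)
        assert result.disposition_tally["kept"] == 2
        assert result.inserts == inserts

    def test_two_primer_substitutions_fail_anchor_fwd(self, qc_config):
        pair = perfect_pair("TGTACTGTTTAGGTTTCTACT", qc_config)
        seq = list(pair.fwd_seq)
        for i in (2, 5):  # both inside the upstream primer region
            seq[i] = "A" if seq[i] != "A" else "G"
        pair.fwd_seq = "".join(seq)
        reason, kept = process_pair(pair, qc_config)
        assert reason == "fail_anchor_fwd" and kept is None

    def test_disagreeing_library_regions_fail_pair_mismatch(self, qc_config):
        insert_a = "TGTACTGTTTAGGTTTCTACT"
        insert_b = "TGTACTGTTTAGGTTTCTACG"
        good = perfect_pair(insert_a, qc_config)
        bad = perfect_pair(insert_b, qc_config)
        mixed = ReadPair("m", good.fwd_seq, good.fwd_qual, bad.rev_seq, bad.rev_qual)
        reason, _ = process_pair(mixed, qc_config)
        assert reason == "fail_pair_mismatch"

    def test_tally_conserves_pair_count(self, small_library, qc_config):
        pairs, _, _ = small_library
        result = run_qc_pairs(pairs, qc_config)
        assert result.n_pairs == len(pairs)
        assert set(result.disposition_tally) == set(DISPOSITIONS)

    def test_order_invariance_of_tally(self, small_library, qc_config):
        pairs, _, _ = small_library
        tally1 = run_qc_pairs(pairs, qc_config).disposition_tally
        shuffled = pairs[:]
        random.Random(7).shuffle(shuffled)
        tally2 = run_qc_pairs(shuffled, qc_config).disposition_tally
        assert tally1 == tally2

    def test_error_free_roundtrip_recovers_planted_inserts(self, small_library, qc_config):
        pairs, truth, _ = small_library
        result = run_qc_pairs(pairs, qc_config)
        assert result.disposition_tally["kept"] == len(pairs)
        assert [(k.id, k.insert) for k in result.kept_inserts] == truth


class TestOracleAgreement:
    def test_dispositions_match_brute_force_reference(self, qc_config):
        """Every disposition equals an independent full-offset-scan pipeline."""
        from amberphage.synth import LibrarySynthConfig, generate_library

        cfg = LibrarySynthConfig(
            n_pairs=50, composition="naive_nnk", substitution_rate=0.02, seed=5
        )
        pairs, _ = generate_library(cfg)
        # also stress the length and quality branches
        pairs.append(ReadPair("short", "A" * 60, [40] * 60, "C" * 150, [40] * 150))
        pairs.append(ReadPair("lowq", pairs[0].fwd_seq, [12] * 150, pairs[0].rev_seq, [12] * 150))
        for pair in pairs:
            reason, _ = process_pair(pair, qc_config)
            assert reason == reference_disposition(pair, qc_config), pair.id


def test_reverse_complement_involution():
    seq = "ACGTTGCANNA"
    assert reverse_complement(reverse_complement(seq)) == seq
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AAC") == "GTT"
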