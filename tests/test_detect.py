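"""SV classification: junction arithmetic, TE retyping, CE flags, recovery scoring."""
import numpy as np
import pytest

from panelsv.align import chain_anchors, find_anchors
from panelsv.detect import (
    DetectorConfig,
    annotate_te_insertions,
    classify_svs,
    flag_complex,
    score_recovery,
)
from panelsv.models import AlignmentBlock, SVCall, SyntenicChain, TruthRecord
from panelsv.seqs import random_seq

CFG = DetectorConfig()


def chain_of(blocks):
    return SyntenicChain("c", "c", blocks)


def blk(rs, re_, qs, qe, strand="+"):
    return AlignmentBlock("c", rs, re_, "c", qs, qe, strand)


REF = {"c": "A" * 100_000}
QRY = {"c": "A" * 100_000}


class TestClassify:
    def test_insertion_from_query_gap(self):
        chains = [chain_of([blk(0, 1_000, 0, 1_000), blk(1_000, 2_000, 1_500, 2_500)])]
        (call,) = classify_svs(chains, REF, QRY, CFG)
        assert call.type == "insertion"
        assert call.length == 500
        assert call.ref_start == call.ref_end == 1_000

    def test_sub_threshold_indel_not_called(self):
        chains = [chain_of([blk(0, 1_000, 0, 1_000), blk(1_000, 2_000, 1_050, 2_050)])]
        assert classify_svs(chains, REF, QRY, CFG) == []

    def test_deletion_from_reference_gap(self):
        chains = [chain_of([blk(0, 1_000, 0, 1_000), blk(1_400, 2_000, 1_000, 1_600)])]
        (call,) = classify_svs(chains, REF, QRY, CFG)
        assert call.type == "deletion"
        assert (call.ref_start, call.ref_end, call.length) == (1_000, 1_400, 400)

    def test_strand_sandwich_is_inversion(self):
        chains = [
            chain_of(
                [
                    blk(0, 1_000, 0, 1_000),
                    blk(1_000, 2_000, 1_000, 2_000, "-"),
                    blk(2_000, 3_000, 2_000, 3_000),
                ]
            )
        ]
        (call,) = classify_svs(chains, REF, QRY, CFG)
        assert call.type == "inversion"
        assert (call.ref_start, call.ref_end) == (1_000, 2_000)

    def test_reference_overlap_is_tandem_duplication_cnv(self):
        chains = [chain_of([blk(0, 5_000, 0, 5_000), blk(3_000, 8_000, 5_000, 10_000)])]
        (call,) = classify_svs(chains, REF, QRY, CFG)
        assert call.type == "duplication" and call.cnv
        assert (call.ref_start, call.ref_end, call.length) == (3_000, 5_000, 2_000)
        assert call.copy_number == 2

    def test_substitution_junction_emits_both_flagged(self):
        # 400 bp deleted AND 300 bp inserted at one junction, sequences differ
        rng = np.random.default_rng(0)
        ref = {"c": random_seq(rng, 3_000)}
        qry = {"c": random_seq(rng, 3_000)}
        chains = [chain_of([blk(0, 1_000, 0, 1_000), blk(1_400, 2_400, 1_300, 2_300)])]
        calls = classify_svs(chains, ref, qry, CFG)
        assert sorted(c.type for c in calls) == ["deletion", "insertion"]
        assert all(c.complex_hint for c in calls)
        calls = flag_complex(calls, CFG)
        assert all(c.ce_flag == 2 for c in calls)

    def test_identical_gap_sequence_is_not_an_event(self):
        # unanchored repeat region: large r == q with matching sequence
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 1_000) + random_seq(rng, 500) + random_seq(rng, 1_000)
        ref = {"c": seq}
        qry = {"c": seq}
        chains = [chain_of([blk(0, 1_000, 0, 1_000), blk(1_500, 2_500, 1_500, 2_500)])]
        assert classify_svs(chains, ref, qry, CFG) == []


class TestAnnotateTE:
    def _ins(self, qs, qe):
        return SVCall("s1", "insertion", "c", 1_000, 1_000, "c", qs, qe, qe - qs)

    def test_contained_annotation_retypes(self):
        call = self._ins(5_000, 6_000)
        (out,) = annotate_te_insertions([call], [("c", 5_100, 5_900, "TE01")])
        assert out.type == "TE_insertion" and out.te_families == ["TE01"]

    def test_half_overlap_does_not_retype(self):
        call = self._ins(5_000, 6_000)
        (out,) = annotate_te_insertions([call], [("c", 5_500, 6_500, "TE01")])
        assert out.type == "insertion" and out.te_families == []

    def test_no_overlap_unchanged(self):
        call = self._ins(5_000, 6_000)
        (out,) = annotate_te_insertions([call], [("c", 9_000, 9_500, "TE01")])
        assert out.type == "insertion"

    def test_unknown_sequence_name_raises(self):
        with pytest.raises(ValueError, match="unknown sequence"):
            annotate_te_insertions([self._ins(0, 10)], [("zzz", 0, 5, "TE01")], chrom_names={"c"})


class TestFlagComplex:
    def test_isolated_call_is_simple(self):
        calls = [SVCall("s", "insertion", "c", 100, 100, "c", 0, 500, 500)]
        assert flag_complex(calls, CFG)[0].ce_flag == 0

    @pytest.mark.parametrize("gap,expected", [(4_999, 1), (5_001, 0)])
    def test_proximity_window_boundary(self, gap, expected):
        complex_call = SVCall(
            "s", "insertion", "c", 10_000, 10_000, "c", 0, 500, 500, complex_hint=True
        )
        clean_start = 10_000 + gap
        clean = SVCall("s", "deletion", "c", clean_start, clean_start + 300, "c", 0, 0, 300)
        out = flag_complex([complex_call, clean], CFG)
        assert out[0].ce_flag == 2
        assert out[1].ce_flag == expected


class TestScoreRecovery:
    def test_exact_calls_score_perfectly(self, small_panel, panel_calls):
        _ref, _panel, _genomes, _ann, truth = small_panel
        calls = [c for calls in panel_calls.values() for c in calls]
        table = score_recovery(calls, truth)
        assert (table["precision"] == 1.0).all()
        assert (table["recall"] == 1.0).all()
        sv_types = {t.type for t in truth if t.type != "snp"}
        assert sv_types <= set(table.index)

    def test_no_sub_threshold_emissions(self, panel_calls):
        for calls in panel_calls.values():
            assert all(c.length > CFG.min_sv_len for c in calls)

    def test_empty_calls_give_zero_recall(self, small_panel):
        truth = small_panel[4]
        table = score_recovery([], truth)
        assert table.loc["overall", "recall"] == 0.0

    def test_jittered_breakpoints_match_within_tolerance(self):
        truth = [
            TruthRecord("SV1", "deletion", "c", 1_000, 1_500, 500, frozenset({"s"})),
            TruthRecord("SV2", "insertion", "c", 9_000, 9_000, 400, frozenset({"s"})),
        ]
        calls = [
            SVCall("s", "deletion", "c", 1_050, 1_545, "c", 0, 0, 495),
            SVCall("s", "insertion", "c", 8_955, 8_955, "c", 0, 400, 400),
        ]
        table = score_recovery(calls, truth, pos_tol=100, len_tol=0.10)
        assert table.loc["overall", "recall"] == 1.0
        # and fails at a tolerance tighter than the jitter
        table = score_recovery(calls, truth, pos_tol=10, len_tol=0.10)
        assert table.loc["overall", "recall"] == 0.0


def test_insertion_deletion_duality(rng):
    """Swapping ref and qry converts an insertion into an equal-length deletion."""
    flank_a = random_seq(rng, 2_000)
    flank_b = random_seq(rng, 2_000)
    insert = random_seq(rng, 300)
    short = flank_a + flank_b
    long = flank_a + insert + flank_b

    def call_one(ref_seq, qry_seq):
        anchors = find_anchors(ref_seq, qry_seq, 20)
        chains, _ = chain_anchors(anchors)
        for ch in chains:
            ch.ref_chrom = "c"
            ch.qry_seq = "c"
            for b in ch.blocks:
                b.ref_chrom = "c"
                b.qry_seq = "c"
        return classify_svs(chains, {"c": ref_seq}, {"c": qry_seq}, CFG)

    (ins,) = call_one(short, long)
    (dele,) = call_one(long, short)
    assert ins.type == "insertion" and dele.type == "deletion"
    assert ins.length == dele.length == 300
    assert abs(ins.ref_start - dele.ref_start) <= 2
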