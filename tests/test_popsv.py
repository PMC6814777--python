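"""Merging, VCF round-trip, folded SFS, chi-square schemes, concordance."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelsv.models import FoldedSFS, MergedSV, SVCall
from panelsv.popsv import (
    call_set_concordance,
    folded_sfs,
    merge_calls,
    read_vcf,
    sfs_chisq,
    truth_folded_sfs,
    write_vcf,
)


def make_call(strain, sv_type, start, end, length=None):
    return SVCall(strain, sv_type, "c", start, end, "c", 0, 0, length or (end - start) or 100,
                  ce_flag=0)


class TestMerge:
    def test_identical_deletion_in_three_strains(self):
        per_strain = {s: [make_call(s, "deletion", 100, 400)] for s in ("a", "b", "c")}
        (m,) = merge_calls(per_strain)
        assert m.allele_count == 3 and m.carriers == frozenset("abc")
        assert (m.ref_start, m.ref_end) == (100, 400)

    def test_distant_insertions_stay_separate(self):
        per_strain = {
            "a": [make_call("a", "insertion", 1_000, 1_000)],
            "b": [make_call("b", "insertion", 1_250, 1_250)],
        }
        merged = merge_calls(per_strain, insertion_tol=100)
        assert len(merged) == 2

    def test_close_insertions_merge(self):
        per_strain = {
            "a": [make_call("a", "insertion", 1_000, 1_000)],
            "b": [make_call("b", "insertion", 1_150, 1_150)],
        }
        merged = merge_calls(per_strain, insertion_tol=100)
        assert len(merged) == 1 and merged[0].allele_count == 2

    def test_overlapping_deletions_union_footprint(self):
        per_strain = {
            "a": [make_call("a", "deletion", 100, 300)],
            "b": [make_call("b", "deletion", 200, 500)],
        }
        (m,) = merge_calls(per_strain)
        assert (m.ref_start, m.ref_end) == (100, 500)
        assert m.carriers == frozenset("ab")

    def test_different_types_never_merge(self):
        per_strain = {
            "a": [make_call("a", "deletion", 100, 300)],
            "b": [make_call("b", "duplication", 100, 300)],
        }
        assert len(merge_calls(per_strain)) == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 60), st.integers(1, 15)), min_size=1, max_size=12))
    def test_matches_transitive_closure_oracle(self, spans):
        intervals = [(s, s + ln) for s, ln in spans]
        per_strain = {
            f"s{i}": [make_call(f"s{i}", "deletion", a, b)] for i, (a, b) in enumerate(intervals)
        }
        merged = merge_calls(per_strain)
        # oracle: union-find over pairwise overlap-or-book-ended intervals
        parent = list(range(len(intervals)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, (a1, b1) in enumerate(intervals):
            for j, (a2, b2) in enumerate(intervals):
                if max(a1, a2) <= min(b1, b2):
                    parent[find(i)] = find(j)
        n_clusters = len({find(i) for i in range(len(intervals))})
        assert len(merged) == n_clusters

    def test_merge_is_idempotent(self, panel_calls):
        merged = merge_calls(panel_calls)
        again = merge_calls({s: [c for m in merged for c in m.members if c.strain_id == s]
                             for s in panel_calls})
        assert [(m.type, m.ref_start, m.ref_end, m.carriers) for m in merged] == [
            (m.type, m.ref_start, m.ref_end, m.carriers) for m in again
        ]

    def test_carrier_conservation(self, panel_calls):
        merged = merge_calls(panel_calls)
        assert sum(m.allele_count for m in merged) == sum(len(c) for c in panel_calls.values())


class TestVCF:
    REF = {"c": "ACGTACGTAC" * 2_000}

    def test_empty_list_gives_valid_header_only_vcf(self, tmp_path):
        p = tmp_path / "empty.vcf"
        write_vcf([], ["s1", "s2"], self.REF, p)
        variants, strains = read_vcf(p)
        assert variants == [] and strains == ["s1", "s2"]

    def test_genotype_columns_mark_the_carrier(self, tmp_path):
        m = MergedSV("MSV00001", "deletion", "c", 100, 400, [], frozenset({"s2"}), 1, 0, [], False, 300)
        p = tmp_path / "one.vcf"
        write_vcf([m], ["s1", "s2", "s3"], self.REF, p)
        text = p.read_text()
        assert "<DEL>" in text
        (got,), strains = read_vcf(p)
        assert got.carriers == frozenset({"s2"})

    def test_round_trip_preserves_records(self, tmp_path, panel_calls):
        merged = merge_calls(panel_calls)
        ref = {"c": "A"}  # not used for coords beyond REF base lookup
        # use real chromosome names present in calls
        chroms = {c.ref_chrom for calls in panel_calls.values() for c in calls}
        ref = {c: "ACGT" * 100_000 for c in chroms}
        p = tmp_path / "all.vcf"
        strains = sorted(panel_calls)
        write_vcf(merged, strains, ref, p)
        got, got_strains = read_vcf(p)
        assert got_strains == strains
        assert len(got) == len(merged)
        for a, b in zip(got, merged):
            assert (a.sv_id, a.type, a.ref_chrom, a.ref_start, a.ref_end) == (
                b.sv_id, b.type, b.ref_chrom, b.ref_start, b.ref_end)
            assert a.carriers == b.carriers and a.ce_flag == b.ce_flag
            assert a.length == b.length and a.te_families == b.te_families

    def test_out_of_reference_coordinate_raises(self, tmp_path):
        m = MergedSV("M1", "deletion", "c", 100, 10**9, [], frozenset({"s"}), 1, 0, [], False, 10)
        with pytest.raises(ValueError):
            write_vcf([m], ["s"], self.REF, tmp_path / "x.vcf")


class TestFoldedSFS:
    def test_singleton_and_folding(self):
        sfs = folded_sfs([1, 12, 13], N=13)
        # x=1 -> class 1; x=12 -> min(12,1)=1; x=13 fixed -> excluded
        assert sfs.counts == {1: 2}

    def test_x_above_N_raises(self):
        with pytest.raises(ValueError):
            folded_sfs([14], N=13)

    def test_complex_exclusion(self):
        variants = [(1, 0), (1, 1), (2, 2), (3, 0)]
        assert folded_sfs(variants, N=13).counts == {1: 1, 3: 1}
        assert folded_sfs(variants, N=13, exclude_complex=False).counts == {1: 2, 2: 1, 3: 1}

    def test_conservation(self, small_panel, panel_calls):
        truth = small_panel[4]
        merged = merge_calls(panel_calls)
        sfs = folded_sfs(merged, N=5)
        polymorphic = [m for m in merged if 0 < min(m.allele_count, 5 - m.allele_count)]
        assert sfs.total() == len(polymorphic)

    def test_pipeline_sfs_equals_truth_sfs(self, small_panel, panel_calls):
        """End-to-end identity: folding merged calls reproduces the truth spectrum."""
        truth = small_panel[4]
        merged = merge_calls(panel_calls)
        got = folded_sfs(merged, N=5)
        want = truth_folded_sfs(
            truth, N=5, types=("TE_insertion", "insertion", "deletion", "duplication", "inversion")
        )
        assert got.counts == want.counts


class TestChisq:
    def test_identical_spectra(self):
        a = FoldedSFS(13, {1: 30, 2: 10, 3: 5})
        stat, df, p = sfs_chisq(a, a, "full")
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_singleton_scheme_closed_form(self):
        a = FoldedSFS(13, {1: 10, 2: 5})
        b = FoldedSFS(13, {1: 5, 2: 10})
        stat, df, p = sfs_chisq(a, b, "singleton")
        assert stat == pytest.approx(10 / 3)
        assert df == 1

    def test_strong_separation_is_significant(self):
        # singleton fractions 0.8 vs 0.4 at n=2000 each
        a = FoldedSFS(13, {1: 1600, 2: 200, 3: 100, 4: 60, 5: 30, 6: 10})
        b = FoldedSFS(13, {1: 800, 2: 600, 3: 300, 4: 180, 5: 90, 6: 30})
        _s, _df, p = sfs_chisq(a, b, "singleton")
        assert p < 1e-10

    def test_mismatched_sample_size_raises(self):
        with pytest.raises(ValueError):
            sfs_chisq(FoldedSFS(13, {1: 5}), FoldedSFS(11, {1: 5}), "full")


class TestConcordance:
    def test_self_comparison_detects_all(self):
        calls = [make_call("s", "deletion", 100, 300), make_call("s", "deletion", 900, 1_200)]
        frac, flags = call_set_concordance(calls, [(c.ref_chrom, c.ref_start, c.ref_end) for c in calls])
        assert frac == 1.0 and all(flags)

    def test_empty_other_detects_none(self):
        calls = [make_call("s", "deletion", 100, 300)]
        frac, flags = call_set_concordance(calls, [])
        assert frac == 0.0 and flags == [False]

    def test_cnv_insertion_padding(self):
        cnv = SVCall("s", "duplication", "c", 5_000, 5_000, "c", 0, 0, 500, cnv=True)
        frac_padded, _ = call_set_concordance([cnv], [("c", 5_050, 5_200)], cnv_extension=100)
        frac_bare, _ = call_set_concordance([cnv], [("c", 5_050, 5_200)], cnv_extension=0)
        assert frac_padded == 1.0 and frac_bare == 0.0
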