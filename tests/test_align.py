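"""Anchoring, chaining and scaffolding, checked against brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelsv.align import chain_anchors, filter_multiplicity, find_anchors, scaffold_by_reference
from panelsv.io import read_alignments, read_coords_tsv, read_paf, write_coords_tsv
from panelsv.models import AlignmentBlock, Anchor
from panelsv.seqs import random_seq, revcomp


def brute_force_mems(ref, qry, min_len):
    """O(n^2) enumeration of maximal exact matches on both strands."""
    out = set()
    for strand, q in (("+", qry), ("-", revcomp(qry))):
        n, m = len(ref), len(q)
        for i in range(n):
            for j in range(m):
                if ref[i] != q[j]:
                    continue
                if i > 0 and j > 0 and ref[i - 1] == q[j - 1]:
                    continue  # not a match start
                k = 0
                while i + k < n and j + k < m and ref[i + k] == q[j + k]:
                    k += 1
                if k >= min_len:
                    if strand == "+":
                        out.add((i, i + k, j, j + k, "+"))
                    else:
                        out.add((i, i + k, len(qry) - (j + k), len(qry) - j, "-"))
    return out


def as_tuples(anchors):
    return {(a.ref_start, a.ref_end, a.qry_start, a.qry_end, a.strand) for a in anchors}


class TestFindAnchors:
    def test_identity_gives_single_full_anchor(self, rng):
        s = random_seq(rng, 1_000)
        anchors = find_anchors(s, s, 20)
        plus = [a for a in anchors if a.strand == "+"]
        assert len(plus) == 1
        a = plus[0]
        assert (a.ref_start, a.ref_end, a.qry_start, a.qry_end) == (0, 1_000, 0, 1_000)

    def test_reverse_complement_gives_minus_anchor(self, rng):
        s = random_seq(rng, 800)
        anchors = find_anchors(s, revcomp(s), 20)
        minus = [a for a in anchors if a.strand == "-"]
        assert len(minus) == 1
        a = minus[0]
        assert (a.ref_start, a.ref_end, a.qry_start, a.qry_end) == (0, 800, 0, 800)

    def test_empty_sequence_gives_empty_list(self):
        assert find_anchors("", "ACGT" * 10, 8) == []

    def test_matches_brute_force_on_planted_block(self, rng):
        block = random_seq(rng, 80)
        ref = random_seq(rng, 100) + block + random_seq(rng, 120)
        qry = random_seq(rng, 60) + block + random_seq(rng, 140)
        got = as_tuples(find_anchors(ref, qry, 20))
        assert got == brute_force_mems(ref, qry, 20)
        assert any(e - s >= 80 for s, e, *_ in got)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_on_random_pairs(self, data):
        seed = data.draw(st.integers(0, 10_000))
        r = np.random.default_rng(seed)
        # low-entropy alphabet arrangement to force repeated matches
        ref = "".join(r.choice(list("ACG"), size=60))
        qry = "".join(r.choice(list("ACG"), size=60))
        got = as_tuples(find_anchors(ref, qry, 8))
        assert got == brute_force_mems(ref, qry, 8)

    def test_symmetry(self, rng):
        a = random_seq(rng, 150) + "ACGTACGTACGTACGTACGTACGT" + random_seq(rng, 150)
        b = random_seq(rng, 100) + "ACGTACGTACGTACGTACGTACGT" + random_seq(rng, 100)
        fwd = {(x.ref_start, x.ref_end, x.qry_start, x.qry_end, x.strand) for x in find_anchors(a, b, 12)}
        rev = {(x.qry_start, x.qry_end, x.ref_start, x.ref_end, x.strand) for x in find_anchors(b, a, 12)}
        assert fwd == rev


def _anchor(rs, re_, qs, qe, strand="+"):
    return Anchor("c", rs, re_, "q", qs, qe, strand)


def chain_score_oracle(anchors, gap_penalty, max_join_gap, slack=50):
    """Exhaustive max chain score over all ordered subsets (plus strand)."""
    anchors = sorted(anchors, key=lambda a: (a.ref_start, a.qry_start))
    n = len(anchors)
    best = 0.0
    for mask in range(1, 1 << n):
        subset = [anchors[i] for i in range(n) if mask >> i & 1]
        score = sum(a.length for a in subset)
        ok = True
        for x, y in zip(subset, subset[1:]):
            rgap = y.ref_start - x.ref_end
            qgap = y.qry_start - x.qry_end
            if not (
                x.ref_end < y.ref_end
                and -slack <= qgap <= max_join_gap
                and -max_join_gap <= rgap <= max_join_gap
            ):
                ok = False
                break
            score -= gap_penalty * (max(rgap, 0) + max(qgap, 0))
        if ok and score > best:
            best = score
    return best


class TestChainAnchors:
    def test_empty_and_single(self):
        assert chain_anchors([]) == ([], [])
        a = _anchor(0, 100, 0, 100)
        chains, sec = chain_anchors([a])
        assert len(chains) == 1 and len(chains[0].blocks) == 1 and sec == []

    def test_two_collinear_anchors_one_chain(self):
        chains, sec = chain_anchors([_anchor(0, 100, 0, 100), _anchor(200, 300, 200, 300)])
        assert len(chains[0].blocks) == 2 and sec == []

    def test_score_matches_exhaustive_oracle(self):
        r = np.random.default_rng(7)
        for _ in range(200):
            n = int(r.integers(1, 9))
            anchors = []
            for _i in range(n):
                rs = int(r.integers(0, 2_000))
                ln = int(r.integers(20, 400))
                qs = int(r.integers(0, 2_000))
                anchors.append(_anchor(rs, rs + ln, qs, qs + ln))
            chains, _sec = chain_anchors(anchors, gap_penalty=0.05, max_multiplicity=None)
            got = chains[0].score if chains else 0.0
            want = chain_score_oracle(anchors, 0.05, 10_000)
            assert got == pytest.approx(want)

    def test_multiplicity_filter_drops_repeat_anchors(self):
        anchors = [_anchor(0, 100, i * 500, i * 500 + 100) for i in range(4)]
        kept, dropped = filter_multiplicity(anchors, max_multiplicity=2)
        assert kept == [] and len(dropped) == 4


class TestReadAlignments:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.paf"
        p.write_text("")
        assert read_paf(p) == []
        c = tmp_path / "empty.tsv"
        c.write_text("")
        assert read_coords_tsv(c) == []

    def test_paf_minus_strand_coords_ascending(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("q1\t500\t100\t200\t-\tchr1\t1000\t300\t400\t100\t100\t60\n")
        (b,) = read_paf(p)
        assert b.strand == "-" and b.qry_start < b.qry_end == 200
        assert (b.ref_chrom, b.ref_start, b.ref_end) == ("chr1", 300, 400)

    def test_coords_round_trip(self, tmp_path):
        blocks = [
            AlignmentBlock("c1", 0, 100, "q", 5, 105, "+", 1.0),
            AlignmentBlock("c1", 200, 350, "q", 210, 360, "-", 0.99),
        ]
        p = tmp_path / "b.tsv"
        write_coords_tsv(p, blocks)
        assert read_coords_tsv(p) == blocks

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.paf"
        p.write_text("q1\t500\t100\n")
        with pytest.raises(ValueError, match="bad.paf:1"):
            read_alignments(p, "paf")

    def test_unknown_chromosome_rejected(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("q1\t500\t0\t100\t+\tweird\t1000\t0\t100\t100\t100\t60\n")
        with pytest.raises(ValueError, match="weird"):
            read_paf(p, known_chroms={"chr1"})


class TestScaffold:
    def test_identity_contig_scaffolds_to_chromosome(self, small_ref):
        contig = small_ref.chromosomes["2L"]
        out = scaffold_by_reference({"ctg1": contig}, small_ref)
        assert out["2L"] == contig and "N" * 100 not in out["2L"]

    def test_two_half_contigs_joined_by_100N(self, small_ref):
        chrom = small_ref.chromosomes["2L"]
        half = len(chrom) // 2
        out = scaffold_by_reference({"a": chrom[:half], "b": chrom[half:]}, small_ref)
        assert out["2L"].count("N" * 100) == 1
        assert out["2L"] == chrom[:half] + "N" * 100 + chrom[half:]
        non_n = len(out["2L"]) - 100
        assert non_n == len(chrom)

    def test_unmatched_contig_gets_U_prefix(self, small_ref, rng):
        junk = random_seq(rng, 5_000)
        out = scaffold_by_reference({"mystery": junk}, small_ref)
        assert out == {"Umystery": junk}

    def test_reverse_oriented_contig_is_flipped(self, small_ref):
        chrom = small_ref.chromosomes["2R"]
        out = scaffold_by_reference({"rc": revcomp(chrom)}, small_ref)
        assert out["2R"] == chrom
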