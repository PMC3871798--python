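"""Scoring model: tables, gap penalty, affine loop aligner, hairpin bound."""

import pytest
from hypothesis import given, settings, strategies as st

from arcalign import (
    DELETED,
    PSEUDO,
    align_loops_affine,
    basepair_score,
    hairpin_upper_bound,
    make_structure,
    region_deletion_penalty,
    simple_scheme,
)
from arcalign.scoring import ScoringError, ScoringScheme, gotoh_traceback_centi

from oracles import enumerate_alignment_score


# ---------------------------------------------------------------------------


class TestBasepairScore:
    def test_table_lookup_is_w1_weighted(self, toy_scheme):
        assert basepair_score("GC", "GC", toy_scheme) == pytest.approx(5.0)

    def test_pseudo_pairs_score_zero(self, toy_scheme):
        assert basepair_score(PSEUDO, PSEUDO, toy_scheme) == 0.0

    def test_pair_deletion_is_free(self, toy_scheme):
        assert basepair_score("GC", DELETED, toy_scheme) == 0.0
        assert basepair_score(DELETED, "AU", toy_scheme) == 0.0

    def test_invalid_dinucleotide_rejected(self, toy_scheme):
        with pytest.raises(ScoringError):
            basepair_score("GX", "GC", toy_scheme)

    def test_unknown_nucleotide_scores_row_minimum(self, default_scheme):
        worst = min(
            basepair_score("G" + b, "GC", default_scheme) for b in "ACGU"
        )
        assert basepair_score("GN", "GC", default_scheme) == pytest.approx(worst)


class TestRegionDeletionPenalty:
    @pytest.mark.parametrize("length,expected", [(0, 0.0), (1, -6.0), (3, -8.0)])
    def test_affine_values(self, toy_scheme, length, expected):
        assert region_deletion_penalty(length, toy_scheme) == pytest.approx(expected)

    def test_negative_length_rejected(self, toy_scheme):
        with pytest.raises(ScoringError):
            region_deletion_penalty(-1, toy_scheme)


class TestLoopAligner:
    def test_identity_alignment(self, toy_scheme):
        assert align_loops_affine("ACGU", "ACGU", toy_scheme) == pytest.approx(8.0)

    def test_empty_vs_region_equals_deletion_penalty(self, toy_scheme):
        assert align_loops_affine("", "AAA", toy_scheme) == pytest.approx(
            region_deletion_penalty(3, toy_scheme)
        )

    def test_single_mismatch_beats_gapping(self, toy_scheme):
        # exhaustively confirmed: gapless 2-1+2+2 = 5 is optimal
        assert align_loops_affine("ACGU", "AGGU", toy_scheme) == pytest.approx(5.0)

    def test_both_empty_scores_zero(self, toy_scheme):
        assert align_loops_affine("", "", toy_scheme) == 0.0

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        st.text(alphabet="ACGU", max_size=5),
        st.text(alphabet="ACGU", max_size=5),
    )
    def test_matches_exhaustive_alignment_enumeration(self, x, y):
        sch = ScoringScheme.default()
        got = round(align_loops_affine(x, y, sch) * 100)
        assert got == enumerate_alignment_score(x, y, sch)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.text(alphabet="ACGU", max_size=6),
        st.text(alphabet="ACGU", max_size=6),
    )
    def test_symmetry_under_symmetric_tables(self, x, y):
        sch = ScoringScheme.default()
        assert align_loops_affine(x, y, sch) == align_loops_affine(y, x, sch)

    def test_identity_is_diagonal_sum_under_default_tables(self, default_scheme):
        x = "GACUGUAC"
        expected = sum(default_scheme.D[(c, c)] for c in x) * default_scheme.w2
        assert align_loops_affine(x, x, default_scheme) == pytest.approx(expected)

    def test_whole_region_deletion_coheres_with_G(self, default_scheme):
        for k in (1, 2, 7):
            assert align_loops_affine("A" * k, "", default_scheme) == pytest.approx(
                region_deletion_penalty(k, default_scheme)
            )

    def test_traceback_alignment_rescias_to_dp_score(self, default_scheme):
        sc, ga, gb = gotoh_traceback_centi("GGAACC", "GACC", default_scheme)
        assert ga.replace("-", "") == "GGAACC"
        assert gb.replace("-", "") == "GACC"
        # rescore the emitted alignment from its columns
        total = 0
        run_a = run_b = 0
        for ca, cb in zip(ga, gb):
            if ca != "-" and cb != "-":
                total += default_scheme.nuc_centi(ca, cb)
            if ca == "-":
                run_a += 1
            elif run_a:
                total += default_scheme.gap_centi(run_a)
                run_a = 0
            if cb == "-":
                run_b += 1
            elif run_b:
                total += default_scheme.gap_centi(run_b)
                run_b = 0
        total += default_scheme.gap_centi(run_a) if run_a else 0
        total += default_scheme.gap_centi(run_b) if run_b else 0
        assert total == sc


class TestHairpinUpperBound:
    def make_pair(self, loop_a: int, loop_b: int):
        seq_a = "G" + "A" * loop_a + "C"
        seq_b = "G" + "A" * loop_b + "C"
        A = make_structure("a", seq_a, [(1, len(seq_a))])
        B = make_structure("b", seq_b, [(1, len(seq_b))])
        return A, B

    def bound_scheme(self):
        # d_max = 2 (match), R[GC,GC] = 4 so S_str = 4, g = -5, e = -1
        return simple_scheme(
            match=2.0, mismatch=-1.0, pair_scores={("GC", "GC"): 4.0}, g=-5.0, e=-1.0
        )

    def test_equal_loops_no_gap_term(self):
        sch = self.bound_scheme()
        A, B = self.make_pair(3, 3)
        assert hairpin_upper_bound(A.pairs[0], B.pairs[0], sch, (A, B)) == pytest.approx(10.0)

    def test_unequal_loops_charge_one_gap_run(self):
        sch = self.bound_scheme()
        A, B = self.make_pair(5, 3)
        assert hairpin_upper_bound(A.pairs[0], B.pairs[0], sch, (A, B)) == pytest.approx(3.0)

    def test_empty_loops_reduce_to_structural_term(self):
        sch = self.bound_scheme()
        A, B = self.make_pair(0, 0)
        assert hairpin_upper_bound(A.pairs[0], B.pairs[0], sch, (A, B)) == pytest.approx(4.0)

    def test_pseudo_pair_rejected(self, default_scheme):
        A, B = self.make_pair(3, 3)
        with pytest.raises(ScoringError):
            hairpin_upper_bound(A.root, B.pairs[0], default_scheme, (A, B))

    def test_bound_dominates_hairpin_case(self, default_scheme):
        """Mh = S_str + loop alignment never exceeds the bound."""
        for la, lb in [(0, 0), (3, 3), (5, 2), (1, 6)]:
            A, B = self.make_pair(la, lb)
            pa, pb = A.pairs[0], B.pairs[0]
            bound = hairpin_upper_bound(pa, pb, default_scheme, (A, B))
            mh = basepair_score("GC", "GC", default_scheme) + align_loops_affine(
                "A" * la, "A" * lb, default_scheme
            )
            assert mh <= bound + 1e-9


def test_scheme_invariants_enforced():
    with pytest.raises(ScoringError, match="g < e < 0"):
        simple_scheme(g=-1.0, e=-5.0)
    d = {(a, b): 1.0 if a == b else -1.0 for a in "ACGU" for b in "ACGU"}
    r = {(x + y, u + v): 1.0 for x in "ACGU" for y in "ACGU" for u in "ACGU" for v in "ACGU"}
    with pytest.raises(ScoringError, match="w1 > w2"):
        ScoringScheme(R=r, D=d, w1=1.0, w2=2.0)


def test_yaml_config_overrides_defaults():
    sch = ScoringScheme.from_yaml("g: -7\ne: -2\nw1: 3\nw2: 1.5\n")
    assert (sch.g, sch.e, sch.w1, sch.w2) == (-7.0, -2.0, 3.0, 1.5)
    assert sch.r_max == ScoringScheme.default().r_max
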