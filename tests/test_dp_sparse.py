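"""Sparse engine: OPM detection, hairpin gate, online pruning."""

import pytest

from arcalign import (
    OPM,
    align_loops_affine,
    compute_m_bar,
    detect_opm,
    full_align,
    make_structure,
    mh_gate,
    prune_bounds,
    random_instance_pair,
    sparse_align,
)
from arcalign._ribosum import RIBOSUM85_60_NUC, RIBOSUM85_60_PAIR
from arcalign.scoring import ScoringScheme


@pytest.fixture(scope="module")
def heavy_structure_scheme():
    """Structure-dominant weighting (w1=4): the regime in which the
    sound pruning bound actually fires on stacked helices."""
    return ScoringScheme(
        R=dict(RIBOSUM85_60_PAIR), D=dict(RIBOSUM85_60_NUC),
        g=-5.0, e=-1.0, w1=4.0, w2=1.0,
    )


class TestDetection:
    def test_boundary_equality_counts_as_opm(self):
        assert detect_opm(None, None, 10.0, 10.0) is True

    def test_lower_matched_score_is_not_an_opm(self):
        assert detect_opm(None, None, 9.0, 10.0) is False

    def test_self_matching_on_identical_structures_is_opm(self, default_scheme):
        A, _ = random_instance_pair(3, target_length=40, target_pairs=6)
        _, state, opms, _ = sparse_align(A, A, default_scheme)
        n = len(A.pairs)
        detected = {(o.idx_a, o.idx_b) for o in opms.entries}
        for i in range(n):
            assert (i, i) in detected

    def test_detection_partitions_couples_by_margin(self, default_scheme):
        """The recorded m_bar is the best window configuration that
        leaves the couple unmatched: detected OPMs beat it strictly,
        all other couples do not."""
        A, B = random_instance_pair(7, target_length=36, target_pairs=5)
        _, state, opms, _ = sparse_align(A, B, default_scheme)
        detected = {(o.idx_a, o.idx_b) for o in opms.entries}
        for key, m_bar in state.m_bar.items():
            if key in detected:
                assert state.M[key] > m_bar
            else:
                assert state.M[key] <= m_bar

    def test_unrestricted_window_score_is_best_of_match_or_not(
        self, default_scheme
    ):
        """The dense recursion on the extended window equals
        max(matched score, best non-matching configuration)."""
        A, B = random_instance_pair(9, target_length=30, target_pairs=4)
        _, state, _, _ = sparse_align(A, B, default_scheme)
        for (i, j), m_bar in state.m_bar.items():
            ref = compute_m_bar(A, B, default_scheme, A.pairs[i], B.pairs[j])
            assert round(ref * 100) == max(state.M[(i, j)], m_bar)

    def test_m_bar_of_pairless_interiors_is_best_of_break_or_match(
        self, default_scheme
    ):
        """With no further pairs inside the spans, the unrestricted
        extended-region score is the better of breaking both pairs
        (plain loop alignment of the spans) and matching them."""
        A = make_structure("a", "GAAAC", [(1, 5)])
        B = make_structure("b", "GAAC", [(1, 4)])
        got = compute_m_bar(A, B, default_scheme, A.pairs[0], B.pairs[0])
        broken = align_loops_affine(A.seq, B.seq, default_scheme)
        matched = (
            default_scheme.pair_centi("GC", "GC") / 100.0
            + align_loops_affine("AAA", "AA", default_scheme)
        )
        assert got == pytest.approx(max(broken, matched))

    def test_every_recorded_opm_satisfied_detection(self, default_scheme):
        A, B = random_instance_pair(13, target_length=50, target_pairs=9)
        _, state, opms, _ = sparse_align(A, B, default_scheme)
        for o in opms.entries:
            assert detect_opm(o.pair_a, o.pair_b, o.score, o.m_bar)
            assert o.score_centi == state.M[(o.idx_a, o.idx_b)]


class TestEquivalence:
    @pytest.mark.parametrize("seed", [0, 4, 8, 15, 23, 42])
    def test_all_switch_combinations_equal_dense_engine(self, default_scheme, seed):
        A, B = random_instance_pair(seed, target_length=50, target_pairs=10)
        full_score, full_state = full_align(A, B, default_scheme)
        for prune in (True, False):
            for gate in (True, False):
                _, st, _, _ = sparse_align(
                    A, B, default_scheme, prune=prune, use_mh_gate=gate
                )
                assert st.score_centi == full_state.score_centi

    def test_pairless_inputs_have_empty_opm_list(self, default_scheme):
        A = make_structure("a", "GGACU", [])
        B = make_structure("b", "GACUU", [])
        score, _, opms, stats = sparse_align(A, B, default_scheme)
        assert stats.z_final == 0 and stats.z_peak == 0
        assert score == pytest.approx(
            align_loops_affine(A.seq, B.seq, default_scheme)
        )

    def test_opm_count_bounded_by_couple_count(self, default_scheme):
        for seed in (2, 6):
            A, B = random_instance_pair(seed, target_length=50, target_pairs=10)
            _, _, opms, stats = sparse_align(A, B, default_scheme)
            assert stats.z_peak <= len(A.pairs) * len(B.pairs)
            assert stats.z_final == stats.z_peak - stats.opms_pruned


class TestHairpinGate:
    def test_strong_chain_case_skips_hairpin_computation(self):
        assert mh_gate is not None  # decision function exercised below

    def test_gate_skips_iff_chain_exceeds_bound(self, default_scheme):
        A = make_structure("a", "GGAAACC", [(2, 6), (1, 7)])
        pa, pb = A.pairs[1], A.pairs[1]
        assert mh_gate(pa, pb, 1000.0, default_scheme, (A, A)) == "skip_Mh"
        assert mh_gate(pa, pb, -1000.0, default_scheme, (A, A)) == "compute_Mh"
        assert mh_gate(pa, pb, None, default_scheme, (A, A)) == "compute_Mh"

    def test_bound_dominates_computed_hairpin_cells(self, default_scheme):
        A, B = random_instance_pair(17, target_length=50, target_pairs=9)
        _, st, _, _ = sparse_align(A, B, default_scheme, use_mh_gate=False)
        for key, mh in st.Mh.items():
            if key in st.mh_bound:
                assert mh <= st.mh_bound[key]

    def test_gate_skips_cells_on_multi_helix_instances(self, default_scheme):
        skipped = 0
        for seed in (1, 3, 5):
            A, B = random_instance_pair(seed, target_length=60, target_pairs=12)
            _, _, _, stats = sparse_align(A, B, default_scheme)
            skipped += stats.mh_cells_skipped
        assert skipped > 0


class TestPruneBounds:
    def make_nested(self, seq, outer, inner, extra=()):
        s = make_structure("x", seq, [outer, inner, *extra])
        return s

    def scheme(self):
        # r_max=6, d_max=2, g=-5, e=-1 under near-unit weights
        from arcalign import simple_scheme

        return simple_scheme(
            match=2.0, mismatch=-1.0,
            pair_scores={("GC", "GC"): 6.0}, pair_default=0.0,
            g=-5.0, e=-1.0,
        )

    def bounds(self, A, inner_pair, outer_pair, sch):
        inner = OPM(0, 0, inner_pair, inner_pair, 0, 0)
        outer = OPM(0, 0, outer_pair, outer_pair, 0, 0)
        return prune_bounds(inner, outer, (A, A), sch)

    def test_perfect_stacking_charges_only_freed_nucleotides(self):
        """Stacked outer/inner pair: the flanks hold exactly the outer
        pair's own nucleotides, each worth at most d_max - g - e = 8."""
        A = self.make_nested("GGAAACC", (1, 7), (2, 6))
        u_l, u_r = self.bounds(A, A.pairs[0], A.pairs[1], self.scheme())
        assert (u_l, u_r) == (8.0, 8.0)

    def test_flank_with_annotated_pair_adds_r_max_term(self):
        # outer (1,12), inner (6,10); left flank [1,5] holds pair (2,4):
        # U_l = 1*r_max + 5*(d_max-g-e) = 6 + 40; right flank [11,12] free
        A = self.make_nested("GGACAGAAACCC", (1, 12), (6, 10), extra=[(2, 4)])
        u_l, u_r = self.bounds(A, A.pairs[1], A.pairs[2], self.scheme())
        assert u_l == pytest.approx(46.0)
        assert u_r == pytest.approx(16.0)

    def test_non_nested_arguments_rejected(self, default_scheme):
        A = self.make_nested("GGAAACC", (1, 7), (2, 6))
        with pytest.raises(ValueError, match="enclosed"):
            self.bounds(A, A.pairs[1], A.pairs[0], default_scheme)


class TestOnlinePruning:
    def test_stacked_identical_helices_keep_one_self_opm(
        self, heavy_structure_scheme
    ):
        """Aligning a perfect helix with itself detects every stacked
        self-matching as an OPM; under structure-heavy weights pruning
        keeps only the outermost one alive."""
        seq = "GGGGGAAAACCCCC"
        s = make_structure("helix", seq, [(k, 15 - k) for k in range(1, 6)])
        _, _, opms, stats = sparse_align(s, s, heavy_structure_scheme)
        self_opms = [o for o in opms.entries if o.idx_a == o.idx_b]
        assert len(self_opms) == 5
        alive = [o for o in self_opms if o.alive]
        assert len(alive) < 5
        assert stats.opms_pruned > 0
        # the survivor is the outermost layer
        assert max(o.idx_a for o in self_opms) in {o.idx_a for o in alive}

    def test_large_flank_bounds_retain_inner_opm(self, default_scheme):
        """When the flanks between inner and outer pairs are large the
        re-splitting bound exceeds the score gap and the inner OPM
        survives."""
        seq = "GAAAAAGAAACAAAAAC"
        s = make_structure("x", seq, [(1, 17), (7, 11)])
        _, _, opms, stats = sparse_align(s, s, default_scheme)
        inner_self = [
            o for o in opms.entries if o.pair_a.left == 7 and o.pair_b.left == 7
        ]
        assert inner_self and all(o.alive for o in inner_self)

    def test_pruning_preserves_every_m_cell(self, default_scheme):
        """Replay audit at unit scale: tombstoning never changes any
        subsequently computed M value."""
        for seed in (21, 34, 55):
            A, B = random_instance_pair(seed, target_length=50, target_pairs=10)
            _, on, _, s_on = sparse_align(A, B, default_scheme, use_mh_gate=False)
            _, off, _, _ = sparse_align(
                A, B, default_scheme, prune=False, use_mh_gate=False
            )
            assert on.M == off.M
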