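"""Structure parsing, relations, loop regions and format round trips."""

import io

import pytest

from arcalign import (
    BasePair,
    GenParams,
    Relation,
    StructureError,
    classify_relation,
    loop_region,
    make_structure,
    parse_bpseq,
    parse_vienna,
    random_structure,
)


class TestParseVienna:
    def test_pairs_sorted_by_right_endpoint(self):
        s = parse_vienna(">x\nGGAAACC\n((...))\n")
        assert [(p.left, p.right) for p in s.pairs] == [(2, 6), (1, 7)]

    def test_unpaired_sequence_has_no_pairs(self):
        s = parse_vienna(">x\nACGU\n....\n")
        assert s.pairs == []

    @pytest.mark.parametrize(
        "record,msg",
        [
            (">x\nACGU\n((..\n", r"unbalanced '\(' at position 1"),
            (">x\nACGU\n)...\n", r"unbalanced '\)' at position 1"),
            (">x\nACGU\n...\n", "does not match"),
            (">x\nACGU\n[..]\n", "unsupported characters"),
            (">x\nACXU\n....\n", "outside"),
        ],
    )
    def test_malformed_input_is_rejected_with_position(self, record, msg):
        with pytest.raises(StructureError, match=msg):
            parse_vienna(record)

    def test_round_trip_reproduces_record(self):
        rec = ">hp\nGGACAAGUCC\n(((....)))\n"
        assert parse_vienna(rec).to_vienna() == rec

    def test_t_normalised_to_u(self):
        s = parse_vienna(">x\nACGT\n....\n")
        assert s.seq == "ACGU"


class TestBpseq:
    def test_round_trip(self):
        s = parse_vienna(">x\nGGAAACC\n((...))\n")
        again = parse_bpseq(s.to_bpseq())
        assert again.seq == s.seq
        assert [(p.left, p.right) for p in again.pairs] == [
            (p.left, p.right) for p in s.pairs
        ]

    def test_non_reciprocal_pairing_rejected(self):
        with pytest.raises(StructureError, match="reciprocal"):
            parse_bpseq("1 G 3\n2 A 0\n3 C 0\n")


class TestRelations:
    def test_nested_pairs_classified_as_enclosing(self):
        assert classify_relation(BasePair(2, 6), BasePair(1, 7)) == Relation.J_ENCLOSES_I
        assert classify_relation(BasePair(1, 7), BasePair(2, 6)) == Relation.I_ENCLOSES_J

    def test_juxtaposed_pairs_classified_by_order(self):
        assert classify_relation(BasePair(1, 4), BasePair(5, 8)) == Relation.I_BEFORE_J
        assert classify_relation(BasePair(5, 8), BasePair(1, 4)) == Relation.J_BEFORE_I

    def test_crossing_pairs_signal_corruption(self):
        with pytest.raises(StructureError, match="cross"):
            classify_relation(BasePair(1, 5), BasePair(3, 8))

    def test_crossing_pairs_rejected_at_construction(self):
        with pytest.raises(StructureError, match="cross"):
            make_structure("x", "ACGUACGU", [(1, 5), (3, 8)])

    def test_duplicate_position_rejected(self):
        with pytest.raises(StructureError, match="occurs in both"):
            make_structure("x", "ACGUACGU", [(1, 5), (5, 8)])


class TestDirectlyBeforeSets:
    """F(p) holds every directly-before juxtaposed pair: q with r(q) < l(p)
    and no pair entirely between q and p.  Members may sit at different
    nesting depths (chains may dive through broken enclosing pairs)."""

    def coords(self, s, idx):
        return {(s.pairs[j].left, s.pairs[j].right) for j in s.F_of[idx]}

    def test_nested_block_exposes_both_depths(self):
        s = make_structure("x", "GCGCAUGCGC", [(1, 4), (2, 3), (5, 8), (6, 7)])
        i58 = next(i for i, p in enumerate(s.pairs) if (p.left, p.right) == (5, 8))
        i67 = next(i for i, p in enumerate(s.pairs) if (p.left, p.right) == (6, 7))
        assert self.coords(s, i58) == {(1, 4), (2, 3)}
        assert self.coords(s, i67) == {(1, 4), (2, 3)}

    def test_intermediate_sibling_blocks_earlier_one(self):
        s = make_structure("x", "GCGCGC", [(1, 2), (3, 4), (5, 6)])
        i56 = next(i for i, p in enumerate(s.pairs) if (p.left, p.right) == (5, 6))
        assert self.coords(s, i56) == {(3, 4)}

    def test_inner_pair_sees_predecessor_through_parent(self):
        s = make_structure("x", "GCGAUC", [(1, 2), (3, 6), (4, 5)])
        i36 = next(i for i, p in enumerate(s.pairs) if (p.left, p.right) == (3, 6))
        i45 = next(i for i, p in enumerate(s.pairs) if (p.left, p.right) == (4, 5))
        assert self.coords(s, i36) == {(1, 2)}
        assert self.coords(s, i45) == {(1, 2)}

    def test_parent_is_innermost_enclosing_pair(self):
        s = make_structure("x", "GCGAUC", [(1, 2), (3, 6), (4, 5)])
        by_coord = {(p.left, p.right): i for i, p in enumerate(s.pairs)}
        assert s.parent_of[by_coord[(4, 5)]] == by_coord[(3, 6)]
        assert s.parent_of[by_coord[(3, 6)]] == -1


class TestLoopRegions:
    def setup_method(self):
        self.s = parse_vienna(">x\nGGAAACC\n((...))\n")
        self.inner = BasePair(2, 6)
        self.outer = BasePair(1, 7)

    def test_hairpin_interior(self):
        r = loop_region(self.s, "hairpin", self.inner)
        assert (r.start, r.end, len(r)) == (3, 5, 3)

    def test_stacked_pair_has_empty_internal_loops(self):
        left = loop_region(self.s, "left_internal", self.inner, self.outer)
        right = loop_region(self.s, "right_internal", self.inner, self.outer)
        assert len(left) == 0 and len(right) == 0

    def test_between_region(self):
        s = make_structure("x", "GCGCAGCGCA", [(1, 4), (2, 3), (6, 9), (7, 8)])
        r = loop_region(s, "between", BasePair(1, 4), BasePair(6, 9))
        assert (r.start, r.end, len(r)) == (5, 5, 1)

    def test_relation_precondition_enforced(self):
        with pytest.raises(StructureError):
            loop_region(self.s, "between", self.outer, self.inner)


def test_every_position_in_exactly_one_pair_or_loop():
    """Partition invariant: pair nucleotides plus loop-region lengths
    under the tree partition cover the sequence exactly once."""
    for seed in range(5):
        s = random_structure(GenParams(target_length=80, target_pairs=14, seed=seed))
        covered = 2 * len(s.pairs)
        # loop regions: per pair, its interior minus children spans; plus root
        def interior_unpaired(lo, hi, children):
            total = hi - lo + 1
            for c in children:
                total -= s.pairs[c].right - s.pairs[c].left + 1
            return total

        for i, p in enumerate(s.pairs):
            covered += interior_unpaired(p.left + 1, p.right - 1, s.children_of(i))
        covered += interior_unpaired(1, s.length, s.children_of(-1))
        assert covered == s.length


def test_generated_structures_round_trip_through_vienna():
    for seed in range(5):
        s = random_structure(GenParams(target_length=70, target_pairs=12, seed=seed))
        again = parse_vienna(s.to_vienna())
        assert again.seq == s.seq
        assert [(p.left, p.right) for p in again.pairs] == [
            (p.left, p.right) for p in s.pairs
        ]


def test_stockholm_output_readable_by_biopython(tmp_path):
    from Bio import AlignIO

    from arcalign import full_align, mispredicted_hairpin_pair, trace_full, write_stockholm

    A, B = mispredicted_hairpin_pair()
    _, st = full_align(A, B)
    res = trace_full(st)
    out = io.StringIO()
    write_stockholm(res, out)
    aln = AlignIO.read(io.StringIO(out.getvalue()), "stockholm")
    assert len(aln) == 2
    assert str(aln[0].seq).replace("-", "") == A.seq
    assert str(aln[1].seq).replace("-", "") == B.seq
    assert len(aln[0].seq) == len(aln[1].seq)
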