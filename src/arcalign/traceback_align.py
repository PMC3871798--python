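"""Alignment recovery and score recomposition.

The DP engines store backpointers for every cell; this module turns a
filled DP state into an :class:`AlignmentResult`: the base-pair
matching relation, the gapped sequences (every input nucleotide in
exactly one column), per-sequence structure annotation (matched pairs
as brackets, broken pairs as dots), and the exact score decomposition
into its structural and sequence parts.

The decomposition is recorded as a list of scored segments (matched
pair columns, loop alignment blocks, whole-span deletion blocks), which
lets :func:`recompose_score` re-derive the engine score from the output
alone -- gap runs are scored per segment, exactly as the recursion
charged them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dp_full import DPState
from .scoring import ScoringScheme, gotoh_traceback_centi
from .structio import BasePair, Relation, StructuredRNA, classify_relation


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentResult:
    """A complete pairwise structure alignment.

    ``segments`` entries (all column ranges inclusive, 0-based):
      ("pair", left_col, right_col, i_a, i_b)  -- matched pair columns
      ("loop", start_col, end_col)             -- affine-aligned loop block
      ("del", side, start_col, end_col)        -- whole-span deletion block
    """

    a_id: str
    b_id: str
    seq_a: str
    seq_b: str
    gapped_a: str
    gapped_b: str
    ss_a: str
    ss_b: str
    matching: list[tuple[BasePair, BasePair]]
    broken_a: list[BasePair]
    broken_b: list[BasePair]
    segments: list[tuple] = field(default_factory=list)
    score_total: float = 0.0
    score_structure: float = 0.0
    score_sequence: float = 0.0

    def rows(self) -> list[tuple[str, str, str]]:
        return [
            (self.a_id, self.gapped_a, self.ss_a),
            (self.b_id, self.gapped_b, self.ss_b),
        ]

    def gap_columns(self) -> int:
        """Number of columns holding a gap in either row."""
        return sum(
            1
            for ca, cb in zip(self.gapped_a, self.gapped_b)
            if ca == "-" or cb == "-"
        )

    def aligned_couples(self) -> set[tuple[int, int]]:
        """Residue-residue aligned position couples (1-based, gaps excluded)."""
        out = set()
        i = j = 0
        for ca, cb in zip(self.gapped_a, self.gapped_b):
            if ca != "-":
                i += 1
            if cb != "-":
                j += 1
            if ca != "-" and cb != "-":
                out.add((i, j))
        return out


class _Builder:
    def __init__(self, state: DPState):
        self.state = state
        self.prob = state.problem
        self.cols_a: list[str] = []
        self.cols_b: list[str] = []
        self.ann_a: list[str] = []
        self.ann_b: list[str] = []
        self.segments: list[tuple] = []
        self.matching: list[tuple[int, int]] = []
        self.structure_centi = 0
        self.sequence_centi = 0

    # -- emission helpers -----------------------------------------------

    def _emit_loop(self, alo: int, ahi: int, blo: int, bhi: int) -> None:
        x = self.prob.A.seq[alo - 1 : ahi] if alo <= ahi else ""
        y = self.prob.B.seq[blo - 1 : bhi] if blo <= bhi else ""
        if not x and not y:
            return
        sc, ga, gb = gotoh_traceback_centi(x, y, self.prob.sch)
        start = len(self.cols_a)
        self.cols_a.extend(ga)
        self.cols_b.extend(gb)
        self.ann_a.extend("." if c != "-" else "-" for c in ga)
        self.ann_b.extend("." if c != "-" else "-" for c in gb)
        self.segments.append(("loop", start, len(self.cols_a) - 1))
        self.sequence_centi += sc

    def _emit_del(self, side: str, lo: int, hi: int) -> None:
        seq = (self.prob.A if side == "A" else self.prob.B).seq
        span = seq[lo - 1 : hi]
        if not span:
            return
        start = len(self.cols_a)
        if side == "A":
            self.cols_a.extend(span)
            self.cols_b.extend("-" * len(span))
            self.ann_a.extend("." * len(span))
            self.ann_b.extend("-" * len(span))
        else:
            self.cols_a.extend("-" * len(span))
            self.cols_b.extend(span)
            self.ann_a.extend("-" * len(span))
            self.ann_b.extend("." * len(span))
        self.segments.append(("del", side, start, len(self.cols_a) - 1))
        self.sequence_centi += self.prob.gap(len(span))

    # -- chain decoding --------------------------------------------------

    def _decode_chain(self, ctx: tuple[int, int]) -> list[tuple]:
        prob = self.prob
        la, ra, lb, rb = prob.la, prob.ra, prob.lb, prob.rb
        p, q = ctx
        lo_a, hi_a = la[p] + 1, ra[p] - 1
        lo_b, hi_b = lb[q] + 1, rb[q] - 1
        bp = self.state.chain_bp[ctx]
        cur = self.state.bp_Ml[ctx]
        prims: list[tuple] = [("loop", ra[cur[0]] + 1, hi_a, rb[cur[1]] + 1, hi_b)]
        while True:
            a, b = cur
            rec = bp[cur]
            tag = rec[0]
            if tag == "start":
                prims = [
                    ("loop", lo_a, la[a] - 1, lo_b, lb[b] - 1),
                    ("anchor", a, b),
                ] + prims
                return prims
            if tag == "ext":
                aj, bj = rec[1], rec[2]
                prims = [
                    ("loop", ra[aj] + 1, la[a] - 1, rb[bj] + 1, lb[b] - 1),
                    ("anchor", a, b),
                ] + prims
                cur = (aj, bj)
            elif tag == "delA":
                aj = rec[1]
                prims = [("delA", ra[aj] + 1, ra[a])] + prims
                cur = (aj, b)
            elif tag == "delB":
                bj = rec[1]
                prims = [("delB", rb[bj] + 1, rb[b])] + prims
                cur = (a, bj)
            else:  # pragma: no cover
                raise AlignmentError(f"unknown chain record {rec!r}")

    # -- recursive rendering ---------------------------------------------

    def render(self, p: int, q: int) -> None:
        prob = self.prob
        is_root = p == prob.ROOT_A
        if not is_root:
            self.matching.append((p, q))
            self.structure_centi += prob.sstr(p, q)
            left_col = len(self.cols_a)
            self.cols_a.append(prob.A.seq[prob.la[p] - 1])
            self.cols_b.append(prob.B.seq[prob.lb[q] - 1])
            self.ann_a.append("(")
            self.ann_b.append("(")
        case = self.state.bp_M[(p, q)]
        if case == "h":
            self._emit_loop(
                prob.la[p] + 1, prob.ra[p] - 1, prob.lb[q] + 1, prob.rb[q] - 1
            )
        else:
            for prim in self._decode_chain((p, q)):
                tag = prim[0]
                if tag == "loop":
                    self._emit_loop(prim[1], prim[2], prim[3], prim[4])
                elif tag == "anchor":
                    self.render(prim[1], prim[2])
                elif tag == "delA":
                    self._emit_del("A", prim[1], prim[2])
                else:
                    self._emit_del("B", prim[1], prim[2])
        if not is_root:
            right_col = len(self.cols_a)
            self.cols_a.append(prob.A.seq[prob.ra[p] - 1])
            self.cols_b.append(prob.B.seq[prob.rb[q] - 1])
            self.ann_a.append(")")
            self.ann_b.append(")")
            self.segments.append(("pair", left_col, right_col, p, q))


def build_alignment(state: DPState) -> AlignmentResult:
    """Walk the backpointers of a filled DP state into an AlignmentResult.

    The recomposed score is checked against the engine score; a mismatch
    means corrupted backpointers and raises :class:`AlignmentError`.
    """
    prob = state.problem
    b = _Builder(state)
    b.render(prob.ROOT_A, prob.ROOT_B)
    total = b.structure_centi + b.sequence_centi
    if total != state.score_centi:
        raise AlignmentError(
            f"traceback recomposition {total} != engine score {state.score_centi}"
        )
    matched_a = {p for p, _ in b.matching}
    matched_b = {q for _, q in b.matching}
    result = AlignmentResult(
        a_id=prob.A.id,
        b_id=prob.B.id,
        seq_a=prob.A.seq,
        seq_b=prob.B.seq,
        gapped_a="".join(b.cols_a),
        gapped_b="".join(b.cols_b),
        ss_a="".join(b.ann_a),
        ss_b="".join(b.ann_b),
        matching=[
            (prob.A.pairs[p], prob.B.pairs[q]) for p, q in sorted(b.matching)
        ],
        broken_a=[prob.A.pairs[i] for i in range(prob.nA) if i not in matched_a],
        broken_b=[prob.B.pairs[j] for j in range(prob.nB) if j not in matched_b],
        segments=b.segments,
        score_total=total / 100.0,
        score_structure=b.structure_centi / 100.0,
        score_sequence=b.sequence_centi / 100.0,
    )
    if result.gapped_a.replace("-", "") != prob.A.seq:
        raise AlignmentError("ungapping row A does not reproduce the input sequence")
    if result.gapped_b.replace("-", "") != prob.B.seq:
        raise AlignmentError("ungapping row B does not reproduce the input sequence")
    return result


# ---------------------------------------------------------------------------
# score recomposition and quality metric
# ---------------------------------------------------------------------------


def _score_block_affine(row: str, other: str, sch: ScoringScheme) -> int:
    """Gap-run cost of one row within a segment block (centi)."""
    cost = 0
    run = 0
    for c in row:
        if c == "-":
            run += 1
        elif run:
            cost += sch.gap_centi(run)
            run = 0
    if run:
        cost += sch.gap_centi(run)
    del other
    return cost


def recompose_score(
    a: AlignmentResult,
    A: StructuredRNA,
    B: StructuredRNA,
    sch: ScoringScheme,
) -> tuple[float, float, float]:
    """Re-derive (total, structure, sequence) from the alignment output.

    Validates that the matching is one-to-one and order consistent
    (matched couples are pairwise either both nested or both juxtaposed,
    in the same direction), then sums the structural terms over the
    matching and the affine sequence terms over the recorded loop
    partition.  The result equals the engine score exactly.
    """
    seen_a: set[tuple[int, int]] = set()
    seen_b: set[tuple[int, int]] = set()
    for pa, pb in a.matching:
        ka, kb = (pa.left, pa.right), (pb.left, pb.right)
        if ka in seen_a or kb in seen_b:
            raise AlignmentError("matching is not one-to-one")
        seen_a.add(ka)
        seen_b.add(kb)
    for i in range(len(a.matching)):
        for j in range(i + 1, len(a.matching)):
            ra = classify_relation(a.matching[i][0], a.matching[j][0])
            rb = classify_relation(a.matching[i][1], a.matching[j][1])
            if ra != rb or ra not in (
                Relation.I_ENCLOSES_J,
                Relation.J_ENCLOSES_I,
                Relation.I_BEFORE_J,
                Relation.J_BEFORE_I,
            ):
                raise AlignmentError(
                    f"matching violates order consistency: {a.matching[i]} vs {a.matching[j]}"
                )
    structure = sum(
        sch.pair_centi(A.dinucleotide(pa), B.dinucleotide(pb))
        for pa, pb in a.matching
    )
    sequence = 0
    for seg in a.segments:
        if seg[0] == "pair":
            continue
        if seg[0] == "del":
            _, side, c0, c1 = seg
            sequence += sch.gap_centi(c1 - c0 + 1)
            continue
        _, c0, c1 = seg
        block_a = a.gapped_a[c0 : c1 + 1]
        block_b = a.gapped_b[c0 : c1 + 1]
        for ca, cb in zip(block_a, block_b):
            if ca != "-" and cb != "-":
                sequence += sch.nuc_centi(ca, cb)
        sequence += _score_block_affine(block_a, block_b, sch)
        sequence += _score_block_affine(block_b, block_a, sch)
    return (structure + sequence) / 100.0, structure / 100.0, sequence / 100.0


def sps(test: AlignmentResult, reference: AlignmentResult) -> float:
    """Sum-of-pairs score: the fraction of reference residue-residue
    aligned couples that the test alignment reproduces."""
    if test.seq_a != reference.seq_a or test.seq_b != reference.seq_b:
        raise AlignmentError("alignments are over different sequences")
    ref = reference.aligned_couples()
    if not ref:
        return 1.0
    return len(ref & test.aligned_couples()) / len(ref)


def dump_text(a: AlignmentResult) -> str:
    """Plain pairwise text dump with the score decomposition."""
    lines = [
        f"# {a.a_id} vs {a.b_id}",
        f"# score_total={a.score_total:.2f} structure={a.score_structure:.2f} "
        f"sequence={a.score_sequence:.2f}",
        f"# matched_pairs={len(a.matching)} broken_A={len(a.broken_a)} "
        f"broken_B={len(a.broken_b)}",
        a.gapped_a,
        a.ss_a,
        a.gapped_b,
        a.ss_b,
    ]
    return "\n".join(lines) + "\n"
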