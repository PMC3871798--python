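"""Baseline dense recursion over all base-pair couples.

For every couple (p_A, p_B) the optimal score M given that the two
pairs match is the better of

* the hairpin case Mh: structural score plus a plain affine-gap
  alignment of the two full interiors (every enclosed pair is broken);
* the loop case Ml: structural score plus the best chain of matched
  enclosed couples, where consecutive chain members are connected
  through their directly-before (F) predecessors, pairs skipped over by
  a chain hop are deleted wholesale at the region deletion penalty G,
  and the flanks against the enclosing couple are aligned as sequence.

The chain table Mc is context dependent (its start case aligns the
region back to the enclosing pair), so it is computed per enclosing
couple.  Complexity is O(n^4 + n^2 l^2): all couples times all enclosed
couple states, plus one affine alignment per distinct region
combination.  This engine is the exactness reference for the sparse
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from ._core import Problem
from .scoring import NEG, ScoringScheme
from .structio import StructuredRNA

Couple = tuple[int, int]


@dataclass
class DPState:
    """Filled DP tables plus backpointers for either engine.

    ``M``, ``Mh``, ``Ml`` map pair-index couples to centi scores (root =
    index n).  ``bp_M`` records which case won ('h' or 'l');
    ``bp_Ml`` the winning final chain state; ``chain_bp`` per enclosing
    couple the chain backpointer records, with the same format in both
    engines:

    ('start',) | ('ext', aj, bj) | ('delA', aj) | ('delB', bj)
    """

    problem: Problem
    engine: str
    M: dict[Couple, int] = field(default_factory=dict)
    Mh: dict[Couple, int] = field(default_factory=dict)
    Ml: dict[Couple, int] = field(default_factory=dict)
    bp_M: dict[Couple, str] = field(default_factory=dict)
    bp_Ml: dict[Couple, Couple] = field(default_factory=dict)
    chain_bp: dict[Couple, dict[Couple, Any]] = field(default_factory=dict)

    @property
    def score_centi(self) -> int:
        return self.M[(self.problem.ROOT_A, self.problem.ROOT_B)]

    @property
    def score(self) -> float:
        return self.score_centi / 100.0


def _chain_full(state: DPState, prob: Problem, p: int, q: int) -> tuple[int, Couple | None]:
    """Compute the chain table Mc under enclosing couple (p, q).

    Returns (Ml - S_str, final state): the best chain value including
    the right flank alignment, without the structural term of (p, q).
    States are visited in lexicographic order of right endpoints, and
    strict improvement is required to overwrite, which makes the
    tie-break deterministic (earliest case, smallest right endpoints).
    """
    la, ra, lb, rb = prob.la, prob.ra, prob.lb, prob.rb
    lo_a, hi_a = la[p] + 1, ra[p] - 1
    lo_b, hi_b = lb[q] + 1, rb[q] - 1
    M = state.M
    states = [(a, b) for a in prob.encA[p] for b in prob.encB[q]]
    states.sort(key=lambda s: (ra[s[0]], rb[s[1]]))
    mc: dict[Couple, int] = {}
    bp: dict[Couple, Any] = {}
    for a, b in states:
        m_ab = M[(a, b)]
        # case 1: (a, b) starts the chain; everything to the left of it is
        # aligned as loop sequence against the enclosing couple
        best = m_ab + prob.sseq(lo_a, la[a] - 1, lo_b, lb[b] - 1)
        rec: Any = ("start",)
        # case 2: extend a chain ending at directly-before heads
        for aj in prob.F_a[a]:
            if not la[aj] > la[p]:
                continue
            for bj in prob.F_b[b]:
                if not lb[bj] > lb[q]:
                    continue
                pred = mc.get((aj, bj))
                if pred is None:
                    continue
                v = pred + m_ab + prob.sseq(ra[aj] + 1, la[a] - 1, rb[bj] + 1, lb[b] - 1)
                if v > best:
                    best, rec = v, ("ext", aj, bj)
        # case 3: delete the B-side head (full span, affine G)
        for bj in prob.F_b[b]:
            if not lb[bj] > lb[q]:
                continue
            pred = mc.get((a, bj))
            if pred is None:
                continue
            v = pred + prob.gap(rb[b] - rb[bj])
            if v > best:
                best, rec = v, ("delB", bj)
        # case 4: delete the A-side head
        for aj in prob.F_a[a]:
            if not la[aj] > la[p]:
                continue
            pred = mc.get((aj, b))
            if pred is None:
                continue
            v = pred + prob.gap(ra[a] - ra[aj])
            if v > best:
                best, rec = v, ("delA", aj)
        mc[(a, b)] = best
        bp[(a, b)] = rec
    state.chain_bp[(p, q)] = bp
    best_val, best_state = NEG, None
    for a, b in states:
        v = mc[(a, b)] + prob.sseq(ra[a] + 1, hi_a, rb[b] + 1, hi_b)
        if v > best_val:
            best_val, best_state = v, (a, b)
    return best_val, best_state


def _compute_couple(state: DPState, prob: Problem, p: int, q: int) -> None:
    sstr = prob.sstr(p, q)
    chain_val, final = _chain_full(state, prob, p, q)
    ml = chain_val + sstr if chain_val > NEG else NEG
    mh = sstr + prob.sseq(prob.la[p] + 1, prob.ra[p] - 1, prob.lb[q] + 1, prob.rb[q] - 1)
    key = (p, q)
    state.Ml[key] = ml
    state.Mh[key] = mh
    if final is not None:
        state.bp_Ml[key] = final
    if mh >= ml:
        state.M[key], state.bp_M[key] = mh, "h"
    else:
        state.M[key], state.bp_M[key] = ml, "l"


def full_align(
    A: StructuredRNA, B: StructuredRNA, sch: ScoringScheme | None = None
) -> tuple[float, DPState]:
    """Optimal structure alignment score by the dense recursion.

    Returns the score (float) and the filled :class:`DPState`; the
    alignment itself is recovered with :func:`trace_full`.
    """
    sch = sch or ScoringScheme.default()
    prob = Problem(A, B, sch)
    state = DPState(problem=prob, engine="full")
    for p, q in prob.couples():
        _compute_couple(state, prob, p, q)
    _compute_couple(state, prob, prob.ROOT_A, prob.ROOT_B)
    return state.score, state


def precompute_loop_similarities(
    A: StructuredRNA, B: StructuredRNA, sch: ScoringScheme | None = None
) -> dict[tuple[int, int, int, int], float]:
    """All loop-similarity scores the dense recursion can request.

    Returns a table keyed by region coordinates (a_lo, a_hi, b_lo,
    b_hi), 1-based inclusive with empty regions normalised to (1, 0);
    every entry equals ``align_loops_affine`` on the two regions.
    """
    sch = sch or ScoringScheme.default()
    prob = Problem(A, B, sch)
    la, ra, lb, rb = prob.la, prob.ra, prob.lb, prob.rb
    contexts = prob.couples() + [(prob.ROOT_A, prob.ROOT_B)]
    for p, q in contexts:
        prob.sseq(la[p] + 1, ra[p] - 1, lb[q] + 1, rb[q] - 1)  # hairpin case
        for a in prob.encA[p]:
            for b in prob.encB[q]:
                prob.sseq(la[p] + 1, la[a] - 1, lb[q] + 1, lb[b] - 1)
                prob.sseq(ra[a] + 1, ra[p] - 1, rb[b] + 1, rb[q] - 1)
                for aj in prob.F_a[a]:
                    if la[aj] > la[p]:
                        for bj in prob.F_b[b]:
                            if lb[bj] > lb[q]:
                                prob.sseq(ra[aj] + 1, la[a] - 1, rb[bj] + 1, lb[b] - 1)
    return {k: v / 100.0 for k, v in prob._sseq_cache.items()}


def trace_full(state: DPState):
    """Recover the full alignment from a dense-engine DP state."""
    from .traceback_align import build_alignment

    return build_alignment(state)
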