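"""Sparse recursion restricted to Optimal Pair Matchings (OPMs).

A couple (p_A, p_B) is an OPM when its matched score M[p_A, p_B] is at
least the *unrestricted* optimal alignment score of the one-column-
extended regions A[l(p_A)..r(p_A)] vs B[l(p_B)..r(p_B)] -- i.e. when no
alternative configuration that leaves the two pairs unmatched beats
matching them.  By the triangular-inequality argument, chains of the
loop recursion only ever need matched couples that are OPMs, so the
engine maintains an online OPM list and restricts every chain match to
it (whole-pair deletion transitions remain available to bridge between
anchors).

Further devices keep the work near O(z(n^2 + l^2)):

* a constant-time hairpin upper bound gates the (expensive) hairpin
  loop alignment: when the chain case already exceeds the bound, the
  hairpin case cannot win and is skipped; the same bound gates the
  break-everything candidate of the detection windows;
* loop alignments inside chains are evaluated lazily under the same
  kind of optimistic bound (branch-and-bound; exact maxima preserved);
* online pruning tombstones an enclosed OPM as soon as an enclosing OPM
  dominates it by more than the upper-bounded gain any future context
  could recover by re-splitting (the flanking-region bounds U_l, U_r).

Scores are exactly those of the dense engine; the sparsification is
lossless.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from ._core import Problem
from .dp_full import DPState, full_align
from .scoring import NEG, ScoringScheme, hairpin_bound_centi
from .structio import BasePair, StructuredRNA

Couple = tuple[int, int]


@dataclass
class OPM:
    """One detected optimal pair matching with its bookkeeping."""

    idx_a: int
    idx_b: int
    pair_a: BasePair
    pair_b: BasePair
    score_centi: int
    m_bar_centi: int
    alive: bool = True
    #: the couple whose detection tombstoned this OPM (indices), if any.
    #: A dead OPM is skipped only by contexts in which its dominator is
    #: itself usable as a chain anchor; in contexts that share a pair
    #: with the dominator (where the dominating path does not exist)
    #: the tombstoned OPM still participates, which keeps the
    #: sparsification exactly lossless.
    pruned_by: tuple[int, int] | None = None

    @property
    def score(self) -> float:
        return self.score_centi / 100.0

    @property
    def m_bar(self) -> float:
        return self.m_bar_centi / 100.0


@dataclass
class OPMList:
    """Ordered candidate list, modified online; tombstoned, never shrunk."""

    entries: list[OPM] = field(default_factory=list)

    def insert(self, opm: OPM) -> None:
        self.entries.append(opm)

    def alive(self) -> list[OPM]:
        return [o for o in self.entries if o.alive]

    @property
    def z(self) -> int:
        return sum(1 for o in self.entries if o.alive)


@dataclass
class SparseStats:
    """Run accounting.  ``z_peak`` counts every OPM ever detected (the
    size the list would reach without pruning), so
    ``z_final = z_peak - opms_pruned`` holds by construction."""

    z_final: int = 0
    z_peak: int = 0
    opms_pruned: int = 0
    mh_cells_computed: int = 0
    mh_cells_skipped: int = 0
    loop_alignments_computed: int = 0
    wall_time: float = 0.0


@dataclass
class SparseState(DPState):
    """DPState plus the sparse engine's detection/pruning records."""

    m_bar: dict[Couple, int] = field(default_factory=dict)
    mh_bound: dict[Couple, int] = field(default_factory=dict)
    mh_skipped: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# sparse chain: head-state recursion with OPM-restricted anchors
# ---------------------------------------------------------------------------


def _chain_sparse(
    state: SparseState,
    prob: Problem,
    bounds: tuple[int, int, int, int],
    heads: tuple[list[int], list[int]],
    anchors: list[Couple],
    store_key: Couple | None,
) -> tuple[int, Couple | None]:
    """Best chain inside ``bounds`` matching only ``anchors``.

    Identical state recursion as the dense engine (chain states are
    head couples, with whole-pair deletion transitions), except that the
    match cases are restricted to the given OPM anchors, and loop
    alignments are evaluated lazily under constant-time optimistic
    bounds: a candidate whose bound cannot beat the incumbent is
    skipped, which leaves the maximum and the stored backpointers
    unchanged while avoiding most long alignments.

    ``bounds`` = (lo_a, hi_a, lo_b, hi_b): leading regions start at lo,
    trailing regions end at hi.  Returns the best chain value including
    the trailing alignment (without any structural term for the
    enclosing couple) and the final state.
    """
    la, ra, lb, rb = prob.la, prob.ra, prob.lb, prob.rb
    lo_a, hi_a, lo_b, hi_b = bounds
    M = state.M
    heads_a, heads_b = heads
    anchor_set = set(anchors)
    if not anchor_set:
        if store_key is not None:
            state.chain_bp[store_key] = {}
        return NEG, None
    bb = prob.bounds_valid  # O(1) optimistic loop bounds admissible
    gap = prob.gap
    # With several anchors, one forward and one reverse Gotoh matrix
    # serve every chain opening (window start .. head left ends) and
    # closing (head right ends .. window end) at O(1) lookup each; for
    # one or two anchors the individual regions are cheaper directly.
    use_matrix = len(anchor_set) >= 3
    if use_matrix:
        wx = prob.A.seq[lo_a - 1 : hi_a] if lo_a <= hi_a else ""
        wy = prob.B.seq[lo_b - 1 : hi_b] if lo_b <= hi_b else ""
        lead = prob.window_matrix(wx, wy, False)
        trail = prob.window_matrix(wx[::-1], wy[::-1], True)
    states = [(u, v) for u in heads_a for v in heads_b]
    states.sort(key=lambda s: (ra[s[0]], rb[s[1]]))
    mc: dict[Couple, int] = {}
    bp: dict[Couple, tuple] = {}
    for u, v in states:
        best = NEG
        rec: tuple | None = None
        fu = [x for x in prob.F_a[u] if la[x] >= lo_a]
        fv = [y for y in prob.F_b[v] if lb[y] >= lo_b]
        if (u, v) in anchor_set:
            m_uv = M[(u, v)]
            # start case: everything left of (u, v) aligned against the
            # window opening
            if use_matrix:
                best = m_uv + int(lead[la[u] - lo_a][lb[v] - lo_b])
            else:
                best = m_uv + prob.sseq(lo_a, la[u] - 1, lo_b, lb[v] - 1)
            rec = ("start",)
            for x in fu:
                for y in fv:
                    pred = mc.get((x, y))
                    if pred is None:
                        continue
                    base = pred + m_uv
                    if bb and base + prob.sseq_bound(
                        ra[x] + 1, la[u] - 1, rb[y] + 1, lb[v] - 1
                    ) <= best:
                        continue
                    val = base + prob.sseq(
                        ra[x] + 1, la[u] - 1, rb[y] + 1, lb[v] - 1
                    )
                    if val > best:
                        best, rec = val, ("ext", x, y)
        # whole-pair deletions extend any reachable state
        for y in fv:
            pred = mc.get((u, y))
            if pred is not None:
                val = pred + gap(rb[v] - rb[y])
                if val > best:
                    best, rec = val, ("delB", y)
        for x in fu:
            pred = mc.get((x, v))
            if pred is not None:
                val = pred + gap(ra[u] - ra[x])
                if val > best:
                    best, rec = val, ("delA", x)
        if rec is not None:
            mc[(u, v)] = best
            bp[(u, v)] = rec
    if store_key is not None:
        state.chain_bp[store_key] = bp
    best_val, best_state = NEG, None
    for key in mc:
        u, v = key
        if use_matrix:
            tail = int(trail[hi_a - ra[u]][hi_b - rb[v]])
        else:
            base = mc[key]
            if bb and base + prob.sseq_bound(
                ra[u] + 1, hi_a, rb[v] + 1, hi_b
            ) <= best_val:
                continue
            tail = prob.sseq(ra[u] + 1, hi_a, rb[v] + 1, hi_b)
        val = mc[key] + tail
        if val > best_val:
            best_val, best_state = val, key
    return best_val, best_state


# ---------------------------------------------------------------------------
# OPM detection, bounds, pruning
# ---------------------------------------------------------------------------


def detect_opm(p_a: BasePair, p_b: BasePair, m_value: float, m_bar_value: float) -> bool:
    """A couple is an OPM iff its matched score reaches the unrestricted
    score of the extended regions (non-strict, as the boundary case
    means matching is at least as good as every alternative)."""
    del p_a, p_b  # the criterion depends on the two scores only
    return m_value >= m_bar_value


def compute_m_bar(
    A: StructuredRNA,
    B: StructuredRNA,
    sch: ScoringScheme,
    p_a: BasePair,
    p_b: BasePair,
) -> float:
    """Unrestricted optimal alignment score of A[l..r] vs B[l'..r'].

    Realised by aligning the two sub-structures spanned by the pairs
    under a pseudo pair at the top (structural score 0), with the dense
    recursion.  Extending a pair's span by one column on each side and
    closing it with a zero-scoring pseudo pair is exactly this quantity,
    clamped at the sequence ends.
    """
    from .structio import make_structure

    def sub(s: StructuredRNA, p: BasePair) -> StructuredRNA:
        lo, hi = p.left, p.right
        shifted = [
            (q.left - lo + 1, q.right - lo + 1)
            for q in s.pairs
            if lo <= q.left and q.right <= hi
        ]
        return make_structure(f"{s.id}[{lo}:{hi}]", s.seq[lo - 1 : hi], shifted)

    score, _ = full_align(sub(A, p_a), sub(B, p_b), sch)
    return score


def _prune_bounds_centi(
    prob: Problem, inner: Couple, outer: Couple
) -> tuple[int, int]:
    la, ra, lb, rb = prob.la, prob.ra, prob.lb, prob.rb
    xi, yi = inner
    oi, oj = outer
    r_gain = max(0, prob.sch.r_max_centi)
    d_gain = max(0, prob.sch.d_max_centi - prob.sch.open_centi - prob.sch.extend_centi)

    def side(lo_out, lo_in, hi_in, hi_out, lefts, rights):
        # beta flank [l(outer), l(inner)-1], delta flank [r(inner)+1, r(outer)]:
        # full lengths (the outer pair's own nucleotides are freed when it is
        # broken in a re-split, so they must be covered by the bound), and
        # pair counts by the endpoint inside the flank (exactly the pairs
        # that can newly match within the extended region).
        len_b = lo_in - lo_out
        len_d = hi_out - hi_in
        m_b = sum(1 for k in range(len(lefts)) if lo_out <= rights[k] < lo_in)
        m_d = sum(1 for k in range(len(lefts)) if hi_in < lefts[k] <= hi_out)
        return len_b, m_b, len_d, m_d

    lbA, mbA, ldA, mdA = side(la[oi], la[xi], ra[xi], ra[oi], la[: prob.nA], ra[: prob.nA])
    lbB, mbB, ldB, mdB = side(lb[oj], lb[yi], rb[yi], rb[oj], lb[: prob.nB], rb[: prob.nB])
    u_l = max(mbA, mbB) * r_gain + max(lbA, lbB) * d_gain
    u_r = max(mdA, mdB) * r_gain + max(ldA, ldB) * d_gain
    return u_l, u_r


def prune_bounds(
    o_inner: OPM,
    o_outer: OPM,
    structs: tuple[StructuredRNA, StructuredRNA],
    sch: ScoringScheme,
) -> tuple[float, float]:
    """Upper bounds (U_l, U_r) on what any future context could gain by
    re-splitting at the inner OPM instead of the outer one.

    The beta (left) and delta (right) gaps are the loop regions between
    the outer and inner pairs; each bound allows every pair annotated
    inside the gap to match at r_max and every gap nucleotide to turn
    into a d_max match while refunding one gap open+extend.
    """
    A, B = structs
    pa_in, pb_in = o_inner.pair_a, o_inner.pair_b
    pa_out, pb_out = o_outer.pair_a, o_outer.pair_b
    if not (
        pa_out.left < pa_in.left
        and pa_in.right < pa_out.right
        and pb_out.left < pb_in.left
        and pb_in.right < pb_out.right
    ):
        raise ValueError("inner OPM must be enclosed by the outer OPM on both sides")
    prob = Problem(A, B, sch)

    def idx(s, p):
        return next(
            i for i, q in enumerate(s.pairs) if (q.left, q.right) == (p.left, p.right)
        )

    u_l, u_r = _prune_bounds_centi(
        prob,
        (idx(A, pa_in), idx(B, pb_in)),
        (idx(A, pa_out), idx(B, pb_out)),
    )
    return u_l / 100.0, u_r / 100.0


def _prune(prob: Problem, opms: OPMList, o_new: OPM) -> int:
    """Tombstone every alive OPM enclosed by ``o_new`` that it dominates
    beyond the re-splitting bounds.  Returns the removal count."""
    la, ra, lb, rb = prob.la, prob.ra, prob.lb, prob.rb
    i, j = o_new.idx_a, o_new.idx_b
    removed = 0
    for o in opms.entries:
        if not o.alive:
            continue
        x, y = o.idx_a, o.idx_b
        if not (la[i] < la[x] and ra[x] < ra[i] and lb[j] < lb[y] and rb[y] < rb[j]):
            continue
        u_l, u_r = _prune_bounds_centi(prob, (x, y), (i, j))
        if o_new.score_centi - o.score_centi >= u_l + u_r:
            o.alive = False
            o.pruned_by = (i, j)
            removed += 1
    return removed


def prune_obsolete(
    opms: OPMList,
    o_new: OPM,
    structs: tuple[StructuredRNA, StructuredRNA],
    sch: ScoringScheme,
) -> int:
    """Public wrapper over the online pruning step."""
    A, B = structs
    return _prune(Problem(A, B, sch), opms, o_new)


def mh_gate(
    p_a: BasePair,
    p_b: BasePair,
    ml_value: float,
    sch: ScoringScheme,
    structs: tuple[StructuredRNA, StructuredRNA],
) -> str:
    """Decide whether the hairpin case must be evaluated for a couple.

    Skipping is sound because the bound dominates Mh; when the chain
    case does not exceed the bound (or no chain exists) the hairpin case
    must be computed.
    """
    if ml_value is None:
        return "compute_Mh"
    bound = hairpin_bound_centi(p_a, p_b, sch, structs)
    if round(ml_value * 100) > bound:
        return "skip_Mh"
    return "compute_Mh"


# ---------------------------------------------------------------------------
# main engine
# ---------------------------------------------------------------------------


def sparse_align(
    A: StructuredRNA,
    B: StructuredRNA,
    sch: ScoringScheme | None = None,
    prune: bool = True,
    use_mh_gate: bool = True,
) -> tuple[float, SparseState, OPMList, SparseStats]:
    """Optimal structure alignment by the OPM-restricted recursion.

    Returns the score (equal to :func:`arcalign.dp_full.full_align`),
    the DP state (traceback-capable), the final OPM list (tombstones
    included) and the run statistics.
    """
    sch = sch or ScoringScheme.default()
    t0 = time.perf_counter()
    prob = Problem(A, B, sch)
    state = SparseState(problem=prob, engine="sparse")
    opms = OPMList()
    stats = SparseStats()
    la, ra, lb, rb = prob.la, prob.ra, prob.lb, prob.rb
    structs = (A, B)

    def anchors_for(p: int, q: int, strict: bool) -> list[Couple]:
        """OPM anchors eligible in the window of (p, q).

        Tombstoned OPMs are skipped only when their dominating OPM is
        itself eligible here; the dominating path then subsumes them
        (in windows sharing a pair with the dominator that path does
        not exist, so the tombstoned OPM must stay available)."""
        out = []
        for o in opms.entries:
            x, y = o.idx_a, o.idx_b
            if strict:
                if not (
                    la[p] < la[x] and ra[x] < ra[p] and lb[q] < lb[y] and rb[y] < rb[q]
                ):
                    continue
            elif not (
                la[p] <= la[x] and ra[x] <= ra[p] and lb[q] <= lb[y] and rb[y] <= rb[q]
            ):
                continue
            if not o.alive:
                d_a, d_b = o.pruned_by
                if strict:
                    dom_ok = (
                        la[p] < la[d_a]
                        and ra[d_a] < ra[p]
                        and lb[q] < lb[d_b]
                        and rb[d_b] < rb[q]
                    )
                else:
                    dom_ok = (
                        la[p] <= la[d_a]
                        and ra[d_a] <= ra[p]
                        and lb[q] <= lb[d_b]
                        and rb[d_b] <= rb[q]
                    )
                if dom_ok:
                    continue
            out.append((x, y))
        return out

    for p, q in prob.couples():
        anchors = anchors_for(p, q, strict=True)
        chain_val, final = _chain_sparse(
            state,
            prob,
            (la[p] + 1, ra[p] - 1, lb[q] + 1, rb[q] - 1),
            (prob.encA[p], prob.encB[q]),
            anchors,
            store_key=(p, q),
        )
        sstr = prob.sstr(p, q)
        ml = chain_val + sstr if chain_val > NEG else NEG
        key = (p, q)
        state.Ml[key] = ml
        if final is not None:
            state.bp_Ml[key] = final
        bound = hairpin_bound_centi(A.pairs[p], B.pairs[q], sch, structs)
        state.mh_bound[key] = bound
        if use_mh_gate and ml > NEG and ml > bound:
            stats.mh_cells_skipped += 1
            state.mh_skipped.add(key)
            state.M[key], state.bp_M[key] = ml, "l"
        else:
            stats.mh_cells_computed += 1
            mh = sstr + prob.sseq(la[p] + 1, ra[p] - 1, lb[q] + 1, rb[q] - 1)
            state.Mh[key] = mh
            if mh >= ml:
                state.M[key], state.bp_M[key] = mh, "h"
            else:
                state.M[key], state.bp_M[key] = ml, "l"
        # -- OPM detection on the one-column-extended regions ------------
        # The engine's m_bar is the best alignment of the extended
        # window that does NOT match (p, q): chains over already-known
        # OPMs (which may match p or q to other partners) or breaking
        # everything into sequence.  The couple is an OPM only when
        # matching it is strictly better -- a tied couple is redundant,
        # since its equal-scoring alternative decomposes into strictly
        # smaller couples (well-founded), so skipping ties is lossless
        # and is what keeps the candidate list far below n^2.  The full
        # unrestricted extended-window score is max(M, m_bar).
        mbar_anchors = anchors_for(p, q, strict=False)
        mbar_chain, _ = _chain_sparse(
            state,
            prob,
            (la[p], ra[p], lb[q], rb[q]),
            (prob.encA[p] + [p], prob.encB[q] + [q]),
            mbar_anchors,
            store_key=None,
        )
        # hairpin-style gate for the break-everything candidate of the
        # extended window (S_str = 0 for the pseudo pair): when the OPM
        # chain already exceeds the bound, the full-span alignment
        # cannot win and need not be computed.
        len_a = ra[p] - la[p] + 1
        len_b = rb[q] - lb[q] + 1
        pseudo_bound = min(len_a, len_b) * sch.d_max_centi + abs(len_a - len_b) * sch.extend_centi
        if len_a != len_b:
            pseudo_bound += sch.open_centi
        if use_mh_gate and mbar_chain > pseudo_bound:
            m_bar = mbar_chain
        else:
            m_bar = max(prob.sseq(la[p], ra[p], lb[q], rb[q]), mbar_chain)
        state.m_bar[key] = m_bar
        if state.M[key] > m_bar:
            o = OPM(
                idx_a=p,
                idx_b=q,
                pair_a=A.pairs[p],
                pair_b=B.pairs[q],
                score_centi=state.M[key],
                m_bar_centi=m_bar,
            )
            opms.insert(o)
            stats.z_peak += 1
            if prune:
                stats.opms_pruned += _prune(prob, opms, o)
    # -- root ------------------------------------------------------------
    rp, rq = prob.ROOT_A, prob.ROOT_B
    anchors = anchors_for(rp, rq, strict=True)
    chain_val, final = _chain_sparse(
        state,
        prob,
        (1, A.length, 1, B.length),
        (prob.encA[rp], prob.encB[rq]),
        anchors,
        store_key=(rp, rq),
    )
    key = (rp, rq)
    state.Ml[key] = chain_val
    if final is not None:
        state.bp_Ml[key] = final
    mh = prob.sseq(1, A.length, 1, B.length)
    state.Mh[key] = mh
    stats.mh_cells_computed += 1
    if mh >= chain_val:
        state.M[key], state.bp_M[key] = mh, "h"
    else:
        state.M[key], state.bp_M[key] = chain_val, "l"
    stats.z_final = opms.z
    stats.loop_alignments_computed = prob.loop_alignments_computed
    stats.wall_time = time.perf_counter() - t0
    return state.score, state, opms, stats


def trace_sparse(state: SparseState):
    """Recover the full alignment from a sparse-engine DP state."""
    from .traceback_align import build_alignment

    return build_alignment(state)
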