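"""Exhaustive reference aligner for small instances.

Enumerates every order-consistent one-to-one matching between the two
base-pair sets and scores each matching directly from the model
definition: structural terms over the matched couples, affine-gap
sequence similarity over the loop partition the matching induces, and
whole-span deletion penalties for unmatched pairs skipped between
consecutive matched chain members (connection paths follow the
directly-before relation).  The maximum over all matchings is the
optimal alignment score.

This evaluator never touches the DP tables of the engines; it is the
ground-truth oracle used to certify them on instances with a handful of
pairs (the matching count grows factorially).
"""

from __future__ import annotations

from .scoring import NEG, ScoringScheme, gotoh_centi
from .structio import StructuredRNA


class _Side:
    """Per-structure geometry used by the matching evaluator."""

    def __init__(self, s: StructuredRNA):
        self.seq = s.seq
        self.n = len(s.pairs)
        self.l = [p.left for p in s.pairs]
        self.r = [p.right for p in s.pairs]
        self.F = s.F_of
        self.length = s.length

    def region(self, lo: int, hi: int) -> str:
        if lo > hi:
            return ""
        return self.seq[lo - 1 : hi]


def _relation(l1: int, r1: int, l2: int, r2: int) -> str:
    if l1 < l2 and r2 < r1:
        return "contains"
    if l2 < l1 and r1 < r2:
        return "inside"
    if r1 < l2:
        return "before"
    if r2 < l1:
        return "after"
    return "crossing"


def enumerate_matchings(A: StructuredRNA, B: StructuredRNA):
    """Yield every order-consistent injective matching as a list of
    (index_in_A, index_in_B) couples (the empty matching included)."""
    la = [p.left for p in A.pairs]
    ra = [p.right for p in A.pairs]
    lb = [p.left for p in B.pairs]
    rb = [p.right for p in B.pairs]
    nA, nB = len(A.pairs), len(B.pairs)

    def consistent(m: list[tuple[int, int]], i: int, j: int) -> bool:
        for i0, j0 in m:
            rel_a = _relation(la[i0], ra[i0], la[i], ra[i])
            rel_b = _relation(lb[j0], rb[j0], lb[j], rb[j])
            if rel_a != rel_b or rel_a == "crossing":
                return False
        return True

    def rec(i: int, used: set[int], m: list[tuple[int, int]]):
        if i == nA:
            yield list(m)
            return
        yield from rec(i + 1, used, m)  # leave pair i unmatched
        for j in range(nB):
            if j in used or not consistent(m, i, j):
                continue
            m.append((i, j))
            used.add(j)
            yield from rec(i + 1, used, m)
            m.pop()
            used.remove(j)

    yield from rec(0, set(), [])


def _gap_paths(
    side: _Side, sch: ScoringScheme, matched: set[int], u: int
) -> dict[int, int]:
    """Best deletion-path cost from matched head ``u`` to every reachable
    last head (including ``u`` itself at cost 0).  Paths hop through
    unmatched heads via the directly-before relation, deleting each full
    span at the affine region penalty."""
    results: dict[int, int] = {u: 0}
    stack = [u]
    while stack:
        cur = stack.pop()
        for w in range(side.n):
            if w in matched or cur not in side.F[w]:
                continue
            c = results[cur] + sch.gap_centi(side.r[w] - side.r[cur])
            if w not in results or c > results[w]:
                results[w] = c
                stack.append(w)
    return results


def score_matching(
    A: StructuredRNA,
    B: StructuredRNA,
    sch: ScoringScheme,
    matching: list[tuple[int, int]],
) -> int:
    """Model score (centi-units) of one fixed matching; NEG when the
    matching is not representable by the chaining recursion."""
    sa, sb = _Side(A), _Side(B)
    matched_a = {i for i, _ in matching}
    matched_b = {j for _, j in matching}

    def sseq(alo, ahi, blo, bhi):
        return gotoh_centi(sa.region(alo, ahi), sb.region(blo, bhi), sch)

    # consensus tree: parent = innermost enclosing matched couple
    def parent_of(ci: int) -> int | None:
        i, _ = matching[ci]
        best, best_span = None, None
        for cj, (i2, _) in enumerate(matching):
            if cj != ci and sa.l[i2] < sa.l[i] and sa.r[i] < sa.r[i2]:
                span = sa.r[i2] - sa.l[i2]
                if best_span is None or span < best_span:
                    best, best_span = cj, span
        return best

    children: dict[int | None, list[int]] = {None: []}
    for ci in range(len(matching)):
        children[ci] = []
    for ci in range(len(matching)):
        children[parent_of(ci)].append(ci)
    for k in children:
        children[k].sort(key=lambda ci: sa.l[matching[ci][0]])

    structure = sum(
        sch.pair_centi(A.dinucleotide(A.pairs[i]), B.dinucleotide(B.pairs[j]))
        for i, j in matching
    )

    def transition(u_a: int, u_b: int, v_a: int, v_b: int) -> int:
        paths_a = _gap_paths(sa, sch, matched_a, u_a)
        paths_b = _gap_paths(sb, sch, matched_b, u_b)
        best = NEG
        for xa, cost_a in paths_a.items():
            if xa not in sa.F[v_a]:
                continue
            for xb, cost_b in paths_b.items():
                if xb not in sb.F[v_b]:
                    continue
                v = cost_a + cost_b + sseq(
                    sa.r[xa] + 1, sa.l[v_a] - 1, sb.r[xb] + 1, sb.l[v_b] - 1
                )
                best = max(best, v)
        return best

    def trailing(u_a: int, u_b: int, hi_a: int, hi_b: int) -> int:
        paths_a = _gap_paths(sa, sch, matched_a, u_a)
        paths_b = _gap_paths(sb, sch, matched_b, u_b)
        best = NEG
        for xa, cost_a in paths_a.items():
            if sa.r[xa] > hi_a:
                continue
            for xb, cost_b in paths_b.items():
                if sb.r[xb] > hi_b:
                    continue
                v = cost_a + cost_b + sseq(sa.r[xa] + 1, hi_a, sb.r[xb] + 1, hi_b)
                best = max(best, v)
        return best

    def interior_score(couple: int | None) -> int:
        if couple is None:
            lo_a, hi_a, lo_b, hi_b = 1, sa.length, 1, sb.length
        else:
            i, j = matching[couple]
            lo_a, hi_a = sa.l[i] + 1, sa.r[i] - 1
            lo_b, hi_b = sb.l[j] + 1, sb.r[j] - 1
        kids = children[couple]
        if not kids:
            return sseq(lo_a, hi_a, lo_b, hi_b)
        total = 0
        first_a, first_b = matching[kids[0]]
        total += sseq(lo_a, sa.l[first_a] - 1, lo_b, sb.l[first_b] - 1)
        for t in range(len(kids) - 1):
            ua, ub = matching[kids[t]]
            va, vb = matching[kids[t + 1]]
            tr = transition(ua, ub, va, vb)
            if tr <= NEG:
                return NEG
            total += tr
        for k in kids:
            sub = interior_score(k)
            if sub <= NEG:
                return NEG
            total += sub
        last_a, last_b = matching[kids[-1]]
        tail = trailing(last_a, last_b, hi_a, hi_b)
        if tail <= NEG:
            return NEG
        total += tail
        return total

    interior = interior_score(None)
    if interior <= NEG:
        return NEG
    return structure + interior


def brute_force_align(
    A: StructuredRNA, B: StructuredRNA, sch: ScoringScheme | None = None
) -> float:
    """Optimal score by exhaustive matching enumeration (small n only)."""
    sch = sch or ScoringScheme.default()
    best = NEG
    for m in enumerate_matchings(A, B):
        v = score_matching(A, B, sch, m)
        if v > best:
            best = v
    return best / 100.0
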