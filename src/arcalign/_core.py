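"""Shared indexed representation used by both alignment engines.

Pairs of each structure are addressed by their index in the
right-endpoint-sorted pair list; the pseudo-root is appended at index
``n`` with coordinates (0, l+1).  Loop-similarity scores (affine-gap
alignments of sequence regions, in centi-units) are memoised by region
coordinates, so each distinct region combination is aligned once per
problem.
"""

from __future__ import annotations

from .scoring import NEG, ScoringScheme, gotoh_best_matrix, gotoh_centi
from .structio import StructuredRNA


class Problem:
    """Indexed view of an alignment instance (A, B, scoring scheme)."""

    def __init__(self, A: StructuredRNA, B: StructuredRNA, sch: ScoringScheme):
        self.A, self.B, self.sch = A, B, sch
        self.nA, self.nB = len(A.pairs), len(B.pairs)
        self.la = [p.left for p in A.pairs] + [0]
        self.ra = [p.right for p in A.pairs] + [A.length + 1]
        self.lb = [p.left for p in B.pairs] + [0]
        self.rb = [p.right for p in B.pairs] + [B.length + 1]
        self.ROOT_A, self.ROOT_B = self.nA, self.nB
        self.dinuc_a = [A.dinucleotide(p) for p in A.pairs]
        self.dinuc_b = [B.dinucleotide(p) for p in B.pairs]
        self.F_a = A.F_of
        self.F_b = B.F_of
        # pairs strictly enclosed by each pair index (root encloses all)
        self.encA = [
            [j for j in range(self.nA) if self.la[i] < self.la[j] and self.ra[j] < self.ra[i]]
            for i in range(self.nA)
        ] + [list(range(self.nA))]
        self.encB = [
            [j for j in range(self.nB) if self.lb[i] < self.lb[j] and self.rb[j] < self.rb[i]]
            for i in range(self.nB)
        ] + [list(range(self.nB))]
        self._sseq_cache: dict[tuple[int, int, int, int], int] = {}
        if len(sch._content_cache) > 400_000:
            sch._content_cache.clear()
        self._content_cache = sch._content_cache
        self.loop_alignments_computed = 0
        # d_max >= 0 is required for the O(1) optimistic loop bound
        self.bounds_valid = sch.d_max_centi >= 0

    # -- scoring ---------------------------------------------------------

    def sstr(self, i: int, j: int) -> int:
        """w1-weighted structural score of matching pair i of A with j of B."""
        if i == self.ROOT_A or j == self.ROOT_B:
            return 0  # pseudo vs pseudo
        return self.sch.pair_centi(self.dinuc_a[i], self.dinuc_b[j])

    def sseq(self, alo: int, ahi: int, blo: int, bhi: int) -> int:
        """Affine-gap alignment score of A[alo..ahi] vs B[blo..bhi] (centi)."""
        if alo > ahi:
            alo, ahi = 1, 0
        if blo > bhi:
            blo, bhi = 1, 0
        key = (alo, ahi, blo, bhi)
        hit = self._sseq_cache.get(key)
        if hit is not None:
            return hit
        x = self.A.seq[alo - 1 : ahi]
        y = self.B.seq[blo - 1 : bhi]
        ckey = (x, y)
        val = self._content_cache.get(ckey)
        if val is None:
            val = gotoh_centi(x, y, self.sch)
            self._content_cache[ckey] = val
            self.loop_alignments_computed += 1
        self._sseq_cache[key] = val
        return val

    def sseq_bound(self, alo: int, ahi: int, blo: int, bhi: int) -> int:
        """Constant-time upper bound on :meth:`sseq` (requires d_max >= 0):
        every aligned couple at d_max, one gap run for the length excess."""
        len_a = max(0, ahi - alo + 1)
        len_b = max(0, bhi - blo + 1)
        if len_a == len_b:
            return len_a * self.sch.d_max_centi
        bound = min(len_a, len_b) * self.sch.d_max_centi
        return bound + self.sch.open_centi + abs(len_a - len_b) * self.sch.extend_centi

    def gap(self, length: int) -> int:
        return self.sch.gap_centi(length)

    def window_matrix(self, x: str, y: str, reverse: bool):
        """Gotoh prefix matrix of a window (pass reversed strings for a
        suffix matrix).  Thin wrapper kept for counting."""
        del reverse
        self.loop_alignments_computed += 1
        return gotoh_best_matrix(x, y, self.sch)

    # -- geometry --------------------------------------------------------

    def inside_a(self, x: int, p: int) -> bool:
        """Pair x strictly enclosed by pair p (both A indices; p may be root)."""
        return self.la[p] < self.la[x] and self.ra[x] < self.ra[p]

    def inside_b(self, y: int, q: int) -> bool:
        return self.lb[q] < self.lb[y] and self.rb[y] < self.rb[q]

    def couples(self) -> list[tuple[int, int]]:
        """All real pair couples in processing order (lexicographic by
        right endpoints), which guarantees every enclosed couple is
        computed before any context that refers to it."""
        cs = [(i, j) for i in range(self.nA) for j in range(self.nB)]
        cs.sort(key=lambda c: (self.ra[c[0]], self.rb[c[1]]))
        return cs
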