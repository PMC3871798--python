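"""Scoring model for general edit-distance structure alignment.

The overall alignment score combines a structural term and a sequence
term::

    M = w1 * sum R(p_A, p_B)  +  w2 * sum S_seq(loop_A, loop_B)

where ``R`` is a 16x16 base-pair substitution table indexed by
dinucleotides, and ``S_seq`` is a global affine-gap sequence alignment
over the unpaired loop regions induced by the base-pair matching, with
nucleotide table ``D``, gap-open ``g`` and gap-extend ``e`` (both
negative, ``g < e``).  A gap run of length ``k`` costs ``g + k*e``, so
fully deleting a region of length ``k`` costs exactly the region
deletion penalty ``G(k)``.  Base-pair deletion/insertion itself is free:
mis-predicted pairs should be breakable without structural penalty.

All effective score atoms (``w1*R``, ``w2*D``, ``w2*g``, ``w2*e``) are
quantised to integer centi-units (0.01 precision) when a scheme is
built.  Every dynamic program then works in exact integer arithmetic,
which makes score equalities between engines and tracebacks exact
rather than float-tolerant.  Public functions report plain floats.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from ._ribosum import (
    NUCLEOTIDE_ORDER,
    RIBOSUM85_60_NUC,
    RIBOSUM85_60_PAIR,
)
from .structio import BasePair, StructuredRNA

NEG = -(10**15)  # -infinity sentinel for integer DPs

#: marker for a pseudo base pair (zero structural score)
PSEUDO = "pseudo"
#: marker for a deleted/inserted base pair (no structural penalty)
DELETED = "deleted"

_ALPHABET = "ACGUN"
_INDEX = {c: i for i, c in enumerate(_ALPHABET)}


class ScoringError(ValueError):
    pass


def _centi(x: float) -> int:
    return int(round(100.0 * x))


@dataclass
class ScoringScheme:
    """Base-pair table R, nucleotide table D, affine gaps and weights.

    ``R`` maps dinucleotide tuples (over ACGU) to scores, ``D`` maps
    nucleotide tuples.  Both must be symmetric.  ``w1 > w2 > 0`` weights
    structure over sequence; ``g < e < 0`` are the affine gap open and
    extend penalties.  ``r_max``/``d_max`` are the (unweighted) table
    maxima, cached for the hairpin and pruning upper bounds.

    Scores against ``N`` take the minimum of the relevant table row
    (conservative treatment of unknown nucleotides).
    """

    R: Mapping[tuple[str, str], float]
    D: Mapping[tuple[str, str], float]
    g: float = -3.0
    e: float = -1.0
    w1: float = 4.0
    w2: float = 1.0
    name: str = "custom"

    # effective (weighted, centi-quantised) tables, built in __post_init__
    _pair_centi: dict[tuple[str, str], int] = field(repr=False, default_factory=dict)
    _nuc_centi: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (self.g < self.e < 0):
            raise ScoringError("gap parameters must satisfy g < e < 0")
        if not (self.w1 > self.w2 > 0):
            raise ScoringError("weights must satisfy w1 > w2 > 0")
        for (a, b), v in self.R.items():
            if abs(self.R[(b, a)] - v) > 1e-9:
                raise ScoringError(f"R is not symmetric at ({a},{b})")
        for (a, b), v in self.D.items():
            if abs(self.D[(b, a)] - v) > 1e-9:
                raise ScoringError(f"D is not symmetric at ({a},{b})")
        self._rebuild()

    # -- effective tables ------------------------------------------------

    def _rebuild(self) -> None:
        self._pair_centi = {
            (x, y): _centi(self.w1 * v) for (x, y), v in self.R.items()
        }
        nuc = np.full((5, 5), NEG, dtype=np.int64)
        for a in NUCLEOTIDE_ORDER:
            for b in NUCLEOTIDE_ORDER:
                nuc[_INDEX[a], _INDEX[b]] = _centi(self.w2 * self.D[(a, b)])
        # N scores as the row minimum (and the global minimum for N vs N)
        for a in NUCLEOTIDE_ORDER:
            row_min = min(nuc[_INDEX[a], _INDEX[b]] for b in NUCLEOTIDE_ORDER)
            nuc[_INDEX[a], 4] = row_min
            nuc[4, _INDEX[a]] = row_min
        nuc[4, 4] = min(
            nuc[_INDEX[a], _INDEX[b]]
            for a in NUCLEOTIDE_ORDER
            for b in NUCLEOTIDE_ORDER
        )
        self._nuc_centi = nuc
        self._nuc_py = [[int(v) for v in row] for row in nuc]
        self._gap_open_centi = _centi(self.w2 * self.g)
        self._gap_extend_centi = _centi(self.w2 * self.e)
        # content-keyed memo of loop alignment scores, shared by every
        # problem built over this scheme (schemes are immutable in use)
        self._content_cache: dict[tuple[str, str], int] = {}
        self._r_max_centi = max(self._pair_centi.values())
        self._d_max_centi = int(
            max(
                self._nuc_centi[_INDEX[a], _INDEX[b]]
                for a in NUCLEOTIDE_ORDER
                for b in NUCLEOTIDE_ORDER
            )
        )

    @property
    def r_max(self) -> float:
        """Maximum entry of R (unweighted)."""
        return max(self.R.values())

    @property
    def d_max(self) -> float:
        """Maximum entry of D (unweighted)."""
        return max(self.D.values())

    # -- integer (centi) primitives used by the engines ------------------

    def pair_centi(self, dinuc_a: str, dinuc_b: str) -> int:
        """w1-weighted base-pair substitution score in centi-units."""
        key = (dinuc_a, dinuc_b)
        if key in self._pair_centi:
            return self._pair_centi[key]
        # expand N against the minimum over completions (conservative)
        candidates = [
            self._pair_centi[(x, y)]
            for x in _expand_dinuc(dinuc_a)
            for y in _expand_dinuc(dinuc_b)
        ]
        return min(candidates)

    def nuc_centi(self, a: str, b: str) -> int:
        try:
            return int(self._nuc_centi[_INDEX[a], _INDEX[b]])
        except KeyError:
            raise ScoringError(f"nucleotide outside ACGUN: {a!r}/{b!r}") from None

    def gap_centi(self, length: int) -> int:
        """Region deletion penalty G in centi-units: 0 if empty, else w2*(g+len*e)."""
        if length < 0:
            raise ScoringError("negative region length")
        if length == 0:
            return 0
        return self._gap_open_centi + length * self._gap_extend_centi

    @property
    def open_centi(self) -> int:
        return self._gap_open_centi

    @property
    def extend_centi(self) -> int:
        return self._gap_extend_centi

    @property
    def r_max_centi(self) -> int:
        return self._r_max_centi

    @property
    def d_max_centi(self) -> int:
        return self._d_max_centi

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.fromiter((_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
        except KeyError as exc:
            raise ScoringError(f"nucleotide outside ACGUN in {seq!r}") from exc

    # -- config IO -------------------------------------------------------

    @classmethod
    def default(cls) -> "ScoringScheme":
        """RIBOSUM85-60 tables with strongly structure-dominant weights.

        w1 = 4*w2 and moderate affine penalties (g=-3, e=-1) are chosen
        so that every canonical pair's diagonal score satisfies
        ``w1*R[x,x] >= 2*w2*(d_max - g - e)``: an enclosing stacked
        pair then always dominates the one it stacks on by more than
        the re-splitting bound, which is the regime in which the online
        candidate pruning actually collapses helices to single
        candidates.
        """
        return cls(
            R=RIBOSUM85_60_PAIR_TUPLES,
            D=RIBOSUM85_60_NUC,
            g=-3.0,
            e=-1.0,
            w1=4.0,
            w2=1.0,
            name="ribosum85_60",
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ScoringScheme":
        """Load a scheme from a YAML config.

        Keys: ``matrices`` ("ribosum85_60" or inline ``R``/``D`` mappings
        keyed by e.g. "GC/GC" and "A/C"), ``g``, ``e``, ``w1``, ``w2``.
        Missing keys fall back to the defaults.
        """
        cfg = yaml.safe_load(text) or {}
        base = cls.default()
        R, D, name = dict(base.R), dict(base.D), "ribosum85_60"
        matrices = cfg.get("matrices", "ribosum85_60")
        if isinstance(matrices, dict):
            name = "inline"
            if "R" in matrices:
                R = _parse_inline(matrices["R"], width=2)
            if "D" in matrices:
                D = _parse_inline(matrices["D"], width=1)
        elif matrices != "ribosum85_60":
            raise ScoringError(f"unknown matrix set {matrices!r}")
        return cls(
            R=R,
            D=D,
            g=float(cfg.get("g", base.g)),
            e=float(cfg.get("e", base.e)),
            w1=float(cfg.get("w1", base.w1)),
            w2=float(cfg.get("w2", base.w2)),
            name=name,
        )

    def dump(self) -> str:
        """Human-readable dump of the effective (weighted) scheme."""
        buf = io.StringIO()
        buf.write(
            f"scheme {self.name}: w1={self.w1} w2={self.w2} g={self.g} e={self.e}\n"
        )
        buf.write(f"r_max={self.r_max} d_max={self.d_max}\n")
        buf.write("effective w2*D (centi-units):\n")
        for a in NUCLEOTIDE_ORDER:
            row = " ".join(
                f"{int(self._nuc_centi[_INDEX[a], _INDEX[b]]):6d}"
                for b in NUCLEOTIDE_ORDER
            )
            buf.write(f"  {a} {row}\n")
        return buf.getvalue()


def _expand_dinuc(d: str) -> list[str]:
    if len(d) != 2 or any(c not in _ALPHABET for c in d):
        raise ScoringError(f"not a dinucleotide over ACGUN: {d!r}")
    opts = [c if c != "N" else NUCLEOTIDE_ORDER for c in d]
    return [a + b for a in opts[0] for b in opts[1]]


def _tuplify(table: Mapping[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    return dict(table)


RIBOSUM85_60_PAIR_TUPLES = _tuplify(RIBOSUM85_60_PAIR)


def _parse_inline(raw: Mapping[str, float], width: int) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for key, v in raw.items():
        a, b = key.split("/")
        if len(a) != width or len(b) != width:
            raise ScoringError(f"bad matrix key {key!r}")
        out[(a, b)] = float(v)
        out[(b, a)] = float(v)
    return out


def simple_scheme(
    match: float = 2.0,
    mismatch: float = -1.0,
    pair_scores: Mapping[tuple[str, str], float] | None = None,
    pair_default: float = 0.0,
    g: float = -5.0,
    e: float = -1.0,
    w1: float = 1.0000001,
    w2: float = 1.0,
) -> ScoringScheme:
    """Small hand-specified scheme, mainly for worked examples and tests.

    ``w1`` defaults to barely above ``w2`` so that effectively-unit
    weights satisfy the w1 > w2 constraint while centi-quantisation
    keeps the structural scores at their face value.
    """
    D = {
        (a, b): (match if a == b else mismatch)
        for a in NUCLEOTIDE_ORDER
        for b in NUCLEOTIDE_ORDER
    }
    R: dict[tuple[str, str], float] = {}
    dinucs = [a + b for a in NUCLEOTIDE_ORDER for b in NUCLEOTIDE_ORDER]
    for x in dinucs:
        for y in dinucs:
            R[(x, y)] = pair_default
    if pair_scores:
        for (x, y), v in pair_scores.items():
            R[(x, y)] = v
            R[(y, x)] = v
    return ScoringScheme(R=R, D=D, g=g, e=e, w1=w1, w2=w2, name="simple")


# ---------------------------------------------------------------------------
# public scoring operations (float-valued wrappers over centi primitives)
# ---------------------------------------------------------------------------


def basepair_score(pair_a: str, pair_b: str, sch: ScoringScheme) -> float:
    """Structural similarity term, already weighted by w1.

    Arguments are real dinucleotides, :data:`PSEUDO`, or :data:`DELETED`.
    Pseudo vs pseudo scores 0 (void interactions); any deletion or
    insertion scores 0 (mis-predicted pairs must be breakable for free).
    """
    if pair_a == DELETED or pair_b == DELETED:
        return 0.0
    if pair_a == PSEUDO or pair_b == PSEUDO:
        if pair_a == PSEUDO and pair_b == PSEUDO:
            return 0.0
        raise ScoringError("a pseudo pair can only be scored against a pseudo pair")
    return sch.pair_centi(pair_a, pair_b) / 100.0


def region_deletion_penalty(length: int, sch: ScoringScheme) -> float:
    """G(|L|), already weighted by w2: 0 for empty regions, else w2*(g+|L|*e)."""
    return sch.gap_centi(length) / 100.0


# ---------------------------------------------------------------------------
# affine-gap loop alignment (Gotoh three-state recursion)
# ---------------------------------------------------------------------------


def gotoh_centi(x: str, y: str, sch: ScoringScheme) -> int:
    """Optimal global affine-gap alignment score of two loop regions, centi-units.

    Gap runs cost g + k*e per run (w2-weighted); substitutions use w2*D.
    """
    a, b = len(x), len(y)
    if a == 0 or b == 0:
        if a == 0 and b == 0:
            return 0
        return sch.gap_centi(max(a, b))
    if a * b > 2048:
        return _gotoh_numpy(x, y, sch)
    return _gotoh_python(x, y, sch)


def _gotoh_python(x: str, y: str, sch: ScoringScheme) -> int:
    # NEG is far below any reachable score, so invalid states propagate
    # harmlessly without explicit guards (exact integer arithmetic).
    a, b = len(x), len(y)
    go, ge = sch.open_centi, sch.extend_centi
    oc = go + ge
    nuc = sch._nuc_py
    idx = _INDEX
    ye = [idx[c] for c in y]
    prevM = [NEG] * (b + 1)
    prevE = [NEG] * (b + 1)
    prevF = [NEG] * (b + 1)
    prevM[0] = 0
    for j in range(1, b + 1):
        prevE[j] = go + j * ge
    rng = range(1, b + 1)
    for i in range(1, a + 1):
        sub = nuc[idx[x[i - 1]]]
        curM = [NEG] * (b + 1)
        curE = [NEG] * (b + 1)
        curF = [NEG] * (b + 1)
        curF[0] = go + i * ge
        eprev = NEG
        mprev = NEG
        fprev = curF[0]
        for j in rng:
            pm = prevM[j - 1]
            pe = prevE[j - 1]
            pf = prevF[j - 1]
            d = pm if pm >= pe else pe
            if pf > d:
                d = pf
            m = d + sub[ye[j - 1]]
            curM[j] = m
            pm = prevM[j]
            pe = prevE[j]
            up = pm if pm >= pe else pe
            f = up + oc
            f2 = prevF[j] + ge
            if f2 > f:
                f = f2
            curF[j] = f
            left = mprev if mprev >= fprev else fprev
            e = left + oc
            e2 = eprev + ge
            if e2 > e:
                e = e2
            curE[j] = e
            eprev, mprev, fprev = e, m, f
        prevM, prevE, prevF = curM, curE, curF
    return max(prevM[b], prevE[b], prevF[b])


def _gotoh_numpy(x: str, y: str, sch: ScoringScheme) -> int:
    a, b = len(x), len(y)
    go = np.int64(sch.open_centi)
    ge = np.int64(sch.extend_centi)
    xe = sch.encode(x)
    ye = sch.encode(y)
    sub = sch._nuc_centi[np.ix_(xe, ye)]  # (a, b)
    ks = np.arange(b + 1, dtype=np.int64)
    M = np.full(b + 1, NEG, dtype=np.int64)
    E = np.full(b + 1, NEG, dtype=np.int64)
    F = np.full(b + 1, NEG, dtype=np.int64)
    M[0] = 0
    E[1:] = go + ks[1:] * ge
    for i in range(1, a + 1):
        best_prev = np.maximum(np.maximum(M, E), F)
        newM = np.full(b + 1, NEG, dtype=np.int64)
        newM[1:] = best_prev[:-1] + sub[i - 1]
        newF = np.maximum(np.maximum(M, E) + go + ge, F + ge)
        # E[j] = max_{k<j} max(newM,newF)[k] + g + (j-k)*e
        mf = np.maximum(newM, newF)
        t = np.maximum.accumulate(mf - ks * ge)
        newE = np.full(b + 1, NEG, dtype=np.int64)
        newE[1:] = go + ks[1:] * ge + t[:-1]
        M, E, F = newM, newE, newF
    return int(max(M[b], E[b], F[b]))


def gotoh_best_matrix(x: str, y: str, sch: ScoringScheme) -> np.ndarray:
    """Full Gotoh prefix matrix: entry [i, j] is the optimal affine-gap
    alignment score (centi) of x[:i] vs y[:j].

    One matrix serves every prefix combination of a region pair, which
    is how the sparse engine scores all chain openings of a window in a
    single pass (and, reversed, all closings).
    """
    a, b = len(x), len(y)
    if (a + 1) * (b + 1) <= 1024:
        return _gotoh_matrix_python(x, y, sch)
    go = np.int64(sch.open_centi)
    ge = np.int64(sch.extend_centi)
    out = np.empty((a + 1, b + 1), dtype=np.int64)
    ks = np.arange(b + 1, dtype=np.int64)
    M = np.full(b + 1, NEG, dtype=np.int64)
    E = np.full(b + 1, NEG, dtype=np.int64)
    F = np.full(b + 1, NEG, dtype=np.int64)
    M[0] = 0
    if b:
        E[1:] = go + ks[1:] * ge
    out[0] = np.maximum(np.maximum(M, E), F)
    out[0, 0] = 0
    if a == 0:
        return out
    xe = sch.encode(x)
    if b == 0:
        out[1:, 0] = go + np.arange(1, a + 1, dtype=np.int64) * ge
        return out
    ye = sch.encode(y)
    sub = sch._nuc_centi[np.ix_(xe, ye)]
    for i in range(1, a + 1):
        best_prev = np.maximum(np.maximum(M, E), F)
        best_prev[0] = max(M[0], F[0])  # no E state at j=0
        newM = np.full(b + 1, NEG, dtype=np.int64)
        newM[1:] = best_prev[:-1] + sub[i - 1]
        newF = np.maximum(np.maximum(M, E) + go + ge, F + ge)
        newF[0] = go + i * ge
        mf = np.maximum(newM, newF)
        t = np.maximum.accumulate(mf - ks * ge)
        newE = np.full(b + 1, NEG, dtype=np.int64)
        newE[1:] = go + ks[1:] * ge + t[:-1]
        M, E, F = newM, newE, newF
        out[i] = np.maximum(np.maximum(M, E), F)
    return out


def _gotoh_matrix_python(x: str, y: str, sch: ScoringScheme):
    """Scalar twin of :func:`gotoh_best_matrix` for small windows,
    where per-row numpy dispatch overhead dominates."""
    a, b = len(x), len(y)
    go, ge = sch.open_centi, sch.extend_centi
    oc = go + ge
    nuc = sch._nuc_py
    idx = _INDEX
    ye = [idx[c] for c in y]
    M = [NEG] * (b + 1)
    E = [NEG] * (b + 1)
    F = [NEG] * (b + 1)
    M[0] = 0
    for j in range(1, b + 1):
        E[j] = go + j * ge
    out = [[0] + E[1:]]
    rng = range(1, b + 1)
    for i in range(1, a + 1):
        sub = nuc[idx[x[i - 1]]]
        curM = [NEG] * (b + 1)
        curE = [NEG] * (b + 1)
        curF = [NEG] * (b + 1)
        curF[0] = go + i * ge
        eprev, mprev, fprev = NEG, NEG, curF[0]
        row = [curF[0]] + [NEG] * b
        for j in rng:
            pm = M[j - 1]
            pe = E[j - 1]
            pf = F[j - 1]
            d = pm if pm >= pe else pe
            if pf > d:
                d = pf
            m = d + sub[ye[j - 1]]
            curM[j] = m
            pm = M[j]
            pe = E[j]
            up = pm if pm >= pe else pe
            f = up + oc
            f2 = F[j] + ge
            if f2 > f:
                f = f2
            curF[j] = f
            left = mprev if mprev >= fprev else fprev
            e = left + oc
            e2 = eprev + ge
            if e2 > e:
                e = e2
            curE[j] = e
            eprev, mprev, fprev = e, m, f
            best = m if m >= e else e
            if f > best:
                best = f
            row[j] = best
        out.append(row)
        M, E, F = curM, curE, curF
    return out


def gotoh_traceback_centi(x: str, y: str, sch: ScoringScheme) -> tuple[int, str, str]:
    """Affine alignment with traceback; returns (centi score, gapped x, gapped y).

    Tie-breaking is deterministic: diagonal, then gap-in-y, then gap-in-x;
    gap extensions are preferred over fresh opens.
    """
    a, b = len(x), len(y)
    if a == 0 and b == 0:
        return 0, "", ""
    if a == 0:
        return sch.gap_centi(b), "-" * b, y
    if b == 0:
        return sch.gap_centi(a), x, "-" * a
    go, ge = sch.open_centi, sch.extend_centi
    open_cost = go + ge
    nuc = sch.nuc_centi
    M = [[NEG] * (b + 1) for _ in range(a + 1)]
    E = [[NEG] * (b + 1) for _ in range(a + 1)]
    F = [[NEG] * (b + 1) for _ in range(a + 1)]
    # pointers: for M the source state; for E/F whether extended and source
    ptrM = [[None] * (b + 1) for _ in range(a + 1)]
    ptrE = [[None] * (b + 1) for _ in range(a + 1)]
    ptrF = [[None] * (b + 1) for _ in range(a + 1)]
    M[0][0] = 0
    for j in range(1, b + 1):
        E[0][j] = go + j * ge
        ptrE[0][j] = "E" if j > 1 else "M"
    for i in range(1, a + 1):
        F[i][0] = go + i * ge
        ptrF[i][0] = "F" if i > 1 else "M"
        for j in range(1, b + 1):
            best_state, best_val = None, NEG
            for st, val in (("M", M[i - 1][j - 1]), ("E", E[i - 1][j - 1]), ("F", F[i - 1][j - 1])):
                if val > best_val:
                    best_state, best_val = st, val
            if best_val > NEG:
                M[i][j] = best_val + nuc(x[i - 1], y[j - 1])
                ptrM[i][j] = best_state
            # F: gap in y, consumes x[i-1]
            cand = []
            if F[i - 1][j] > NEG:
                cand.append(("F", F[i - 1][j] + ge))
            for st, val in (("M", M[i - 1][j]), ("E", E[i - 1][j])):
                if val > NEG:
                    cand.append((st, val + open_cost))
            if cand:
                st, val = max(cand, key=lambda t: t[1])
                F[i][j], ptrF[i][j] = val, st
            # E: gap in x, consumes y[j-1]
            cand = []
            if E[i][j - 1] > NEG:
                cand.append(("E", E[i][j - 1] + ge))
            for st, val in (("M", M[i][j - 1]), ("F", F[i][j - 1])):
                if val > NEG:
                    cand.append((st, val + open_cost))
            if cand:
                st, val = max(cand, key=lambda t: t[1])
                E[i][j], ptrE[i][j] = val, st
    end = max((("M", M[a][b]), ("E", E[a][b]), ("F", F[a][b])), key=lambda t: t[1])
    state, score = end
    gx: list[str] = []
    gy: list[str] = []
    i, j = a, b
    while i > 0 or j > 0:
        if state == "M":
            gx.append(x[i - 1])
            gy.append(y[j - 1])
            state = ptrM[i][j]
            i, j = i - 1, j - 1
        elif state == "E":
            gx.append("-")
            gy.append(y[j - 1])
            state = ptrE[i][j]
            j -= 1
        else:
            gx.append(x[i - 1])
            gy.append("-")
            state = ptrF[i][j]
            i -= 1
    return score, "".join(reversed(gx)), "".join(reversed(gy))


def align_loops_affine(
    region_a: str,
    region_b: str,
    sch: ScoringScheme,
    traceback: bool = False,
):
    """S_seq: optimal global affine-gap alignment of two loop regions.

    Returns the w2-weighted score (float), or ``(score, gapped_a,
    gapped_b)`` when ``traceback`` is requested.  Either region may be
    empty; deleting a whole region of length k costs exactly G(k).
    """
    if traceback:
        sc, ga, gb = gotoh_traceback_centi(region_a, region_b, sch)
        return sc / 100.0, ga, gb
    return gotoh_centi(region_a, region_b, sch) / 100.0


# ---------------------------------------------------------------------------
# hairpin upper bound
# ---------------------------------------------------------------------------


def hairpin_bound_centi(
    p_a: BasePair, p_b: BasePair, sch: ScoringScheme, structs: tuple[StructuredRNA, StructuredRNA]
) -> int:
    if p_a.is_pseudo or p_b.is_pseudo:
        raise ScoringError("hairpin bound is only defined for real base pairs")
    A, B = structs
    la = p_a.right - p_a.left - 1
    lb = p_b.right - p_b.left - 1
    s_str = sch.pair_centi(A.dinucleotide(p_a), B.dinucleotide(p_b))
    diff = abs(la - lb)
    bound = s_str + min(la, lb) * sch.d_max_centi + diff * sch.extend_centi
    if diff:
        bound += sch.open_centi
    return bound


def hairpin_upper_bound(
    p_a: BasePair,
    p_b: BasePair,
    sch: ScoringScheme,
    structs: tuple[StructuredRNA, StructuredRNA],
) -> float:
    """Constant-time upper bound on the hairpin case score of a pair couple.

    Assumes the maximum possible number of nucleotide matches (each at
    d_max) and the minimum number of gaps (a single run covering the
    loop-length difference).  Valid whenever d_max >= 0, which holds for
    the default tables; the hairpin case is then provably never better
    than this bound.
    """
    return hairpin_bound_centi(p_a, p_b, sch, structs) / 100.0
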