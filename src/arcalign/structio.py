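"""Parsing, validation and modelling of fixed RNA secondary structures.

A fixed secondary structure is a single non-crossing set of base pairs
annotated on a nucleotide sequence.  Pairs are kept in the partial order
used throughout the alignment recursions: sorted by increasing right
endpoint.  On top of the raw pair set this module precomputes

* ``parent_of`` -- for each pair, the innermost enclosing pair (or the
  pseudo-root spanning the whole molecule), i.e. the structure tree;
* ``F_of`` -- for each pair ``p``, the set of pairs that are *directly
  before and juxtaposed to* ``p``: every ``q`` with ``r(q) < l(p)`` such
  that no pair lies entirely between ``q`` and ``p``.  This set is what
  the chaining recursion of the aligners walks through, and it may
  contain pairs at different nesting depths (a chain may dive through a
  broken enclosing pair).

Coordinates are 1-based and inclusive at every public interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Sequence

NUCLEOTIDES = "ACGUN"


class StructureError(ValueError):
    """Raised for malformed or inconsistent structure input."""


class Relation(Enum):
    """Mutual arrangement of two non-crossing base pairs."""

    I_ENCLOSES_J = "i_encloses_j"
    J_ENCLOSES_I = "j_encloses_i"
    I_BEFORE_J = "i_before_j"
    J_BEFORE_I = "j_before_i"


@dataclass(frozen=True)
class BasePair:
    """A base pair (l, r), 1-based inclusive, l < r.

    Pseudo pairs carry zero structural score and exist only as region
    bookkeeping (the root and one-column-extended spans); they never
    appear in an output matching.
    """

    left: int
    right: int
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise StructureError(
                f"base pair ({self.left},{self.right}) must satisfy left < right"
            )

    def span(self) -> int:
        return self.right - self.left + 1

    def __repr__(self) -> str:  # compact, used in error messages
        tag = "~" if self.is_pseudo else ""
        return f"{tag}({self.left},{self.right})"


@dataclass(frozen=True)
class Region:
    """A contiguous 1-based inclusive sequence region; empty iff start > end."""

    start: int
    end: int

    def __len__(self) -> int:
        return max(0, self.end - self.start + 1)

    def extract(self, seq: str) -> str:
        if len(self) == 0:
            return ""
        return seq[self.start - 1 : self.end]


@dataclass
class StructuredRNA:
    """A nucleotide sequence with one fixed, non-crossing base-pair set.

    ``pairs`` is sorted by increasing right endpoint; ``parent_of[i]`` is
    the index of the innermost enclosing pair of ``pairs[i]`` (or -1 for
    the pseudo-root) and ``F_of[i]`` lists indices of the directly-before
    juxtaposed pairs of ``pairs[i]``.
    """

    id: str
    seq: str
    pairs: list[BasePair] = field(default_factory=list)
    parent_of: list[int] = field(default_factory=list)
    F_of: list[list[int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def root(self) -> BasePair:
        """Pseudo-root (0, l+1), strictly enclosing every position."""
        return BasePair(0, self.length + 1, is_pseudo=True)

    def dinucleotide(self, pair: BasePair) -> str:
        return self.seq[pair.left - 1] + self.seq[pair.right - 1]

    def children_of(self, idx: int) -> list[int]:
        """Direct children (in the structure tree) of pair index ``idx`` (-1 = root)."""
        return [i for i, par in enumerate(self.parent_of) if par == idx]

    def enclosed_by(self, idx: int) -> list[int]:
        """All pair indices strictly enclosed by pair index ``idx`` (-1 = root)."""
        if idx == -1:
            return list(range(len(self.pairs)))
        p = self.pairs[idx]
        return [
            i
            for i, q in enumerate(self.pairs)
            if p.left < q.left and q.right < p.right
        ]

    def to_vienna(self) -> str:
        """Serialise back to a FASTA-like dot-bracket record."""
        db = ["."] * self.length
        for p in self.pairs:
            db[p.left - 1] = "("
            db[p.right - 1] = ")"
        return f">{self.id}\n{self.seq}\n{''.join(db)}\n"

    def to_bpseq(self) -> str:
        partner = [0] * (self.length + 1)
        for p in self.pairs:
            partner[p.left] = p.right
            partner[p.right] = p.left
        lines = [
            f"{i} {self.seq[i - 1]} {partner[i]}" for i in range(1, self.length + 1)
        ]
        return "\n".join(lines) + "\n"


def _validate_sequence(seq: str) -> None:
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise StructureError(
            f"sequence contains characters outside {{A,C,G,U,N}}: {sorted(bad)}"
        )


def classify_relation(p_i: BasePair, p_j: BasePair) -> Relation:
    """Classify two distinct pairs as nested or juxtaposed.

    Crossing pairs violate the fixed-structure invariant and raise
    :class:`StructureError`.
    """
    if (p_i.left, p_i.right) == (p_j.left, p_j.right):
        raise StructureError(f"identical pairs {p_i} passed to classify_relation")
    if p_j.left < p_i.left and p_i.right < p_j.right:
        return Relation.J_ENCLOSES_I
    if p_i.left < p_j.left and p_j.right < p_i.right:
        return Relation.I_ENCLOSES_J
    if p_i.right < p_j.left:
        return Relation.I_BEFORE_J
    if p_j.right < p_i.left:
        return Relation.J_BEFORE_I
    raise StructureError(f"pairs {p_i} and {p_j} cross: structure is corrupted")


def _check_pairs(seq_len: int, pairs: Sequence[BasePair]) -> None:
    seen: dict[int, BasePair] = {}
    for p in pairs:
        if p.left < 1 or p.right > seq_len:
            raise StructureError(f"pair {p} outside sequence of length {seq_len}")
        for pos in (p.left, p.right):
            if pos in seen:
                raise StructureError(
                    f"position {pos} occurs in both {seen[pos]} and {p}"
                )
            seen[pos] = p
    ordered = sorted(pairs, key=lambda q: q.left)
    stack: list[BasePair] = []
    for p in ordered:
        while stack and stack[-1].right < p.left:
            stack.pop()
        if stack and not (p.right < stack[-1].right):
            raise StructureError(f"pairs {stack[-1]} and {p} cross")
        stack.append(p)


def build_relations(s: StructuredRNA) -> StructuredRNA:
    """Fill ``parent_of`` and ``F_of`` for a validated pair set (in place).

    ``parent_of[i]`` is the innermost enclosing pair (else -1, the
    pseudo-root).  ``F_of[i]`` contains every pair ``q`` with
    ``r(q) < l(p_i)`` such that no pair ``k`` satisfies ``q <J k <J p_i``,
    i.e. the directly-before juxtaposed predecessors of ``p_i``.
    """
    pairs = s.pairs
    n = len(pairs)
    parent = [-1] * n
    for i, p in enumerate(pairs):
        best = -1
        best_span = None
        for j, q in enumerate(pairs):
            if q.left < p.left and p.right < q.right:
                if best_span is None or q.span() < best_span:
                    best, best_span = j, q.span()
        parent[i] = best
    f_of: list[list[int]] = []
    for i, p in enumerate(pairs):
        members: list[int] = []
        for j, q in enumerate(pairs):
            if not q.right < p.left:
                continue
            blocked = any(
                q.right < k.left and k.right < p.left for k in pairs
            )
            if not blocked:
                members.append(j)
        f_of.append(sorted(members, key=lambda j: pairs[j].right))
    s.parent_of = parent
    s.F_of = f_of
    return s


def make_structure(
    id: str, seq: str, pairs: Iterable[tuple[int, int]]
) -> StructuredRNA:
    """Build and fully validate a StructuredRNA from raw (l, r) tuples."""
    _validate_sequence(seq)
    pair_objs = sorted(
        (BasePair(l, r) for l, r in pairs), key=lambda p: p.right
    )
    _check_pairs(len(seq), pair_objs)
    s = StructuredRNA(id=id, seq=seq, pairs=pair_objs)
    return build_relations(s)


def parse_vienna(text: str) -> StructuredRNA:
    """Parse a FASTA-like record with a dot-bracket structure line.

    Accepted characters in the structure line are ``.``, ``(`` and ``)``;
    extended bracket dialects (pseudoknots) are rejected, as fixed
    structures are non-crossing by definition.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty input")
    if lines[0].startswith(">"):
        name = lines[0][1:].split()[0] if len(lines[0]) > 1 else "unnamed"
        lines = lines[1:]
    else:
        name = "unnamed"
    if len(lines) < 2:
        raise StructureError("expected a sequence line and a structure line")
    seq = lines[0].upper().replace("T", "U")
    db = lines[1]
    _validate_sequence(seq)
    if len(db) != len(seq):
        raise StructureError(
            f"structure length {len(db)} does not match sequence length {len(seq)}"
        )
    bad = set(db) - set(".()")
    if bad:
        raise StructureError(
            f"structure line contains unsupported characters {sorted(bad)}; "
            "only '.', '(' and ')' are accepted"
        )
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[0]}")
    return make_structure(name, seq, pairs)


def parse_bpseq(text: str) -> StructuredRNA:
    """Parse bpseq (``index base partner`` per line, 1-based, 0 = unpaired)."""
    seq_chars: list[str] = []
    partner: list[int] = []
    for ln in text.strip().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        fields = ln.split()
        if len(fields) != 3:
            raise StructureError(f"malformed bpseq line: {ln!r}")
        idx, base, mate = int(fields[0]), fields[1].upper(), int(fields[2])
        if idx != len(seq_chars) + 1:
            raise StructureError(f"non-consecutive bpseq index {idx}")
        seq_chars.append(base.replace("T", "U"))
        partner.append(mate)
    pairs = []
    for i, j in enumerate(partner, start=1):
        if j == 0:
            continue
        if j < 1 or j > len(partner):
            raise StructureError(f"bpseq partner {j} out of range at position {i}")
        if partner[j - 1] != i:
            raise StructureError(f"bpseq pairing of {i} and {j} is not reciprocal")
        if i < j:
            pairs.append((i, j))
    return make_structure("bpseq", "".join(seq_chars), pairs)


def loop_region(
    s: StructuredRNA,
    kind: str,
    p_i: BasePair,
    p_j: BasePair | None = None,
) -> Region:
    """Loop regions delimited by base pairs.

    kind='hairpin':        interior of p_i, [l(p_i)+1, r(p_i)-1]
    kind='left_internal':  requires p_i nested in p_j, [l(p_j)+1, l(p_i)-1]
    kind='right_internal': requires p_i nested in p_j, [r(p_i)+1, r(p_j)-1]
    kind='between':        requires p_i before p_j,    [r(p_i)+1, l(p_j)-1]

    Empty regions (start > end) are legitimate.
    """
    if kind == "hairpin":
        return Region(p_i.left + 1, p_i.right - 1)
    if p_j is None:
        raise StructureError(f"loop kind {kind!r} requires a second pair")
    if kind in ("left_internal", "right_internal"):
        if not (p_j.left < p_i.left and p_i.right < p_j.right):
            raise StructureError(f"{p_i} is not enclosed by {p_j}")
        if kind == "left_internal":
            return Region(p_j.left + 1, p_i.left - 1)
        return Region(p_i.right + 1, p_j.right - 1)
    if kind == "between":
        if not p_i.right < p_j.left:
            raise StructureError(f"{p_i} is not juxtaposed before {p_j}")
        return Region(p_i.right + 1, p_j.left - 1)
    raise StructureError(f"unknown loop kind {kind!r}")


def write_stockholm(result, out: IO[str]) -> None:
    """Write an AlignmentResult as Stockholm 1.0.

    Each sequence row is followed by a ``#=GR <name> SS`` line annotating
    matched pairs as brackets; broken pairs render as dots (their
    interaction was dissolved and the nucleotides align as loop residues).
    """
    rows = result.rows()
    out.write("# STOCKHOLM 1.0\n")
    if rows:
        width = max(len(name) for name, _, _ in rows) + 10
        for name, gapped, ss in rows:
            if len(gapped) != len(ss):
                raise RuntimeError("gapped sequence and structure annotation differ")
            out.write(f"{name:<{width}}{gapped}\n")
            out.write(f"{'#=GR ' + name + ' SS':<{width}}{ss}\n")
    out.write("//\n")
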