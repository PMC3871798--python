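"""Seeded generation of fixed RNA structures and homologs.

The generator emulates the statistics the aligners are designed around:
helices (stacked base-pair runs) whose outer span follows a power law
P(span) ~ span^(-c) with c > 1 -- the polymer-zeta regime, under which
the number of retained pair-matching candidates grows near-linearly in
the pair count.  Paired positions draw canonical dinucleotides
(GC/CG/AU/UA/GU/UG); loop positions are uniform over ACGU.

Homologs are derived by compensatory substitutions at paired sites,
point substitutions in loops, loop-restricted indels (the structure
skeleton is preserved) and optional pair breaking.  A single integer
seed drives each operation end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import StructuredRNA, make_structure

CANONICAL_PAIRS = ("GC", "CG", "AU", "UA", "GU", "UG")
LOOP_BASES = "ACGU"


class GenerationError(RuntimeError):
    pass


@dataclass
class GenParams:
    """Knobs for one random structure draw.

    target_length: sequence length (nt); target_pairs: requested pair
    count (achieved within +-10% or generation fails); span_exponent:
    the polymer-zeta exponent c > 1 of the helix span distribution;
    helix_len_range: stacked-run length bounds; loop_len_range: minimum
    and typical hairpin interior bounds; seed: the run seed.
    """

    target_length: int = 100
    target_pairs: int = 20
    span_exponent: float = 1.5
    helix_len_range: tuple[int, int] = (2, 5)
    loop_len_range: tuple[int, int] = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_pairs * 2 > self.target_length:
            raise GenerationError("target_pairs*2 must not exceed target_length")
        if self.span_exponent <= 1.0:
            raise GenerationError("span_exponent must exceed 1 (polymer-zeta regime)")


@dataclass
class MutParams:
    """Per-event probabilities for homolog derivation (all in [0, 1])."""

    sub_rate: float = 0.15
    loop_indel_rate: float = 0.3
    pair_break_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.loop_indel_rate, self.pair_break_rate):
            if not 0.0 <= r <= 1.0:
                raise GenerationError("mutation rates must lie in [0, 1]")


def _crosses(l: int, r: int, pairs: list[tuple[int, int]]) -> bool:
    return any((a < l < b < r) or (l < a < r < b) for a, b in pairs)


def _sample_span(rng: np.random.Generator, lo: int, hi: int, c: float) -> int:
    spans = np.arange(lo, hi + 1, dtype=np.float64)
    w = spans ** (-c)
    return int(rng.choice(np.arange(lo, hi + 1), p=w / w.sum()))


def random_structure(p: GenParams) -> StructuredRNA:
    """Draw one valid non-crossing structure; identical seeds give
    byte-identical results.

    Helix spans are sampled from the configured power law up front and
    placed largest-first: long-span helices would otherwise be rejected
    by collisions far more often than short ones, which truncates the
    span tail and flattens the nesting depth that the polymer-zeta
    regime implies.  An unlucky draw (a giant helix blocking the rest)
    restarts from a derived stream; the whole procedure stays a pure
    function of the seed.
    """
    last: GenerationError | None = None
    for restart in range(12):
        try:
            return _random_structure_once(p, restart)
        except GenerationError as exc:
            last = exc
    raise last


def _random_structure_once(p: GenParams, restart: int) -> StructuredRNA:
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, restart]))
    L = p.target_length
    free = np.ones(L + 2, dtype=bool)  # 1-based
    pairs: list[tuple[int, int]] = []
    h_min, h_max = p.helix_len_range
    loop_min = p.loop_len_range[0]
    specs: list[tuple[int, int]] = []
    remaining = p.target_pairs
    while remaining > 0:
        h = min(int(rng.integers(h_min, h_max + 1)), remaining)
        span_lo = 2 * h + loop_min
        if span_lo > L:
            h = max(1, (L - loop_min) // 2)
            span_lo = 2 * h + loop_min
        specs.append((_sample_span(rng, span_lo, L, p.span_exponent), h))
        remaining -= h
    specs.sort(reverse=True)
    attempts = 0
    for s, h in specs:
        placed = False
        for _ in range(80):
            attempts += 1
            left = int(rng.integers(1, L - s + 2))
            helix = [(left + k, left + s - 1 - k) for k in range(h)]
            if all(
                free[a] and free[b] and not _crosses(a, b, pairs)
                for a, b in helix
            ):
                for a, b in helix:
                    free[a] = free[b] = False
                    pairs.append((a, b))
                placed = True
                break
        if not placed:
            # shrink the span and retry once more at a feasible scale
            for _ in range(80):
                attempts += 1
                s2 = _sample_span(rng, 2 * h + loop_min, max(2 * h + loop_min, s), p.span_exponent)
                left = int(rng.integers(1, L - s2 + 2))
                helix = [(left + k, left + s2 - 1 - k) for k in range(h)]
                if all(
                    free[a] and free[b] and not _crosses(a, b, pairs)
                    for a, b in helix
                ):
                    for a, b in helix:
                        free[a] = free[b] = False
                        pairs.append((a, b))
                    break
    if p.target_pairs and not (
        0.9 * p.target_pairs <= len(pairs) <= 1.1 * p.target_pairs
    ):
        raise GenerationError(
            f"could not place {p.target_pairs} pairs in length {L} "
            f"(got {len(pairs)} after {attempts} attempts)"
        )
    seq = [""] * (L + 1)
    for a, b in sorted(pairs):
        dinuc = CANONICAL_PAIRS[int(rng.integers(len(CANONICAL_PAIRS)))]
        seq[a], seq[b] = dinuc[0], dinuc[1]
    for i in range(1, L + 1):
        if not seq[i]:
            seq[i] = LOOP_BASES[int(rng.integers(4))]
    return make_structure(f"synth{p.seed}", "".join(seq[1:]), pairs)


def mutate_homolog(s: StructuredRNA, m: MutParams) -> StructuredRNA:
    """Derive a homolog: compensatory substitutions at kept pairs, point
    substitutions and short indels in loops, optional pair breaking."""
    rng = np.random.default_rng(m.seed)
    chars = list(s.seq)  # 0-based tokens
    kept_pairs = []
    for p in s.pairs:
        if rng.random() < m.pair_break_rate:
            continue
        kept_pairs.append((p.left, p.right))
    paired_pos = {pos for lp, rp in kept_pairs for pos in (lp, rp)}
    # substitutions: compensatory at paired sites, pointwise in loops
    for lp, rp in kept_pairs:
        if rng.random() < m.sub_rate:
            dinuc = CANONICAL_PAIRS[int(rng.integers(len(CANONICAL_PAIRS)))]
            chars[lp - 1], chars[rp - 1] = dinuc[0], dinuc[1]
    for pos in range(1, len(chars) + 1):
        if pos in paired_pos:
            continue
        if rng.random() < m.sub_rate:
            options = [b for b in LOOP_BASES if b != chars[pos - 1]]
            chars[pos - 1] = options[int(rng.integers(len(options)))]
    # loop indels: tokens tagged by original position; pairs follow tokens
    tokens: list[tuple[int, str]] = [(i + 1, c) for i, c in enumerate(chars)]
    loops: list[list[int]] = []
    run: list[int] = []
    for pos in range(1, len(chars) + 1):
        if pos in paired_pos:
            if run:
                loops.append(run)
                run = []
        else:
            run.append(pos)
    if run:
        loops.append(run)
    remove: set[int] = set()
    insert_after: dict[int, str] = {}
    for loop in loops:
        if rng.random() >= m.loop_indel_rate:
            continue
        if rng.random() < 0.5 and loop:
            k = int(rng.integers(1, min(2, len(loop)) + 1))
            start = int(rng.integers(0, len(loop) - k + 1))
            remove.update(loop[start : start + k])
        else:
            anchor = loop[int(rng.integers(0, len(loop)))]
            ins = "".join(
                LOOP_BASES[int(rng.integers(4))]
                for _ in range(int(rng.integers(1, 3)))
            )
            insert_after[anchor] = ins
    new_seq: list[str] = []
    new_pos: dict[int, int] = {}
    for orig, c in tokens:
        if orig in remove:
            continue
        new_seq.append(c)
        new_pos[orig] = len(new_seq)
        if orig in insert_after:
            new_seq.extend(insert_after[orig])
    new_pairs = [(new_pos[lp], new_pos[rp]) for lp, rp in kept_pairs]
    return make_structure(f"{s.id}_hom{m.seed}", "".join(new_seq), new_pairs)


def random_instance_pair(
    seed: int,
    target_length: int = 60,
    target_pairs: int = 12,
    span_exponent: float = 1.5,
    sub_rate: float = 0.15,
    loop_indel_rate: float = 0.3,
    pair_break_rate: float = 0.1,
) -> tuple[StructuredRNA, StructuredRNA]:
    """One reproducible test instance: a structure and a derived homolog.

    Component seeds are spawned from the single run seed.
    """
    ss = np.random.SeedSequence(seed)
    gen_seed, mut_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    A = random_structure(
        GenParams(
            target_length=target_length,
            target_pairs=target_pairs,
            span_exponent=span_exponent,
            seed=gen_seed,
        )
    )
    B = mutate_homolog(
        A,
        MutParams(
            sub_rate=sub_rate,
            loop_indel_rate=loop_indel_rate,
            pair_break_rate=pair_break_rate,
            seed=mut_seed,
        ),
    )
    return A, B


def mispredicted_hairpin_pair() -> tuple[StructuredRNA, StructuredRNA]:
    """Fixture: two hairpins identical except that the first carries an
    inserted U which led a structure predictor to call one extra inner
    pair.  The correct alignment breaks that pair and opens exactly one
    single-column gap for the U."""
    a = make_structure("extra_pair", "GGACAAGUCC", [(1, 10), (2, 9), (3, 8)])
    b = make_structure("plain", "GGACAAGCC", [(1, 9), (2, 8)])
    return a, b
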