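"""Default substitution tables (RIBOSUM85-60 style).

The 4x4 nucleotide matrix and the canonical base-pair block (AU, CG, GC,
GU, UA, UG against each other) carry the widely used RIBOSUM85-60 values
derived from rRNA alignment counts.  The remaining 16x16 entries --
every combination involving a non-canonical dinucleotide -- are a
synthetic completion set to a uniform strong penalty of -10.00, since
such pairs do not occur in canonical fixed structures but can appear in
user input after mutations.  Both tables are symmetric.
"""

from __future__ import annotations

NUCLEOTIDE_ORDER = "ACGU"

# Single-nucleotide substitution scores (symmetric, log-odds, RIBOSUM85-60).
RIBOSUM85_60_NUC: dict[tuple[str, str], float] = {}


def _fill_nuc() -> None:
    upper = {
        ("A", "A"): 2.22,
        ("A", "C"): -1.86,
        ("A", "G"): -1.46,
        ("A", "U"): -1.39,
        ("C", "C"): 1.16,
        ("C", "G"): -2.48,
        ("C", "U"): -1.05,
        ("G", "G"): 1.03,
        ("G", "U"): -1.74,
        ("U", "U"): 1.65,
    }
    for (a, b), v in upper.items():
        RIBOSUM85_60_NUC[(a, b)] = v
        RIBOSUM85_60_NUC[(b, a)] = v


_fill_nuc()

CANONICAL = ("AU", "CG", "GC", "GU", "UA", "UG")
NONCANONICAL_SCORE = -10.00

# Canonical base-pair substitution block (symmetric, RIBOSUM85-60).
_CANONICAL_BLOCK = {
    ("AU", "AU"): 4.49,
    ("AU", "CG"): 1.67,
    ("AU", "GC"): 2.70,
    ("AU", "GU"): 0.59,
    ("AU", "UA"): 1.61,
    ("AU", "UG"): -0.51,
    ("CG", "CG"): 5.36,
    ("CG", "GC"): 2.11,
    ("CG", "GU"): -0.27,
    ("CG", "UA"): 2.75,
    ("CG", "UG"): 1.32,
    ("GC", "GC"): 5.62,
    ("GC", "GU"): 1.21,
    ("GC", "UA"): 1.60,
    ("GC", "UG"): -0.08,
    ("GU", "GU"): 3.47,
    ("GU", "UA"): -0.57,
    ("GU", "UG"): -2.09,
    ("UA", "UA"): 4.97,
    ("UA", "UG"): -0.62,
    ("UG", "UG"): 3.36,
}

RIBOSUM85_60_PAIR: dict[tuple[str, str], float] = {}


def _fill_pair() -> None:
    dinucs = [a + b for a in NUCLEOTIDE_ORDER for b in NUCLEOTIDE_ORDER]
    for x in dinucs:
        for y in dinucs:
            RIBOSUM85_60_PAIR[(x, y)] = NONCANONICAL_SCORE
    for (x, y), v in _CANONICAL_BLOCK.items():
        RIBOSUM85_60_PAIR[(x, y)] = v
        RIBOSUM85_60_PAIR[(y, x)] = v


_fill_pair()
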