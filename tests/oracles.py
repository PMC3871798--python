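"""Shared independent oracles for the test suite."""

from __future__ import annotations

from arcalign.scoring import ScoringScheme


def enumerate_alignment_score(x: str, y: str, sch: ScoringScheme) -> int:
    """Best score over all global alignments of two short strings,
    enumerated as column sequences and scored from the definition:
    substitutions per aligned column, each maximal gap run costing
    g + len*e (centi-units)."""
    best = [None]

    def rec(i, j, score, gap_x, gap_y):
        if i == len(x) and j == len(y):
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < len(x) and j < len(y):
            rec(i + 1, j + 1, score + sch.nuc_centi(x[i], y[j]), 0, 0)
        if i < len(x):  # gap in y
            extra = sch.extend_centi + (0 if gap_y else sch.open_centi)
            rec(i + 1, j, score + extra, 0, 1)
        if j < len(y):  # gap in x
            extra = sch.extend_centi + (0 if gap_x else sch.open_centi)
            rec(i, j + 1, score + extra, 1, 0)

    rec(0, 0, 0, 0, 0)
    return best[0]
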