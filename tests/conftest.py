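"""Shared fixtures: scoring schemes and cached engine sweeps.

The medium-instance sweep (full engine plus all four sparse variants on
200 seeded homolog pairs) is computed once per session and shared by
the equivalence, pruning-audit and bound-validity tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest

from arcalign import full_align, random_instance_pair, simple_scheme, sparse_align
from arcalign.scoring import ScoringScheme

SUITE_SEEDS = range(200)
SUITE_LENGTH = 60
SUITE_PAIRS = 12


@pytest.fixture(scope="session")
def default_scheme() -> ScoringScheme:
    return ScoringScheme.default()


@pytest.fixture(scope="session")
def toy_scheme() -> ScoringScheme:
    """match +2 / mismatch -1, R[GC,GC]=5, R[GU,GU]=4, g=-5, e=-1."""
    return simple_scheme(
        match=2.0,
        mismatch=-1.0,
        pair_scores={("GC", "GC"): 5.0, ("GU", "GU"): 4.0},
        g=-5.0,
        e=-1.0,
    )


@dataclass
class SweepRecord:
    seed: int
    full_score: int
    sparse_scores: dict = field(default_factory=dict)  # (prune, gate) -> centi
    M_prune_on: dict = field(default_factory=dict)
    M_prune_off: dict = field(default_factory=dict)
    Mh_all: dict = field(default_factory=dict)  # gate-off run: every Mh
    mh_bound: dict = field(default_factory=dict)
    z_final: int = 0
    z_peak: int = 0
    opms_pruned: int = 0
    n_a: int = 0
    n_b: int = 0


@pytest.fixture(scope="session")
def medium_sweep(default_scheme) -> list[SweepRecord]:
    records = []
    for seed in SUITE_SEEDS:
        A, B = random_instance_pair(
            seed, target_length=SUITE_LENGTH, target_pairs=SUITE_PAIRS
        )
        _, full_state = full_align(A, B, default_scheme)
        rec = SweepRecord(
            seed=seed,
            full_score=full_state.score_centi,
            n_a=len(A.pairs),
            n_b=len(B.pairs),
        )
        for prune in (True, False):
            for gate in (True, False):
                _, st, opms, stats = sparse_align(
                    A, B, default_scheme, prune=prune, use_mh_gate=gate
                )
                rec.sparse_scores[(prune, gate)] = st.score_centi
                if (prune, gate) == (True, False):
                    rec.M_prune_on = dict(st.M)
                    rec.z_final = stats.z_final
                    rec.z_peak = stats.z_peak
                    rec.opms_pruned = stats.opms_pruned
                if (prune, gate) == (False, False):
                    rec.M_prune_off = dict(st.M)
                    rec.Mh_all = dict(st.Mh)
                    rec.mh_bound = dict(st.mh_bound)
        records.append(rec)
    return records
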