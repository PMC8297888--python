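"""Shared fixtures: small diagrams and a cached synthetic cohort table."""

from __future__ import annotations

import numpy as np
import pytest

from topohrv import (
    PersistenceDiagram,
    PersistencePair,
    con_like,
    feature_table,
    generate_cohorts,
    str_like,
)


def diagram_from_pairs(pairs, n_beats=None) -> PersistenceDiagram:
    return PersistenceDiagram(
        tuple(PersistencePair(float(b), float(d)) for b, d in pairs),
        n_beats=n_beats,
    )


@pytest.fixture(scope="session")
def cohort_table():
    """Feature table of a con-like vs str-like synthetic cohort (25+25).

    Session-scoped: the full pipeline (persistence, triangle fit,
    spectral analysis) runs once and is reused by evaluation tests.
    """
    con, strk = generate_cohorts(
        con_like(n_subjects=25, seed=41), str_like(n_subjects=25, seed=42)
    )
    return feature_table(con + strk)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
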