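"""Shared fixtures: canonical study sets and sweeps (seed 0, CI scale).

Heavy study-level objects are session-scoped so the acceptance tests can
share one regeneration of the study conditions (200 patterns per
numerosity, 5-px grid) instead of recomputing it per test.
"""

from __future__ import annotations

import numpy as np
import pytest

import numgraph as ng
from numgraph import sweep_study as sw

SEED = 0
R = 160.0
DELTA = 10.0
CI_PATTERNS = 200


@pytest.fixture(scope="session")
def study22() -> list[ng.PointConfiguration]:
    return ng.generate_study_set([22], CI_PATTERNS, R=R, delta=DELTA, seed=SEED)


@pytest.fixture(scope="session")
def study40() -> list[ng.PointConfiguration]:
    return ng.generate_study_set([40], CI_PATTERNS, R=R, delta=DELTA, seed=SEED)


@pytest.fixture(scope="session")
def study40_full() -> list[ng.PointConfiguration]:
    """The reference scale for the connectivity-threshold check."""
    return ng.generate_study_set([40], 1000, R=R, delta=DELTA, seed=SEED)


@pytest.fixture(scope="session")
def sweep22(study22) -> sw.IndexTable:
    """Full-grid sweep at n=22, all indices except RW (not used by the PCA)."""
    return sw.sweep(
        study22,
        sw.default_d_grid(R=R, delta=DELTA, step=5),
        indices=[m for m in sw.ALL_INDICES if m != "RW"],
        settings=sw.SweepSettings(seed=SEED),
    )


@pytest.fixture(scope="session")
def sweep40(study40) -> sw.IndexTable:
    return sw.sweep(
        study40,
        sw.default_d_grid(R=R, delta=DELTA, step=5),
        indices=[m for m in sw.ALL_INDICES if m != "RW"],
        settings=sw.SweepSettings(seed=SEED),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
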