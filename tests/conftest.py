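"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from synsel.synthetic import (
    NeighborhoodParams,
    ProgramParams,
    SimulationConfig,
    UtrParams,
)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_config() -> SimulationConfig:
    """A miniature simulation: 4 tips, 3 planted orthologs, 4 decoys,
    10 genes per program — fast enough for unit and smoke tests."""
    return SimulationConfig(
        seed=7,
        n_tips=4,
        neighborhood=NeighborhoodParams(planted=3, decoys=4,
                                        decoy_protein_len=60),
        program=ProgramParams(n_genes=10, protein_len=80),
        utr=UtrParams(length=200),
    )
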