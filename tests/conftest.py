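"""Shared fixtures: parameter sets and hand-built worlds for scripted tests."""

from __future__ import annotations

import numpy as np
import pytest

from careimmune import ParameterSet, WorldState


@pytest.fixture
def params() -> ParameterSet:
    """A canonical mid-grid configuration."""
    return ParameterSet(
        disease_mortality_pct=10,
        transmissibility_pct=50,
        extrinsic_mortality_pct=5,
        care_intensity=10,
    )


@pytest.fixture
def make_world():
    """Factory for empty worlds with arbitrary (possibly off-grid) parameters."""

    def _make(seed: int = 0, **overrides) -> WorldState:
        p = ParameterSet(**overrides)
        return WorldState(p, seed=seed)

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
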