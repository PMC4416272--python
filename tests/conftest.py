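"""Shared fixtures: cached simulations and the small comparison experiment."""

from __future__ import annotations

import numpy as np
import pytest

from meritsim import GeneticParams, SchemeConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def params():
    return GeneticParams()


@pytest.fixture(scope="session")
def smoke_sim():
    """One small simulated replicate shared across the suite."""
    from meritsim.simulate import simulate_breeding_scheme

    return simulate_breeding_scheme(GeneticParams(), SchemeConfig.smoke(), seed=11)

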