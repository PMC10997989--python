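"""Shared fixtures: small seeded trial sets, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from emgonset.signal_models import SimulatedTrial, generate_phenomenological


@pytest.fixture(scope="session")
def gaussian_trial():
    """One Gaussian-model trial at 0 dB (full 13 s geometry)."""
    return generate_phenomenological("gaussian", 0.0, 1, 101)[0]


@pytest.fixture(scope="session")
def short_trial():
    """A 4.2 s trial (3 s baseline + margin) for fast per-detector checks."""
    rng = np.random.default_rng(7)
    n_rest, n_move = 3600, 600
    x = rng.standard_normal(n_rest + n_move)
    x[n_rest:] *= np.sqrt(2.0)
    return SimulatedTrial(x, 1000.0, n_rest, "gaussian", 0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
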