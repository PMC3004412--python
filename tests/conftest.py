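from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mrsr import DegradationSpec, PhantomSpec, RicianNoiseSpec, Volume3D, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_volume(rng):
    """Unit-scale 8^3 random volume (float64)."""
    return Volume3D(rng.random((8, 8, 8)), range_peak=1.0)


@pytest.fixture(scope="session")
def small_bundle():
    """Noise-free 32^3 phantom study, z-factor 2 — shared cheap end-to-end input."""
    return simulate_study(
        PhantomSpec(shape=(32, 32, 32), seed=7),
        DegradationSpec((1, 1, 2)),
        RicianNoiseSpec(sigma=0.0, seed=0),
    )
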