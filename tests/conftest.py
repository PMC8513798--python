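"""Shared fixtures: the synthetic helmet and derived objects are built
once per session — every matrix in the package keys its row order to the
array's channel ordering, so sharing them is safe."""

import numpy as np
import pytest

from megshield import (
    Recording,
    build_sss_basis,
    build_synthetic_helmet,
    perturb_calibration,
)
from megshield.simulate import simulate_empty_room


@pytest.fixture(scope="session")
def helmet():
    return build_synthetic_helmet()


@pytest.fixture(scope="session")
def basis(helmet):
    return build_sss_basis(helmet)


@pytest.fixture(scope="session")
def perturbed_helmet(helmet):
    """0.5%-miscalibrated copy (channel gains + gradiometer loop balance)."""
    return perturb_calibration(helmet, 0.005, seed=1)


@pytest.fixture(scope="session")
def empty_room(perturbed_helmet):
    """30-s empty-room fixture recorded with the miscalibrated array."""
    return simulate_empty_room(perturbed_helmet, duration=30.0, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
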