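from __future__ import annotations

import pytest

from shiftnet.examples import example_attendance, worked_example_network
from shiftnet.synthetic_data import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def worked_example():
    """Four-person shift whose medication-advice dyad network has 5 of 6 ties."""
    return worked_example_network()


@pytest.fixture(scope="session")
def attendance():
    """Bundled 24-shift-point attendance table."""
    return example_attendance()


@pytest.fixture(scope="session")
def small_dataset():
    """Three-week synthetic study (6 shift-points), defaults otherwise."""
    return simulate(SyntheticConfig(n_weeks=3, seed=101))


@pytest.fixture(scope="session")
def full_dataset():
    """Full 12-week x {day, night} synthetic study under default conditions."""
    return simulate(SyntheticConfig(seed=2024))
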