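"""Shared fixtures: Table-2-style fuzzy sets and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from fuzzpipe import (
    FuzzySet,
    TrapezoidParams,
    AcquisitionConfig,
    DynamicsConfig,
    simulate_dataset,
)

#: size-feature trapezoids of the reference benchmark statistics
THETA = {
    "volume": (449.0, 617.0, 1405.0, 2016.0),
    "width": (13.0, 15.0, 24.0, 31.0),
    "height": (13.0, 15.0, 24.0, 34.0),
    "depth": (3.0, 5.0, 8.0, 11.0),
}


@pytest.fixture(scope="session")
def size_sets() -> list[FuzzySet]:
    return [
        FuzzySet("correct", TrapezoidParams(*params), feat)
        for feat, params in THETA.items()
    ]


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small single-frame benchmark: 30 nuclei on a 32x128x128 grid."""
    dyn = DynamicsConfig(n_initial=30, n_frames=1)
    acq = AcquisitionConfig()
    return simulate_dataset(dyn, acq, (32, 128, 128), seed=7)


@pytest.fixture(scope="session")
def tiny_timeseries():
    """Two-view 4-frame benchmark with divisions, 25 nuclei initially."""
    dyn = DynamicsConfig(n_initial=25, n_frames=4, division_rate=0.05)
    acq = AcquisitionConfig(views=(0, 1))
    return simulate_dataset(dyn, acq, (32, 128, 128), seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
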