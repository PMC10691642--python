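"""Shared fixtures.

The Monte Carlo fixtures are session-scoped and reused across test modules
so each configuration is transported exactly once; seeds are fixed so every
stochastic assertion is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

from plaquedose import (build_coms_plaque, build_notched_plaque,
                        load_default_dataset)
from plaquedose.pipeline import (eye_study, mc_to_tg43_calibration,
                                 mc_water_run)


@pytest.fixture(scope="session")
def dataset():
    return load_default_dataset()


@pytest.fixture(scope="session")
def coms16():
    return build_coms_plaque(16)


@pytest.fixture(scope="session")
def coms20():
    return build_coms_plaque(20)


@pytest.fixture(scope="session")
def notched20():
    return build_notched_plaque()


@pytest.fixture(scope="session")
def water16(dataset):
    """Water-mode MC, 16 mm non-uniform loading, 1 mm scoring grid."""
    return mc_water_run("coms16", "nonuniform", "tg43_water", 3_000_000, 101,
                        dataset)


@pytest.fixture(scope="session")
def water20(dataset):
    return mc_water_run("notched20", "nonuniform", "tg43_water", 2_000_000,
                        103, dataset)


@pytest.fixture(scope="session")
def calib16(dataset):
    return mc_to_tg43_calibration("coms16", "nonuniform", 4_000_000, 107,
                                  dataset)


@pytest.fixture(scope="session")
def calib20(dataset):
    return mc_to_tg43_calibration("notched20", "nonuniform", 4_000_000, 109,
                                  dataset)


@pytest.fixture(scope="session")
def full16(dataset):
    """Full heterogeneous MC of the 16 mm plaque in the water box."""
    return mc_water_run("coms16", "nonuniform", "full", 10_000_000, 113,
                        dataset)


@pytest.fixture(scope="session")
def full20(dataset):
    return mc_water_run("notched20", "nonuniform", "full", 10_000_000, 127,
                        dataset)


@pytest.fixture(scope="session")
def eye_notched(dataset, calib20):
    return eye_study("notched20_nonuniform", 3_000_000, 131, dataset,
                     calibration=calib20)


@pytest.fixture(scope="session")
def eye16(dataset, calib16):
    return eye_study("coms16_nonuniform", 3_000_000, 137, dataset,
                     calibration=calib16)


@pytest.fixture
def rng():
    return np.random.default_rng(2023)
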