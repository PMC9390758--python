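"""Shared fixtures: session-scoped solver artifacts to avoid recomputation."""

import numpy as np
import pytest

from lumenpd.geometry import Centerline
from lumenpd.hemodynamics import (
    FlowWaveform,
    calibrate_windkessel,
    mirror_network,
)
from lumenpd.synthetic import nominal_dissection_model

# re-exported for tests that build the symmetry-null network
make_mirror_network = mirror_network


@pytest.fixture(scope="session")
def inlet_waveform() -> FlowWaveform:
    return FlowWaveform.default_aortic()


@pytest.fixture(scope="session")
def calibrated_outlets(inlet_waveform):
    """TL/FL outlet pair calibrated for 120/80 mmHg at a 0.6/0.4 split."""
    return calibrate_windkessel(120.0, 80.0, inlet_waveform, splits=(0.6, 0.4))


@pytest.fixture(scope="session")
def single_outlet(inlet_waveform):
    return calibrate_windkessel(120.0, 80.0, inlet_waveform)[0]


@pytest.fixture
def nominal_model():
    return nominal_dissection_model()


@pytest.fixture
def straight_centerline():
    """500 mm straight centerline with the LSA landmark at arc 0."""
    z = np.arange(0.0, 501.0, 5.0)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), -z])
    return Centerline(points=pts, landmark_arc=0.0)
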