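"""Shared fixtures. Expensive simulated datasets are session-scoped and
reused across modules; everything is generated at test time from seeds."""

from __future__ import annotations

import numpy as np
import pytest

from spinescan.geometry import BeamGeometry
from spinescan.synthetic import (
    BonePhantom,
    NOISELESS,
    NoiseConfig,
    default_scan,
    simulate_frame,
    simulate_scan,
)


@pytest.fixture(scope="session")
def beam() -> BeamGeometry:
    return BeamGeometry()


@pytest.fixture(scope="session")
def phantom() -> BonePhantom:
    return BonePhantom()


@pytest.fixture(scope="session")
def center_frame_noiseless(phantom, beam):
    """Noiseless frame for a center chord of the default phantom."""
    scan = default_scan(radius_um=phantom.radius_um)
    return simulate_frame(phantom, 0.0, 5.0, beam, scan, NOISELESS)


@pytest.fixture(scope="session")
def dataset_noisy(beam):
    """One noisy tomographic scan of the default phantom with injected
    fractional drift — the workhorse dataset for tomo/xrf/strain tests."""
    ph = BonePhantom(strain_edge=-0.001)
    scan = default_scan(radius_um=ph.radius_um, seed=101)
    rng = np.random.default_rng(101)
    scan.drift_px = rng.uniform(-2.0, 2.0, scan.n_omega)
    return simulate_scan(ph, beam, scan, NoiseConfig(), seed=202)


@pytest.fixture(scope="session")
def dataset_noiseless_driftfree(beam):
    """Small noiseless, drift-free scan (fewer angles) for exactness tests."""
    ph = BonePhantom(strain_edge=-0.001)
    scan = default_scan(radius_um=ph.radius_um, n_omega=6, seed=7)
    return simulate_scan(ph, beam, scan, NOISELESS, seed=7)
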