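"""Shared fixtures: small, fast phantom datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from fetalcine.phantom import PhantomConfig, SceneGeometry, simulate_acquisition
from fetalcine.trajectory import SpiralProtocol


@pytest.fixture(scope="session")
def small_protocol() -> SpiralProtocol:
    """Coarse 64x64 protocol for fast solver tests."""
    return SpiralProtocol(res_mm=240.0 / 64, n_samples_per_arm=256)


@pytest.fixture(scope="session")
def static_dataset(small_protocol):
    """Noiseless, motionless, non-beating acquisition of 144 arms (one full
    pseudo golden-angle period) on the 64x64 grid."""
    cfg = PhantomConfig(geometry=SceneGeometry(systolic_radius_frac=1.0),
                        n_arms=144, rr_sd_ms=0.0, resp_amp_mm=0.0,
                        noise_sd=0.0, seed=99)
    ds, gt = simulate_acquisition(small_protocol, cfg)
    return ds, gt, cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
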