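"""Shared fixtures: small ground-truthed synthetic gels built at test time."""

import numpy as np
import pytest

from fecgel import sim


def standard_lanes(n_lanes: int = 10) -> list:
    """Marker lane plus four sample lanes with well-separated band pairs."""
    lanes = [sim.LaneSpec()]  # lane 0: marker ladder only
    for i in range(4):
        lanes.append(sim.LaneSpec(
            bands=[sim.BandSpec(120.0 - 20.0 * i, 1.0),
                   sim.BandSpec(45.0 - 5.0 * i, 0.6)],
            label=f"sample{i}"))
    lanes += [sim.LaneSpec() for _ in range(n_lanes - len(lanes))]
    return lanes


def make_gel(rotation_deg: float = 0.0, noise_sigma: float = 0.0,
             bleed_k: float = 0.0, seed: int = 1, exposure: float = 1.0):
    cfg = sim.SimConfig(lanes=standard_lanes(), rotation_deg=rotation_deg,
                        noise_sigma=noise_sigma, bleed_k=bleed_k,
                        exposure=exposure, seed=seed)
    return sim.simulate_gel(cfg), cfg


@pytest.fixture
def clean_gel():
    """Noise-free, unrotated gel with ground truth."""
    (img, truth), cfg = make_gel()
    return img, truth, cfg


@pytest.fixture
def noisy_rotated_gel():
    """Rotated, noisy, bleed-contaminated gel — the realistic case."""
    (img, truth), cfg = make_gel(rotation_deg=2.0, noise_sigma=10.0,
                                 bleed_k=0.1, seed=2)
    return img, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
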