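"""Shared fixtures: synthetic frames, cohorts, and a small grown spheroid."""

from __future__ import annotations

import numpy as np
import pytest

from spherobridge.growthspace import RichardsParams
from spherobridge.imaging import FrameImage
from spherobridge.simulator import SimulationConfig, run_simulation
from spherobridge.synthetic import SyntheticSpec


def make_disc_frame(
    radius_px: float,
    size: int = 256,
    pixel_size_um: float = 1.0,
    day: float = 0.0,
    noise_sigma: float = 0.0,
    speckles: int = 0,
    seed: int = 0,
    center: tuple[float, float] | None = None,
) -> FrameImage:
    """Dark disc on a bright background, optionally noisy/speckled."""
    rng = np.random.default_rng(seed)
    img = np.full((size, size), 200.0)
    if noise_sigma:
        img += rng.normal(0.0, noise_sigma, img.shape)
    cy, cx = center if center is not None else (size / 2.0, size / 2.0)
    yy, xx = np.mgrid[0:size, 0:size]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    img[inside] = 60.0
    if noise_sigma:
        img[inside] += rng.normal(0.0, noise_sigma, int(inside.sum()))
    for _ in range(speckles):
        r, c = rng.integers(8, size - 8, size=2)
        if not inside[r, c]:
            img[r, c] = 60.0
    return FrameImage(pixels=np.clip(img, 0, 255).astype(np.uint8),
                      pixel_size_um=pixel_size_um, timestamp_days=day)


@pytest.fixture(scope="session")
def small_synthetic_spec() -> SyntheticSpec:
    """Compact acquisition spec: 256 px frames, moderate plateau."""
    return SyntheticSpec(
        richards=RichardsParams(A=1.0, B=0.9, C=2000.0, M=7.0, T=1.0),
        image_size_px=256,
        seed=123,
    )


@pytest.fixture(scope="session")
def grown_trajectory():
    """A small spheroid grown to ~exhaustion, shared across tests."""
    cfg = SimulationConfig(n_initial=16, Kc=0.5, Ke=0.1, capacity=2.5e5,
                           total_days=4.0, seed=7, initial_age_spread_h=18.0)
    return run_simulation(cfg, start_day=4.0)
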