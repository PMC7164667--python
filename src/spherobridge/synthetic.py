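"""Synthetic fixtures: growth curves, time-lapse stacks, cohorts.

The pipeline was designed around time-lapse phase-contrast imaging of
single spheroids (nominally 1000 x 1000 px frames every 3 h over days
2-15 of culture).  No public image archive accompanies that protocol,
so this module emulates its statistical structure: a Richards growth
curve drives the estimated cell count, the count is inverted through
the FCC packing estimate to a disc radius, and the disc is rendered
with background noise and speckle.  Cohorts of noisy Richards curves
with varied parameters feed the PCA feature plane.  All generators are
deterministic functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .imaging import FCC_DENSITY, FrameImage, GrowthCurve
from .growthspace import RichardsParams, richards_eval


@dataclass(frozen=True)
class SyntheticSpec:
    """Settings for one synthetic spheroid acquisition.

    Defaults mirror the imaging protocol the analysis assumes: 3 h
    frame interval over days 2-15 (105 frames), 1000 px frames at
    0.65 um/px (10x objective scale), dark spheroid on a bright
    background.
    """

    richards: RichardsParams = field(
        default_factory=lambda: RichardsParams(A=1.0, B=0.8, C=8000.0,
                                               M=8.0, T=1.0))
    start_day: float = 2.0
    end_day: float = 15.0
    frame_interval_h: float = 3.0
    pixel_size_um: float = 0.65
    image_size_px: int = 1000
    cell_diameter_um: float = 10.0
    background_level: int = 200
    object_level: int = 80
    background_sigma: float = 6.0
    speckle_count: int = 20
    curve_noise_sigma: float = 0.05
    polarity: str = "dark"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_h <= 0 or self.pixel_size_um <= 0:
            raise ValueError("interval and pixel size must be positive")
        if self.image_size_px < 64:
            raise ValueError("image_size_px must be >= 64")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")
        if self.end_day <= self.start_day:
            raise ValueError("end_day must exceed start_day")

    @property
    def frame_times_days(self) -> np.ndarray:
        step = self.frame_interval_h / 24.0
        n = int(math.floor((self.end_day - self.start_day) / step + 1e-9)) + 1
        return self.start_day + step * np.arange(n)


def generate_growth_curve(
    spec: SyntheticSpec,
) -> tuple[GrowthCurve, RichardsParams]:
    """Noisy Richards samples at the frame times, with the ground truth.

    Counts are the Richards curve multiplied by lognormal noise of the
    configured sigma, rounded to integers and clamped to >= 1.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.frame_times_days
    ideal = richards_eval(spec.richards, times)
    if spec.curve_noise_sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=spec.curve_noise_sigma,
                              size=times.shape)
    else:
        noise = np.ones_like(times)
    counts = np.maximum(np.round(ideal * noise), 1.0)
    curve = GrowthCurve(times_days=times, counts=counts,
                        cell_diameter_um=spec.cell_diameter_um)
    return curve, spec.richards


def count_to_disc_radius_um(count: float, cell_diameter_um: float) -> float:
    """Invert the FCC packing estimate: spheroid radius for a count.

    D = d (count / rho_fcc)^(1/3); the projected disc radius is D/2.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    return cell_diameter_um * (count / FCC_DENSITY) ** (1.0 / 3.0) / 2.0


def render_frame(
    radius_px: float, spec: SyntheticSpec, rng: np.random.Generator,
) -> np.ndarray:
    """One 8-bit frame: centred disc, Gaussian background, speckles."""
    size = spec.image_size_px
    if radius_px >= size / 2 - 2:
        raise ValueError(
            f"disc radius {radius_px:.1f} px does not fit a {size} px frame")
    bg, obj = (spec.background_level, spec.object_level)
    if spec.polarity == "bright":
        bg, obj = obj, bg
    img = np.full((size, size), float(bg))
    img += rng.normal(0.0, spec.background_sigma, size=img.shape)
    rr, cc = draw_disk((size / 2.0, size / 2.0), radius_px, shape=img.shape)
    img[rr, cc] = obj + rng.normal(0.0, spec.background_sigma, size=len(rr))
    if spec.speckle_count:
        rows = rng.integers(0, size, size=spec.speckle_count)
        cols = rng.integers(0, size, size=spec.speckle_count)
        img[rows, cols] = obj
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_timelapse(
    spec: SyntheticSpec,
) -> tuple[list[FrameImage], np.ndarray]:
    """Full synthetic frame series plus ground-truth disc radii (um).

    Each frame's disc radius follows the (noisy) growth curve through
    the FCC inversion, so running the imaging pipeline on the output
    recovers the generating counts up to discretisation.
    """
    curve, _ = generate_growth_curve(spec)
    rng = np.random.default_rng(spec.seed + 1)  # image noise stream
    frames, radii = [], []
    for t, count in zip(curve.times_days, curve.counts):
        radius_um = count_to_disc_radius_um(count, spec.cell_diameter_um)
        frames.append(FrameImage(
            pixels=render_frame(radius_um / spec.pixel_size_um, spec, rng),
            pixel_size_um=spec.pixel_size_um,
            timestamp_days=float(t),
        ))
        radii.append(radius_um)
    return frames, np.array(radii)


@dataclass(frozen=True)
class CohortDistributions:
    """Independent sampling distributions for cohort Richards parameters.

    A is fixed at the single-cell stage; B, C and T are lognormal
    (positive by construction) and M is normal, centred on values that
    give curves plateauing at several thousand cells around day 8-11,
    the scale of small spheroids grown over two weeks.
    """

    A: float = 1.0
    B_log_mean: float = math.log(0.8)
    B_log_sigma: float = 0.3
    C_log_mean: float = math.log(8000.0)
    C_log_sigma: float = 0.5
    M_mean: float = 8.0
    M_sigma: float = 1.5
    T_log_mean: float = 0.0
    T_log_sigma: float = 0.5


def generate_cohort(
    n: int,
    distributions: CohortDistributions | None = None,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Cohort of noisy growth curves with a ground-truth table.

    Each member's Richards parameters are drawn independently from the
    stated distributions; curves are generated with the per-member
    seed ``seed + i`` so the cohort is reproducible element-wise.
    """
    if n < 3:
        raise ValueError("cohort size must be >= 3")
    dist = distributions or CohortDistributions()
    base = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    curves, rows = [], []
    for i in range(n):
        params = RichardsParams(
            A=dist.A,
            B=float(rng.lognormal(dist.B_log_mean, dist.B_log_sigma)),
            C=float(rng.lognormal(dist.C_log_mean, dist.C_log_sigma)),
            M=float(rng.normal(dist.M_mean, dist.M_sigma)),
            T=float(rng.lognormal(dist.T_log_mean, dist.T_log_sigma)),
        )
        member = replace(base, richards=params, seed=seed + i)
        curve, _ = generate_growth_curve(member)
        curves.append(curve)
        rows.append({"spheroid_id": i, "A": params.A, "B": params.B,
                     "C": params.C, "M": params.M, "T": params.T})
    return curves, pd.DataFrame(rows)


def random_packing_count(
    outer_diameter: float,
    sphere_diameter: float,
    seed: int = 0,
    max_sweeps: int = 6000,
    tol_frac: float = 1e-3,
) -> int:
    """Monte-Carlo random close packing of spheres in a sphere.

    Starts deliberately overfilled with uniform random centres, then
    repeatedly pushes overlapping pairs apart and confines centres to
    the container; whenever a relaxation block fails to remove all
    overlap, the most-overlapped particles are evicted.  The returned
    count is the size of the first overlap-free configuration — a
    physical random packing, typically near the empirical random
    close-packing density of ~0.64, between the simple cubic and FCC
    lattice bounds.
    """
    from scipy.spatial import cKDTree

    d = sphere_diameter
    rc = (outer_diameter - d) / 2.0  # centre container radius
    if rc <= 0:
        raise ValueError("container must hold at least one sphere")
    rng = np.random.default_rng(seed)
    n0 = int(0.9 * (outer_diameter / d) ** 3)
    # uniform sampling in a ball
    pos = rng.normal(size=(n0, 3))
    pos *= (rc * rng.uniform(size=n0) ** (1 / 3)
            / np.linalg.norm(pos, axis=1))[:, None]
    tol = tol_frac * d
    block = 25
    for sweep in range(max_sweeps):
        pairs = cKDTree(pos).query_pairs(d, output_type="ndarray")
        if len(pairs) == 0:
            break
        i, j = pairs[:, 0], pairs[:, 1]
        diff = pos[i] - pos[j]
        dist = np.linalg.norm(diff, axis=1)
        dist = np.maximum(dist, 1e-9)
        overlap = d - dist
        if overlap.max() < tol:
            break
        push = (0.55 * overlap / dist)[:, None] * diff
        np.add.at(pos, i, push)
        np.add.at(pos, j, -push)
        norms = np.linalg.norm(pos, axis=1)
        outside = norms > rc
        if outside.any():
            pos[outside] *= (rc / norms[outside])[:, None]
        if (sweep + 1) % block == 0:
            # jammed: evict the worst-overlapped 0.5%
            load = np.zeros(len(pos))
            np.add.at(load, i, overlap)
            np.add.at(load, j, overlap)
            n_evict = max(1, int(0.005 * len(pos)))
            keep = np.argsort(load)[: len(pos) - n_evict]
            pos = pos[keep]
    return len(pos)
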