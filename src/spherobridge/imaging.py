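"""Spheroid segmentation and image-derived growth curves.

One spheroid grows per time-lapse frame series (phase-contrast, 8-bit
grayscale).  Each frame is segmented to a single connected region, the
region is replaced by the circle of equal area, and the cell count is
estimated by treating the spheroid as a sphere of that diameter packed
with cells on a face-centered cubic (FCC) lattice.  Simple cubic packing
provides the matching lower bound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

#: packing density of a simple cubic sphere lattice
SIMPLE_CUBIC_DENSITY = math.pi / 6.0
#: packing density of a face-centered cubic (close-packed) sphere lattice
FCC_DENSITY = math.pi / (3.0 * math.sqrt(2.0))


class EmptySegmentationError(ValueError):
    """No foreground remained after thresholding and cleanup."""


class InsufficientSeriesError(ValueError):
    """Fewer than two frames segmented successfully."""


@dataclass(frozen=True)
class FrameImage:
    """A single 8-bit grayscale time-lapse frame.

    Parameters
    ----------
    pixels
        2-D uint8 array (row-major, origin top-left).
    pixel_size_um
        Physical size of one pixel in micrometres.
    timestamp_days
        Acquisition time in days since seeding.
    """

    pixels: np.ndarray
    pixel_size_um: float
    timestamp_days: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("frame must be a 2-D grayscale array")
        if min(self.pixels.shape) < 64:
            raise ValueError("frame must be at least 64x64 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray
    area_px: int
    equivalent_radius_um: float


@dataclass
class SegmentationConfig:
    """Settings for threshold + morphology segmentation.

    ``object_polarity`` is ``"dark"`` for the usual phase-contrast
    appearance (dark spheroid body on a bright background) or
    ``"bright"`` for the inverse.
    """

    object_polarity: str = "dark"
    opening_radius_px: int = 3
    closing_radius_px: int = 3
    min_object_px: int = 1

    def __post_init__(self) -> None:
        if self.object_polarity not in ("dark", "bright"):
            raise ValueError("object_polarity must be 'dark' or 'bright'")


@dataclass
class GrowthCurve:
    """Estimated cell counts e(t) over time for one spheroid."""

    times_days: np.ndarray
    counts: np.ndarray
    cell_diameter_um: float = 10.0
    diameters_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times_days.shape != self.counts.shape:
            raise ValueError("times and counts must have the same length")
        if len(self.times_days) and np.any(np.diff(self.times_days) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.counts) and np.any(self.counts < 1):
            raise ValueError("counts must be >= 1")

    def __len__(self) -> int:
        return len(self.times_days)


def segment_spheroid(
    frame: FrameImage, config: SegmentationConfig | None = None
) -> SegmentationResult:
    """Segment the single spheroid in a frame.

    Otsu threshold, then binary opening (speckle removal) and closing,
    hole filling, and retention of the largest connected component.
    """
    config = config or SegmentationConfig()
    img = frame.pixels
    if img.max() == img.min():
        raise EmptySegmentationError(
            f"frame at day {frame.timestamp_days}: uniform image, no object"
        )
    thresh = threshold_otsu(img)
    # skimage convention: the upper class is img > thresh
    mask = img <= thresh if config.object_polarity == "dark" else img > thresh
    if not mask.any():
        raise EmptySegmentationError(
            f"frame at day {frame.timestamp_days}: no foreground after threshold"
        )
    mask = morphology.opening(mask, morphology.disk(config.opening_radius_px))
    mask = morphology.closing(mask, morphology.disk(config.closing_radius_px))
    mask = morphology.remove_small_holes(mask, max_size=mask.size // 4)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise EmptySegmentationError(
            f"frame at day {frame.timestamp_days}: no region after morphology"
        )
    areas = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(areas)) + 1
    mask = labels == keep
    area_px = int(mask.sum())
    if area_px < config.min_object_px:
        raise EmptySegmentationError(
            f"frame at day {frame.timestamp_days}: object below minimum size"
        )
    return SegmentationResult(
        mask=mask,
        area_px=area_px,
        equivalent_radius_um=equivalent_circle_radius(area_px, frame.pixel_size_um),
    )


def equivalent_circle_radius(area_px: float, pixel_size_um: float) -> float:
    """Radius (um) of the circle with the same area as the segmented region."""
    if area_px <= 0:
        raise ValueError("area_px must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return pixel_size_um * math.sqrt(area_px / math.pi)


def packing_count_bounds(
    spheroid_diameter_um: float, cell_diameter_um: float
) -> tuple[int, int]:
    """Lower/upper cell-count bounds for a spheroid of diameter D.

    The count of cells of diameter d filling a sphere of diameter D at
    packing density rho is (D/d)^3 * rho.  Simple cubic packing
    (rho = pi/6) gives the lower bound and FCC packing
    (rho = pi/(3 sqrt 2)) the upper bound; the ratio of the two
    densities is exactly 2^(-1/2).  Counts are floored and clamped to
    at least one cell.
    """
    if cell_diameter_um <= 0:
        raise ValueError("cell_diameter_um must be positive")
    if spheroid_diameter_um < cell_diameter_um:
        raise ValueError("spheroid smaller than a single cell")
    ratio_cubed = (spheroid_diameter_um / cell_diameter_um) ** 3
    lower = max(1, math.floor(ratio_cubed * SIMPLE_CUBIC_DENSITY))
    upper = max(1, math.floor(ratio_cubed * FCC_DENSITY))
    return lower, upper


def estimate_cell_count(
    spheroid_diameter_um: float, cell_diameter_um: float
) -> int:
    """Point estimate of the cell count: the FCC (upper-bound) packing count."""
    return packing_count_bounds(spheroid_diameter_um, cell_diameter_um)[1]


def extract_growth_curve(
    series: list[FrameImage],
    cell_diameter_um: float,
    config: SegmentationConfig | None = None,
) -> GrowthCurve:
    """Segment every frame of a series and build the growth curve e(t).

    Frames that fail segmentation are dropped with a logged warning; at
    least two frames must survive.
    """
    if len(series) < 2:
        raise InsufficientSeriesError("need at least 2 frames")
    series = sorted(series, key=lambda f: f.timestamp_days)
    times, counts, diameters = [], [], []
    for frame in series:
        try:
            seg = segment_spheroid(frame, config)
        except EmptySegmentationError as exc:
            logger.warning("dropping frame: %s", exc)
            continue
        diameter = 2.0 * seg.equivalent_radius_um
        times.append(frame.timestamp_days)
        diameters.append(diameter)
        counts.append(estimate_cell_count(max(diameter, cell_diameter_um),
                                          cell_diameter_um))
    if len(times) < 2:
        raise InsufficientSeriesError(
            f"only {len(times)} frame(s) segmented successfully"
        )
    return GrowthCurve(
        times_days=np.array(times),
        counts=np.array(counts, dtype=float),
        cell_diameter_um=cell_diameter_um,
        diameters_um=np.array(diameters),
    )


def estimate_single_cell_size(
    frames: list[FrameImage],
    cells_per_frame: list[int] | None = None,
    config: SegmentationConfig | None = None,
) -> float:
    """Single-cell diameter (um) from one- or two-cell-stage frames.

    For a frame flagged as two-cell the segmented area is halved before
    the equivalent-circle conversion.  Returns the mean diameter across
    frames that segment successfully.
    """
    if not frames:
        raise ValueError("no frames supplied")
    if cells_per_frame is None:
        cells_per_frame = [1] * len(frames)
    if len(cells_per_frame) != len(frames):
        raise ValueError("cells_per_frame must match frames")
    diameters = []
    for frame, n_cells in zip(frames, cells_per_frame):
        if n_cells not in (1, 2):
            raise ValueError("frames must be one- or two-cell stage")
        try:
            seg = segment_spheroid(frame, config)
        except EmptySegmentationError as exc:
            logger.warning("dropping cell-size frame: %s", exc)
            continue
        radius = equivalent_circle_radius(seg.area_px / n_cells,
                                          frame.pixel_size_um)
        diameters.append(2.0 * radius)
    if not diameters:
        raise EmptySegmentationError("no cell-size frame segmented successfully")
    return float(np.mean(diameters))


def relative_size_ratios(
    diameters_um: list[float] | np.ndarray, reference_index: int = 0
) -> np.ndarray:
    """Diameter of each spheroid relative to a reference, rounded to 2 d.p.

    Used for the relative spatial bookkeeping that compares end-point
    spheroid sizes across a cohort (each diameter divided by the
    reference spheroid's diameter).
    """
    diameters = np.asarray(diameters_um, dtype=float)
    ref = diameters[reference_index]
    if ref <= 0:
        raise ValueError("reference diameter must be positive")
    return np.round(diameters / ref, 2)
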