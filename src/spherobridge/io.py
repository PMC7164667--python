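"""Configuration and file formats shared by the pipeline stages.

All tabular data travel as CSV with unit-suffixed headers; frames are
single-page 8-bit TIFF or PNG; configuration is YAML (or JSON) with
unknown keys rejected and every validation problem reported at once.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .imaging import FrameImage, GrowthCurve
from .simulator import SimulationConfig, SpheroidState

logger = logging.getLogger(__name__)

GROWTH_CURVE_COLUMNS = ["day", "cell_count", "equiv_diameter_um"]
SNAPSHOT_COLUMNS = ["id", "x_um", "y_um", "z_um", "generation",
                    "cycle_age_min", "N", "density", "mobility"]


class SchemaError(ValueError):
    """CSV columns do not match the documented schema."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ImagingSection(_Section):
    pixel_size_um: float = Field(0.65, gt=0)
    object_polarity: str = "dark"
    cell_diameter_um: float = Field(10.0, gt=0)
    opening_radius_px: int = Field(3, ge=0)
    closing_radius_px: int = Field(3, ge=0)


class SimulatorSection(_Section):
    dt_min: float = Field(1.0, gt=0)
    total_days: float = Field(5.0, ge=0)
    cell_diameter_um: float = Field(10.0, gt=0)
    k: float = Field(0.005, gt=0)
    R: float = Field(1.106, gt=0)
    G: float = Field(1.5, gt=0)
    max_depth_um: float = Field(200.0, gt=0)
    alpha_over_D: float = Field(20.0, gt=0)
    shell_width_um: float = Field(5.0, gt=0)
    min_cycle_h: float = Field(18.0, gt=0)
    capacity: float = Field(float("inf"), gt=0)
    Kc: float = Field(1.0, gt=0)
    Ke: float = Field(1.0, gt=0)
    n_initial: int = Field(1, ge=1)
    initial_age_spread_h: float = Field(0.0, ge=0)
    snapshot_interval_h: float = Field(3.0, gt=0)

    @model_validator(mode="after")
    def _check_force_roots(self) -> "SimulatorSection":
        if self.R >= self.G:
            raise ValueError("repulsion constant R must be < attraction "
                             "constant G")
        return self

    def to_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            total_days=self.total_days, dt_min=self.dt_min,
            cell_diameter_um=self.cell_diameter_um, k=self.k, R=self.R,
            G=self.G, max_depth_um=self.max_depth_um,
            alpha_over_D_mm2=self.alpha_over_D,
            shell_width_um=self.shell_width_um,
            min_cycle_h=self.min_cycle_h, capacity=self.capacity,
            Kc=self.Kc, Ke=self.Ke, seed=seed, n_initial=self.n_initial,
            initial_age_spread_h=self.initial_age_spread_h,
            snapshot_interval_h=self.snapshot_interval_h,
        )


class BridgeSection(_Section):
    budget: int = Field(30, ge=1)
    start_Kc: float = Field(1.0, gt=0)
    start_Ke: float = Field(1.0, gt=0)
    start_day: float = Field(4.0, ge=0)
    plateau_threshold: float = Field(0.01, gt=0)


class ActivitySection(_Section):
    slab_thickness_um: float = Field(10.0, gt=0)


class SyntheticSection(_Section):
    frame_interval_h: float = Field(3.0, gt=0)
    image_size_px: int = Field(1000, ge=64)
    background_sigma: float = Field(6.0, ge=0)
    speckle_count: int = Field(20, ge=0)
    curve_noise_sigma: float = Field(0.05, ge=0)


class PipelineConfig(_Section):
    """Validated top-level configuration with per-stage sections."""

    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"
    imaging: ImagingSection = Field(default_factory=ImagingSection)
    simulator: SimulatorSection = Field(default_factory=SimulatorSection)
    bridge: BridgeSection = Field(default_factory=BridgeSection)
    activity: ActivitySection = Field(default_factory=ActivitySection)
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline configuration.

    An empty file (or ``None``) yields all defaults.  Validation
    problems — unknown keys, out-of-range values, R >= G — are raised
    together in a single error.
    """
    if path is None:
        return PipelineConfig()
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml", "") \
        else json.loads(text or "{}")
    if data is None:
        data = {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    # dump to python objects, not JSON: YAML round-trips inf (".inf")
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
    return path


def _check_columns(frame: pd.DataFrame, expected: list[str],
                   what: str) -> None:
    missing = [c for c in expected if c not in frame.columns]
    extra = [c for c in frame.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{what}: missing columns {missing}, unexpected columns {extra}")


def write_growth_curve_csv(curve: GrowthCurve, path: str | Path) -> Path:
    path = Path(path)
    diameters = curve.diameters_um if curve.diameters_um is not None \
        else np.full(len(curve), np.nan)
    pd.DataFrame({
        "day": curve.times_days,
        "cell_count": curve.counts,
        "equiv_diameter_um": diameters,
    }).to_csv(path, index=False)
    return path


def read_growth_curve_csv(path: str | Path,
                          cell_diameter_um: float = 10.0) -> GrowthCurve:
    frame = pd.read_csv(path)
    _check_columns(frame, GROWTH_CURVE_COLUMNS, f"growth curve {path}")
    diameters = frame["equiv_diameter_um"].to_numpy()
    return GrowthCurve(
        times_days=frame["day"].to_numpy(),
        counts=frame["cell_count"].to_numpy(),
        cell_diameter_um=cell_diameter_um,
        diameters_um=None if np.isnan(diameters).all() else diameters,
    )


def write_snapshot_csv(state: SpheroidState, path: str | Path) -> Path:
    path = Path(path)
    n = state.n_particles
    nan = np.full(n, np.nan)
    pd.DataFrame({
        "id": np.arange(n),
        "x_um": state.positions[:, 0],
        "y_um": state.positions[:, 1],
        "z_um": state.positions[:, 2],
        "generation": state.generations,
        "cycle_age_min": state.cycle_age_min,
        "N": state.supply if state.supply is not None else nan,
        "density": state.density if state.density is not None else nan,
        "mobility": state.mobility if state.mobility is not None else nan,
    }).to_csv(path, index=False)
    return path


def read_snapshot_csv(path: str | Path, r0_um: float = 10.0,
                      time_min: float = 0.0) -> SpheroidState:
    frame = pd.read_csv(path)
    _check_columns(frame, SNAPSHOT_COLUMNS, f"snapshot {path}")
    def _optional(col: str) -> np.ndarray | None:
        values = frame[col].to_numpy(dtype=float)
        return None if np.isnan(values).all() else values
    return SpheroidState(
        positions=frame[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        generations=frame["generation"].to_numpy(dtype=int),
        cycle_age_min=frame["cycle_age_min"].to_numpy(dtype=float),
        time_min=time_min,
        r0_um=r0_um,
        supply=_optional("N"),
        density=_optional("density"),
        mobility=_optional("mobility"),
    )


def read_frames(
    source: str | Path,
    pixel_size_um: float,
    frame_interval_h: float | None = None,
    start_day: float = 2.0,
) -> list[FrameImage]:
    """Load a frame series from a sidecar CSV or a directory.

    A sidecar CSV has columns ``frame,path,day`` (paths relative to the
    CSV).  A directory is read in sorted filename order with frames
    spaced ``frame_interval_h`` apart from ``start_day``.
    """
    source = Path(source)
    frames: list[FrameImage] = []
    if source.is_dir():
        if frame_interval_h is None:
            raise ValueError("directory input needs frame_interval_h")
        paths = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff", ".png"))
        for i, p in enumerate(paths):
            frames.append(FrameImage(
                pixels=np.asarray(iio.imread(p)),
                pixel_size_um=pixel_size_um,
                timestamp_days=start_day + i * frame_interval_h / 24.0,
            ))
    else:
        table = pd.read_csv(source)
        _check_columns(table, ["frame", "path", "day"], f"sidecar {source}")
        for _, row in table.sort_values("day").iterrows():
            frames.append(FrameImage(
                pixels=np.asarray(iio.imread(source.parent / row["path"])),
                pixel_size_um=pixel_size_um,
                timestamp_days=float(row["day"]),
            ))
    if not frames:
        raise ValueError(f"no frames found in {source}")
    return frames


def write_frames(frames: list[FrameImage], out_dir: str | Path,
                 fmt: str = "png") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    rows = []
    for i, frame in enumerate(frames):
        p = out_dir / f"frame_{i:04d}.{fmt}"
        iio.imwrite(p, frame.pixels)
        paths.append(p)
        rows.append({"frame": i, "path": p.name, "day": frame.timestamp_days})
    pd.DataFrame(rows).to_csv(out_dir / "frames.csv", index=False)
    return paths
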