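"""Virtual inner proliferative activity from particle generations.

Each cellular particle carries a generation number (divisions since
the founding cell).  Comparing the per-generation census between two
consecutive simulated days identifies the generations that are no
longer turning over: a generation whose count is unchanged has *low*
virtual inner proliferative activity (quiescent), while any change
marks active division (*high*).  The cutoff generation g* is the top
of the contiguous run of unchanged generations counted from the
lowest; the low-activity ratio — the fraction of particles at
generation <= g* — corresponds to the quiescent-zone share of the
spheroid, the complement to the proliferating rim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import SpheroidState

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenerationCensus:
    """Particle counts per generation at one simulated day."""

    day: float
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def generations(self) -> list[int]:
        return sorted(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": self.generations,
             "count": [self.counts[g] for g in self.generations]}
        )


@dataclass(frozen=True)
class ActivityProfile:
    """Low/high activity labelling at a cutoff generation g*."""

    cutoff_generation: int
    low_ratio: float
    labels: np.ndarray  # per-particle "low"/"high"


def generation_census(state: SpheroidState, day: float | None = None
                      ) -> GenerationCensus:
    """Exact per-generation particle counts of a snapshot."""
    if state.n_particles < 1:
        raise ValueError("state has no particles")
    gens, counts = np.unique(state.generations, return_counts=True)
    return GenerationCensus(
        day=day if day is not None else state.time_min / 1440.0,
        counts={int(g): int(c) for g, c in zip(gens, counts)},
    )


def activity_cutoff(census_d: GenerationCensus,
                    census_d1: GenerationCensus) -> int:
    """Highest generation g* of the unchanged-count run from the bottom.

    g* is the largest g such that for every generation <= g the counts
    on the two days are identical (exact integer equality); the run
    must be contiguous from the lowest generation present.  If the two
    censuses agree everywhere no generation is still dividing and g*
    is the maximum generation (all particles low), with a warning.
    """
    all_gens = sorted(set(census_d.counts) | set(census_d1.counts))
    if not all_gens:
        raise ValueError("empty censuses")
    if census_d.counts == census_d1.counts:
        logger.warning(
            "censuses at days %s and %s are identical: no generation is "
            "dividing, all activity low", census_d.day, census_d1.day)
        return all_gens[-1]
    g_star = all_gens[0] - 1
    for g in all_gens:
        if census_d.counts.get(g, 0) == census_d1.counts.get(g, 0):
            g_star = g
        else:
            break
    return g_star


def low_activity_ratio(census: GenerationCensus, g_star: int) -> float:
    """Fraction of particles at generation <= g* (the quiescent share)."""
    total = census.total
    if total == 0:
        raise ValueError("empty census")
    low = sum(c for g, c in census.counts.items() if g <= g_star)
    return low / total


def label_particles(state: SpheroidState, g_star: int) -> np.ndarray:
    """Per-particle activity labels: 'low' for generation <= g*."""
    return np.where(state.generations <= g_star, "low", "high")


def cross_sections(
    state: SpheroidState,
    color_by: np.ndarray | None = None,
    slab_thickness_um: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Three orthogonal cross-sections through the spheroid centroid.

    Returns, per mid-plane ("xy", "xz", "yz"), the particles whose
    centres lie within half a slab thickness (default: one cell
    diameter) of the plane, with their in-plane coordinates, their
    generation, and the supplied colour value.
    """
    if state.n_particles < 1:
        raise ValueError("state has no particles")
    slab = slab_thickness_um if slab_thickness_um is not None else state.r0_um
    rel = state.positions - state.center
    sections = {}
    for name, (u, v, w) in {"xy": (0, 1, 2), "xz": (0, 2, 1),
                            "yz": (1, 2, 0)}.items():
        mask = np.abs(rel[:, w]) <= slab / 2.0
        frame = pd.DataFrame({
            "u_um": rel[mask, u],
            "v_um": rel[mask, v],
            "generation": state.generations[mask],
        })
        if color_by is not None:
            frame["color"] = np.asarray(color_by)[mask]
        sections[name] = frame
    return sections


def render_cross_sections(
    sections: dict[str, pd.DataFrame],
    out_path: str | Path,
    title: str = "",
    cell_diameter_um: float = 10.0,
) -> Path:
    """Render the three sections to one PNG (deterministic layout)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4), constrained_layout=True)
    for ax, (name, frame) in zip(axes, sorted(sections.items())):
        if "color" in frame.columns and frame["color"].dtype == object:
            colors = np.where(frame["color"] == "low", "#ffd27f", "#7f2704")
            ax.scatter(frame["u_um"], frame["v_um"], s=12, c=colors,
                       edgecolors="none")
        else:
            values = frame["color"] if "color" in frame.columns \
                else frame["generation"]
            sc = ax.scatter(frame["u_um"], frame["v_um"], s=12, c=values,
                            cmap="viridis", edgecolors="none")
            fig.colorbar(sc, ax=ax, shrink=0.8)
        ax.set_aspect("equal")
        ax.set_title(f"{name} plane")
        ax.set_xlabel("um")
        ax.set_ylabel("um")
    if title:
        fig.suptitle(title)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def quiescent_volume_ratio(inner_diameter_um: float,
                           outer_diameter_um: float) -> float:
    """Quiescent-zone share of the spheroid volume: (inner/outer)^3.

    Models the quiescent core and the whole spheroid as concentric
    spheres fitted to a section; the proliferation-zone ratio is the
    complement, 1 - (inner/outer)^3.
    """
    if outer_diameter_um <= 0:
        raise ValueError("outer diameter must be positive")
    if not 0 <= inner_diameter_um <= outer_diameter_um:
        raise ValueError("need 0 <= inner <= outer diameter")
    return (inner_diameter_um / outer_diameter_um) ** 3
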