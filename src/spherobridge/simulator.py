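"""Lattice-free cellular-particle simulation of spheroid growth.

A spheroid in silico is a set of cellular particles (10 um spheres by
default) moving freely in 3-D under pairwise attraction/repulsion

    F(r) = k (1 - r / (R r0)) (1 - r / (G r0)),        r < G r0

whose two roots R r0 (equilibrium) and G r0 (interaction range) keep
the cluster near a hexagonal close-packed structure with kissing
number 12.  Growth sources (nutrients + oxygen, one lumped species)
come from a finite local budget Q0: the residual index

    R_t = 1 - sum_k C_k / Q0

is delivered at the spheroid surface and diffuses inward with fixed
per-particle consumption, d R/d t = D d^2R/dx^2 - alpha, never beyond a
maximum depth (200 um by default).  Each particle's cell-cycle length
is set by a Monod-type supply term and a crowding term,

    T_z = (1/mu_max) * (1 + (Kc/N_z)^2) / (1 + Kc^2) * (1 + Ke D_z / P_z)

so that T_z attains the minimum cycle time 1/mu_max at full supply
(N_z = 1) and zero density.  On division the parent is replaced by two
daughters, both carrying generation = parent generation + 1; the
generation number records how many divisions preceded a particle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

MOBILITY_EPS = 1e-3  # clamp for the central particle's mobility


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message lists every problem."""


class CoincidentParticlesError(ValueError):
    """Two particles at identical positions (force direction undefined)."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceParams:
    """Pairwise force constants; defaults balance a near-HCP packing."""

    k: float = 0.005
    R: float = 1.106
    G: float = 1.5
    r0_um: float = 10.0

    def __post_init__(self) -> None:
        errors = []
        if self.k <= 0:
            errors.append("k must be > 0")
        if not (0 < self.R < self.G):
            errors.append("need 0 < R < G")
        if self.r0_um <= 0:
            errors.append("r0_um must be > 0")
        if errors:
            raise ConfigurationError("; ".join(errors))

    @property
    def equilibrium_um(self) -> float:
        return self.R * self.r0_um

    @property
    def cutoff_um(self) -> float:
        return self.G * self.r0_um


@dataclass(frozen=True)
class DiffusionParams:
    """Growth-source diffusion settings.

    ``alpha_over_D_mm2`` is the consumption-to-diffusion ratio in
    mm^-2 (distances inside the diffusion equation are in mm); the
    source never penetrates deeper than ``max_depth_um`` from the
    spheroid surface.
    """

    alpha_over_D_mm2: float = 20.0
    max_depth_um: float = 200.0
    shell_width_um: float = 5.0

    def __post_init__(self) -> None:
        if self.max_depth_um <= 0 or self.shell_width_um <= 0:
            raise ConfigurationError("depths and shell widths must be > 0")


@dataclass(frozen=True)
class CycleParams:
    """Cell-cycle control: minimum cycle plus two relaxation coefficients."""

    min_cycle_min: float = 18.0 * 60.0
    Kc: float = 1.0
    Ke: float = 1.0

    def __post_init__(self) -> None:
        if self.min_cycle_min <= 0 or self.Kc <= 0 or self.Ke <= 0:
            raise ConfigurationError("cycle parameters must be > 0")

    @property
    def mu_max(self) -> float:
        return 1.0 / self.min_cycle_min


@dataclass
class SimulationConfig:
    """Full configuration of a growth run.

    ``capacity`` is the growth-source budget Q0/c in particle-minutes
    of supply (``inf`` = unlimited).  ``eta_um`` is the overdamped
    mobility constant (displacement per unit net force per step) and
    ``max_step_frac`` caps any displacement at that fraction of r0.
    """

    total_days: float = 5.0
    dt_min: float = 1.0
    cell_diameter_um: float = 10.0
    k: float = 0.005
    R: float = 1.106
    G: float = 1.5
    max_depth_um: float = 200.0
    alpha_over_D_mm2: float = 20.0
    shell_width_um: float = 5.0
    min_cycle_h: float = 18.0
    capacity: float = math.inf
    Kc: float = 1.0
    Ke: float = 1.0
    seed: int = 0
    n_initial: int = 1
    initial_age_spread_h: float = 0.0
    snapshot_interval_h: float = 3.0
    eta_um: float = 1000.0
    max_step_frac: float = 0.2

    def validate(self) -> None:
        errors = []
        if self.total_days < 0:
            errors.append("total_days must be >= 0")
        if self.dt_min <= 0:
            errors.append("dt_min must be > 0")
        if self.cell_diameter_um <= 0:
            errors.append("cell_diameter_um must be > 0")
        if not (0 < self.R < self.G):
            errors.append("need 0 < R < G")
        if self.k <= 0:
            errors.append("k must be > 0")
        if self.min_cycle_h <= 0:
            errors.append("min_cycle_h must be > 0")
        if self.capacity <= 0:
            errors.append("capacity must be > 0 (use inf for unlimited)")
        if self.Kc <= 0 or self.Ke <= 0:
            errors.append("Kc and Ke must be > 0")
        if self.n_initial < 1:
            errors.append("n_initial must be >= 1")
        if self.snapshot_interval_h <= 0:
            errors.append("snapshot_interval_h must be > 0")
        if errors:
            raise ConfigurationError("; ".join(errors))

    @property
    def force(self) -> ForceParams:
        return ForceParams(k=self.k, R=self.R, G=self.G,
                           r0_um=self.cell_diameter_um)

    @property
    def diffusion(self) -> DiffusionParams:
        return DiffusionParams(alpha_over_D_mm2=self.alpha_over_D_mm2,
                               max_depth_um=self.max_depth_um,
                               shell_width_um=self.shell_width_um)

    @property
    def cycle(self) -> CycleParams:
        return CycleParams(min_cycle_min=self.min_cycle_h * 60.0,
                           Kc=self.Kc, Ke=self.Ke)


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class SourceBudget:
    """Finite growth-source budget in particle-minutes of supply."""

    capacity: float = math.inf
    consumed: float = 0.0

    @property
    def residual_index(self) -> float:
        return residual_source_index(self.consumed, self.capacity)


def residual_source_index(consumed: float, capacity: float) -> float:
    """R_t = max(0, 1 - consumed/Q0); 1 when the budget is unlimited."""
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    if math.isinf(capacity):
        return 1.0
    return max(0.0, 1.0 - consumed / capacity)


@dataclass
class SpheroidState:
    """All particles of one spheroid at a single simulated time.

    Per-particle diagnostic arrays (supply N_z, density D_z, mobility
    P_z, cycle length T_z) hold the values computed in the most recent
    step.
    """

    positions: np.ndarray            # (n, 3) um
    generations: np.ndarray          # (n,) int
    cycle_age_min: np.ndarray        # (n,) minutes since birth
    time_min: float = 0.0
    budget: SourceBudget = field(default_factory=SourceBudget)
    r0_um: float = 10.0
    supply: np.ndarray | None = None
    density: np.ndarray | None = None
    mobility: np.ndarray | None = None
    cycle_length_min: np.ndarray | None = None
    source_profile: np.ndarray | None = None  # warm start for diffusion

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def center(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def center_distances(self) -> np.ndarray:
        return np.linalg.norm(self.positions - self.center, axis=1)

    @property
    def radius_um(self) -> float:
        """Geometric radius: farthest particle centre + one cell radius."""
        return float(self.center_distances.max()) + self.r0_um / 2.0

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um

    def copy(self) -> "SpheroidState":
        return SpheroidState(
            positions=self.positions.copy(),
            generations=self.generations.copy(),
            cycle_age_min=self.cycle_age_min.copy(),
            time_min=self.time_min,
            budget=SourceBudget(self.budget.capacity, self.budget.consumed),
            r0_um=self.r0_um,
            supply=None if self.supply is None else self.supply.copy(),
            density=None if self.density is None else self.density.copy(),
            mobility=None if self.mobility is None else self.mobility.copy(),
            cycle_length_min=(None if self.cycle_length_min is None
                              else self.cycle_length_min.copy()),
            source_profile=(None if self.source_profile is None
                            else self.source_profile.copy()),
        )


def hcp_lattice(spacing_um: float, max_radius_um: float) -> np.ndarray:
    """Sites of a hexagonal close-packed lattice within a ball.

    ABAB-stacked triangular layers with nearest-neighbour distance
    ``spacing_um``; one site sits at the origin.  Returns sites sorted
    by distance from the origin.
    """
    a = spacing_um
    row = a * math.sqrt(3.0) / 2.0
    layer = a * math.sqrt(2.0 / 3.0)
    n = int(math.ceil(max_radius_um / min(row, layer))) + 2
    pts = []
    for kz in range(-n, n + 1):
        z = kz * layer
        # B layers shift to the triangle centroid of the A layer
        ox, oy = (a / 2.0, a / (2.0 * math.sqrt(3.0))) if kz % 2 else (0.0, 0.0)
        for j in range(-n, n + 1):
            y = j * row + oy
            for i in range(-n, n + 1):
                x = i * a + (a / 2.0 if j % 2 else 0.0) + ox
                if x * x + y * y + z * z <= max_radius_um ** 2:
                    pts.append((x, y, z))
    pts_arr = np.array(pts, dtype=float)
    order = np.argsort(np.linalg.norm(pts_arr, axis=1), kind="stable")
    return pts_arr[order]


def initial_state(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> SpheroidState:
    """Starting state: one particle at the origin, or a relaxed HCP
    cluster of ``n_initial`` particles with generation ceil(log2 n).

    ``initial_age_spread_h`` > 0 draws each starting particle's cycle
    age uniformly from [0, spread) (an asynchronous population, as in
    a cluster partway through an experiment); 0 starts all ages at 0.
    """
    config.validate()
    n0 = config.n_initial
    if n0 == 1:
        positions = np.zeros((1, 3))
    else:
        spacing = config.R * config.cell_diameter_um
        radius = spacing * (2.0 + (3.0 * n0) ** (1.0 / 3.0))
        sites = hcp_lattice(spacing, radius)
        while len(sites) < n0:  # pragma: no cover - generous radius above
            radius *= 1.5
            sites = hcp_lattice(spacing, radius)
        positions = sites[:n0]
    g0 = 0 if n0 == 1 else int(math.ceil(math.log2(n0)))
    if config.initial_age_spread_h > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        ages = rng.uniform(0.0, config.initial_age_spread_h * 60.0, size=n0)
    else:
        ages = np.zeros(n0)
    return SpheroidState(
        positions=positions,
        generations=np.full(n0, g0, dtype=int),
        cycle_age_min=ages,
        budget=SourceBudget(capacity=config.capacity),
        r0_um=config.cell_diameter_um,
    )


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def pair_force(r, params: ForceParams):
    """Signed force magnitude between two particles at distance r (um).

    Positive = repulsion, negative = attraction; zero at the
    equilibrium distance R r0 and cut off to zero at and beyond the
    attraction range G r0.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise CoincidentParticlesError("pair distance must be > 0")
    f = params.k * (1.0 - r_arr / (params.R * params.r0_um)) \
        * (1.0 - r_arr / (params.G * params.r0_um))
    f = np.where(r_arr >= params.G * params.r0_um, 0.0, f)
    return float(f) if np.isscalar(r) else f


def _neighbor_pairs(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """All particle pairs closer than ``cutoff`` (spatial-tree search;
    identical in output to the brute-force all-pairs scan)."""
    if len(positions) < 2:
        return np.empty((0, 2), dtype=np.intp)
    tree = cKDTree(positions)
    return tree.query_pairs(cutoff, output_type="ndarray")


def relax_positions(
    positions: np.ndarray,
    force: ForceParams,
    eta_um: float,
    max_step_um: float,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """One overdamped relaxation move: dx_i = eta * sum_j F_ij u_ij,
    each displacement capped at ``max_step_um``."""
    if pairs is None:
        pairs = _neighbor_pairs(positions, force.cutoff_um)
    if len(pairs) == 0:
        return positions
    i, j = pairs[:, 0], pairs[:, 1]
    diff = positions[i] - positions[j]
    dist = np.linalg.norm(diff, axis=1)
    if np.any(dist == 0):
        raise CoincidentParticlesError("coincident particles in relaxation")
    f = pair_force(dist, force)
    push = (eta_um * f / dist)[:, None] * diff  # along j -> i for repulsion
    disp = np.zeros_like(positions)
    np.add.at(disp, i, push)
    np.add.at(disp, j, -push)
    norms = np.linalg.norm(disp, axis=1)
    over = norms > max_step_um
    if np.any(over):
        disp[over] *= (max_step_um / norms[over])[:, None]
    return positions + disp


# ---------------------------------------------------------------------------
# growth-source diffusion
# ---------------------------------------------------------------------------

def relax_source_profile(
    surface_value: float,
    n_shells: int,
    shell_width_um: float,
    alpha_over_D_mm2: float,
    occupied: np.ndarray | None = None,
    init: np.ndarray | None = None,
    pseudo_dt: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Quasi-steady radial source profile by explicit finite differences.

    Nodes sit at depths j*h (j = 0..n_shells) from the surface; node 0
    is pinned to ``surface_value``, the deep end has a zero-flux
    boundary, occupied shells consume at rate alpha, and the profile is
    clamped at zero.  Iteration uses pseudo-time in units where D = 1;
    the stable pseudo-step is h^2/2 and a larger explicit ``pseudo_dt``
    is rejected.
    """
    h = shell_width_um / 1000.0  # distances in the PDE are in mm
    dt_max = h * h / 2.0
    if pseudo_dt is None:
        pseudo_dt = dt_max
    elif pseudo_dt > dt_max:
        raise ConfigurationError(
            f"pseudo_dt {pseudo_dt:g} unstable for shell width "
            f"{shell_width_um:g} um; maximal stable value is {dt_max:g}"
        )
    n_nodes = n_shells + 1
    if occupied is None:
        occupied = np.ones(n_nodes, dtype=bool)
    profile = (np.full(n_nodes, surface_value) if init is None
               else np.asarray(init, dtype=float).copy())
    if len(profile) != n_nodes:
        profile = np.full(n_nodes, surface_value)
    profile[0] = surface_value
    sink = pseudo_dt * alpha_over_D_mm2 * occupied[1:].astype(float)
    coef = pseudo_dt / (h * h)
    check_every = 16
    padded = np.empty(n_nodes + 1)
    previous = profile.copy()
    for it in range(max_iter):
        padded[:-1] = profile
        padded[-1] = profile[-1]  # zero-flux deep end
        lap = padded[:-2] - 2.0 * profile[1:] + padded[2:]
        np.maximum(profile[1:] + coef * lap - sink, 0.0, out=profile[1:])
        if (it + 1) % check_every == 0:
            if np.abs(profile - previous).max() < tol * check_every:
                break
            previous[:] = profile
    return profile


def diffuse_source(
    state: SpheroidState,
    params: DiffusionParams,
    r_t: float | None = None,
    tol: float = 1e-9,
    max_iter: int | None = None,
    depth_um: np.ndarray | None = None,
) -> np.ndarray:
    """Per-particle supplied source N_z from the radial diffusion profile.

    Depth is measured from the outermost particle inward; N_z is zero
    beyond the maximum diffusion depth and non-increasing with depth.
    The shell profile is updated by explicit finite differences,
    warm-started from the profile stored on the state; a cold start is
    iterated to the quasi-steady fixed point, a warm start for a
    bounded number of sweeps (the boundary value moves slowly between
    steps, so the profile tracks the steady state closely).
    """
    if r_t is None:
        r_t = state.budget.residual_index
    if depth_um is None:
        dists = state.center_distances
        depth_um = dists.max() - dists
    if r_t <= 0.0:
        state.supply = np.zeros(state.n_particles)
        state.source_profile = None
        return state.supply
    grid_depth = min(float(depth_um.max()), params.max_depth_um)
    n_shells = max(2, int(math.ceil(grid_depth / params.shell_width_um)) + 1)
    init = state.source_profile
    if init is not None and len(init) != n_shells + 1:
        # grid grew with the spheroid: extend the warm start inward
        if len(init) < n_shells + 1:
            init = np.concatenate([
                init, np.full(n_shells + 1 - len(init), init[-1])
            ])
        else:
            init = init[: n_shells + 1]
    if max_iter is None:
        max_iter = 96 if init is not None else 200_000
    profile = relax_source_profile(
        surface_value=r_t,
        n_shells=n_shells,
        shell_width_um=params.shell_width_um,
        alpha_over_D_mm2=params.alpha_over_D_mm2,
        init=init,
        tol=tol,
        max_iter=max_iter,
    )
    nodes_um = np.arange(n_shells + 1) * params.shell_width_um
    n_z = np.interp(depth_um, nodes_um, profile, right=0.0)
    n_z[depth_um > params.max_depth_um] = 0.0
    state.supply = n_z
    state.source_profile = profile
    return n_z


# ---------------------------------------------------------------------------
# density, mobility, cell cycle
# ---------------------------------------------------------------------------

def compute_density(state: SpheroidState, force: ForceParams) -> np.ndarray:
    """Neighbour count D_z per particle: others within the attraction
    range G r0 (12 for an interior particle of a perfect HCP cluster)."""
    counts = np.zeros(state.n_particles, dtype=int)
    pairs = _neighbor_pairs(state.positions, force.cutoff_um)
    if len(pairs):
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    state.density = counts
    return counts


def compute_mobility(state: SpheroidState, eps: float = MOBILITY_EPS) -> np.ndarray:
    """Mobility P_z: centre distance over the outermost particle's
    distance, clamped to [eps, 1] (eps guards the central particle)."""
    dists = state.center_distances
    r_max = dists.max()
    if r_max == 0:
        p = np.full(state.n_particles, eps)
    else:
        p = np.clip(dists / r_max, eps, 1.0)
    state.mobility = p
    return p


def cell_cycle_time(n_z, d_z, p_z, cp: CycleParams):
    """Cycle length T_z (minutes) from supply, density and mobility.

    T_z = (1/mu_max) * (1 + (Kc/N)^2)/(1 + Kc^2) * (1 + Ke D/P);
    infinite (quiescent, no division) when the supply N_z is zero, and
    never below the minimum cycle time 1/mu_max.
    """
    n_arr = np.asarray(n_z, dtype=float)
    d_arr = np.asarray(d_z, dtype=float)
    p_arr = np.asarray(p_z, dtype=float)
    with np.errstate(divide="ignore"):
        supply_term = (1.0 + (cp.Kc / n_arr) ** 2) / (1.0 + cp.Kc ** 2)
    env_term = 1.0 + cp.Ke * d_arr / p_arr
    t_z = cp.min_cycle_min * supply_term * env_term
    t_z = np.where(n_arr <= 0.0, np.inf, np.maximum(t_z, cp.min_cycle_min))
    return float(t_z) if np.isscalar(n_z) else t_z


def divide_particle(
    position: np.ndarray, generation: int, r0_um: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace a parent with two daughters at +/- r0/4 along a random
    direction; both daughters carry generation + 1 and cycle age 0."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    offset = (r0_um / 4.0) * u
    return position + offset, position - offset


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def step(
    state: SpheroidState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SpheroidState:
    """Advance the state by one time step (in place; returns the state).

    Order: (1) residual budget and source diffusion, (2) cycle advance
    and divisions, (3) overdamped position relaxation.  Consumption of
    one unit per supplied particle per minute is accrued to the budget.
    """
    dt = config.dt_min
    force = config.force
    dists = state.center_distances
    r_max = float(dists.max())
    pairs = _neighbor_pairs(state.positions, force.cutoff_um)

    # (1) growth-source transport
    n_z = diffuse_source(state, config.diffusion, depth_um=r_max - dists)
    supplied = int(np.count_nonzero(n_z > 0.0))
    state.budget.consumed += supplied * dt

    # (2) cell cycle and division
    d_z = np.zeros(state.n_particles, dtype=int)
    if len(pairs):
        np.add.at(d_z, pairs[:, 0], 1)
        np.add.at(d_z, pairs[:, 1], 1)
    state.density = d_z
    p_z = np.clip(dists / r_max, MOBILITY_EPS, 1.0) if r_max > 0 \
        else np.full(state.n_particles, MOBILITY_EPS)
    state.mobility = p_z
    t_z = cell_cycle_time(n_z, d_z, p_z, config.cycle)
    state.cycle_length_min = t_z
    state.cycle_age_min += dt
    dividing = np.nonzero((state.cycle_age_min >= t_z) & (n_z > 0.0))[0]
    if len(dividing):
        keep = np.ones(state.n_particles, dtype=bool)
        keep[dividing] = False
        new_pos, new_gen = [], []
        for idx in dividing:
            d1, d2 = divide_particle(state.positions[idx],
                                     int(state.generations[idx]),
                                     config.cell_diameter_um, rng)
            new_pos.extend([d1, d2])
            new_gen.extend([state.generations[idx] + 1] * 2)
        state.positions = np.vstack([state.positions[keep],
                                     np.asarray(new_pos)])
        state.generations = np.concatenate([state.generations[keep],
                                            np.asarray(new_gen, dtype=int)])
        state.cycle_age_min = np.concatenate([state.cycle_age_min[keep],
                                              np.zeros(2 * len(dividing))])
        state.supply = state.density = state.mobility = None
        state.cycle_length_min = None
        pairs = None  # particle set changed: rebuild neighbour pairs

    # (3) mechanical relaxation
    state.positions = relax_positions(
        state.positions, force, config.eta_um,
        config.max_step_frac * config.cell_diameter_um,
        pairs=pairs,
    )
    state.time_min += dt
    return state


@dataclass
class Trajectory:
    """Snapshots of a growth run plus the derived growth curve n(t)."""

    config: SimulationConfig
    snapshots: list[SpheroidState]

    @property
    def days(self) -> np.ndarray:
        return np.array([s.time_min / 1440.0 for s in self.snapshots])

    @property
    def n_particles(self) -> np.ndarray:
        return np.array([s.n_particles for s in self.snapshots])

    @property
    def diameters_um(self) -> np.ndarray:
        return np.array([s.diameter_um for s in self.snapshots])

    @property
    def residual_index(self) -> np.ndarray:
        return np.array([s.budget.residual_index for s in self.snapshots])

    @property
    def final_state(self) -> SpheroidState:
        return self.snapshots[-1]

    def index_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.days,
            "n_particles": self.n_particles,
            "diameter_um": self.diameters_um,
            "R_t": self.residual_index,
        })

    def state_at_day(self, day: float) -> SpheroidState:
        """Snapshot closest to the requested day."""
        return self.snapshots[int(np.argmin(np.abs(self.days - day)))]


def run_simulation(
    config: SimulationConfig,
    start_day: float = 0.0,
) -> Trajectory:
    """Run a full growth simulation; deterministic for a fixed seed.

    Snapshots (full state copies) are stored every
    ``snapshot_interval_h`` hours, including the initial and final
    states.  ``start_day`` offsets the reported times, for runs that
    begin from an already-grown cluster partway through an experiment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = initial_state(config, rng=rng)
    state.time_min = start_day * 1440.0
    n_steps = int(round(config.total_days * 1440.0 / config.dt_min))
    snap_every = max(1, int(round(config.snapshot_interval_h * 60.0
                                  / config.dt_min)))
    snapshots = [state.copy()]
    for k in range(1, n_steps + 1):
        step(state, config, rng)
        if k % snap_every == 0 or k == n_steps:
            snapshots.append(state.copy())
    return Trajectory(config=config, snapshots=snapshots)


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

def radial_profiles(
    state: SpheroidState,
    params: DiffusionParams | None = None,
    shell_width_um: float | None = None,
    force: ForceParams | None = None,
) -> pd.DataFrame:
    """Per-shell density and growth-source profiles.

    Shells are concentric annuli of the attraction range G r0 by
    default (the regions where the attractive force acts).  A particle
    belongs to every shell its body overlaps, so ``n_particles`` per
    shell can exceed the kissing number; ``cell_density`` is the mean
    neighbour count D_z of those particles, which approaches 12 in the
    packed interior and falls toward the surface.  ``source_index`` is
    the diffusion-profile value at the shell centre.
    """
    force = force or ForceParams(r0_um=state.r0_um)
    params = params or DiffusionParams()
    width = shell_width_um or force.cutoff_um
    dists = state.center_distances
    radius = state.radius_um
    n_shells = max(1, int(math.ceil(radius / width)))
    d_z = state.density if state.density is not None \
        else compute_density(state, force)
    n_z = state.supply if state.supply is not None \
        else diffuse_source(state, params)
    half = state.r0_um / 2.0
    rows = []
    depth_nodes = np.arange(len(state.source_profile)) * params.shell_width_um \
        if state.source_profile is not None else None
    max_dist = dists.max()
    for s in range(n_shells):
        lo, hi = s * width, (s + 1) * width
        overlap = (dists + half > lo) & (dists - half < hi)
        count = int(np.count_nonzero(overlap))
        mid = (lo + hi) / 2.0
        depth_mid = max(max_dist - mid, 0.0)
        if depth_nodes is not None:
            src = float(np.interp(depth_mid, depth_nodes,
                                  state.source_profile, right=0.0))
            if depth_mid > params.max_depth_um:
                src = 0.0
        else:
            src = float(n_z[overlap].mean()) if count else 0.0
        rows.append({
            "shell_inner_um": lo,
            "shell_outer_um": hi,
            "n_particles": count,
            "cell_density": float(d_z[overlap].mean()) if count else 0.0,
            "source_index": src,
        })
    return pd.DataFrame(rows)


def growth_curve_from_trajectory(traj: Trajectory) -> "np.ndarray":
    """Convenience (day, n_particles) array of the simulated curve."""
    return np.column_stack([traj.days, traj.n_particles])
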