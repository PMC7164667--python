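# Methods

`spherobridge` replicates individual spheroid growth *in silico* from
time-lapse images of the same spheroid *in vitro*, and uses the
replica's per-particle division history to label the quiescent and
proliferating zones.  This note records the models, the parameter
choices, the numerical decisions, and what the synthetic fixtures do
and do not establish.

## From images to cell counts

Each frame (8-bit grayscale, one spheroid, nominally 1000 × 1000 px at
3 h intervals) is thresholded with Otsu's method — parameter-free and
adequate for a roughly bimodal phase-contrast histogram — followed by
binary opening and closing with a 3 px disc, hole filling, and
retention of the largest connected component.  Whether the object is
dark on bright (the default, matching the usual phase-contrast
appearance) or inverted is a configuration flag; the pixel size
(default 0.65 µm/px) must be supplied because it depends on the
optics.

The segmented region is replaced by the circle of equal area,
`r = p · sqrt(area/π)` for pixel size `p`, and the spheroid is treated
as the sphere of that diameter `D`.  The cell count is bounded by
sphere packings of the single-cell diameter `d` (itself estimated from
one- or two-cell-stage frames, area halved for two cells):

    lower = floor[(D/d)³ · π/6]          (simple cubic, ρ ≈ 0.5236)
    upper = floor[(D/d)³ · π/(3√2)]      (FCC,          ρ ≈ 0.7405)

The FCC count is the point estimate e(t).  The ratio of the two
densities is exactly 2^(−1/2) before flooring; counts are floored and
clamped to ≥ 1 because cells are whole.  A Monte-Carlo random-packing
oracle (iterative overlap-removal from an overfilled start, which
settles near the empirical random-close-packing density ≈ 0.64)
confirms that physical packings fall between the two lattice bounds.

## Growth-curve summary and the feature plane

Each curve is fitted with the five-parameter Richards (generalized
logistic) curve

    y(x) = A + C / (1 + T e^(−B(x−M)))^(1/T)

by bounded nonlinear least squares (B, C, T > 0), evaluated in log
space to avoid overflow far from the inflection.  The default start is
deterministic: A = min count, C = range, M = time of steepest
numerical gradient, B = 4·max-slope/C, T = 1.

Cohort fits are centred and scaled per parameter (population SD; the
convention is stored in the normalization record so projections
round-trip exactly; a zero-variance parameter is centred only, with a
warning) and decomposed by PCA.  Eigenvector signs are fixed so that
the loading of C on component 1 and of B on component 2 are
non-negative, giving reproducible quadrant labels.  Points on a
quadrant axis go to the lower-numbered adjacent quadrant.  A cohort
whose normalized covariance has rank < 2 is rejected rather than given
a degenerate second axis.

## The particle simulation

Cellular particles (diameter r0 = 10 µm) move freely in 3-D under the
pairwise force

    F(r) = k (1 − r/(R·r0)) (1 − r/(G·r0)),   k = 0.005, R = 1.106, G = 1.5

repulsive below the equilibrium distance R·r0 = 11.06 µm, attractive
up to the cutoff G·r0 = 15 µm, and zero beyond (the polynomial turns
positive again past G·r0, which is unphysical, so the interaction is
truncated there).  These constants balance a near-hexagonal
close-packed cluster: at equilibrium spacing an interior particle has
exactly the kissing number 12 of neighbours within the cutoff, and the
second HCP shell at √2 · 11.06 ≈ 15.64 µm stays outside it.  Motion is
overdamped: per 1-minute step each particle moves η · ΣF·û (η =
1000 µm per unit force), capped at 0.2·r0, which relaxes a jittered
cluster back to equilibrium spacing within ~100 steps and is stable at
the default step.

Growth sources (nutrients and oxygen, lumped) form a finite local
budget.  With cumulative consumption C_k against capacity Q0, the
residual index R_t = 1 − ΣC_k/Q0 (clamped at 0) is delivered at the
spheroid surface and diffuses inward with fixed per-particle
consumption:

    ∂R/∂t = D ∂²R/∂x² − α,   α/D = 20 mm⁻²

solved on a radial shell grid (5 µm shells by default) by explicit
finite differences with the surface shell pinned to R_t, a zero-flux
deep boundary, clamping at zero, and no supply beyond 200 µm from the
surface.  Distances inside the equation are in mm, so the penetration
depth sqrt(2·R_t·D/α) is ≤ 316 µm, consistent with the 200 µm cap.
Within a step the profile is iterated toward its fixed point
(warm-started between steps, since the boundary value drifts slowly);
the fixed point reproduces the closed-form parabolic profile
R_s − (α/2D)·x·(2L − x) to a few parts in 10⁴ on a 200-shell grid.
Consumption is accounted as one unit per supplied particle per minute,
so the capacity is configured in particle-minutes; the per-run default
is chosen so the budget runs out mid-run, which is what makes growth
plateau.

Each particle's cycle length couples a Monod-type supply term to a
crowding term:

    T_z = (1/µ_max) · (1 + (Kc/N_z)²)/(1 + Kc²) · (1 + Ke·D_z/P_z)

with supply N_z (the diffusion profile at the particle's depth),
density D_z (neighbours within the attraction cutoff), mobility P_z
(centre distance over the outermost particle's distance, clamped to
[10⁻³, 1] to protect the central particle), and µ_max set by the
minimum cycle time (default 18 h).  The printed form of this
expression in the source material is typographically garbled; this
arrangement is the canonical reconstruction in which T_z attains the
minimum cycle exactly at full supply and zero density, the supply term
is a squared Monod-type saturation, and the environment term grows
with crowding and falls with mobility.  It is isolated in one function
so alternative arrangements can be swapped; the property tests rely
only on the minimum and on monotonicity.  N_z = 0 means quiescence
(T_z = ∞), never death — the particle count never decreases.

On division the parent is replaced by two daughters at ±r0/4 along a
seeded random direction, both with generation = parent + 1 and cycle
age 0.  A run from n0 > 1 particles starts from the n0 innermost sites
of an HCP lattice at equilibrium spacing with generation ⌈log₂ n0⌉, so
generation numbers approximate divisions since seeding.  Initial cycle
ages are 0 by default (a lone founder then divides at exactly 18 h);
`initial_age_spread_h` draws them uniformly instead, which is the
realistic choice for a cluster captured mid-experiment — a
synchronized start stalls the population for a full cycle and the
plateau detector reads that lag as an initial plateau.

Every step performs, in order: source update and diffusion, cycle
advance and divisions, mechanical relaxation.  Neighbour search uses a
spatial tree whose pair list is tested to be identical to the
brute-force all-pairs scan.  All randomness (initial ages, division
directions) flows from a single integer seed; runs are bit-reproducible.

## Bridging simulation to experiment

The two relaxation coefficients are the only fitted quantities.  The
mismatch between the estimated curve e(t) and the simulated particle
count n(t) is

    f(Kc, Ke) = Σ_t ((log₁₀ e(t) − log₁₀ n(t)) / log₁₀ e(t))²

over estimated points from day 4 (earlier frames fluctuate while the
aggregate is a few cells) with e(t) ≥ 2, simulated counts linearly
interpolated in count (counts are near piecewise-linear at 3 h
resolution).  The log base is a recorded convention; the reference
procedure left it unstated.

Minimisation is budgeted and derivative-free, in the spirit of the
~15 manual evaluations of the original procedure, but staged to match
the model's structure.  The two coefficients trade off along a
shallow valley — both lengthen the cycle — which defeats a plain
simplex search: the objective is piecewise-constant at small particle
counts (division events are discrete), a simplex started on a flat
plateau collapses without moving, and one that reaches the valley
parks anywhere along it.  However, the two coefficients control
different parts of the curve — Ke the crowding-limited early phase,
Kc the source-limited approach to plateau — and the mean signed
log-bias between simulated and estimated counts over a window is
monotone decreasing in either coefficient (more braking, fewer
cells), which turns each into a 1-D root-finding problem.  The search
therefore (1) bisects log Ke against the leading ~35% of the curve,
probing with an unlimited source budget so the supply term is pinned
at saturation and Kc is exactly inert (probing with the real budget
leaves a residual Kc imprint on the early window that biases Ke low
and lets Kc over-compensate); (2) bisects log Kc against the
remainder of the curve under the real budget at the chosen Ke;
(3) repeats both bisections with narrowed brackets to absorb the
remaining coupling; and (4) polishes the pair jointly with
Nelder-Mead on (log Kc, log Ke), restarted with a shrinking simplex
while evaluations remain.  The configurable start defaults to (1, 1);
order-one coefficients already sit deep in the slow regime, so the
bisection brackets extend downward from it.

The plateau day of a curve is the first grid time whose forward 1-day
window shows a relative increase below 1% (threshold configurable);
values one day ahead are interpolated on the curve's own grid, so
plateau days inherit the grid resolution (eighths of a day at 3 h).
This operationalizes a quantity the reference material reports without
stating a rule; a curve that is still rising at the end of its range
has no plateau day.

## Virtual inner proliferative activity

Comparing per-generation particle censuses between consecutive days,
the cutoff g* is the top of the contiguous run (from the lowest
generation) of generations whose counts are exactly equal on both days
— counts are integers and stasis means no division, so equality is
exact, and a single changed generation breaks the run.  Particles at
generation ≤ g* are labelled low-activity (quiescent); the low-activity
ratio is their fraction of the earlier day's census.  When the two
censuses agree everywhere, nothing is dividing and the whole spheroid
is quiescent (g* = max generation, with a warning).  Cross-sections
through the centroid (slab of one cell diameter) visualise the labels;
the concentric-sphere helper converts an inner/outer diameter ratio
into a quiescent volume share (inner/outer)³.

## Synthetic fixtures and their limits

No public archive of the assumed acquisition exists, so fixtures are
generated: a Richards curve drives counts (lognormal noise, σ = 0.05
by default), counts invert through the FCC estimate to a disc radius,
and discs are rendered with Gaussian background noise (σ = 6 grey
levels) and isolated speckles on the imaging module's default
polarity.  Cohorts draw B, C, T lognormally and M normally around
values that plateau at a few thousand cells near day 8–11, the scale
of small spheroids grown over two weeks.  The generators are
deterministic in (spec, seed).

The fixtures validate the pipeline's plumbing and estimators, not the
microscope: discs have no phase halo, no focus drift, no debris, and
one object per frame; passing tests show the analysis recovers what
the generator embedded, not that segmentation is robust to real
optical artefacts.

## Scaled-down study sizes

The self-consistency studies run at desk scale: coefficient recovery
grows a 48-particle cluster for 7.5 simulated days (to ~150
particles) under a 1.3 × 10⁶ particle-minute budget with truth
(Kc, Ke) = (0.5, 0.1), and the ordering study compares 16-particle
runs at capacities 2.5 × 10⁵ vs 6 × 10⁵ over 5.5 days.  Both recovery
choices are identifiability-driven: with fewer particles the discrete
division sequence is literally identical across distinct coefficient
pairs, leaving a flat ridge in f, and a run whose source does not
exhaust inside the window lacks the full plateau whose onset pins Kc.
Full-scale runs (~10⁴ particles over 20 days) use the same code path;
nothing in the implementation depends on the reduced size.

## Known limitations

- No cell death or necrotic-core mass loss; the quiescent core is
  inferred from division stasis only.
- One lumped growth-source species; oxygen and glucose are not
  separated.
- The cell-cycle expression is a reconstruction (above); alternates
  would change fitted coefficient values, though not the qualitative
  supply/crowding behaviour.
- The bridge fits two coefficients only; shape mismatches that need
  other degrees of freedom (as in slow, late-transition spheroids)
  remain as residual error.
- Segmentation assumes a single isolated in-focus spheroid per frame;
  there is no tracking or merging detection.
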