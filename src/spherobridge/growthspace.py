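"""Richards growth-curve fitting and the PCA feature plane.

A spheroid growth curve is summarised by the five-parameter generalized
logistic (Richards) curve

    y(x) = A + C / (1 + T exp(-B (x - M)))^(1/T)

with lower asymptote A, growth rate B, asymptotic rise C, time of
maximum growth M, and inflection-shape parameter T.  A cohort of fitted
parameter vectors, centred and scaled per parameter, is projected onto
its first two principal components; the resulting plane separates
growth-curve "types" by quadrant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .imaging import GrowthCurve

logger = logging.getLogger(__name__)

PARAM_NAMES = ("A", "B", "C", "M", "T")


class FitError(RuntimeError):
    """Nonlinear least squares failed; carries best-so-far parameters."""

    def __init__(self, message: str, params: "RichardsParams | None" = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class RichardsParams:
    """Parameters of the generalized logistic curve.

    A: lower asymptote (cells); B: growth rate (1/day); C: asymptotic
    rise (cells); M: time of maximum growth (day); T: inflection-shape
    parameter (dimensionless).
    """

    A: float
    B: float
    C: float
    M: float
    T: float

    def __post_init__(self) -> None:
        if self.B <= 0 or self.C <= 0 or self.T <= 0:
            raise ValueError("B, C and T must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.M, self.T])

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "RichardsParams":
        return cls(*map(float, vec))


def richards_eval(params: RichardsParams, x: float | np.ndarray) -> np.ndarray:
    """Evaluate the Richards curve at time(s) ``x`` (days).

    Evaluated in log space so that large |B (x - M)| does not overflow:
    log(1 + T e^u) = logaddexp(0, u + log T).
    """
    x = np.asarray(x, dtype=float)
    u = -params.B * (x - params.M)
    log_denom = np.logaddexp(0.0, u + np.log(params.T)) / params.T
    return params.A + params.C * np.exp(-log_denom)


def _initial_guess(times: np.ndarray, counts: np.ndarray) -> RichardsParams:
    """Deterministic sigmoid heuristics for the starting point."""
    a0 = float(counts.min())
    c0 = max(float(counts.max() - counts.min()), 1e-6)
    grad = np.gradient(counts, times)
    i_max = int(np.argmax(grad))
    m0 = float(times[i_max])
    b0 = max(4.0 * float(grad[i_max]) / c0, 1e-3)
    return RichardsParams(A=a0, B=b0, C=c0, M=m0, T=1.0)


def fit_richards(
    curve: GrowthCurve,
    init: RichardsParams | None = None,
    max_nfev: int = 2000,
) -> tuple[RichardsParams, float]:
    """Fit the Richards curve to a growth curve by bounded least squares.

    Returns the fitted parameters and the residual sum of squares.
    B, C, T are kept positive via bounds; the fit is deterministic for a
    given curve and starting point.
    """
    times, counts = curve.times_days, curve.counts
    if len(times) < 6:
        raise ValueError("need at least 6 points to fit 5 parameters")
    if np.ptp(counts) == 0:
        raise FitError("constant curve: no growth to fit",
                       RichardsParams(A=float(counts[0]), B=1e-3, C=1e-6,
                                      M=float(times[0]), T=1.0))
    p0 = (init or _initial_guess(times, counts)).as_array()
    lo = np.array([-np.inf, 1e-6, 1e-6, -np.inf, 1e-6])
    hi = np.array([np.inf, np.inf, np.inf, np.inf, np.inf])
    p0 = np.clip(p0, lo, hi)

    def residuals(p: np.ndarray) -> np.ndarray:
        return richards_eval(RichardsParams.from_array(p), times) - counts

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = least_squares(residuals, p0, bounds=(lo, hi),
                               max_nfev=max_nfev, xtol=1e-12, ftol=1e-12)
    params = RichardsParams.from_array(result.x)
    rss = float(np.sum(result.fun ** 2))
    if not result.success:
        raise FitError(f"fit did not converge: {result.message}", params)
    return params, rss


@dataclass
class Normalization:
    """Per-parameter centring/scaling record (population SD convention).

    Parameters with zero variance are centred only (scale 1) and logged.
    """

    mean: np.ndarray
    scale: np.ndarray

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        return (np.asarray(vectors, dtype=float) - self.mean) / self.scale


def normalize_param_vectors(
    cohort: list[RichardsParams],
) -> tuple[np.ndarray, Normalization]:
    """Z-score the cohort's (A, B, C, M, T) vectors parameter-wise."""
    if len(cohort) < 3:
        raise ValueError("need a cohort of at least 3 spheroids")
    mat = np.stack([p.as_array() for p in cohort])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)  # population SD (divide by n)
    scale = sd.copy()
    for j, s in enumerate(sd):
        if s == 0:
            logger.warning("parameter %s has zero variance; centred only",
                           PARAM_NAMES[j])
            scale[j] = 1.0
    norm = Normalization(mean=mean, scale=scale)
    return norm.apply(mat), norm


@dataclass
class FeaturePlane:
    """First two principal components of the normalized parameter cohort."""

    component_vectors: np.ndarray      # (2, 5) orthonormal rows
    contribution_rates: np.ndarray     # (5,) percent of variance, sums to 100
    points: np.ndarray                 # (n, 2) per-spheroid scores (C1, C2)
    normalization: Normalization

    def project(self, params: RichardsParams) -> np.ndarray:
        """Score a (new) parameter vector on the stored plane."""
        z = self.normalization.apply(params.as_array()[None, :])
        return (z @ self.component_vectors.T)[0]


def pca_feature_plane(normalized: np.ndarray,
                      normalization: Normalization) -> FeaturePlane:
    """Build the two-component feature plane from normalized 5-vectors.

    Eigenvector signs are fixed so the loading of C on component 1 and
    of B on component 2 are non-negative, giving reproducible quadrant
    labels (C/T load into quadrant 1, B/M into quadrant 2, A into 3).
    """
    normalized = np.asarray(normalized, dtype=float)
    n = normalized.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cohort members")
    cov = (normalized.T @ normalized) / n
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    if eigvals[1] <= 1e-12 * max(eigvals[0], 1.0):
        raise ValueError("cohort covariance has rank < 2")
    comps = eigvecs[:, :2].T.copy()
    if comps[0, PARAM_NAMES.index("C")] < 0:
        comps[0] *= -1
    if comps[1, PARAM_NAMES.index("B")] < 0:
        comps[1] *= -1
    total = eigvals.sum()
    rates = 100.0 * eigvals / total
    points = normalized @ comps.T
    return FeaturePlane(component_vectors=comps, contribution_rates=rates,
                        points=points, normalization=normalization)


def quadrant_of(point: tuple[float, float] | np.ndarray) -> int:
    """Quadrant (1-4) of a feature-plane point by sign of (C1, C2).

    A point on an axis is assigned to the lower-numbered adjacent
    quadrant, e.g. (0, 1) -> 1 and (0, -1) -> 3.
    """
    c1, c2 = float(point[0]), float(point[1])
    candidates = []
    for quad, (s1, s2) in enumerate(
        [(1, 1), (-1, 1), (-1, -1), (1, -1)], start=1
    ):
        if (c1 == 0 or c1 * s1 > 0) and (c2 == 0 or c2 * s2 > 0):
            candidates.append(quad)
    return min(candidates)
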