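"""Collective variables and confinement restraints.

Implements the path progress variable s (exponentially weighted average index
over ordered reference frames), the orthogonal path distance z, a simple
distance CV, and the funnel (cone + cylinder) and upper-wall harmonic
restraints used to confine ligand-release sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import logsumexp


def _sq_cv_metric(config: np.ndarray, frame: np.ndarray) -> float:
    """Default path metric: squared CV-space distance (Å²).

    An RMSD-over-atoms metric can be injected instead for atomistic frames.
    """
    d = np.asarray(config, float) - np.asarray(frame, float)
    return float(np.dot(d.ravel(), d.ravel()))


@dataclass
class PathCV:
    """Ordered reference path from the bound state (frame 1) to the unbound
    state (frame N), with weighting sharpness lambda (Å^-2)."""

    reference_frames: list
    lam: float = 92.0
    metric: Callable = _sq_cv_metric
    label: str = "s"

    def __post_init__(self):
        if len(self.reference_frames) < 2:
            raise ValueError("a path needs at least 2 reference frames")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        self.reference_frames = [np.atleast_1d(np.asarray(f, float))
                                 for f in self.reference_frames]

    def metrics(self, config) -> np.ndarray:
        config = np.atleast_1d(np.asarray(config, float))
        return np.array([self.metric(config, f) for f in self.reference_frames])


@dataclass
class DistanceCV:
    """Distance from a reference anchor point (the active-site centre)."""

    reference_point: np.ndarray = field(default_factory=lambda: np.zeros(1))
    label: str = "d1"

    def __post_init__(self):
        self.reference_point = np.atleast_1d(
            np.asarray(self.reference_point, float))
        if not np.all(np.isfinite(self.reference_point)):
            raise ValueError("reference point must be finite")

    def value(self, config) -> float:
        d = np.atleast_1d(np.asarray(config, float)) - self.reference_point
        return float(np.sqrt(np.dot(d, d)))


@dataclass
class FunnelRestraint:
    """Cone-plus-cylinder confinement around the unbinding axis.

    The axis runs from point A (origin, the active site) toward point B; alpha
    is the cone half-angle (rad), z_cc the axial distance where the cone meets
    the cylinder, r_cyl the cylinder radius, and k the harmonic force constant
    applied outside the allowed radius R(z)."""

    point_a: np.ndarray = field(default_factory=lambda: np.zeros(3))
    point_b: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    alpha: float = 0.55  # rad
    z_cc: float = 20.0  # Å
    r_cyl: float = 5.0  # Å
    k: float = 83.6  # kcal/mol/Å²

    def __post_init__(self):
        self.point_a = np.asarray(self.point_a, float)
        self.point_b = np.asarray(self.point_b, float)
        if not (0.0 < self.alpha < np.pi / 2):
            raise ValueError("alpha must be in (0, pi/2)")
        if self.z_cc <= 0 or self.r_cyl <= 0 or self.k <= 0:
            raise ValueError("z_cc, r_cyl and k must be positive")
        axis = self.point_b - self.point_a
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("points A and B must differ")
        self._axis = axis / n

    def allowed_radius(self, z: float) -> float:
        if z < self.z_cc:
            return (self.z_cc - z) * np.tan(self.alpha) + self.r_cyl
        return self.r_cyl

    def axial_radial(self, position) -> tuple[float, float]:
        p = np.asarray(position, float) - self.point_a
        z = float(np.dot(p, self._axis))
        radial = p - z * self._axis
        return z, float(np.linalg.norm(radial))


def path_s(config, path: PathCV) -> float:
    """Path progress s in [1, N]: s = sum_i i e^(-lam m_i) / sum_i e^(-lam m_i).

    Computed with log-sum-exp so that large lambda or large metrics cannot
    underflow all weights to zero.
    """
    m = path.metrics(config)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("non-finite path metric")
    logw = -path.lam * m
    idx = np.arange(1, len(m) + 1, dtype=float)
    lse = logsumexp(logw)
    return float(np.sum(idx * np.exp(logw - lse)))


def path_z(config, path: PathCV) -> float:
    """Orthogonal path distance z = -(1/lam) ln sum_i e^(-lam m_i)."""
    m = path.metrics(config)
    return float(-logsumexp(-path.lam * m) / path.lam)


def funnel_energy(position, funnel: FunnelRestraint,
                  with_gradient: bool = False):
    """Harmonic penalty outside the funnel surface; 0 inside.

    Returns the energy (kcal/mol), or (energy, gradient wrt position) when
    ``with_gradient`` is set.
    """
    position = np.asarray(position, float)
    z, rho = funnel.axial_radial(position)
    r_allow = funnel.allowed_radius(z)
    excess = rho - r_allow
    if excess <= 0.0:
        return (0.0, np.zeros_like(position)) if with_gradient else 0.0
    e = 0.5 * funnel.k * excess ** 2
    if not with_gradient:
        return float(e)
    p = position - funnel.point_a
    radial_vec = p - z * funnel._axis
    rho_hat = radial_vec / rho if rho > 0 else np.zeros_like(p)
    # d(excess)/dpos = rho_hat - dR/dz * axis
    dR_dz = -np.tan(funnel.alpha) if z < funnel.z_cc else 0.0
    grad = funnel.k * excess * (rho_hat - dR_dz * funnel._axis)
    return float(e), grad


@dataclass
class UpperWall:
    """One-sided harmonic wall on a distance CV: 0 below `at`,
    0.5 k (d-at)^2 above."""

    cv: DistanceCV = field(default_factory=DistanceCV)
    at: float = 23.0  # Å
    k: float = 12.0  # kcal/mol/Å²

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("force constant must be positive")

    def energy(self, d: float) -> float:
        return upper_wall_energy(d, self)

    def gradient(self, d: float) -> float:
        return self.k * (d - self.at) if d > self.at else 0.0


def upper_wall_energy(d: float, wall: UpperWall) -> float:
    """Energy of the one-sided harmonic upper wall, kcal/mol."""
    if d <= wall.at:
        return 0.0
    return 0.5 * wall.k * (d - wall.at) ** 2
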