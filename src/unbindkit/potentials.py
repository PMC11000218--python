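"""Analytic model potentials with a bound basin and an escape barrier.

These landscapes stand in for a protein--ligand energy surface at the
level needed to exercise enhanced-sampling analysis: a single bound
minimum, a barrier of several kT, and a flat "solvated" region beyond.
All quantities are in reduced units (energies in kT at the reference
temperature, lengths in the CV unit of the model).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DomainError",
    "DoubleWell1D",
    "RadialBinding2D",
    "ZeroPotential1D",
    "Harmonic1D",
    "evaluate_potential",
    "potential_gradient",
]


class DomainError(ValueError):
    """A point lies outside a potential's evaluation domain."""


def _check_domain(potential, point) -> np.ndarray:
    p = np.atleast_1d(np.asarray(point, dtype=float))
    if p.shape != (potential.ndim,):
        raise ValueError(
            f"expected a {potential.ndim}-vector, got shape {p.shape}"
        )
    for i, (lo, hi) in enumerate(potential.domain):
        if not (lo <= p[i] <= hi):
            raise DomainError(
                f"coordinate {i} = {p[i]:g} outside domain [{lo:g}, {hi:g}]"
            )
    return p


@dataclass(frozen=True)
class ZeroPotential1D:
    """Flat potential: free diffusion along one coordinate."""

    domain: tuple = ((-1e6, 1e6),)
    ndim: int = 1

    def energy(self, point) -> float:
        return 0.0

    def gradient(self, point) -> np.ndarray:
        return np.zeros(1)


@dataclass(frozen=True)
class Harmonic1D:
    """Harmonic well U = k x^2 / 2; stationary variance is kT/k."""

    stiffness: float = 1.0
    domain: tuple = ((-1e6, 1e6),)
    ndim: int = 1

    def energy(self, point) -> float:
        x = float(np.atleast_1d(point)[0])
        return 0.5 * self.stiffness * x * x

    def gradient(self, point) -> np.ndarray:
        x = float(np.atleast_1d(point)[0])
        return np.array([self.stiffness * x])


@dataclass(frozen=True)
class DoubleWell1D:
    """Symmetric quartic double well.

    U(x) = barrier * ((x/x0)^2 - 1)^2 has minima at x = +-x0 with U = 0
    and a barrier of height ``barrier`` at x = 0.
    """

    barrier: float = 5.0
    x0: float = 1.0
    domain: tuple = ((-3.0, 3.0),)
    ndim: int = 1

    def energy(self, point) -> float:
        x = float(np.atleast_1d(point)[0])
        u = (x / self.x0) ** 2 - 1.0
        return self.barrier * u * u

    def gradient(self, point) -> np.ndarray:
        x = float(np.atleast_1d(point)[0])
        u = (x / self.x0) ** 2 - 1.0
        return np.array([4.0 * self.barrier * u * x / self.x0**2])

    def minima(self) -> np.ndarray:
        return np.array([-self.x0, self.x0])


@dataclass(frozen=True)
class RadialBinding2D:
    """Radially symmetric 2D binding landscape in Cartesian (x, y).

    The radial profile is a Gaussian bound well of depth ``well_depth``
    below the outer plateau, plus a Gaussian barrier bump of height
    ``barrier_height`` above the plateau::

        U(rho) = plateau
                 - well_depth   * exp(-(rho - rho_min)^2     / (2 well_width^2))
                 + barrier_height * exp(-(rho - rho_barrier)^2 / (2 barrier_width^2))

    Beyond ``flat_radius`` the profile is constant (to < 1e-9) by
    construction of the widths.  Dynamics run in (x, y); the collective
    variables are rho = sqrt(x^2 + y^2) and a synthetic coordination
    number that decays smoothly with rho (see ``synthetic_coordination``).
    """

    well_depth: float = 6.0
    barrier_height: float = 2.0
    rho_min: float = 1.0
    rho_barrier: float = 2.0
    well_width: float = 0.35
    barrier_width: float = 0.30
    plateau: float = 0.0
    flat_radius: float = 4.5
    box: float = 6.0
    # synthetic coordination: cn_max / (1 + (rho/cn_r0)^cn_m)
    cn_max: float = 190.0
    cn_r0: float = 1.26
    cn_m: int = 12
    ndim: int = 2

    @property
    def domain(self) -> tuple:
        return ((-self.box, self.box), (-self.box, self.box))

    # -- radial profile -------------------------------------------------
    def radial_energy(self, rho):
        rho = np.asarray(rho, dtype=float)
        well = -self.well_depth * np.exp(
            -((rho - self.rho_min) ** 2) / (2.0 * self.well_width**2)
        )
        bump = self.barrier_height * np.exp(
            -((rho - self.rho_barrier) ** 2) / (2.0 * self.barrier_width**2)
        )
        return self.plateau + well + bump

    def radial_gradient(self, rho):
        rho = np.asarray(rho, dtype=float)
        dwell = (
            self.well_depth
            * (rho - self.rho_min)
            / self.well_width**2
            * np.exp(-((rho - self.rho_min) ** 2) / (2.0 * self.well_width**2))
        )
        dbump = (
            -self.barrier_height
            * (rho - self.rho_barrier)
            / self.barrier_width**2
            * np.exp(
                -((rho - self.rho_barrier) ** 2) / (2.0 * self.barrier_width**2)
            )
        )
        return dwell + dbump

    def energy(self, point) -> float:
        p = np.atleast_1d(np.asarray(point, dtype=float))
        rho = float(np.hypot(p[0], p[1]))
        return float(self.radial_energy(rho))

    def gradient(self, point) -> np.ndarray:
        p = np.atleast_1d(np.asarray(point, dtype=float))
        rho = float(np.hypot(p[0], p[1]))
        if rho < 1e-12:
            return np.zeros(2)
        drho = float(self.radial_gradient(rho))
        return drho * p / rho

    # -- derived quantities ---------------------------------------------
    def stationary_points(self) -> tuple[float, float]:
        """(rho at the well minimum, rho at the barrier top), found numerically."""
        grid = np.linspace(1e-3, self.flat_radius, 4001)
        u = self.radial_energy(grid)
        i_min = int(np.argmin(u))
        inner = grid <= grid[i_min]
        outer = (grid >= grid[i_min]) & (grid <= self.flat_radius - 0.5)
        i_max = int(np.argmax(np.where(outer, u, -np.inf)))
        del inner
        return float(grid[i_min]), float(grid[i_max])

    def effective_barrier(self) -> float:
        """Barrier height (kT) of the bare radial profile, well -> top."""
        r0, rb = self.stationary_points()
        return float(self.radial_energy(rb) - self.radial_energy(r0))

    def curvatures(self) -> tuple[float, float]:
        """d2U/drho2 at the well minimum and at the barrier top (numeric)."""
        r0, rb = self.stationary_points()
        h = 1e-4

        def d2(r):
            return (
                self.radial_energy(r + h)
                - 2.0 * self.radial_energy(r)
                + self.radial_energy(r - h)
            ) / h**2

        return float(d2(r0)), float(d2(rb))

    def scaled(self, factor: float) -> "RadialBinding2D":
        """Same landscape with all energies multiplied by ``factor``."""
        return replace(
            self,
            well_depth=self.well_depth * factor,
            barrier_height=self.barrier_height * factor,
            plateau=self.plateau * factor,
        )

    # -- synthetic coordination CV --------------------------------------
    def synthetic_coordination(self, rho):
        """Smooth stand-in for a ligand--protein coordination number.

        Monotonically decreasing in rho; near cn_max in the bound well
        (~180 at the well minimum for the defaults, matching the scale
        of a heavy-atom contact count) and < 0.01 well past the barrier.
        """
        rho = np.asarray(rho, dtype=float)
        return self.cn_max / (1.0 + (rho / self.cn_r0) ** self.cn_m)

    def coordination_threshold_radius(self, cn_threshold: float) -> float:
        """rho at which the synthetic coordination drops below a threshold."""
        if not (0.0 < cn_threshold < self.cn_max):
            raise ValueError("threshold must be in (0, cn_max)")
        return self.cn_r0 * (self.cn_max / cn_threshold - 1.0) ** (
            1.0 / self.cn_m
        )


def evaluate_potential(potential, point) -> float:
    """Energy at ``point``; raises DomainError outside the domain."""
    p = _check_domain(potential, point)
    return float(potential.energy(p))


def potential_gradient(potential, point) -> np.ndarray:
    """Analytic gradient at ``point``; raises DomainError outside the domain."""
    p = _check_domain(potential, point)
    return np.asarray(potential.gradient(p), dtype=float)
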