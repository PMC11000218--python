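"""Collective variables for ligand-unbinding analysis.

Spherical CVs of the ligand--host displacement, the one-sided harmonic
wall that confines the unbound ligand to a sphere (volume-based
metadynamics), the rational switching function and coordination number
that count ligand--host contacts, and the commitment monitor that turns
a coordination time series into an escape time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WallParams",
    "CoordinationSpec",
    "SphericalCV",
    "spherical_cvs",
    "spherical_to_cartesian",
    "wall_potential",
    "wall_gradient",
    "switching_value",
    "coordination_number",
    "unbinding_monitor",
    "FirstPassage",
]


@dataclass(frozen=True)
class WallParams:
    """One-sided harmonic restraint V = k (rho - rho_s)^2 for rho > rho_s.

    Note the convention: no 1/2 prefactor (upper-wall convention of the
    metadynamics ecosystem).  Typical protein-scale values are
    k = 200 kJ/mol/A^2 with rho_s = 28 A; reduced-unit toy systems use
    k of order tens of kT per length^2.
    """

    k: float = 200.0
    rho_s: float = 28.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("wall spring constant must be >= 0")
        if self.rho_s <= 0:
            raise ValueError("restraint radius must be > 0")


@dataclass(frozen=True)
class CoordinationSpec:
    """Rational switching-function contact count between two atom groups.

    s(r) = (1 - (r/r0)^m) / (1 - (r/r0)^n), with the removable
    singularity at r = r0 evaluated analytically as m/n.  Defaults match
    a heavy-atom native-contact definition: r0 = 4.5 A, m = 6, n = 12.
    """

    r0: float = 4.5
    m: int = 6
    n: int = 12
    group_a: tuple = field(default_factory=tuple)
    group_b: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not (0 < self.m < self.n):
            raise ValueError("exponents must satisfy 0 < m < n")
        if self.r0 <= 0:
            raise ValueError("cutoff r0 must be > 0")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("atom groups must be disjoint")


@dataclass(frozen=True)
class SphericalCV:
    """(rho, polar, azimuth) of a displacement vector."""

    rho: float
    polar: float
    azimuth: float

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not (0.0 <= self.polar <= np.pi):
            raise ValueError("polar angle must lie in [0, pi]")
        if not (-np.pi < self.azimuth <= np.pi + 1e-15):
            raise ValueError("azimuth must lie in (-pi, pi]")


def spherical_cvs(point, center) -> SphericalCV:
    """Spherical coordinates of (point - center).

    The polar angle is measured from the +z axis, the azimuth from +x in
    the x-y plane.  Raises ValueError for zero displacement (angles
    undefined).
    """
    d = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    if d.shape != (3,):
        raise ValueError("point and center must be 3-vectors")
    rho = float(np.linalg.norm(d))
    if rho == 0.0:
        raise ValueError("zero displacement: spherical angles undefined")
    polar = float(np.arccos(np.clip(d[2] / rho, -1.0, 1.0)))
    azimuth = float(np.arctan2(d[1], d[0]))
    if azimuth <= -np.pi:
        azimuth = np.pi
    return SphericalCV(rho=rho, polar=polar, azimuth=azimuth)


def spherical_to_cartesian(cv: SphericalCV, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    s = np.sin(cv.polar)
    return c + cv.rho * np.array(
        [s * np.cos(cv.azimuth), s * np.sin(cv.azimuth), np.cos(cv.polar)]
    )


def wall_potential(rho, wall: WallParams):
    """Restraint energy: 0 inside the sphere, k (rho - rho_s)^2 outside.

    Continuous with continuous first derivative at rho_s.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be >= 0")
    excess = np.maximum(rho - wall.rho_s, 0.0)
    out = wall.k * excess * excess
    return float(out) if out.ndim == 0 else out


def wall_gradient(rho, wall: WallParams):
    """dV/drho of the one-sided harmonic wall."""
    rho = np.asarray(rho, dtype=float)
    excess = np.maximum(rho - wall.rho_s, 0.0)
    out = 2.0 * wall.k * excess
    return float(out) if out.ndim == 0 else out


def switching_value(r, spec: CoordinationSpec):
    """Rational switching function in [0, 1], monotone decreasing in r.

    Evaluates (1 - x^m)/(1 - x^n) with x = r/r0; at x = 1 the removable
    singularity is handled analytically (value m/n, first-order series
    in a small neighborhood for numerical continuity).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    x = r / spec.r0
    m, n = spec.m, spec.n
    eps = x - 1.0
    near = np.abs(eps) < 1e-7
    xsafe = np.where(near, 0.5, x)  # dummy away from the singularity
    regular = (1.0 - xsafe**m) / (1.0 - xsafe**n)
    # (1 - x^m)/(1 - x^n) = (m/n) (1 + (m - n)/2 eps + O(eps^2)) near x=1
    series = (m / n) * (1.0 + 0.5 * (m - n) * eps)
    out = np.where(near, series, regular)
    return float(out) if out.ndim == 0 else out


def coordination_number(
    positions_a, positions_b, spec: CoordinationSpec
) -> float:
    """Smooth contact count: sum of switching_value over all A x B pairs."""
    a = np.atleast_2d(np.asarray(positions_a, dtype=float))
    b = np.atleast_2d(np.asarray(positions_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both atom groups must be non-empty")
    diff = a[:, None, :] - b[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    return float(np.sum(switching_value(r, spec)))


@dataclass(frozen=True)
class FirstPassage:
    """Outcome of the unbinding monitor: a time and an event flag."""

    time: float
    event: bool
    index: int | None = None


def unbinding_monitor(times, values, threshold: float) -> FirstPassage:
    """First time the coordination series drops below ``threshold``.

    Commitment rule: the earliest sample with value < threshold is the
    escape; no re-entry is considered.  If the series never drops below
    the threshold, the record is censored at the final time.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0 or t.size != v.size:
        raise ValueError("times and values must be non-empty, equal length")
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise ValueError(f"non-finite coordination value at sample {bad}")
    below = v < threshold
    if not np.any(below):
        return FirstPassage(time=float(t[-1]), event=False, index=None)
    i = int(np.argmax(below))
    return FirstPassage(time=float(t[i]), event=True, index=i)
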