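"""Overdamped Langevin (Euler--Maruyama) integration of model potentials.

Position Langevin dynamics

    x(t + dt) = x(t) - dt/friction * grad U + sqrt(2 kT dt / friction) * xi

with xi ~ N(0, 1) i.i.d. per coordinate, which samples the Boltzmann
distribution exp(-U/kT) in the long run.  Trajectories are fully
reproducible: identical seed and configuration give bit-identical
output.  Long unbiased runs on the built-in landscapes dispatch to
numba kernels; arbitrary potentials/biases fall back to a plain loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .potentials import DoubleWell1D, RadialBinding2D

__all__ = ["LangevinConfig", "Trajectory", "DomainExitError", "integrate_langevin"]


@dataclass(frozen=True)
class LangevinConfig:
    """Integrator settings, in reduced units (kT = 1 by default)."""

    timestep: float = 0.005
    friction: float = 1.0
    kT: float = 1.0
    n_steps: int = 10_000
    seed: int = 0
    save_stride: int = 10

    def __post_init__(self):
        if self.timestep <= 0 or self.friction <= 0 or self.kT <= 0:
            raise ValueError("timestep, friction and kT must be positive")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")


@dataclass
class Trajectory:
    """Saved CV values and instantaneous bias energy for one run."""

    times: np.ndarray
    positions: np.ndarray  # (n_saved, ndim)
    bias: np.ndarray  # (n_saved,), 0 for unbiased runs
    config: LangevinConfig | None = None

    def __len__(self) -> int:
        return len(self.times)


class DomainExitError(RuntimeError):
    """Trajectory left the potential's evaluation domain."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"trajectory left the evaluation domain at step {step}")


def _initial_point(potential, start):
    if start is not None:
        return np.atleast_1d(np.asarray(start, dtype=float)).copy()
    if isinstance(potential, DoubleWell1D):
        return np.array([potential.x0])
    if isinstance(potential, RadialBinding2D):
        r0, _ = potential.stationary_points()
        return np.array([r0, 0.0])
    return np.zeros(potential.ndim)


def integrate_langevin(
    potential,
    config: LangevinConfig,
    bias=None,
    wall=None,
    start=None,
) -> Trajectory:
    """Integrate one overdamped trajectory on ``potential`` (+ optional bias).

    Parameters
    ----------
    bias : optional callable ``bias(point) -> (energy, gradient)``
        evaluated at every visited point (e.g. a fixed metadynamics
        bias).  Growing-bias simulations live in
        :func:`unbindkit.metad.run_metad`.
    wall : optional :class:`unbindkit.cvs.WallParams`
        one-sided harmonic restraint on the radial CV (|x| in 1D).

    Raises :class:`DomainExitError` naming the step if the trajectory
    leaves the potential's evaluation domain.
    """
    x = _initial_point(potential, start)
    rng = np.random.default_rng(config.seed)

    if bias is None and isinstance(potential, (DoubleWell1D, RadialBinding2D)):
        return _integrate_fast(potential, config, wall, x, rng)
    return _integrate_generic(potential, config, bias, wall, x, rng)


def _empty_hills():
    return np.empty(0), np.empty(0)


def _integrate_fast(potential, config, wall, x, rng) -> Trajectory:
    n = config.n_steps
    n_save = n // config.save_stride
    wall_k = wall.k if wall is not None else 0.0
    wall_r = wall.rho_s if wall is not None else 1.0
    hc, hh = _empty_hills()
    if isinstance(potential, DoubleWell1D):
        saved_x = np.empty(n_save)
        saved_v = np.empty(n_save)
        noise = rng.standard_normal(n)
        lo, hi = potential.domain[0]
        xf, n_saved, exit_step = _kernels.dw1d_chunk(
            float(x[0]), n, config.timestep, config.friction, config.kT,
            potential.barrier, potential.x0, lo, hi,
            hc, hh, 1.0, wall_k, wall_r, noise,
            config.save_stride, saved_x, saved_v,
        )
        if exit_step >= 0:
            raise DomainExitError(exit_step)
        positions = saved_x[:n_saved, None]
    else:
        saved_rho = np.empty(n_save)
        saved_v = np.empty(n_save)
        noise = rng.standard_normal((n, 2))
        p = potential
        xf, yf, n_saved, exit_step, _ = _kernels.radial2d_chunk(
            float(x[0]), float(x[1]), n, config.timestep, config.friction,
            config.kT, p.well_depth, p.rho_min, p.well_width,
            p.barrier_height, p.rho_barrier, p.barrier_width, p.box,
            hc, hh, 1.0, wall_k, wall_r, -1.0,
            np.ascontiguousarray(noise[:, 0]),
            np.ascontiguousarray(noise[:, 1]),
            config.save_stride, saved_rho, saved_v,
        )
        if exit_step >= 0:
            raise DomainExitError(exit_step)
        positions = saved_rho[:n_saved, None]
    times = config.timestep * config.save_stride * np.arange(1, n_saved + 1)
    return Trajectory(
        times=times,
        positions=positions,
        bias=saved_v[:n_saved].copy(),
        config=config,
    )


def _integrate_generic(potential, config, bias, wall, x, rng) -> Trajectory:
    from .cvs import wall_gradient

    dt, fr, kT = config.timestep, config.friction, config.kT
    amp = np.sqrt(2.0 * kT * dt / fr)
    domain = getattr(potential, "domain", None)
    n_save = config.n_steps // config.save_stride
    positions = np.empty((n_save, potential.ndim))
    biases = np.empty(n_save)
    times = np.empty(n_save)
    k = 0
    for i in range(config.n_steps):
        f = -np.asarray(potential.gradient(x), dtype=float)
        if wall is not None:
            rho = float(np.linalg.norm(x))
            if rho > 1e-12:
                f -= wall_gradient(rho, wall) * x / rho
        v = 0.0
        if bias is not None:
            v, g = bias(x)
            f -= np.asarray(g, dtype=float)
        x = x + dt * f / fr + amp * rng.standard_normal(x.shape)
        if domain is not None:
            for d, (lo, hi) in enumerate(domain):
                if not (lo <= x[d] <= hi):
                    raise DomainExitError(i)
        if (i + 1) % config.save_stride == 0:
            if bias is not None:
                v, _ = bias(x)
            positions[k] = x
            biases[k] = v
            times[k] = dt * (i + 1)
            k += 1
    return Trajectory(
        times=times[:k], positions=positions[:k], bias=biases[:k], config=config
    )
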