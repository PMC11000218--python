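"""Well-tempered metadynamics: hill deposition, bias evaluation, runs.

The bias is a sum of Gaussians deposited along the trajectory every
``stride_time``, with heights tempered as

    w = w0 * exp(-V(s, t) / ((gamma_wt - 1) kT))

so that the bias converges to -(1 - 1/gamma_wt) F(s).  The engine also
records the instantaneous bias V^r(t) at the trajectory's current CV
point -- the ingredient of the survivor-averaged maximum bias used by
Kramers time-dependent rate fitting.

Bias evaluation is direct summation over hills (exact; hill counts at
desk scale are small).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .cvs import FirstPassage
from .langevin import DomainExitError, LangevinConfig, Trajectory
from .potentials import DoubleWell1D, RadialBinding2D

__all__ = [
    "MetadParams",
    "Hill",
    "BiasTrace",
    "MetadRun",
    "bias_value",
    "bias_gradient",
    "deposit_hill",
    "hills_as_bias",
    "run_metad",
    "survivor_max_bias",
    "VMBSeries",
]


@dataclass(frozen=True)
class MetadParams:
    """Deposition settings: initial height w0, stride, widths, bias factor."""

    height: float = 1.0
    stride_time: float = 1.0
    sigmas: tuple = (0.1,)
    bias_factor: float = 10.0
    kT: float = 1.0

    def __post_init__(self):
        if self.height < 0:
            raise ValueError("hill height must be >= 0")
        if self.stride_time <= 0:
            raise ValueError("deposition stride must be > 0")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("Gaussian widths must be > 0")
        if self.bias_factor <= 1:
            raise ValueError("well-tempered bias factor must be > 1")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian."""

    center: tuple
    widths: tuple
    height: float
    time: float


@dataclass
class BiasTrace:
    """Instantaneous bias V^r(t) at the run's current CV point."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")


@dataclass
class MetadRun:
    """Output of one metadynamics run."""

    trajectory: Trajectory
    hills: list
    bias_trace: BiasTrace
    escape: FirstPassage | None = None


def _hill_arrays(hills):
    if not hills:
        return np.empty((0, 0)), np.empty((0, 0)), np.empty(0)
    c = np.array([h.center for h in hills], dtype=float)
    w = np.array([h.widths for h in hills], dtype=float)
    h = np.array([h.height for h in hills], dtype=float)
    return c, w, h


def bias_value(hills, point) -> float:
    """Sum-of-Gaussians bias at a CV point (0 for an empty hill list)."""
    if not hills:
        return 0.0
    p = np.atleast_1d(np.asarray(point, dtype=float))
    c, w, h = _hill_arrays(hills)
    if c.shape[1] != p.shape[0]:
        raise ValueError(
            f"CV dimension mismatch: hills are {c.shape[1]}-dimensional, "
            f"point is {p.shape[0]}-dimensional"
        )
    z = (p[None, :] - c) / w
    return float(np.sum(h * np.exp(-0.5 * np.sum(z * z, axis=1))))


def bias_gradient(hills, point) -> np.ndarray:
    """Gradient of the sum-of-Gaussians bias with respect to the CVs."""
    p = np.atleast_1d(np.asarray(point, dtype=float))
    if not hills:
        return np.zeros_like(p)
    c, w, h = _hill_arrays(hills)
    if c.shape[1] != p.shape[0]:
        raise ValueError("CV dimension mismatch")
    z = (p[None, :] - c) / w
    g = h[:, None] * np.exp(-0.5 * np.sum(z * z, axis=1))[:, None]
    return -np.sum(g * z / w, axis=0)


def deposit_hill(hills, point, params: MetadParams, time: float) -> Hill:
    """Append a well-tempered hill at the current CV point.

    The new height is w0 * exp(-V(point)/((gamma_wt - 1) kT)) with V the
    bias accumulated so far; the first hill has the full height w0.
    """
    p = tuple(np.atleast_1d(np.asarray(point, dtype=float)))
    v = bias_value(hills, p)
    height = params.height * np.exp(
        -v / ((params.bias_factor - 1.0) * params.kT)
    )
    hill = Hill(center=p, widths=tuple(params.sigmas), height=float(height), time=time)
    hills.append(hill)
    return hill


def hills_as_bias(hills):
    """Freeze a hill list into a ``point -> (energy, gradient)`` callable."""

    def _bias(point):
        return bias_value(hills, point), bias_gradient(hills, point)

    return _bias


def run_metad(
    potential,
    params: MetadParams,
    config: LangevinConfig,
    wall=None,
    start=None,
    cn_threshold: float | None = None,
) -> MetadRun:
    """Well-tempered metadynamics on a built-in model landscape.

    The biased CV is x for the 1D double well and the radial distance
    rho for the 2D binding landscape.  Langevin steps are interleaved
    with hill deposition every ``params.stride_time``.  When
    ``cn_threshold`` is given (infrequent-metadynamics mode on the
    radial landscape), the run stops at the unbinding commitment -- the
    synthetic coordination CV dropping below the threshold -- and the
    escape is recorded; otherwise the run uses the full step budget.
    Zero hill height reduces exactly to plain Langevin dynamics.
    """
    if len(params.sigmas) != 1:
        raise ValueError("built-in model landscapes bias a single CV")
    is_1d = isinstance(potential, DoubleWell1D)
    if not is_1d and not isinstance(potential, RadialBinding2D):
        raise TypeError("run_metad supports the built-in model landscapes")
    if cn_threshold is not None and is_1d:
        raise ValueError("the unbinding monitor needs the radial landscape")

    dt = config.timestep
    stride_steps = int(round(params.stride_time / dt))
    if stride_steps < 1:
        raise ValueError("deposition stride must cover at least one step")
    if stride_steps % config.save_stride != 0:
        raise ValueError("save_stride must divide the deposition stride")

    rng = np.random.default_rng(config.seed)
    sigma = float(params.sigmas[0])
    wall_k = wall.k if wall is not None else 0.0
    wall_r = wall.rho_s if wall is not None else 1.0
    stop_rho = -1.0
    if cn_threshold is not None:
        stop_rho = potential.coordination_threshold_radius(cn_threshold)

    if start is not None:
        x = np.atleast_1d(np.asarray(start, dtype=float)).copy()
    elif is_1d:
        x = np.array([potential.x0])
    else:
        r0, _ = potential.stationary_points()
        x = np.array([r0, 0.0])

    hills: list[Hill] = []
    hc = np.empty(0)
    hh = np.empty(0)
    n_chunks = config.n_steps // stride_steps
    per_chunk = stride_steps // config.save_stride
    cv_out = np.empty(n_chunks * per_chunk)
    v_out = np.empty(n_chunks * per_chunk)
    t_out = np.empty(n_chunks * per_chunk)
    n_tot = 0
    escape: FirstPassage | None = None
    t_offset = 0.0

    sx = np.empty(per_chunk)
    sv = np.empty(per_chunk)
    for _ in range(n_chunks):
        if is_1d:
            noise = rng.standard_normal(stride_steps)
            lo, hi = potential.domain[0]
            xf, n_saved, exit_step = _kernels.dw1d_chunk(
                float(x[0]), stride_steps, dt, config.friction, config.kT,
                potential.barrier, potential.x0, lo, hi,
                hc, hh, sigma, wall_k, wall_r, noise,
                config.save_stride, sx, sv,
            )
            stop_step = -1
            x = np.array([xf])
        else:
            noise = rng.standard_normal((stride_steps, 2))
            p = potential
            xf, yf, n_saved, exit_step, stop_step = _kernels.radial2d_chunk(
                float(x[0]), float(x[1]), stride_steps, dt, config.friction,
                config.kT, p.well_depth, p.rho_min, p.well_width,
                p.barrier_height, p.rho_barrier, p.barrier_width, p.box,
                hc, hh, sigma, wall_k, wall_r, stop_rho,
                np.ascontiguousarray(noise[:, 0]),
                np.ascontiguousarray(noise[:, 1]),
                config.save_stride, sx, sv,
            )
            x = np.array([xf, yf])
        if exit_step >= 0:
            raise DomainExitError(int(t_offset / dt) + exit_step)
        k = n_tot
        cv_out[k : k + n_saved] = sx[:n_saved]
        v_out[k : k + n_saved] = sv[:n_saved]
        t_out[k : k + n_saved] = t_offset + dt * config.save_stride * np.arange(
            1, n_saved + 1
        )
        n_tot += n_saved
        if stop_step >= 0:
            escape = FirstPassage(
                time=t_offset + dt * (stop_step + 1), event=True, index=n_tot - 1
            )
            break
        t_offset += stride_steps * dt
        if params.height > 0.0:
            cv_now = float(x[0]) if is_1d else float(np.hypot(x[0], x[1]))
            deposit_hill(hills, (cv_now,), params, t_offset)
            hc, _, hh = _hill_arrays(hills)
            hc = hc[:, 0].copy()

    traj = Trajectory(
        times=t_out[:n_tot].copy(),
        positions=cv_out[:n_tot, None].copy(),
        bias=v_out[:n_tot].copy(),
        config=config,
    )
    if escape is None and cn_threshold is not None:
        escape = FirstPassage(time=float(config.n_steps * dt), event=False)
    trace = BiasTrace(times=traj.times.copy(), values=traj.bias.copy())
    return MetadRun(trajectory=traj, hills=hills, bias_trace=trace, escape=escape)


@dataclass
class VMBSeries:
    """Survivor-averaged maximum bias V_MB(t) on a common time grid."""

    times: np.ndarray
    values: np.ndarray
    n_survivors: np.ndarray


def survivor_max_bias(
    traces,
    escape_times,
    events=None,
    running_max: bool = True,
) -> VMBSeries:
    """Average the (running maximum of the) bias over surviving runs.

    At each grid time t, only runs whose escape time exceeds t -- still
    in the initial basin -- contribute; the series ends once no
    survivors remain.  Traces are linearly resampled onto a common grid
    at the coarsest stride present.  With ``running_max=False`` the
    instantaneous bias is averaged instead of its running maximum.
    """
    if len(traces) == 0:
        raise ValueError("need at least one bias trace")
    esc = np.asarray(escape_times, dtype=float)
    if len(esc) != len(traces):
        raise ValueError("one escape time per trace required")
    strides = [
        float(np.median(np.diff(tr.times))) if len(tr.times) > 1 else np.inf
        for tr in traces
    ]
    dt = max(s for s in strides if np.isfinite(s)) if any(
        np.isfinite(s) for s in strides
    ) else 1.0
    t_end = float(np.max(esc))
    grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    vals = np.zeros((len(traces), len(grid)))
    for r, tr in enumerate(traces):
        v = np.interp(grid, tr.times, tr.values, left=0.0)
        if running_max:
            v = np.maximum.accumulate(v)
        vals[r] = v
    alive = grid[None, :] <= esc[:, None]
    n_surv = alive.sum(axis=0)
    keep = n_surv > 0
    with np.errstate(invalid="ignore"):
        avg = np.where(
            keep, np.sum(vals * alive, axis=0) / np.maximum(n_surv, 1), np.nan
        )
    return VMBSeries(
        times=grid[keep], values=avg[keep], n_survivors=n_surv[keep]
    )
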