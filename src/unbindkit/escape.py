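"""Synthetic escape-time ensembles with known ground truth.

Direct samplers of the time-dependent-rate survival law

    S(t) = exp( -k0 * int_0^t exp(gamma beta V_MB(t')) dt' )

with V_MB(t) = a log(1 + b t) up to a cutoff t_c and constant beyond,
plus the full biased-dynamics route: ensembles of infrequent-
metadynamics Langevin runs on a model binding landscape.  The sampler
carries its own closed-form integrated hazard, written independently of
the fitting module, so generator and fitter can cross-validate each
other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .langevin import LangevinConfig
from .metad import BiasTrace, MetadParams, run_metad

__all__ = ["GroundTruthRates", "EscapeTimeSet", "sample_escape_times",
           "generate_imetad_ensemble"]


@dataclass(frozen=True)
class GroundTruthRates:
    """True (k0, gamma) and the V_MB = a log(1 + b t) bias model."""

    k0: float = 1.0
    gamma: float = 0.7
    a: float = 3.0  # kT
    b: float = 1.0  # 1/time
    t_c: float = 20.0

    def __post_init__(self):
        if self.k0 <= 0:
            raise ValueError("k0 must be > 0")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.a < 0 or self.b <= 0 or self.t_c <= 0:
            raise ValueError("need a >= 0, b > 0, t_c > 0")

    def vmb(self, t):
        t = np.asarray(t, dtype=float)
        out = self.a * np.log1p(self.b * np.minimum(t, self.t_c))
        return float(out) if out.ndim == 0 else out


@dataclass
class EscapeTimeSet:
    """Per-run biased escape times, event flags, and bias traces."""

    times: np.ndarray
    events: np.ndarray  # True = escape observed, False = censored
    traces: list | None = None
    horizon: float | None = None
    meta: dict | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape:
            raise ValueError("times and event flags must align")
        if np.any(self.times <= 0):
            raise ValueError("all escape/censoring times must be > 0")
        if self.traces is not None and len(self.traces) != len(self.times):
            raise ValueError("one bias trace per run required")

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_censored(self) -> int:
        return int((~self.events).sum())

    def __len__(self) -> int:
        return len(self.times)

    def subset(self, idx) -> "EscapeTimeSet":
        idx = np.asarray(idx)
        return EscapeTimeSet(
            times=self.times[idx],
            events=self.events[idx],
            traces=[self.traces[i] for i in idx] if self.traces else None,
            horizon=self.horizon,
            meta=self.meta,
        )


def _integrated_hazard(truth: GroundTruthRates, t: float, kT: float) -> float:
    # closed form of int_0^t (1 + b t')^c dt', c = gamma a / kT, then the
    # constant-hazard tail beyond t_c (generator-side copy, kept
    # independent of the fitting module)
    c = truth.gamma * truth.a / kT
    b = truth.b
    th = min(t, truth.t_c)
    if abs(c + 1.0) < 1e-12:
        head = np.log1p(b * th) / b
    else:
        head = ((1.0 + b * th) ** (c + 1.0) - 1.0) / (b * (c + 1.0))
    tail = max(t - truth.t_c, 0.0) * (1.0 + b * truth.t_c) ** c
    return truth.k0 * (head + tail)


def sample_escape_times(
    truth: GroundTruthRates,
    n_runs: int,
    horizon: float,
    kT: float = 1.0,
    seed: int = 0,
    trace_points: int = 400,
) -> EscapeTimeSet:
    """Draw escape times from the survival law by inverse sampling.

    Per run, u ~ Uniform(0,1) and S(t) = u is solved for t by root
    bracketing on the closed-form integrated hazard.  Runs with t beyond
    ``horizon`` are returned censored at the horizon.  Each run carries
    the deterministic V_MB(t) model curve as its bias trace.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n_runs)
    target = -np.log(u)  # solve Lambda(t) = -ln u
    times = np.empty(n_runs)
    events = np.zeros(n_runs, dtype=bool)
    lam_h = _integrated_hazard(truth, horizon, kT)
    for i in range(n_runs):
        if target[i] >= lam_h:
            times[i] = horizon
            continue
        times[i] = brentq(
            lambda t: _integrated_hazard(truth, t, kT) - target[i],
            1e-300,
            horizon,
            xtol=1e-12,
            rtol=1e-12,
        )
        events[i] = True
    grid = np.linspace(0.0, horizon, trace_points)
    vals = truth.vmb(grid)
    traces = []
    for i in range(n_runs):
        end = times[i] if events[i] else horizon
        # keep one grid point past the escape so the trace covers it
        n_keep = min(len(grid), max(2, int(np.searchsorted(grid, end)) + 1))
        traces.append(
            BiasTrace(times=grid[:n_keep].copy(), values=vals[:n_keep].copy())
        )
    return EscapeTimeSet(
        times=times,
        events=events,
        traces=traces,
        horizon=horizon,
        meta={"truth": truth, "kT": kT, "seed": seed},
    )


def generate_imetad_ensemble(
    potential,
    metad: MetadParams,
    config: LangevinConfig,
    n_runs: int,
    cn_threshold: float = 0.01,
    wall=None,
) -> EscapeTimeSet:
    """Ensemble of independent infrequent-metadynamics unbinding runs.

    Each run starts from the bound minimum with its own seed (spawned
    from ``config.seed``), deposits bias on the radial CV, and ends at
    the unbinding commitment (synthetic coordination below the
    threshold) or, censored, at the step budget.  Returned times are
    biased simulation times; the per-run instantaneous-bias traces feed
    the survivor-averaged maximum bias.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    times = np.empty(n_runs)
    events = np.zeros(n_runs, dtype=bool)
    traces = []
    for i in range(n_runs):
        run = run_metad(
            potential,
            metad,
            replace(config, seed=int(seeds[i])),
            wall=wall,
            cn_threshold=cn_threshold,
        )
        times[i] = run.escape.time
        events[i] = run.escape.event
        traces.append(run.bias_trace)
    return EscapeTimeSet(
        times=times,
        events=events,
        traces=traces,
        horizon=config.n_steps * config.timestep,
        meta={"cn_threshold": cn_threshold, "seed": config.seed},
    )
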