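"""From biased trajectories to binding thermodynamics.

Pipeline: the time-independent reweighting estimator (bias offset c(t)
computed from the growing well-tempered bias), a reweighted free-energy
surface on a CV grid, bound/unbound region integration of exp(-F/kT),
the restraint-volume entropy correction to a standard-state binding
free energy, the K_d conversion, and block-analysis error bars.

Sign conventions: DG_MetaD < 0 when the bound basin is deeper/wider;
DG_b0 = DG_MetaD - TdS with TdS = R T ln(V_accessible / V0) > 0 for an
accessible volume larger than the standard volume; K_d = C0 exp(DG_b0/RT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "R_KCAL_PER_MOL_K",
    "AVOGADRO",
    "FESGrid",
    "RegionBox",
    "ThermoParams",
    "ThermoResult",
    "ReweightState",
    "compute_c_of_t",
    "c_at_times",
    "reweight_fes",
    "free_energy_difference",
    "volume_entropy_correction",
    "standard_binding_free_energy",
    "kd_from_dg",
    "block_error",
    "BlockAnalysis",
    "dg_convergence",
    "dg_block_error",
]

R_KCAL_PER_MOL_K = 1.9872e-3  # gas constant, kcal/mol/K
AVOGADRO = 6.02214076e23


# --------------------------------------------------------------------------
# grids and containers
# --------------------------------------------------------------------------
@dataclass
class FESGrid:
    """Free energy on a rectangular CV grid; unvisited cells are +inf."""

    edges: list  # per-axis cell edges, strictly increasing
    free_energy: np.ndarray
    kT: float
    shifted: bool = True
    effective_samples: np.ndarray | None = None

    def __post_init__(self):
        for e in self.edges:
            if np.any(np.diff(e) <= 0):
                raise ValueError("grid edges must be strictly increasing")
        shape = tuple(len(e) - 1 for e in self.edges)
        if self.free_energy.shape != shape:
            raise ValueError("free-energy array does not match the grid")

    @property
    def centers(self) -> list:
        return [0.5 * (e[:-1] + e[1:]) for e in self.edges]

    @property
    def cell_volumes(self) -> np.ndarray:
        widths = [np.diff(e) for e in self.edges]
        out = widths[0]
        for w in widths[1:]:
            out = np.multiply.outer(out, w)
        return out


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned CV-space region (e.g. the bound or unbound state)."""

    intervals: tuple  # ((lo, hi), ...) per CV axis
    label: str = ""

    def __post_init__(self):
        for lo, hi in self.intervals:
            if not hi > lo:
                raise ValueError(f"empty interval in region '{self.label}'")

    def mask(self, fes: FESGrid) -> np.ndarray:
        if len(self.intervals) != len(fes.edges):
            raise ValueError("region dimensionality does not match the grid")
        m = np.ones(fes.free_energy.shape, dtype=bool)
        for ax, ((lo, hi), c) in enumerate(zip(self.intervals, fes.centers)):
            inside = (c >= lo) & (c <= hi)
            shape = [1] * len(fes.edges)
            shape[ax] = len(c)
            m &= inside.reshape(shape)
        return m


# --------------------------------------------------------------------------
# time-independent reweighting
# --------------------------------------------------------------------------
@dataclass
class ReweightState:
    """Bias offset c(t) after each hill, for sample reweighting."""

    times: np.ndarray  # hill deposition times
    c: np.ndarray  # offset c(t), same energy unit as the bias
    bias_factor: float
    kT: float


def compute_c_of_t(hills, edges, bias_factor: float, kT: float) -> ReweightState:
    """Offset c(t) of the time-independent free-energy estimator.

    After each deposited hill,

        c(t) = kT * ln[ sum_s e^{g/(g-1) V(s,t)/kT} / sum_s e^{1/(g-1) V(s,t)/kT} ]

    with the sums taken over grid cells (cell-volume weighted) covering
    the sampled domain; evaluated with log-sum-exp for stability.
    """
    if len(edges) == 0 or any(len(e) < 2 for e in edges):
        raise ValueError("need a non-empty evaluation grid")
    if not hills:
        return ReweightState(
            times=np.empty(0), c=np.empty(0), bias_factor=bias_factor, kT=kT
        )
    centers = [0.5 * (np.asarray(e)[:-1] + np.asarray(e)[1:]) for e in edges]
    mesh = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    widths = [np.diff(np.asarray(e)) for e in edges]
    vol = widths[0]
    for w in widths[1:]:
        vol = np.multiply.outer(vol, w)
    logvol = np.log(vol.ravel())

    beta = 1.0 / kT
    g = bias_factor
    centers_h = np.array([h.center for h in hills], dtype=float)
    widths_h = np.array([h.widths for h in hills], dtype=float)
    heights_h = np.array([h.height for h in hills], dtype=float)
    v = np.zeros(pts.shape[0])
    c_out = np.empty(len(hills))
    for i in range(len(hills)):
        z = (pts - centers_h[i]) / widths_h[i]
        v += heights_h[i] * np.exp(-0.5 * np.sum(z * z, axis=1))
        num = logsumexp(beta * g / (g - 1.0) * v + logvol)
        den = logsumexp(beta / (g - 1.0) * v + logvol)
        c_out[i] = kT * (num - den)
    times = np.array([h.time for h in hills], dtype=float)
    return ReweightState(times=times, c=c_out, bias_factor=g, kT=kT)


def c_at_times(state: ReweightState, times) -> np.ndarray:
    """c(t) at sample times: piecewise constant between hill depositions."""
    t = np.asarray(times, dtype=float)
    if len(state.times) == 0:
        return np.zeros_like(t)
    idx = np.searchsorted(state.times, t, side="right") - 1
    out = np.where(idx >= 0, state.c[np.clip(idx, 0, None)], 0.0)
    return out


def reweight_fes(
    cv_samples,
    bias_samples,
    c_samples,
    edges,
    kT: float,
) -> FESGrid:
    """Weighted histogram -> free-energy surface.

    Each sample carries weight exp[(V(s_t, t) - c(t))/kT]; the FES is
    F = -kT ln(weighted density), shifted so the visited minimum is 0.
    Unvisited cells are +inf.  ``effective_samples`` holds the per-cell
    Kish effective sample count (sum w)^2 / sum w^2.
    """
    cv = np.atleast_2d(np.asarray(cv_samples, dtype=float))
    if cv.shape[1] != len(edges):
        if cv.shape[0] == len(edges):
            cv = cv.T
        else:
            raise ValueError("cv_samples shape does not match the grid")
    v = np.asarray(bias_samples, dtype=float)
    c = np.asarray(c_samples, dtype=float)
    log_w = (v - c) / kT
    log_w -= np.max(log_w)
    w = np.exp(log_w)
    if not np.any(w > 0):
        raise ValueError("all reweighting weights are zero")
    hist_w, _ = np.histogramdd(cv, bins=edges, weights=w)
    hist_w2, _ = np.histogramdd(cv, bins=edges, weights=w * w)
    widths = [np.diff(np.asarray(e)) for e in edges]
    vol = widths[0]
    for wd in widths[1:]:
        vol = np.multiply.outer(vol, wd)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = -kT * np.log(hist_w / (np.sum(w) * vol))
        n_eff = np.where(hist_w2 > 0, hist_w**2 / hist_w2, 0.0)
    f[hist_w == 0] = np.inf
    f -= np.min(f)
    return FESGrid(
        edges=[np.asarray(e, dtype=float) for e in edges],
        free_energy=f,
        kT=kT,
        shifted=True,
        effective_samples=n_eff,
    )


# --------------------------------------------------------------------------
# region integration and standard-state bookkeeping
# --------------------------------------------------------------------------
def free_energy_difference(
    fes: FESGrid, bound: RegionBox, unbound: RegionBox, kT: float | None = None
) -> float:
    """Bound-vs-unbound free-energy difference by grid integration.

    DG = -kT ln( sum_bound e^{-F/kT} dA / sum_unbound e^{-F/kT} dA ),
    cell-volume weighted, unvisited cells excluded (F = +inf).  Negative
    when the bound basin is deeper or wider.
    """
    kT = fes.kT if kT is None else kT
    vol = fes.cell_volumes
    logvol = np.where(vol > 0, np.log(vol), -np.inf)
    terms = []
    for region in (bound, unbound):
        m = region.mask(fes)
        if not np.any(m):
            raise ValueError(
                f"region '{region.label or '?'}' does not overlap the grid"
            )
        visited = m & np.isfinite(fes.free_energy)
        if not np.any(visited):
            raise ValueError(
                f"region '{region.label or '?'}' contains no visited cells"
            )
        frac_unvisited = 1.0 - visited.sum() / m.sum()
        if frac_unvisited > 0.10:
            warnings.warn(
                f"region '{region.label or '?'}': "
                f"{100 * frac_unvisited:.0f}% of cells unvisited",
                stacklevel=2,
            )
        terms.append(
            logsumexp(
                -fes.free_energy[visited] / kT + logvol[visited]
            )
        )
    return float(-kT * (terms[0] - terms[1]))


@dataclass(frozen=True)
class ThermoParams:
    """Inputs of the standard-state correction, in protein-scale units."""

    temperature: float = 300.0  # K
    gas_constant: float = R_KCAL_PER_MOL_K  # kcal/mol/K
    standard_volume: float = 1660.0  # A^3, inverse of 1 M
    standard_concentration: float = 1.0  # mol/L
    restraint_radius: float = 28.0  # A
    protein_volume: float = 48300.0  # A^3 inside the restraint sphere

    def __post_init__(self):
        if min(
            self.temperature,
            self.gas_constant,
            self.standard_volume,
            self.standard_concentration,
            self.restraint_radius,
        ) <= 0 or self.protein_volume < 0:
            raise ValueError("thermodynamic parameters must be positive")
        # V0 must be the inverse of C0 (1e27 A^3 per liter)
        v0_expected = 1e27 / (self.standard_concentration * AVOGADRO)
        if abs(self.standard_volume - v0_expected) / v0_expected > 1e-3:
            raise ValueError(
                "standard volume and concentration are inconsistent: "
                f"V0 = {self.standard_volume} A^3 vs 1/(C0 N_A) = "
                f"{v0_expected:.1f} A^3"
            )


def volume_entropy_correction(params: ThermoParams) -> float:
    """Translational-entropy correction TdS = R T ln(V_accessible / V0).

    V_accessible = (4/3) pi rho_s^3 - V_prot is the solvent volume of
    the restraint sphere available to the unbound ligand.  Returned in
    the unit of ``gas_constant`` * K (kcal/mol by default).
    """
    v_sphere = 4.0 / 3.0 * np.pi * params.restraint_radius**3
    v_acc = v_sphere - params.protein_volume
    if v_acc <= 0:
        raise ValueError(
            f"accessible volume is not positive: sphere {v_sphere:.0f} A^3 "
            f"minus protein {params.protein_volume:.0f} A^3"
        )
    return float(
        params.gas_constant
        * params.temperature
        * np.log(v_acc / params.standard_volume)
    )


def standard_binding_free_energy(dg_metad: float, tds: float) -> float:
    """DG_b0 = DG_MetaD - TdS (same units in, same units out)."""
    return dg_metad - tds


def kd_from_dg(
    dg_b: float,
    temperature: float = 300.0,
    standard_concentration: float = 1.0,
    gas_constant: float = R_KCAL_PER_MOL_K,
) -> float:
    """Dissociation constant K_d = C0 exp(DG_b0 / RT).

    More negative binding free energy gives a smaller K_d.  Units follow
    ``standard_concentration`` (mol/L by default).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return float(
        standard_concentration
        * np.exp(dg_b / (gas_constant * temperature))
    )


@dataclass
class ThermoResult:
    """Bookkeeping row: DG_MetaD -> DG_b0 -> K_d with its error bar."""

    dg_metad: float  # kcal/mol
    tds: float  # kcal/mol
    dg_b: float  # kcal/mol
    kd_mM: float
    block_se: float = 0.0  # kcal/mol, on DG_MetaD
    dg_b_se: float = 0.0  # kcal/mol, propagated (equal: TdS is exact)
    temperature: float = 300.0

    def __post_init__(self):
        if abs(self.dg_b - (self.dg_metad - self.tds)) > 1e-9:
            raise ValueError("DG_b0 != DG_MetaD - TdS")
        kd_expected = 1e3 * kd_from_dg(self.dg_b, self.temperature)
        if abs(self.kd_mM - kd_expected) > 1e-9 * max(1.0, kd_expected):
            raise ValueError("K_d inconsistent with DG_b0")

    @classmethod
    def from_dg(
        cls, dg_metad: float, params: ThermoParams, block_se: float = 0.0
    ) -> "ThermoResult":
        tds = volume_entropy_correction(params)
        dg_b = standard_binding_free_energy(dg_metad, tds)
        return cls(
            dg_metad=dg_metad,
            tds=tds,
            dg_b=dg_b,
            kd_mM=1e3 * kd_from_dg(dg_b, params.temperature),
            block_se=block_se,
            dg_b_se=block_se,
            temperature=params.temperature,
        )


# --------------------------------------------------------------------------
# error bars and convergence
# --------------------------------------------------------------------------
@dataclass
class BlockAnalysis:
    sizes: np.ndarray
    errors: np.ndarray

    @property
    def error(self) -> float:
        """Plateau estimate: the largest standard error over the scan."""
        return float(np.max(self.errors)) if len(self.errors) else 0.0


def block_error(values, weights=None, block_sizes=None) -> BlockAnalysis:
    """Block-analysis standard error of a (weighted) mean.

    For each block size the series is cut into contiguous blocks, block
    means are treated as (approximately) independent, and the standard
    error of the overall mean is computed from their scatter.  For
    correlated data the error grows with block size and plateaus at the
    true statistical error; the reported value is the maximum over the
    scanned sizes.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != n:
        raise ValueError("weights must match values")
    if block_sizes is None:
        block_sizes = [2**k for k in range(0, max(1, int(np.log2(n // 2)) + 1))]
    block_sizes = sorted(set(int(b) for b in block_sizes))
    if n < 2 * min(block_sizes):
        raise ValueError("need at least two blocks at the smallest size")
    sizes, errs = [], []
    for b in block_sizes:
        n_blocks = n // b
        if n_blocks < 2:
            continue
        xb = x[: n_blocks * b].reshape(n_blocks, b)
        wb = w[: n_blocks * b].reshape(n_blocks, b)
        bw = wb.sum(axis=1)
        bm = (xb * wb).sum(axis=1) / bw
        frac = bw / bw.sum()
        mean = float((frac * bm).sum())
        var = float(np.sum(frac**2 * (bm - mean) ** 2)) * n_blocks / (
            n_blocks - 1.0
        )
        sizes.append(b)
        errs.append(np.sqrt(var))
    return BlockAnalysis(sizes=np.array(sizes), errors=np.array(errs))


def dg_block_error(
    cv_samples,
    bias_samples,
    c_samples,
    edges,
    bound: RegionBox,
    unbound: RegionBox,
    kT: float,
    n_blocks: int = 5,
) -> float:
    """Standard error of DG_MetaD from contiguous-segment estimates."""
    cv = np.atleast_2d(np.asarray(cv_samples, dtype=float))
    if cv.shape[1] != len(edges):
        cv = cv.T
    n = cv.shape[0]
    if n < 2 * n_blocks:
        raise ValueError("too few samples for the requested block count")
    dgs = []
    for j in range(n_blocks):
        sl = slice(j * n // n_blocks, (j + 1) * n // n_blocks)
        try:
            f = reweight_fes(
                cv[sl], np.asarray(bias_samples)[sl], np.asarray(c_samples)[sl],
                edges, kT,
            )
            dgs.append(free_energy_difference(f, bound, unbound, kT))
        except ValueError:
            continue
    if len(dgs) < 2:
        raise ValueError("fewer than two usable blocks")
    dgs = np.asarray(dgs)
    return float(np.std(dgs, ddof=1) / np.sqrt(len(dgs)))


def dg_convergence(
    cv_samples,
    times,
    bias_samples,
    state: ReweightState,
    edges,
    bound: RegionBox,
    unbound: RegionBox,
    kT: float,
    checkpoints,
    discard_fraction: float = 0.1,
) -> np.ndarray:
    """DG_MetaD recomputed with data up to each checkpoint time.

    The first ``discard_fraction`` of the run (by time) is discarded as
    the filling transient before reweighting.
    """
    t = np.asarray(times, dtype=float)
    cps = np.asarray(checkpoints, dtype=float)
    if np.any(np.diff(cps) <= 0):
        raise ValueError("checkpoints must be increasing")
    cv = np.atleast_2d(np.asarray(cv_samples, dtype=float))
    if cv.shape[1] != len(edges):
        cv = cv.T
    v = np.asarray(bias_samples, dtype=float)
    c = c_at_times(state, t)
    t_min = discard_fraction * t[-1]
    out = np.empty(len(cps))
    for i, cp in enumerate(cps):
        sel = (t >= t_min) & (t <= cp)
        if sel.sum() < 10:
            out[i] = np.nan
            continue
        f = reweight_fes(cv[sel], v[sel], c[sel], edges, kT)
        out[i] = free_energy_difference(f, bound, unbound, kT)
    return out
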