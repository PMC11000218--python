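"""Readers/writers for PLUMED-style whitespace tables and run configs.

Formats: COLVAR-like CV/bias time series and HILLS-like Gaussian
deposition records (``#! FIELDS ...`` header, one numeric row per
record), a plain-text FES grid, an escape-time table, and a
YAML run configuration validated against a strict schema.  Values are
printed at 12 significant digits and round-trip exactly at that
precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .fes import FESGrid
from .metad import BiasTrace, Hill

__all__ = [
    "ColvarTable",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
    "read_fes",
    "write_fes",
    "read_escape_table",
    "write_escape_table",
    "read_traces",
    "write_traces",
    "RunConfig",
    "load_config",
    "config_hash",
]

_FMT = "%.12e"


class ParseError(ValueError):
    pass


@dataclass
class ColvarTable:
    """Named numeric columns from a ``#! FIELDS`` table."""

    names: list
    data: np.ndarray  # (n_rows, n_cols)
    comments: list = field(default_factory=list)
    source: str | None = None
    # time-series tables require a strictly increasing time column;
    # per-run tables (one row per run) switch this off
    check_time: bool = True

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.size == 0:
            self.data = self.data.reshape(0, len(self.names))
        if self.data.shape[1] != len(self.names):
            raise ValueError("column names do not match data width")
        if self.check_time and "time" in self.names:
            t = self.column("time")
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("time column must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.names)


def read_colvar(path, check_time: bool = True) -> ColvarTable:
    """Parse a COLVAR-like whitespace table; errors carry line numbers."""
    path = Path(path)
    names = None
    comments = []
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#!"):
                parts = s.split()
                if len(parts) >= 2 and parts[1] == "FIELDS":
                    names = parts[2:]
                else:
                    comments.append(s)
                continue
            if s.startswith("#"):
                continue
            if names is None:
                raise ParseError(
                    f"{path}:{ln}: data before the '#! FIELDS' header"
                )
            vals = s.split()
            if len(vals) != len(names):
                raise ParseError(
                    f"{path}:{ln}: expected {len(names)} columns, "
                    f"got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
    if names is None:
        raise ParseError(f"{path}: missing '#! FIELDS' header")
    data = np.array(rows, dtype=float).reshape(len(rows), len(names))
    try:
        return ColvarTable(
            names=names, data=data, comments=comments, source=str(path),
            check_time=check_time,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_colvar(table: ColvarTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(table.names) + "\n")
        for c in table.comments:
            fh.write(c + "\n")
        np.savetxt(fh, table.data, fmt=_FMT)


def write_hills(hills, path, cv_names=None, bias_factor: float = 0.0) -> None:
    """HILLS-like table: time, centers, widths, height, biasf."""
    path = Path(path)
    if hills:
        k = len(hills[0].center)
    else:
        k = len(cv_names) if cv_names else 1
    if cv_names is None:
        cv_names = [f"cv{i + 1}" for i in range(k)]
    names = (
        ["time"] + list(cv_names) + [f"sigma_{c}" for c in cv_names]
        + ["height", "biasf"]
    )
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for h in hills:
            row = (
                [h.time] + list(h.center) + list(h.widths)
                + [h.height, bias_factor]
            )
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_hills(path):
    """Read a HILLS-like table back into (hills, cv_names, bias_factor)."""
    t = read_colvar(path)
    names = t.names
    if names[-2:] != ["height", "biasf"]:
        raise ParseError(f"{path}: not a HILLS table (missing height/biasf)")
    k = (len(names) - 3) // 2
    cv_names = names[1 : 1 + k]
    hills = [
        Hill(
            center=tuple(row[1 : 1 + k]),
            widths=tuple(row[1 + k : 1 + 2 * k]),
            height=float(row[1 + 2 * k]),
            time=float(row[0]),
        )
        for row in t.data
    ]
    biasf = float(t.data[0, -1]) if len(t.data) else 0.0
    return hills, cv_names, biasf


def write_fes(fes: FESGrid, path, cv_names=None) -> None:
    """Plain-text FES grid: edge metadata lines plus one row per cell."""
    k = len(fes.edges)
    if cv_names is None:
        cv_names = [f"cv{i + 1}" for i in range(k)]
    centers = fes.centers
    mesh = np.meshgrid(*centers, indexing="ij")
    n_eff = (
        fes.effective_samples
        if fes.effective_samples is not None
        else np.zeros_like(fes.free_energy)
    )
    with open(path, "w") as fh:
        fh.write(
            "#! FIELDS " + " ".join(cv_names) + " free_energy n_eff\n"
        )
        fh.write(f"#! SET kT {_FMT % fes.kT}\n")
        fh.write(f"#! SET shifted {int(fes.shifted)}\n")
        for name, e in zip(cv_names, fes.edges):
            fh.write(
                f"#! SET edges_{name} " + " ".join(_FMT % v for v in e) + "\n"
            )
        cols = [m.ravel() for m in mesh] + [
            fes.free_energy.ravel(), n_eff.ravel()
        ]
        for row in zip(*cols):
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_fes(path) -> FESGrid:
    path = Path(path)
    kT = None
    shifted = True
    edges = {}
    names = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#!"):
                parts = s.split()
                if parts[1] == "FIELDS":
                    names = parts[2:]
                elif parts[1] == "SET" and parts[2] == "kT":
                    kT = float(parts[3])
                elif parts[1] == "SET" and parts[2] == "shifted":
                    shifted = bool(int(parts[3]))
                elif parts[1] == "SET" and parts[2].startswith("edges_"):
                    edges[parts[2][6:]] = np.array(
                        [float(v) for v in parts[3:]]
                    )
                continue
            rows.append([float(v) for v in s.split()])
    if names is None or kT is None or not edges:
        raise ParseError(f"{path}: incomplete FES header")
    cv_names = names[:-2]
    edge_list = [edges[n] for n in cv_names]
    shape = tuple(len(e) - 1 for e in edge_list)
    data = np.array(rows, dtype=float)
    f = data[:, len(cv_names)].reshape(shape)
    n_eff = data[:, len(cv_names) + 1].reshape(shape)
    return FESGrid(
        edges=edge_list, free_energy=f, kT=kT, shifted=shifted,
        effective_samples=n_eff,
    )


def write_escape_table(data, path) -> None:
    """One row per run: run_id, biased escape time, event flag (1/0)."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS run_id time event\n")
        for i, (t, e) in enumerate(zip(data.times, data.events)):
            fh.write(f"{i:d} {_FMT % t} {int(e):d}\n")


def read_escape_table(path):
    """Returns (times, events) arrays from an escape-time table."""
    t = read_colvar(path, check_time=False)
    if t.names != ["run_id", "time", "event"]:
        raise ParseError(f"{path}: not an escape-time table")
    return t.data[:, 1].copy(), t.data[:, 2].astype(bool)


def write_traces(traces, path) -> None:
    """Bias traces on a common grid as one wide table (time, v_000...)."""
    grid = traces[0].times
    n = max(len(tr.times) for tr in traces)
    longest = max(traces, key=lambda tr: len(tr.times))
    grid = longest.times
    cols = [grid]
    for tr in traces:
        v = np.full(n, np.nan)
        v[: len(tr.values)] = tr.values
        cols.append(v)
    names = ["time"] + [f"v_{i:03d}" for i in range(len(traces))]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        np.savetxt(fh, np.column_stack(cols), fmt=_FMT)


def read_traces(path):
    """Inverse of :func:`write_traces` (NaN padding trimmed per run)."""
    t = read_colvar(path)
    grid = t.column("time")
    traces = []
    for name in t.names[1:]:
        v = t.column(name)
        m = ~np.isnan(v)
        traces.append(BiasTrace(times=grid[m].copy(), values=v[m].copy()))
    return traces


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------
class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSystemConfig(_Strict):
    kind: str = "double_well_1d"  # or radial_binding_2d
    barrier: float = 5.0  # kT; double-well barrier or radial target barrier


class LangevinSection(_Strict):
    timestep: float = 0.005
    friction: float = 1.0
    kT: float = 1.0
    n_steps: int = 200_000
    seed: int = 0
    save_stride: int = 10


class WallSection(_Strict):
    k: float = 0.0
    rho_s: float = 3.5


class MetadSection(_Strict):
    height: float = 0.8
    stride_time: float = 1.0
    sigma: float = 0.15
    bias_factor: float = 10.0


class FESSection(_Strict):
    n_bins: int = 60
    transient_fraction: float = 0.1
    bound: list = Field(default_factory=lambda: [[-1.5, -0.5]])
    unbound: list = Field(default_factory=lambda: [[0.5, 1.5]])


class ThermoSection(_Strict):
    temperature: float = 300.0
    restraint_radius: float = 28.0  # Angstrom
    protein_volume: float = 48300.0  # Angstrom^3
    standard_volume: float = 1660.0  # Angstrom^3


class KineticsSection(_Strict):
    n_runs: int = 41
    cn_threshold: float = 0.01
    horizon: float = 2000.0
    n_boot: int = 50
    bootstrap_seed: int = 0


class RunConfig(_Strict):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_system: ModelSystemConfig = Field(default_factory=ModelSystemConfig)
    langevin: LangevinSection = Field(default_factory=LangevinSection)
    wall: WallSection = Field(default_factory=WallSection)
    metad: MetadSection = Field(default_factory=MetadSection)
    fes: FESSection = Field(default_factory=FESSection)
    thermo: ThermoSection = Field(default_factory=ThermoSection)
    kinetics: KineticsSection = Field(default_factory=KineticsSection)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a configuration, for run provenance."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
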