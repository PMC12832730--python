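"""Hemolysis-severity metrics per snapshot and over the systolic window.

A :class:`FlowSnapshot` is one time instant of solver output: per-cell
volume, centroid, velocity, velocity-gradient tensor and optional
turbulence channels, plus per-wall-face area, wall shear stress, optional
pressure and a wall-group label.  The severity metrics flag hemolysis via
a critical shear-stress threshold (300 Pa by default):

* V300 — fluid volume where tau >= tau_c;
* A300 — wall area (by default the leak wall group) where tau >= tau_c;
* tauV_max / tauA_max — stress maxima over all cells / selected walls;
* tauV_avg / tauA_avg — volume-/area-weighted means over the critical
  subset only (absent when the subset is empty);
* u_avg — volume-weighted mean speed of the critical cells;
* t300 — residence-time estimate, cube root of V300 divided by u_avg.

The threshold comparison is inclusive (tau >= tau_c) throughout; the
analysis window defaults to 0.04-0.32 s, excluding valve opening/closing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ThresholdSpec
from .errors import SchemaError, UsageError, ValidationError

__all__ = [
    "FlowSnapshot",
    "SeveritySeries",
    "METRICS",
    "DEFAULT_WINDOW",
    "DEFAULT_WALL_GROUPS",
    "critical_volume",
    "critical_wall_area",
    "stress_extremes_and_averages",
    "StressStats",
    "residence_time",
    "mean_wall_pressure",
    "severity_series",
]

#: Metric columns of a severity series, in reporting order.
METRICS = ("V300", "A300", "tauV_max", "tauA_max", "tauV_avg", "tauA_avg", "u_avg", "t300")

#: Systolic analysis window (s), excluding valve opening/closing transients.
DEFAULT_WINDOW = (0.04, 0.32)

#: Wall groups used for the area-based metrics by default (leak wall only).
DEFAULT_WALL_GROUPS = ("wall-pvl",)


@dataclass
class FlowSnapshot:
    """One time instant of per-cell and per-wall-face flow data (SI units).

    Cell channels are 1-D (or (n,3)/(n,3,3)) arrays over n cells; wall
    channels are arrays over m wall faces.  ``cell_tau`` is populated by
    :func:`pvlhemo.rheostress.snapshot_stress`; ``cell_mu_t`` defaults to
    zero and ``cell_k`` is carried but unused.
    """

    time: float
    cell_volume: np.ndarray
    cell_centroid: np.ndarray
    cell_velocity: np.ndarray
    cell_grad_v: Optional[np.ndarray] = None
    cell_mu_t: Optional[np.ndarray] = None
    cell_k: Optional[np.ndarray] = None
    cell_tau: Optional[np.ndarray] = None
    wall_area: np.ndarray = field(default_factory=lambda: np.empty(0))
    wall_tau: np.ndarray = field(default_factory=lambda: np.empty(0))
    wall_pressure: Optional[np.ndarray] = None
    wall_group: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U16"))

    def __post_init__(self) -> None:
        self.cell_volume = np.asarray(self.cell_volume, dtype=float)
        self.cell_centroid = np.asarray(self.cell_centroid, dtype=float)
        self.cell_velocity = np.asarray(self.cell_velocity, dtype=float)
        for name in ("cell_grad_v", "cell_mu_t", "cell_k", "cell_tau", "wall_pressure"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        self.wall_area = np.asarray(self.wall_area, dtype=float)
        self.wall_tau = np.asarray(self.wall_tau, dtype=float)
        self.wall_group = np.asarray(self.wall_group)
        self.validate()

    def validate(self) -> None:
        n = len(self.cell_volume)
        if self.time < 0:
            raise ValidationError(f"snapshot time must be non-negative, got {self.time}")
        if np.any(self.cell_volume <= 0):
            raise ValidationError("cell volumes must be positive")
        if self.cell_centroid.shape != (n, 3) or self.cell_velocity.shape != (n, 3):
            raise SchemaError("cell centroid/velocity must have shape (n, 3)")
        if self.cell_grad_v is not None and self.cell_grad_v.shape != (n, 3, 3):
            raise SchemaError("cell velocity_gradient must have shape (n, 3, 3)")
        for name in ("cell_mu_t", "cell_k", "cell_tau"):
            v = getattr(self, name)
            if v is not None and v.shape != (n,):
                raise SchemaError(f"{name} must have shape (n,)")
        if self.cell_mu_t is not None and np.any(self.cell_mu_t < 0):
            raise ValidationError("mu_t must be non-negative")
        m = len(self.wall_area)
        if np.any(self.wall_area <= 0):
            raise ValidationError("wall-face areas must be positive")
        if self.wall_tau.shape != (m,) or self.wall_group.shape != (m,):
            raise SchemaError("wall channels must share the face count")
        if self.wall_pressure is not None and self.wall_pressure.shape != (m,):
            raise SchemaError("wall_pressure must have shape (m,)")

    @property
    def n_cells(self) -> int:
        return len(self.cell_volume)

    @property
    def n_wall_faces(self) -> int:
        return len(self.wall_area)

    @property
    def total_fluid_volume(self) -> float:
        return float(self.cell_volume.sum())

    def wall_groups_present(self) -> set:
        return set(np.unique(self.wall_group).tolist())


def _require_tau(snapshot: FlowSnapshot) -> np.ndarray:
    if snapshot.cell_tau is None:
        raise SchemaError("per-cell tau not populated; run rheostress.snapshot_stress first")
    return snapshot.cell_tau


def _wall_mask(snapshot: FlowSnapshot, groups: Optional[Sequence[str]]) -> np.ndarray:
    if groups is None:
        return np.ones(snapshot.n_wall_faces, dtype=bool)
    present = snapshot.wall_groups_present()
    unknown = [g for g in groups if g not in present]
    if unknown:
        raise UsageError(f"unknown wall group(s) {unknown}; present: {sorted(present)}")
    return np.isin(snapshot.wall_group, list(groups))


def critical_volume(snapshot: FlowSnapshot, spec: ThresholdSpec = ThresholdSpec()) -> float:
    """V300: total volume (m^3) of cells at or above the critical stress."""
    tau = _require_tau(snapshot)
    return float(snapshot.cell_volume[spec.mask(tau)].sum())


def critical_wall_area(
    snapshot: FlowSnapshot,
    spec: ThresholdSpec = ThresholdSpec(),
    groups: Optional[Sequence[str]] = DEFAULT_WALL_GROUPS,
) -> float:
    """A300: wall area (m^2) in the selected groups at/above the threshold."""
    sel = _wall_mask(snapshot, groups)
    return float(snapshot.wall_area[sel & spec.mask(snapshot.wall_tau)].sum())


@dataclass(frozen=True)
class StressStats:
    """Stress maxima over everything, means over the critical subset only."""

    tauV_max: float
    tauA_max: float
    tauV_avg: float  # NaN when no cell is critical
    tauA_avg: float  # NaN when no selected face is critical


def stress_extremes_and_averages(
    snapshot: FlowSnapshot,
    spec: ThresholdSpec = ThresholdSpec(),
    groups: Optional[Sequence[str]] = DEFAULT_WALL_GROUPS,
) -> StressStats:
    """Maximum and critical-subset-averaged stresses (Pa).

    Maxima run over all cells and the selected wall groups; averages are
    volume-weighted (cells) / area-weighted (faces) over the critical
    subset and reported as NaN (absent) when that subset is empty.
    """
    tau = _require_tau(snapshot)
    sel = _wall_mask(snapshot, groups)
    wtau = snapshot.wall_tau[sel]
    warea = snapshot.wall_area[sel]

    tauV_max = float(tau.max()) if tau.size else float("nan")
    tauA_max = float(wtau.max()) if wtau.size else float("nan")

    cmask = spec.mask(tau)
    if cmask.any():
        w = snapshot.cell_volume[cmask]
        tauV_avg = float(np.average(tau[cmask], weights=w))
    else:
        tauV_avg = float("nan")
    fmask = spec.mask(wtau)
    if fmask.any():
        tauA_avg = float(np.average(wtau[fmask], weights=warea[fmask]))
    else:
        tauA_avg = float("nan")
    return StressStats(tauV_max, tauA_max, tauV_avg, tauA_avg)


def residence_time(
    snapshot: FlowSnapshot, spec: ThresholdSpec = ThresholdSpec()
) -> tuple[float, float]:
    """(u_avg, t300): mean critical-cell speed and residence-time estimate.

    u_avg = (1/V300) * sum over critical cells of |u_i| V_i, and
    t300 = V300^(1/3) / u_avg.  When no cell is critical both are absent
    (NaN) and a warning is issued rather than an exception.
    """
    tau = _require_tau(snapshot)
    cmask = spec.mask(tau)
    if not cmask.any():
        warnings.warn("no critical cells: u_avg and t300 are undefined", stacklevel=2)
        return float("nan"), float("nan")
    vol = snapshot.cell_volume[cmask]
    speed = np.linalg.norm(snapshot.cell_velocity[cmask], axis=1)
    V300 = float(vol.sum())
    u_avg = float(np.sum(speed * vol) / V300)
    t300 = float(np.cbrt(V300) / u_avg)
    return u_avg, t300


def mean_wall_pressure(snapshot: FlowSnapshot, group: str) -> float:
    """Area-weighted mean wall pressure (Pa) over one wall group."""
    if snapshot.wall_pressure is None:
        raise SchemaError("snapshot has no wall pressure channel")
    sel = _wall_mask(snapshot, (group,))
    if not sel.any():
        raise UsageError(f"wall group {group!r} selects no faces")
    return float(np.average(snapshot.wall_pressure[sel], weights=snapshot.wall_area[sel]))


@dataclass
class SeveritySeries:
    """Time series of the severity metrics over the analysis window.

    ``frame`` has a ``time`` column (s) plus one column per metric in
    :data:`METRICS`; absent values (empty critical subsets) are NaN.
    """

    frame: pd.DataFrame
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        missing = [c for c in ("time", *METRICS) if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"severity series missing columns: {missing}")
        t = self.frame["time"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("severity-series times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    def metric(self, name: str) -> np.ndarray:
        if name not in METRICS:
            raise UsageError(f"unknown metric {name!r}; known: {METRICS}")
        return self.frame[name].to_numpy()

    def copy(self) -> "SeveritySeries":
        return SeveritySeries(self.frame.copy(), self.window)


def severity_series(
    snapshots: Sequence[FlowSnapshot],
    spec: ThresholdSpec = ThresholdSpec(),
    window: tuple[float, float] = DEFAULT_WINDOW,
    groups: Optional[Sequence[str]] = DEFAULT_WALL_GROUPS,
) -> SeveritySeries:
    """Apply every per-snapshot metric over the analysis window.

    Snapshots must be in strictly increasing time order; only those with
    t_lo <= t <= t_hi (inclusive) contribute.
    """
    times = np.array([s.time for s in snapshots], dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValidationError("snapshots must be ordered by strictly increasing time")
    t_lo, t_hi = window
    rows = []
    for snap in snapshots:
        if not (t_lo <= snap.time <= t_hi):
            continue
        stats = stress_extremes_and_averages(snap, spec, groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u_avg, t300 = residence_time(snap, spec)
        rows.append(
            {
                "time": snap.time,
                "V300": critical_volume(snap, spec),
                "A300": critical_wall_area(snap, spec, groups),
                "tauV_max": stats.tauV_max,
                "tauA_max": stats.tauA_max,
                "tauV_avg": stats.tauV_avg,
                "tauA_avg": stats.tauA_avg,
                "u_avg": u_avg,
                "t300": t300,
            }
        )
    frame = pd.DataFrame(rows, columns=["time", *METRICS])
    return SeveritySeries(frame, window=window)
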