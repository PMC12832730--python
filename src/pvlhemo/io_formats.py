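"""Readers and writers for the on-disk formats.

Conventions
-----------
* Surface meshes travel as STL (ASCII or binary, via trimesh) with
  coordinates in mm — the medical-imaging convention; a JSON sidecar can
  override the unit.
* Flow snapshots travel as a documented container: a directory holding
  ``meta.json`` (time, units, counts), ``cells.csv`` and ``walls.csv``
  with fixed column names.  All field data are SI.
* Every CSV written by the package carries a header row and a units row.
* Parsing is locale-independent: comma separators, UTF-8, '.' decimal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, UnitError, ValidationError
from .geometry import TriSurface, boundary_edges, enclosed_volume
from .severity import METRICS, FlowSnapshot, SeveritySeries

__all__ = [
    "read_surface",
    "write_surface",
    "read_snapshot",
    "write_snapshot",
    "read_severity_series",
    "write_severity_series",
    "write_waveforms",
    "write_comparison",
    "RunManifest",
]

_CELL_COLUMNS = {
    "volume": "m3",
    "cx": "m", "cy": "m", "cz": "m",
    "vx": "m_s", "vy": "m_s", "vz": "m_s",
    "g00": "1_s", "g01": "1_s", "g02": "1_s",
    "g10": "1_s", "g11": "1_s", "g12": "1_s",
    "g20": "1_s", "g21": "1_s", "g22": "1_s",
}
_CELL_OPTIONAL = {"mu_t": "Pa_s", "k": "m2_s2", "tau": "Pa"}
_WALL_COLUMNS = {"area": "m2", "tau_wall": "Pa", "group": "-"}
_WALL_OPTIONAL = {"pressure": "Pa"}

_METRIC_UNITS = {
    "time": "s", "V300": "m3", "A300": "m2",
    "tauV_max": "Pa", "tauA_max": "Pa", "tauV_avg": "Pa", "tauA_avg": "Pa",
    "u_avg": "m_s", "t300": "s",
}


# ---------------------------------------------------------------------------
# Surfaces (STL)


def read_surface(path, unit: str = "mm", strict: bool = True) -> TriSurface:
    """Read an STL surface; validate watertightness and normalise orientation.

    Duplicate vertices are merged (STL stores a triangle soup).  An
    inward-oriented surface is silently reoriented outward.  With
    ``strict`` (default) a surface with boundary edges raises a validation
    error listing the count; ``strict=False`` downgrades that to a warning.
    """
    import trimesh

    mesh = trimesh.load_mesh(str(path))
    surf = TriSurface(np.asarray(mesh.vertices, dtype=float),
                      np.asarray(mesh.faces, dtype=np.int64), unit=unit)
    bad = boundary_edges(surf)
    if len(bad):
        msg = f"{path}: surface has {len(bad)} boundary/non-manifold edges"
        if strict:
            raise ValidationError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
        return surf
    if enclosed_volume(surf, validate=False) < 0:
        surf.faces = surf.faces[:, ::-1]
    return surf


def write_surface(surface: TriSurface, path, ascii_stl: bool = True) -> None:
    """Write a surface to STL (ASCII by default) with a JSON unit sidecar."""
    import trimesh

    mesh = trimesh.Trimesh(surface.vertices, surface.faces, process=False)
    path = Path(path)
    if ascii_stl:
        path.write_text(
            mesh.export(file_type="stl_ascii"), encoding="utf-8"
        )
    else:
        mesh.export(str(path))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"unit": surface.unit}), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Flow snapshots (directory container: meta.json + cells.csv + walls.csv)


def write_snapshot(snapshot: FlowSnapshot, path) -> None:
    """Write a snapshot to its directory container (SI units throughout)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cells = {
        "volume": snapshot.cell_volume,
        "cx": snapshot.cell_centroid[:, 0],
        "cy": snapshot.cell_centroid[:, 1],
        "cz": snapshot.cell_centroid[:, 2],
        "vx": snapshot.cell_velocity[:, 0],
        "vy": snapshot.cell_velocity[:, 1],
        "vz": snapshot.cell_velocity[:, 2],
    }
    if snapshot.cell_grad_v is not None:
        for i in range(3):
            for j in range(3):
                cells[f"g{i}{j}"] = snapshot.cell_grad_v[:, i, j]
    for name, attr in (("mu_t", "cell_mu_t"), ("k", "cell_k"), ("tau", "cell_tau")):
        v = getattr(snapshot, attr)
        if v is not None:
            cells[name] = v
    cdf = pd.DataFrame(cells)
    walls = {
        "area": snapshot.wall_area,
        "tau_wall": snapshot.wall_tau,
        "group": snapshot.wall_group,
    }
    if snapshot.wall_pressure is not None:
        walls["pressure"] = snapshot.wall_pressure
    wdf = pd.DataFrame(walls)

    units = {**_CELL_COLUMNS, **_CELL_OPTIONAL, **_WALL_COLUMNS, **_WALL_OPTIONAL}
    _write_csv_with_units(cdf, path / "cells.csv", units)
    _write_csv_with_units(wdf, path / "walls.csv", units)
    meta = {
        "format": "pvlhemo-snapshot-v1",
        "time_s": snapshot.time,
        "n_cells": snapshot.n_cells,
        "n_wall_faces": snapshot.n_wall_faces,
        "length_unit": "m",
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_snapshot(path) -> FlowSnapshot:
    """Read a snapshot container; missing mandatory channels raise by name."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SchemaError(f"{path}: not a snapshot container (meta.json missing)")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))
    if meta.get("length_unit", "m") != "m":
        raise UnitError(f"{path}: snapshot fields must be SI (m), got {meta['length_unit']!r}")
    cdf = _read_csv_with_units(path / "cells.csv")
    wdf = _read_csv_with_units(path / "walls.csv")
    for col in ("volume", "cx", "cy", "cz", "vx", "vy", "vz"):
        if col not in cdf.columns:
            raise SchemaError(f"{path}: cells.csv missing mandatory channel {col!r}")
    grad_cols = [f"g{i}{j}" for i in range(3) for j in range(3)]
    missing_grad = [c for c in grad_cols if c not in cdf.columns]
    if missing_grad:
        raise SchemaError(
            f"{path}: cells.csv missing mandatory channel 'velocity_gradient' "
            f"(columns {missing_grad})"
        )
    n = len(cdf)
    grad = np.stack(
        [cdf[f"g{i}{j}"].to_numpy() for i in range(3) for j in range(3)], axis=1
    ).reshape(n, 3, 3)
    for col in ("area", "tau_wall", "group"):
        if col not in wdf.columns:
            raise SchemaError(f"{path}: walls.csv missing mandatory channel {col!r}")
    return FlowSnapshot(
        time=float(meta["time_s"]),
        cell_volume=cdf["volume"].to_numpy(),
        cell_centroid=cdf[["cx", "cy", "cz"]].to_numpy(),
        cell_velocity=cdf[["vx", "vy", "vz"]].to_numpy(),
        cell_grad_v=grad,
        cell_mu_t=cdf["mu_t"].to_numpy() if "mu_t" in cdf.columns else None,
        cell_k=cdf["k"].to_numpy() if "k" in cdf.columns else None,
        cell_tau=cdf["tau"].to_numpy() if "tau" in cdf.columns else None,
        wall_area=wdf["area"].to_numpy(),
        wall_tau=wdf["tau_wall"].to_numpy(),
        wall_pressure=wdf["pressure"].to_numpy() if "pressure" in wdf.columns else None,
        wall_group=wdf["group"].to_numpy().astype("U16"),
    )


# ---------------------------------------------------------------------------
# CSV with a units row


def _write_csv_with_units(df: pd.DataFrame, path, units: dict) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(df.columns) + "\n")
        fh.write(",".join(units.get(c, "-") for c in df.columns) + "\n")
        df.to_csv(fh, index=False, header=False, float_format="%.17g")


def _read_csv_with_units(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"missing file {path}")
    return pd.read_csv(path, skiprows=[1])


def write_severity_series(series: SeveritySeries, path) -> None:
    """Severity series to CSV (header + units row)."""
    _write_csv_with_units(series.frame, path, _METRIC_UNITS)


def read_severity_series(path, window=None) -> SeveritySeries:
    df = _read_csv_with_units(path)
    missing = [c for c in ("time", *METRICS) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: severity CSV missing columns {missing}")
    kwargs = {} if window is None else {"window": tuple(window)}
    return SeveritySeries(df, **kwargs)


def write_waveforms(df: pd.DataFrame, path) -> None:
    """Boundary-condition waveform table to CSV (header + units row)."""
    units = {"t_s": "s", "Q_m3s": "m3_s", "ejected_m3": "m3",
             "pLA_mmHg": "mmHg", "paorta_mmHg": "mmHg"}
    _write_csv_with_units(df, path, units)


def write_comparison(summary, path) -> None:
    """Comparison summary (metrics x (eps, sigma)) to CSV."""
    df = summary.table.reset_index()
    units = {"metric": "-", "eps_mean_pct": "pct", "eps_std_pct": "pct",
             "n_used": "-", "n_skipped": "-"}
    _write_csv_with_units(df, path, units)


# ---------------------------------------------------------------------------
# Run manifest


@dataclass
class RunManifest:
    """Inventory of one model-variant run on disk."""

    variant: str
    snapshot_dirs: Sequence[str]
    times: Sequence[float]
    keyframes: Sequence[str]
    seed: int
    config_hash: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) != len(self.snapshot_dirs):
            raise ValidationError("one time per snapshot required")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("manifest times must be strictly increasing")

    def validate_paths(self, root) -> None:
        root = Path(root)
        missing = [p for p in (*self.snapshot_dirs, *self.keyframes)
                   if not (root / p).exists()]
        if missing:
            raise ValidationError(f"manifest references missing paths: {missing}")

    def write(self, path) -> None:
        payload = {
            "variant": self.variant,
            "snapshots": [{"path": p, "time_s": t}
                          for p, t in zip(self.snapshot_dirs, self.times)],
            "keyframes": list(self.keyframes),
            "seed": self.seed,
            "config_hash": self.config_hash,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def read(cls, path) -> "RunManifest":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            variant=payload["variant"],
            snapshot_dirs=[s["path"] for s in payload["snapshots"]],
            times=[s["time_s"] for s in payload["snapshots"]],
            keyframes=payload.get("keyframes", []),
            seed=payload.get("seed", 0),
            config_hash=payload.get("config_hash", ""),
        )


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
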