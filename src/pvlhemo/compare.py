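"""Model-variant comparison: relative-error series and summary tables.

Simplified model variants (universal geometry, static mesh, or both) are
judged against the reference run by the per-time relative error of each
severity metric,

    eps_X(t) = 100 * |X_var(t) - X_ref(t)| / |X_ref(t)|   [%],

always normalised by the reference.  Summaries report the mean and the
population standard deviation of eps over the analysis window — the
standard deviation is descriptive over a fixed time grid, not an estimate
from a sample.  Timepoints where the reference magnitude falls below an
absolute floor, or where a metric is absent, are skipped and counted so
truncation is never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError
from .severity import METRICS, SeveritySeries

__all__ = [
    "ErrorSeries",
    "ComparisonSummary",
    "relative_error_series",
    "summarize_errors",
    "flow_split",
    "FlowSplit",
]


@dataclass
class ErrorSeries:
    """Per-time relative errors (%) per metric, plus skipped-point counts."""

    eps: pd.DataFrame  # 'time' column + one column per metric, NaN where skipped
    skipped: dict
    ref_label: str = "reference"
    variant_label: str = "variant"
    window: tuple[float, float] = (0.04, 0.32)


@dataclass
class ComparisonSummary:
    """Per-metric mean and population standard deviation of eps (%)."""

    table: pd.DataFrame  # index: metric; columns: eps_mean_pct, eps_std_pct, n_used, n_skipped
    ref_label: str = "reference"
    variant_label: str = "variant"
    window: tuple[float, float] = (0.04, 0.32)


def _resample(variant: SeveritySeries, ref_times: np.ndarray) -> pd.DataFrame:
    vt = variant.times
    if ref_times.min() < vt.min() - 1e-12 or ref_times.max() > vt.max() + 1e-12:
        raise ValidationError(
            "variant time range does not cover the reference grid; cannot resample"
        )
    out = {"time": ref_times}
    for m in METRICS:
        out[m] = np.interp(ref_times, vt, variant.metric(m))
    return pd.DataFrame(out)


def relative_error_series(
    ref: SeveritySeries,
    variant: SeveritySeries,
    floor: float = 1e-12,
    metrics: Sequence[str] = METRICS,
    ref_label: str = "reference",
    variant_label: str = "variant",
) -> ErrorSeries:
    """Per-time relative error (%) of each metric, variant versus reference.

    If the time grids differ, the variant is resampled onto the reference
    grid by linear interpolation.  Timepoints with |X_ref| < ``floor`` (SI
    units) or with absent (NaN) values are skipped and counted per metric.
    """
    rt = ref.times
    if len(rt) == 0:
        raise ValidationError("reference series is empty")
    vt = variant.times
    if len(vt) == len(rt) and np.allclose(vt, rt, rtol=0, atol=1e-12):
        vframe = variant.frame
    else:
        vframe = _resample(variant, rt)
    eps = {"time": rt}
    skipped = {}
    for m in metrics:
        if m not in METRICS:
            raise UsageError(f"unknown metric {m!r}")
        x_ref = ref.metric(m)
        x_var = vframe[m].to_numpy()
        ok = np.isfinite(x_ref) & np.isfinite(x_var) & (np.abs(x_ref) >= floor)
        e = np.full(len(rt), np.nan)
        e[ok] = 100.0 * np.abs(x_var[ok] - x_ref[ok]) / np.abs(x_ref[ok])
        eps[m] = e
        skipped[m] = int((~ok).sum())
    return ErrorSeries(
        pd.DataFrame(eps), skipped, ref_label, variant_label, window=ref.window
    )


def summarize_errors(err: ErrorSeries) -> ComparisonSummary:
    """Mean and population standard deviation of eps per metric.

    Metrics with no usable timepoint are reported absent (NaN) with a
    warning rather than dropped, so the table layout is stable.
    """
    rows = []
    for m in [c for c in err.eps.columns if c != "time"]:
        vals = err.eps[m].to_numpy()
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"metric {m}: every timepoint skipped; summary absent", stacklevel=2)
            mean, std = float("nan"), float("nan")
        else:
            mean = float(np.mean(vals))
            std = float(np.std(vals))  # population std: descriptive over the fixed grid
        rows.append(
            {
                "metric": m,
                "eps_mean_pct": mean,
                "eps_std_pct": std,
                "n_used": len(vals),
                "n_skipped": err.skipped.get(m, 0),
            }
        )
    table = pd.DataFrame(rows).set_index("metric")
    return ComparisonSummary(table, err.ref_label, err.variant_label, err.window)


@dataclass
class FlowSplit:
    """Leak fraction of total outflow: per-time series and window extremes."""

    times: np.ndarray
    fraction: np.ndarray  # Q_pvl / (Q_pvl + Q_aorta), NaN where skipped
    fraction_min: float
    fraction_max: float
    n_skipped: int


def flow_split(times, Q_aorta, Q_pvl, window: Optional[tuple[float, float]] = None) -> FlowSplit:
    """Fraction of total outflow passing through the leak.

    fraction(t) = Q_pvl / (Q_pvl + Q_aorta).  Timepoints with zero total
    flow are skipped (NaN) and counted; min/max are over the window (whole
    series if None).
    """
    t = np.asarray(times, dtype=float)
    qa = np.asarray(Q_aorta, dtype=float)
    qp = np.asarray(Q_pvl, dtype=float)
    if not (t.shape == qa.shape == qp.shape):
        raise ValidationError("times, Q_aorta and Q_pvl must be aligned 1-D series")
    total = qa + qp
    frac = np.full_like(total, np.nan)
    ok = total > 0
    frac[ok] = qp[ok] / total[ok]
    sel = ok if window is None else ok & (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise UsageError("no usable timepoints in the requested window")
    return FlowSplit(
        times=t,
        fraction=frac,
        fraction_min=float(frac[sel].min()),
        fraction_max=float(frac[sel].max()),
        n_skipped=int((~ok).sum()),
    )
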