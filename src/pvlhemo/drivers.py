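"""Analytic boundary-condition models for the systolic phase.

The ventricular outflow is a parabola in time,

    Q(t) = -4 Qmax / tmax^2 * (t - tmax/2)^2 + Qmax,

zero at both ends of systole and peaking at tmax/2, whose integral over
systole is the total ejected volume dV = (2/3) Qmax tmax.  Outlet pressures
are trigonometric approximations of measured atrial and aortic waveforms in
patients with a paravalvular leak (c-wave omitted).  All pressures are in
mmHg; flow is SI.
"""

from __future__ import annotations

import numpy as np

from .core import PressureParams, SystoleDrive
from .errors import DomainError, UsageError, ValidationError

__all__ = [
    "peak_flow",
    "flow_rate",
    "ejected_volume",
    "atrial_pressure",
    "aortic_pressure",
]


def peak_flow(dV_total: float, tmax: float) -> float:
    """Peak flow Qmax = 3 dV / (2 tmax) making the parabola eject dV.

    dV_total in m^3, tmax in s; result in m^3 s^-1.
    """
    if not tmax > 0:
        raise DomainError(f"tmax must be positive, got {tmax}")
    if dV_total < 0:
        raise DomainError(f"dV_total must be non-negative, got {dV_total}")
    return 3.0 * dV_total / (2.0 * tmax)


def _check_t(t, tmax: float) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0) or np.any(arr > tmax):
        raise DomainError(f"t must lie in [0, {tmax}]")
    return arr


def flow_rate(t, drive: SystoleDrive):
    """Parabolic systolic flow Q(t) in m^3 s^-1; vectorised over t."""
    tt = _check_t(t, drive.tmax)
    q = -4.0 * drive.Qmax / drive.tmax**2 * (tt - drive.tmax / 2.0) ** 2 + drive.Qmax
    return float(q) if q.ndim == 0 else q


def ejected_volume(t, drive: SystoleDrive):
    """Cumulative ejected volume (m^3): closed-form integral of Q from 0 to t.

    integral = Qmax * [t - 4/(3 tmax^2) * ((t - tmax/2)^3 + (tmax/2)^3)]
    """
    tt = _check_t(t, drive.tmax)
    half = drive.tmax / 2.0
    v = drive.Qmax * (tt - 4.0 / (3.0 * drive.tmax**2) * ((tt - half) ** 3 + half**3))
    return float(v) if v.ndim == 0 else v


def atrial_pressure(t, params: PressureParams, tmax: float = 0.36):
    """Left-atrial pressure profile in mmHg.

    p_LA(t) = 0.5 (pv - pa) (1 - cos(pi (t - ta)/(tmax - ta))) + pa,
    applied over the whole systole: the minimum pa_wave occurs at ta_wave
    (the x-descent) and the profile rises to pv_wave at end systole
    (v-wave); for t < ta_wave the same expression gives the tail of the
    a-wave.
    """
    if params.ta_wave >= tmax:
        raise ValidationError(f"ta_wave={params.ta_wave} must be below tmax={tmax}")
    tt = _check_t(t, tmax)
    arg = np.pi * (tt - params.ta_wave) / (tmax - params.ta_wave)
    p = 0.5 * (params.pv_wave - params.pa_wave) * (1.0 - np.cos(arg)) + params.pa_wave
    return float(p) if p.ndim == 0 else p


def aortic_pressure(t, params: PressureParams, tmax: float = 0.36):
    """Aortic pressure profile in mmHg (two-branch trigonometric model).

    ``as_printed`` mode evaluates the tabulated branches verbatim:

        t <  ta: 0.5 (pmax - pmin) (1 - cos(pi t / ta)) + pmin
        t >= ta: 0.5 (pmax - pmin) (1 - cos(2 pi (t - ta)/(tmax - ta))) + pmin

    which is discontinuous at ta (branch 1 reaches pmax there, branch 2
    restarts at pmin).  ``continuous`` mode replaces the second branch by
    0.5 (pmax - pmin)(1 + cos(pi (t - ta)/(tmax - ta))) + pmin, joining the
    first branch at pmax and decaying to pmin at tmax.  With
    ``swap_max_min`` the tabulated pmax/pmin values are exchanged.
    """
    if params.ta_wave >= tmax:
        raise ValidationError(f"ta_wave={params.ta_wave} must be below tmax={tmax}")
    if params.aortic_mode not in ("as_printed", "continuous"):
        raise UsageError(f"unknown aortic mode {params.aortic_mode!r}")
    tt = _check_t(t, tmax)
    pmax, pmin = params.pmax_effective, params.pmin_effective
    amp = 0.5 * (pmax - pmin)
    ta = params.ta_wave
    before = amp * (1.0 - np.cos(np.pi * tt / ta)) + pmin
    if params.aortic_mode == "as_printed":
        after = amp * (1.0 - np.cos(2.0 * np.pi * (tt - ta) / (tmax - ta))) + pmin
    else:
        after = amp * (1.0 + np.cos(np.pi * (tt - ta) / (tmax - ta))) + pmin
    p = np.where(tt < ta, before, after)
    return float(p) if p.ndim == 0 else p
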