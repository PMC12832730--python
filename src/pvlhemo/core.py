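"""Shared physical constants, parameter records and unit conversions.

All internal computation is carried out in SI units.  Millimetres (surface
meshes, channel dimensions) and millimetres of mercury (pressure tables)
appear only at configuration and reporting boundaries, with explicit
converters.

The parameter records collect the scalar constants of the study in one
place: blood density and Carreau-Yasuda rheology, the systolic flow drive
(peak flow ``Qmax``, systole duration ``tmax``, total ejected volume), the
trigonometric atrial/aortic pressure-profile constants, and the critical
shear-stress threshold of the hemolysis criterion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import numpy as np
import yaml

from .errors import DomainError, UsageError, ValidationError

__all__ = [
    "MMHG_TO_PA",
    "MM3_TO_M3",
    "M3_TO_MM3",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "BloodProps",
    "CYParams",
    "SystoleDrive",
    "PressureParams",
    "ThresholdSpec",
    "default_config",
    "load_config",
    "dump_config",
]

#: Conventional millimetre-of-mercury to pascal factor.
MMHG_TO_PA = 133.322

MM3_TO_M3 = 1e-9
M3_TO_MM3 = 1e9


def _require_finite(x: Any, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} must be finite")
    return arr


def mmhg_to_pa(p_mmhg):
    """Convert pressure from mmHg to Pa (factor 133.322).

    Accepts scalars or arrays; rejects non-finite input.  The inverse is
    :func:`pa_to_mmhg`; the round trip is exact to 1e-12 relative.
    """
    p = _require_finite(p_mmhg, "pressure")
    out = p * MMHG_TO_PA
    return float(out) if np.isscalar(p_mmhg) or out.ndim == 0 else out


def pa_to_mmhg(p_pa):
    """Convert pressure from Pa to mmHg (inverse of :func:`mmhg_to_pa`)."""
    p = _require_finite(p_pa, "pressure")
    out = p / MMHG_TO_PA
    return float(out) if np.isscalar(p_pa) or out.ndim == 0 else out


@dataclass(frozen=True)
class BloodProps:
    """Bulk blood properties: homogeneous fluid of constant density.

    Parameters
    ----------
    rho : float
        Mass density in kg m^-3.  Default 1060.
    """

    rho: float = 1060.0

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValidationError(f"rho must be positive, got {self.rho}")


@dataclass(frozen=True)
class CYParams:
    """Carreau-Yasuda shear-thinning viscosity constants.

    mu(gamma) = mu_inf + (mu0 - mu_inf) * [1 + (lam*gamma)^a]^((n-1)/a)

    Defaults are the blood-rheology constants used throughout the study:
    mu0 = 0.16 Pa s, mu_inf = 0.0035 Pa s, a = 0.64, n = 0.2128,
    lam = 8.2 s.
    """

    mu0: float = 0.16
    mu_inf: float = 0.0035
    a: float = 0.64
    n: float = 0.2128
    lam: float = 8.2

    def __post_init__(self) -> None:
        if not (self.mu0 >= self.mu_inf > 0):
            raise ValidationError(
                f"need mu0 >= mu_inf > 0, got mu0={self.mu0}, mu_inf={self.mu_inf}"
            )
        if not self.a > 0:
            raise ValidationError(f"a must be positive, got {self.a}")
        if self.lam < 0:
            raise ValidationError(f"lam must be non-negative, got {self.lam}")


@dataclass(frozen=True)
class SystoleDrive:
    """Parabolic systolic flow waveform parameters.

    The waveform Q(t) = -4*Qmax/tmax^2 * (t - tmax/2)^2 + Qmax integrates
    to dV_total = (2/3)*Qmax*tmax over one systole, which ties the three
    fields together; construct with :meth:`from_ejected_volume` or
    :meth:`from_volumes` to guarantee consistency.

    Fields are SI: Qmax in m^3 s^-1, tmax in s (default 0.36, one systole
    at a resting heart rate of 60 bpm), dV_total in m^3.
    """

    Qmax: float
    tmax: float = 0.36
    dV_total: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Qmax > 0 and self.tmax > 0):
            raise ValidationError("Qmax and tmax must be positive")
        implied = 3.0 * self.dV_total / (2.0 * self.tmax)
        if abs(self.Qmax - implied) / self.Qmax > 1e-12:
            raise ValidationError(
                "inconsistent drive: Qmax must equal 3*dV_total/(2*tmax) "
                f"(got Qmax={self.Qmax!r}, implied {implied!r})"
            )

    @classmethod
    def from_ejected_volume(cls, dV_total: float, tmax: float = 0.36) -> "SystoleDrive":
        """Build from the total ejected volume (m^3) and systole duration (s)."""
        if not tmax > 0:
            raise DomainError(f"tmax must be positive, got {tmax}")
        if not dV_total > 0:
            raise DomainError(f"dV_total must be positive, got {dV_total}")
        return cls(Qmax=3.0 * dV_total / (2.0 * tmax), tmax=tmax, dV_total=dV_total)

    @classmethod
    def from_volumes(
        cls, V_diastole_m3: float, V_systole_m3: float, tmax: float = 0.36
    ) -> "SystoleDrive":
        """Build from end-diastolic and end-systolic chamber volumes (m^3)."""
        if V_diastole_m3 <= V_systole_m3:
            raise DomainError("diastolic volume must exceed systolic volume")
        return cls.from_ejected_volume(V_diastole_m3 - V_systole_m3, tmax)


@dataclass(frozen=True)
class PressureParams:
    """Constants of the trigonometric atrial/aortic pressure profiles.

    Defaults are mean values for patients with a paravalvular leak at a
    resting heart rate: pv_wave = 38 mmHg, pa_wave = 18 mmHg,
    ta_wave = 0.2 s, p_max = 50 mmHg, p_min = 110 mmHg.

    The printed p_max/p_min values contradict their names; they are kept
    exactly as tabulated, with ``swap_max_min`` available to exchange them.
    ``aortic_mode`` selects between the verbatim two-branch aortic profile
    (``"as_printed"``, discontinuous at ta_wave) and a ``"continuous"``
    variant whose second branch is rephased to join the first.
    """

    pv_wave: float = 38.0
    pa_wave: float = 18.0
    ta_wave: float = 0.2
    p_max: float = 50.0
    p_min: float = 110.0
    aortic_mode: str = "as_printed"
    swap_max_min: bool = False

    def __post_init__(self) -> None:
        if not self.ta_wave > 0:
            raise ValidationError(f"ta_wave must be positive, got {self.ta_wave}")
        if not self.pv_wave > self.pa_wave:
            raise ValidationError("pv_wave must exceed pa_wave")
        if self.aortic_mode not in ("as_printed", "continuous"):
            raise UsageError(
                f"aortic_mode must be 'as_printed' or 'continuous', got {self.aortic_mode!r}"
            )

    @property
    def pmax_effective(self) -> float:
        return self.p_min if self.swap_max_min else self.p_max

    @property
    def pmin_effective(self) -> float:
        return self.p_max if self.swap_max_min else self.p_min


@dataclass(frozen=True)
class ThresholdSpec:
    """Critical shear-stress threshold of the hemolysis criterion.

    tau_c is 300 Pa by default; ``inclusive`` selects tau >= tau_c
    (default) versus strict tau > tau_c.
    """

    tau_c: float = 300.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise ValidationError(f"tau_c must be positive, got {self.tau_c}")

    def mask(self, tau: np.ndarray) -> np.ndarray:
        """Boolean mask of values meeting the criterion."""
        tau = np.asarray(tau, dtype=float)
        return tau >= self.tau_c if self.inclusive else tau > self.tau_c


# ---------------------------------------------------------------------------
# Flat key/value configuration


_CONFIG_SECTIONS = {
    "blood": BloodProps,
    "rheology": CYParams,
    "pressure": PressureParams,
    "threshold": ThresholdSpec,
}


def default_config() -> dict:
    """Nested dict of every default parameter record (YAML-serialisable)."""
    out: dict = {}
    for key, cls in _CONFIG_SECTIONS.items():
        out[key] = dataclasses.asdict(cls())
    out["drive"] = {"tmax": 0.36, "dV_total_m3": None, "Qmax_m3s": None}
    return out


def load_config(path) -> dict:
    """Read a YAML configuration file, merged over the defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValidationError(f"config root must be a mapping, got {type(user).__name__}")
    cfg = default_config()
    for section, values in user.items():
        if section in cfg and isinstance(values, dict):
            cfg[section] = {**cfg[section], **values}
        else:
            cfg[section] = values
    return cfg


def dump_config(cfg: dict, path) -> None:
    """Write a configuration mapping to YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def records_from_config(cfg: dict) -> dict:
    """Instantiate parameter records from a (possibly merged) config dict."""
    out = {}
    for key, cls in _CONFIG_SECTIONS.items():
        out[key] = cls(**cfg.get(key, {}))
    return out
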