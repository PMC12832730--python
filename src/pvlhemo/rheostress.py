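"""Carreau-Yasuda viscosity and the scalar effective shear stress.

The local deformation rate is the symmetric part of the velocity gradient,
D_ij = (dv_i/dx_j + dv_j/dx_i)/2, and the scalar shear rate entering the
rheology model is gamma = sqrt(2 D_ij D_ij) — the standard frame-invariant
magnitude, which reduces to the velocity gradient G in simple shear.  The
effective stress combines molecular and turbulent viscosity,

    tau = (mu(gamma) + mu_t) * gamma,

with mu_t supplied by the upstream turbulence model (not computed here).
The isotropic -(2/3) rho k I part of the eddy-viscosity Reynolds-stress
closure does not enter this scalar; k is carried through the data model
untouched.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import CYParams
from .errors import DomainError, SchemaError, ValidationError

__all__ = [
    "cy_viscosity",
    "strain_rate_and_shear",
    "effective_stress",
    "snapshot_stress",
]


def cy_viscosity(gamma_dot, params: CYParams = CYParams()):
    """Carreau-Yasuda viscosity mu(gamma) in Pa s; vectorised.

    mu = mu_inf + (mu0 - mu_inf) [1 + (lam*gamma)^a]^((n-1)/a).
    Monotone non-increasing in gamma for n < 1, bounded in [mu_inf, mu0].
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise DomainError("shear rate must be non-negative")
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lam * g) ** params.a
    ) ** ((params.n - 1.0) / params.a)
    return float(mu) if mu.ndim == 0 else mu


def strain_rate_and_shear(grad_v):
    """Strain-rate tensor and scalar shear rate from a velocity gradient.

    ``grad_v`` has shape (..., 3, 3) with grad_v[..., i, j] = dv_i/dx_j
    in s^-1.  Returns (D, gamma) with D the symmetric part and
    gamma = sqrt(2 * sum_ij D_ij^2).
    """
    g = np.asarray(grad_v, dtype=float)
    if g.shape[-2:] != (3, 3):
        raise ValidationError(f"velocity gradient must be (..., 3, 3), got {g.shape}")
    if not np.all(np.isfinite(g)):
        raise ValidationError("velocity gradient contains non-finite entries")
    D = 0.5 * (g + np.swapaxes(g, -1, -2))
    gamma = np.sqrt(2.0 * np.einsum("...ij,...ij->...", D, D))
    return D, gamma


def effective_stress(grad_v, mu_t=0.0, params: CYParams = CYParams()):
    """Scalar effective shear stress tau = (mu + mu_t) * gamma, in Pa."""
    mu_t_arr = np.asarray(mu_t, dtype=float)
    if np.any(mu_t_arr < 0):
        raise DomainError("turbulent viscosity must be non-negative")
    _, gamma = strain_rate_and_shear(grad_v)
    tau = (cy_viscosity(gamma, params) + mu_t_arr) * gamma
    return float(tau) if np.ndim(tau) == 0 else tau


def snapshot_stress(snapshot, params: CYParams = CYParams()):
    """Return a copy of a flow snapshot with per-cell tau populated.

    Wall faces keep their provided wall shear stress unchanged.  Missing
    mu_t defaults to zero.  Idempotent: tau depends only on the gradient
    and mu_t channels.
    """
    if snapshot.cell_grad_v is None:
        raise SchemaError("snapshot has no velocity_gradient channel; cannot compute tau")
    mu_t = snapshot.cell_mu_t if snapshot.cell_mu_t is not None else 0.0
    tau = effective_stress(snapshot.cell_grad_v, mu_t, params)
    return dataclasses.replace(snapshot, cell_tau=np.asarray(tau, dtype=float))
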