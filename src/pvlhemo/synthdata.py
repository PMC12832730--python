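"""Synthetic inputs with closed-form structure for every pipeline stage.

The CFD solve itself is out of scope; these generators emulate its outputs
with fields whose stress structure is known in closed form, so every
downstream operator can be verified against an analytic oracle:

* Poiseuille pipe flow — the laminar profile u_z(r) = u_max (1 - r^2/R^2)
  has a linear stress profile tau(r) = tau_wall * r / R, so thresholded
  volumes have the exact closed form V(tau >= tau_c)/V = 1 - (tau_c/tau_wall)^2.
* A Gaussian free-shear jet — u_x(y) = U exp(-y^2 / 2 sigma^2), whose shear
  rate peaks at y = +/- sigma with value U/(sigma sqrt(e)), mimicking the
  jet shear layers where hemolysis is predicted.
* Keyframe surfaces at prescribed volumes — uniform scaling of a watertight
  base about its centroid, which hits requested volumes exactly (volume is
  cubic in scale) and gives perfect node correspondence by construction.
* Perturbed severity-series variants with a known injected relative error,
  the ground truth for the comparison machinery.

Synthetic "cells" are centroid + exact analytic volume on structured
cylindrical/box bins rather than true tetrahedra: exactly integrable and
sufficient for every downstream operator.  Stress magnitudes are
test-scaled (e.g. a 400 Pa wall stress) by back-computing the centreline
velocity, accepting unphysical viscosity/velocity pairings in exchange for
oracle precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import CYParams, SystoleDrive, ThresholdSpec
from .drivers import flow_rate
from .errors import DomainError, UsageError, ValidationError
from .geometry import TriSurface, enclosed_volume
from .kinematics import KeyframeSet
from .rheostress import snapshot_stress
from .severity import DEFAULT_WINDOW, METRICS, FlowSnapshot, SeveritySeries, severity_series

__all__ = [
    "PoiseuilleSpec",
    "newtonian_params",
    "poiseuille_snapshot",
    "gaussian_jet_snapshot",
    "keyframe_set",
    "icosphere",
    "perturbed_variant",
    "synthetic_study",
    "SyntheticStudy",
]

#: Default deterministic seed for the stochastic generators.
DEFAULT_SEED = 7


def newtonian_params(mu: float) -> CYParams:
    """Rheology record that collapses Carreau-Yasuda to a constant viscosity."""
    return CYParams(mu0=mu, mu_inf=mu, a=1.0, n=1.0, lam=0.0)


@dataclass(frozen=True)
class PoiseuilleSpec:
    """Poiseuille verification fixture parameters (SI).

    R, L: pipe radius and length (m); tau_wall: target wall shear stress
    (Pa); mu: Newtonian viscosity (Pa s); n_r, n_theta, n_z: structured
    binning counts; seed: reserved for perturbed descendants.
    """

    R: float = 1.8e-3
    L: float = 5.0e-3
    tau_wall: float = 400.0
    mu: float = 3.5e-3
    n_r: int = 200
    n_theta: int = 16
    n_z: int = 4
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.L > 0 and self.tau_wall > 0 and self.mu > 0):
            raise ValidationError("R, L, tau_wall and mu must all be positive")
        if self.n_r < 8 or self.n_theta < 4 or self.n_z < 1:
            raise ValidationError("binning too coarse: need n_r >= 8, n_theta >= 4, n_z >= 1")

    @property
    def u_max(self) -> float:
        """Centreline speed back-computed from tau_wall = 2 mu u_max / R."""
        return self.tau_wall * self.R / (2.0 * self.mu)


def poiseuille_snapshot(spec: PoiseuilleSpec = PoiseuilleSpec(), time: float = 0.0) -> FlowSnapshot:
    """Cylindrical-bin snapshot of laminar pipe flow with exact analytics.

    Cell volumes are exact ring-sector volumes; velocities and velocity
    gradients are the analytic values at the cell centroids (radial area
    centroid, angular midpoint).  Wall faces at r = R carry the analytic
    wall shear stress and the group label ``wall-pvl``; mu_t = 0.
    """
    R, L = spec.R, spec.L
    r_edges = np.linspace(0.0, R, spec.n_r + 1)
    th_edges = np.linspace(0.0, 2.0 * np.pi, spec.n_theta + 1)
    z_edges = np.linspace(0.0, L, spec.n_z + 1)
    dth = np.diff(th_edges)
    dz = np.diff(z_edges)

    r0, r1 = r_edges[:-1], r_edges[1:]
    ring_area2 = r1**2 - r0**2  # actually 2*area/dtheta; exact volumes below
    # radial area centroid of each ring sector
    r_c = (2.0 / 3.0) * (r1**3 - r0**3) / ring_area2
    th_c = 0.5 * (th_edges[:-1] + th_edges[1:])
    z_c = 0.5 * (z_edges[:-1] + z_edges[1:])

    rr, tt, zz = np.meshgrid(r_c, th_c, z_c, indexing="ij")
    vol = (
        0.5 * ring_area2[:, None, None] * dth[None, :, None] * dz[None, None, :]
    ) * np.ones_like(rr)

    u_max = spec.u_max
    uz = u_max * (1.0 - rr**2 / R**2)
    x = rr * np.cos(tt)
    y = rr * np.sin(tt)
    centroid = np.stack([x, y, zz], axis=-1).reshape(-1, 3)
    velocity = np.zeros_like(centroid)
    velocity[:, 2] = uz.ravel()

    # grad u_z = u'(r) * (x/r, y/r, 0) with u'(r) = -2 u_max r / R^2
    n = centroid.shape[0]
    grad = np.zeros((n, 3, 3))
    uprime = (-2.0 * u_max * rr / R**2).ravel()
    rr_flat = rr.ravel()
    grad[:, 2, 0] = uprime * centroid[:, 0] / rr_flat
    grad[:, 2, 1] = uprime * centroid[:, 1] / rr_flat

    # wall faces at r = R: one per (theta, z) bin
    wth, wz = np.meshgrid(th_c, z_c, indexing="ij")
    wall_area = (R * dth[:, None] * dz[None, :]).ravel() * np.ones(wth.size)
    wall_tau = np.full(wth.size, spec.tau_wall)
    wall_group = np.full(wth.size, "wall-pvl", dtype="U16")

    return FlowSnapshot(
        time=time,
        cell_volume=vol.ravel(),
        cell_centroid=centroid,
        cell_velocity=velocity,
        cell_grad_v=grad,
        cell_mu_t=np.zeros(n),
        wall_area=wall_area,
        wall_tau=wall_tau,
        wall_pressure=None,
        wall_group=wall_group,
    )


def gaussian_jet_snapshot(
    U: float = 4.0,
    sigma: float = 1.0e-3,
    box: tuple[float, float, float] = (10e-3, 8e-3, 4e-3),
    bins: tuple[int, int, int] = (8, 200, 4),
    mu_t: float = 0.0,
    time: float = 0.0,
) -> FlowSnapshot:
    """Box-bin snapshot of a planar Gaussian jet u_x(y) = U exp(-y^2/2 sigma^2).

    The analytic shear rate |du_x/dy| = U |y|/sigma^2 * exp(-y^2/2 sigma^2)
    vanishes on the centreline and peaks at y = +/- sigma with value
    U/(sigma sqrt(e)) — the jet shear-layer structure where high stresses
    concentrate.  No wall faces; uniform mu_t optional.
    """
    if not (U > 0 and sigma > 0) or any(b <= 0 for b in box):
        raise ValidationError("U, sigma and box dimensions must be positive")
    if any(b < 2 for b in bins):
        raise ValidationError("need at least 2 bins per direction")
    if mu_t < 0:
        raise DomainError("mu_t must be non-negative")
    Lx, Ly, Lz = box
    nx, ny, nz = bins
    xc = (np.arange(nx) + 0.5) * Lx / nx - Lx / 2
    yc = (np.arange(ny) + 0.5) * Ly / ny - Ly / 2
    zc = (np.arange(nz) + 0.5) * Lz / nz - Lz / 2
    xx, yy, zz = np.meshgrid(xc, yc, zc, indexing="ij")
    n = xx.size
    centroid = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    vol = np.full(n, (Lx / nx) * (Ly / ny) * (Lz / nz))
    ux = U * np.exp(-(yy**2) / (2.0 * sigma**2)).ravel()
    velocity = np.zeros((n, 3))
    velocity[:, 0] = ux
    grad = np.zeros((n, 3, 3))
    grad[:, 0, 1] = -centroid[:, 1] / sigma**2 * ux  # du_x/dy
    return FlowSnapshot(
        time=time,
        cell_volume=vol,
        cell_centroid=centroid,
        cell_velocity=velocity,
        cell_grad_v=grad,
        cell_mu_t=np.full(n, float(mu_t)),
    )


def icosphere(radius: float = 1.0, subdivisions: int = 3, unit: str = "mm") -> TriSurface:
    """Watertight icosphere (via trimesh), rescaled to enclose (4/3) pi r^3 exactly.

    A faceted sphere of circumscribed radius r encloses slightly less than
    the ball volume; the vertices are rescaled so the *meshed* volume equals
    the analytic ball volume, making spheres exact volume oracles.
    """
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    surf = TriSurface(np.asarray(m.vertices), np.asarray(m.faces), unit=unit)
    target = 4.0 / 3.0 * np.pi * radius**3
    scale = (target / enclosed_volume(surf)) ** (1.0 / 3.0)
    surf.vertices *= scale
    return surf


def keyframe_set(base: TriSurface, volumes, labels: Optional[Sequence[str]] = None) -> KeyframeSet:
    """Correspondent keyframes by uniform scaling of a base surface.

    Each keyframe scales the base about its vertex centroid by
    (V_target / V_base)^(1/3), hitting the requested volume exactly (the
    enclosed volume is exactly cubic in the scale factor).  Volumes must be
    positive and strictly decreasing.
    """
    v = np.asarray(volumes, dtype=float)
    if np.any(v <= 0) or not np.all(np.diff(v) < 0):
        raise ValidationError("volumes must be positive and strictly decreasing")
    V_base = enclosed_volume(base)  # validates watertightness
    centroid = base.vertices.mean(axis=0)
    meshes = []
    for vt in v:
        s = (vt / V_base) ** (1.0 / 3.0)
        verts = centroid + (base.vertices - centroid) * s
        meshes.append(TriSurface(verts, base.faces.copy(), base.unit))
    return KeyframeSet(meshes, v, labels)


def perturbed_variant(
    ref: SeveritySeries,
    delta: float,
    mode: str = "uniform",
    seed: int = DEFAULT_SEED,
) -> SeveritySeries:
    """Variant series with a known injected relative perturbation.

    ``uniform`` multiplies every metric by (1 + delta), so the comparison
    stage must recover eps = 100 |delta| % with zero spread.  ``noisy``
    multiplies each timepoint by (1 + delta * eta_t) with eta_t standard
    normal (fixed seed); the expected per-metric mean error is then the
    half-normal mean 100 |delta| sqrt(2/pi) %.
    """
    if abs(delta) >= 1:
        raise DomainError(f"|delta| must be < 1, got {delta}")
    if mode not in ("uniform", "noisy"):
        raise UsageError(f"mode must be 'uniform' or 'noisy', got {mode!r}")
    frame = ref.frame.copy()
    if mode == "uniform":
        factors = np.full(len(frame), 1.0 + delta)
    else:
        rng = np.random.default_rng(seed)
        factors = 1.0 + delta * rng.standard_normal(len(frame))
    for m in METRICS:
        frame[m] = frame[m].to_numpy() * factors
    return SeveritySeries(frame, ref.window)


@dataclass
class SyntheticStudy:
    """End-to-end fixture: a reference run and perturbed model variants.

    ``snapshots`` is the reference run — Poiseuille flow in a leak-sized
    pipe whose wall stress follows the systolic flow waveform; ``reference``
    is its severity series; ``variants`` maps labels to perturbed series
    with the documented injected deltas.
    """

    drive: SystoleDrive
    snapshots: list
    reference: SeveritySeries
    variants: dict
    deltas: dict
    keyframes: KeyframeSet
    seed: int


#: Injected relative perturbations of the three synthetic model variants,
#: spanning the sub-0.5% and sub-4% error regimes.
VARIANT_DELTAS = {"variant-II": 0.005, "variant-III": 0.02, "variant-IV": 0.04}

#: Keyframe chamber volumes of the synthetic study (mm^3), diastole to systole.
STUDY_VOLUMES_MM3 = (173_803.0, 122_935.0, 81_943.0, 68_484.0)


def synthetic_study(
    seed: int = DEFAULT_SEED,
    n_times: int = 15,
    n_r: int = 40,
    peak_tau_wall: float = 400.0,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> SyntheticStudy:
    """Deterministic end-to-end fixture mirroring the four-model comparison.

    The reference run places Poiseuille snapshots on a uniform grid of
    ``n_times`` instants across the analysis window, with the wall stress
    scaled by the instantaneous flow fraction Q(t)/Qmax of the drive built
    from the keyframe chamber volumes.  Three variants carry uniform
    injected perturbations (:data:`VARIANT_DELTAS`), the ground truth the
    comparison table must recover.  Fully deterministic given ``seed``.
    """
    drive = SystoleDrive.from_volumes(
        STUDY_VOLUMES_MM3[0] * 1e-9, STUDY_VOLUMES_MM3[-1] * 1e-9
    )
    times = np.linspace(window[0], window[1], n_times)
    snapshots = []
    for t in times:
        frac = flow_rate(float(t), drive) / drive.Qmax
        spec = PoiseuilleSpec(tau_wall=peak_tau_wall * frac, n_r=n_r, seed=seed)
        snap = poiseuille_snapshot(spec, time=float(t))
        snapshots.append(snapshot_stress(snap, newtonian_params(spec.mu)))
    reference = severity_series(snapshots, ThresholdSpec(), window=window)
    variants = {
        label: perturbed_variant(reference, delta, mode="uniform", seed=seed)
        for label, delta in VARIANT_DELTAS.items()
    }
    base = icosphere(radius=35.0, subdivisions=3)
    keyframes = keyframe_set(
        base,
        STUDY_VOLUMES_MM3,
        labels=["diastole", "half-contraction", "two-thirds-contraction", "systole"],
    )
    return SyntheticStudy(
        drive=drive,
        snapshots=snapshots,
        reference=reference,
        variants=variants,
        deltas=dict(VARIANT_DELTAS),
        keyframes=keyframes,
        seed=seed,
    )
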