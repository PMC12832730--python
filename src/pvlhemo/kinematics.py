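"""Keyframe-based ventricular motion with volume-constrained morphing.

Correspondent surface keyframes (same vertex count, node-to-node
correspondence established upstream) are interpolated per vertex along a
morph parameter s in [0, 1].  Keyframes are placed at their normalised
ejected-volume fraction, s_k = (V_0 - V_k)/(V_0 - V_last), which makes the
parametrisation geometry-intrinsic.  With two keyframes the trajectories
are straight lines; with three or more they are per-coordinate cubic
Hermite curves with Catmull-Rom tangents (one-sided at the ends), so each
keyframe is reproduced exactly and the interior is C1.

At each time step the morph parameter is advanced by root-finding so that
the enclosed mesh volume matches the ejection schedule of the parabolic
flow waveform to a relative accuracy of 1e-8.

Units: surface coordinates and volumes in mm / mm^3; the flow drive is SI
(m^3), converted at the schedule boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core import M3_TO_MM3, SystoleDrive
from .drivers import ejected_volume
from .errors import (
    ConvergenceError,
    CorrespondenceError,
    DomainError,
    UsageError,
    ValidationError,
)
from .geometry import TriSurface, enclosed_volume

__all__ = [
    "KeyframeSet",
    "NodeTrajectorySet",
    "keyframe_params",
    "node_trajectories",
    "contraction_schedule",
    "advance_to_volume",
    "generate_motion",
    "MotionStep",
]

#: Default relative volume-matching accuracy of the morph.
VOLUME_RTOL = 1e-8


@dataclass
class KeyframeSet:
    """Ordered correspondent keyframe surfaces with their enclosed volumes.

    Volumes (mm^3) must be strictly decreasing from diastole to systole
    and agree with the meshed enclosed volumes to 1e-9 relative.
    """

    meshes: Sequence[TriSurface]
    volumes: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.meshes) < 2:
            raise ValidationError("need at least two keyframes")
        if len(self.meshes) != len(self.volumes):
            raise ValidationError("one volume per keyframe required")
        nv = {m.n_vertices for m in self.meshes}
        nf = {m.n_faces for m in self.meshes}
        if len(nv) != 1 or len(nf) != 1:
            raise CorrespondenceError(
                f"keyframes are not correspondent: vertex counts {sorted(nv)}, "
                f"face counts {sorted(nf)}"
            )
        if not np.all(np.diff(self.volumes) < 0):
            raise ValidationError("keyframe volumes must be strictly decreasing")
        for i, (m, v) in enumerate(zip(self.meshes, self.volumes)):
            mv = enclosed_volume(m)
            if abs(mv - v) / v > 1e-9:
                raise ValidationError(
                    f"keyframe {i}: stored volume {v:g} disagrees with meshed volume {mv:g}"
                )
        if self.labels is None:
            self.labels = [f"keyframe-{i}" for i in range(len(self.meshes))]

    @classmethod
    def from_meshes(
        cls, meshes: Sequence[TriSurface], labels: Sequence[str] | None = None
    ) -> "KeyframeSet":
        vols = np.array([enclosed_volume(m) for m in meshes])
        return cls(meshes, vols, labels)


def keyframe_params(volumes) -> np.ndarray:
    """Morph parameters s_k = (V_0 - V_k)/(V_0 - V_last) for the keyframes.

    Maps strictly decreasing volumes to [0, 1] by normalised ejected
    fraction: s_0 = 0, s_last = 1.
    """
    v = np.asarray(volumes, dtype=float)
    if len(v) < 2 or not np.all(np.diff(v) < 0):
        raise ValidationError("volumes must be a strictly decreasing sequence of length >= 2")
    return (v[0] - v) / (v[0] - v[-1])


@dataclass
class NodeTrajectorySet:
    """Per-vertex parametric curves through the keyframe positions.

    ``positions`` has shape (K, N, 3); evaluation at s_k reproduces
    keyframe k exactly.  Linear for K = 2, cubic Hermite (Catmull-Rom
    tangents, one-sided at the ends) for K >= 3.
    """

    positions: np.ndarray
    s_k: np.ndarray
    faces: np.ndarray
    unit: str = "mm"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.s_k = np.asarray(self.s_k, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError("positions must be (K, N, 3)")
        if len(self.s_k) != self.positions.shape[0]:
            raise ValidationError("one parameter per keyframe required")
        if not np.all(np.diff(self.s_k) > 0):
            raise ValidationError("keyframe parameters must be strictly increasing")
        self._tangents = self._catmull_rom_tangents() if len(self.s_k) >= 3 else None

    def _catmull_rom_tangents(self) -> np.ndarray:
        P, s = self.positions, self.s_k
        m = np.empty_like(P)
        m[0] = (P[1] - P[0]) / (s[1] - s[0])
        m[-1] = (P[-1] - P[-2]) / (s[-1] - s[-2])
        m[1:-1] = (P[2:] - P[:-2]) / (s[2:] - s[:-2])[:, None, None]
        return m

    def evaluate(self, s: float) -> np.ndarray:
        """Vertex coordinates (N, 3) at morph parameter s in [s_0, s_last]."""
        s = float(s)
        if s < self.s_k[0] - 1e-12 or s > self.s_k[-1] + 1e-12:
            raise DomainError(f"s={s} outside [{self.s_k[0]}, {self.s_k[-1]}]")
        s = min(max(s, self.s_k[0]), self.s_k[-1])
        P, sk = self.positions, self.s_k
        if len(sk) == 2:
            u = (s - sk[0]) / (sk[1] - sk[0])
            return (1.0 - u) * P[0] + u * P[1]
        k = int(np.clip(np.searchsorted(sk, s, side="right") - 1, 0, len(sk) - 2))
        dt = sk[k + 1] - sk[k]
        u = (s - sk[k]) / dt
        h00 = 2 * u**3 - 3 * u**2 + 1
        h10 = u**3 - 2 * u**2 + u
        h01 = -2 * u**3 + 3 * u**2
        h11 = u**3 - u**2
        m = self._tangents
        return h00 * P[k] + h10 * dt * m[k] + h01 * P[k + 1] + h11 * dt * m[k + 1]

    def mesh_at(self, s: float) -> TriSurface:
        return TriSurface(self.evaluate(s), self.faces, self.unit)

    def volume_at(self, s: float) -> float:
        return enclosed_volume(self.mesh_at(s), validate=False)


def node_trajectories(keyframes: KeyframeSet) -> NodeTrajectorySet:
    """Interpolated node paths through a correspondent keyframe set."""
    positions = np.stack([m.vertices for m in keyframes.meshes])
    s_k = keyframe_params(keyframes.volumes)
    units = {m.unit for m in keyframes.meshes}
    if len(units) != 1:
        raise ValidationError(f"keyframes mix length units: {sorted(units)}")
    return NodeTrajectorySet(positions, s_k, keyframes.meshes[0].faces.copy(), units.pop())


def contraction_schedule(drive: SystoleDrive, V0_mm3: float, times) -> np.ndarray:
    """Target chamber volumes (mm^3) V(t) = V0 - integral of Q over [0, t].

    Uses the closed-form cumulative of the parabolic waveform; ``times``
    must lie within [0, tmax].
    """
    ejected = np.atleast_1d(ejected_volume(times, drive)) * M3_TO_MM3
    return V0_mm3 - ejected


def advance_to_volume(
    traj: NodeTrajectorySet,
    s_prev: float,
    V_target: float,
    rel_tol: float = VOLUME_RTOL,
    max_iter: int = 200,
) -> tuple[float, TriSurface]:
    """Advance the morph parameter so the mesh volume matches V_target.

    Searches s >= s_prev by bracketing root-finding (Brent with a bisection
    fallback) and verifies |V(s) - V_target| / V_target <= rel_tol.  The
    matcher never moves backwards.
    """
    v_prev = traj.volume_at(s_prev)
    if abs(v_prev - V_target) / V_target <= rel_tol:
        return s_prev, traj.mesh_at(s_prev)
    if V_target > v_prev:
        raise UsageError(
            f"V_target={V_target:g} exceeds current volume {v_prev:g}; "
            "the matcher cannot move backwards"
        )
    s_end = float(traj.s_k[-1])
    v_end = traj.volume_at(s_end)
    if V_target < v_end * (1.0 - rel_tol):
        raise UsageError(f"V_target={V_target:g} is below the final achievable volume {v_end:g}")

    def g(s: float) -> float:
        return traj.volume_at(s) - V_target

    try:
        s_next = brentq(g, s_prev, s_end, xtol=1e-15, rtol=8.9e-16, maxiter=max_iter)
    except (ValueError, RuntimeError):
        # volume may be non-monotone between keyframes; fall back to bisection
        lo, hi = s_prev, s_end
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
        s_next = 0.5 * (lo + hi)
    s_next = max(s_next, s_prev)
    mesh = traj.mesh_at(s_next)
    achieved = enclosed_volume(mesh, validate=False)
    if abs(achieved - V_target) / V_target > rel_tol:
        raise ConvergenceError(
            f"volume matching stalled at |dV|/V = {abs(achieved - V_target) / V_target:g} "
            f"(target {rel_tol:g}) near s = {s_next:g}"
        )
    return s_next, mesh


@dataclass(frozen=True)
class MotionStep:
    time: float
    s: float
    volume: float
    mesh: TriSurface


def generate_motion(
    keyframes: KeyframeSet, drive: SystoleDrive, n_steps: int
) -> list[MotionStep]:
    """Meshes at uniform times over [0, tmax], each matching its scheduled volume.

    ``n_steps`` is the number of time instants (endpoints included).  The
    drive's total ejected volume must equal the keyframes' volume drop; the
    cumulative ejection at tmax then matches to the solver tolerance.
    """
    if n_steps < 2:
        raise ValidationError(f"n_steps must be >= 2, got {n_steps}")
    traj = node_trajectories(keyframes)
    V0 = float(keyframes.volumes[0])
    dv_mm3 = drive.dV_total * M3_TO_MM3
    drop = V0 - float(keyframes.volumes[-1])
    if abs(dv_mm3 - drop) / drop > 1e-6:
        raise UsageError(
            f"drive ejects {dv_mm3:g} mm^3 but keyframes span {drop:g} mm^3; "
            "build the drive from the keyframe volumes"
        )
    times = np.linspace(0.0, drive.tmax, n_steps)
    targets = contraction_schedule(drive, V0, times)
    steps: list[MotionStep] = []
    s = 0.0
    for t, vt in zip(times, targets):
        s, mesh = advance_to_volume(traj, s, float(vt))
        steps.append(MotionStep(float(t), s, enclosed_volume(mesh, validate=False), mesh))
    return steps
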