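"""Parametric left-ventricle surfaces, leak-channel descriptors and mesh volumes.

The universal ventricle is an axisymmetric body: an ellipsoid of revolution
(width ``D``, height ``H``) truncated at the height where its cross-section
width equals ``d``, continued by a cylinder of diameter ``d`` and height
``h``, optionally rounded at the top edge by a circular fillet, and closed
by a flat top disc.  Because a closed composition of the printed dimensions
does not pin down the published chamber volumes uniquely, the target volume
is treated as the binding contract: :func:`solve_dims_for_volume` rescales
the ellipsoid until the meshed volume matches.

Leak-channel descriptors follow the hydraulic-diameter convention
``d_h = 4 A / P`` for a non-circular cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError, GeometryError, UsageError, ValidationError

__all__ = [
    "LVDims",
    "TriSurface",
    "PVLChannel",
    "hydraulic_diameter",
    "pvl_aggregate",
    "build_universal_lv",
    "solve_dims_for_volume",
    "enclosed_volume",
    "boundary_edges",
]


@dataclass(frozen=True)
class LVDims:
    """Universal-ventricle dimensions, all in mm.

    d, h: diameter and height of the top cylinder; D, H: width and height
    of the ellipsoid of revolution.
    """

    d: float
    h: float
    D: float
    H: float

    def __post_init__(self) -> None:
        for name in ("d", "h", "D", "H"):
            v = getattr(self, name)
            if name != "h" and not v > 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.h < 0:
            raise ValidationError(f"h must be non-negative, got {self.h}")
        if self.d > self.D:
            raise GeometryError(f"cylinder diameter d={self.d} exceeds ellipsoid width D={self.D}")


@dataclass
class TriSurface:
    """Triangle surface mesh: ``vertices`` (n, 3) float, ``faces`` (m, 3) int.

    ``unit`` declares the length unit of the coordinates (default mm).
    """

    vertices: np.ndarray
    faces: np.ndarray
    unit: str = "mm"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError(f"faces must be (m, 3), got {self.faces.shape}")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValidationError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.faces.copy(), self.unit)


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def boundary_edges(surface: TriSurface) -> np.ndarray:
    """Undirected edges not shared by exactly two faces (empty if watertight)."""
    und = np.sort(_directed_edges(surface.faces), axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    return uniq[counts != 2]


def _check_watertight(surface: TriSurface) -> None:
    bad = boundary_edges(surface)
    if len(bad):
        raise ValidationError(
            f"surface is not watertight: {len(bad)} boundary/non-manifold edges, "
            f"first few: {bad[:5].tolist()}"
        )
    # consistent orientation: every directed edge must be unique
    d = _directed_edges(surface.faces)
    if len(np.unique(d, axis=0)) != len(d):
        raise ValidationError("surface orientation is inconsistent (repeated directed edge)")


def enclosed_volume(surface: TriSurface, *, validate: bool = True) -> float:
    """Signed enclosed volume by the divergence theorem, in ``unit**3``.

    Sum over faces of det(v1, v2, v3)/6; positive for outward orientation.
    Raises a validation error for non-watertight input and an orientation
    error (GeometryError) if the signed volume comes out negative.
    """
    if validate:
        _check_watertight(surface)
    v = surface.vertices[surface.faces]
    vol = float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2]))) / 6.0
    if validate and vol < 0:
        raise GeometryError(f"surface is inward-oriented (signed volume {vol:g})")
    return vol


# ---------------------------------------------------------------------------
# Leak-channel descriptors


@dataclass(frozen=True)
class PVLChannel:
    """Leak-channel cross-section: perimeter (mm) and area (mm^2)."""

    perimeter: float
    area: float

    def __post_init__(self) -> None:
        if not (self.perimeter > 0 and self.area > 0):
            raise ValidationError("perimeter and area must be positive")
        iso = self.perimeter**2 / (4.0 * np.pi)
        if self.area > iso * (1 + 1e-12):
            raise ValidationError(
                f"area {self.area} violates the isoperimetric bound P^2/(4*pi) = {iso:g}"
            )

    @property
    def hydraulic_diameter(self) -> float:
        return hydraulic_diameter(self.perimeter, self.area)


def hydraulic_diameter(perimeter: float, area: float) -> float:
    """Hydraulic (equivalent) diameter 4*A/P of a channel cross-section.

    Degree-1 homogeneous under uniform scaling; equals the diameter for a
    circle.  Inputs in mm and mm^2 give the result in mm.
    """
    if not (perimeter > 0 and area > 0):
        raise DomainError(f"perimeter and area must be positive, got P={perimeter}, A={area}")
    return 4.0 * area / perimeter


def pvl_aggregate(channels: Sequence[PVLChannel]) -> PVLChannel:
    """Whole-leak descriptor: perimeter and area summed over channels."""
    if not channels:
        raise UsageError("cannot aggregate an empty channel list")
    return PVLChannel(
        perimeter=float(sum(c.perimeter for c in channels)),
        area=float(sum(c.area for c in channels)),
    )


# ---------------------------------------------------------------------------
# Universal ventricle construction


def _profile(dims: LVDims, fillet_radius: float, n_axial: int) -> tuple[np.ndarray, np.ndarray]:
    """(r, z) generatrix from the bottom pole (r=0) to the top-disc rim.

    z increases from -H/2 (apex) upward; the profile excludes the top
    centre point (the revolve closes the disc with a centre vertex).
    """
    a, c = dims.D / 2.0, dims.H / 2.0
    rcyl = dims.d / 2.0
    rf = fillet_radius
    if rf < 0:
        raise GeometryError(f"fillet radius must be non-negative, got {rf}")
    if rf > dims.h:
        raise GeometryError(f"fillet radius {rf} exceeds cylinder height h={dims.h}")
    if rf >= rcyl:
        raise GeometryError(f"fillet radius {rf} must be smaller than d/2 = {rcyl}")

    # ellipsoid arc: r = a cos(phi), z = c sin(phi), phi from -pi/2 to phi_t
    phi_t = np.arccos(min(dims.d / dims.D, 1.0))
    phis = np.linspace(-np.pi / 2.0, phi_t, n_axial + 1)
    r = a * np.cos(phis)
    z = c * np.sin(phis)
    z_t = float(z[-1])
    r_parts = [r]
    z_parts = [z]

    z_top = z_t + dims.h
    if dims.h > 0:
        n_cyl = max(2, int(round(n_axial * dims.h / dims.H)) + 1)
        zc = np.linspace(z_t, z_top - rf, n_cyl + 1)[1:]
        r_parts.append(np.full_like(zc, rcyl))
        z_parts.append(zc)
    if rf > 0:
        n_f = max(4, n_axial // 8)
        ang = np.linspace(0.0, np.pi / 2.0, n_f + 1)[1:]
        r_parts.append((rcyl - rf) + rf * np.cos(ang))
        z_parts.append((z_top - rf) + rf * np.sin(ang))
    # top disc, from rim inward (excluding the centre)
    rim = rcyl - rf
    n_disc = max(2, n_axial // 4)
    rd = np.linspace(rim, 0.0, n_disc + 1)[1:-1]
    r_parts.append(rd)
    z_parts.append(np.full_like(rd, z_top))

    r_all = np.concatenate(r_parts)
    z_all = np.concatenate(z_parts)
    # drop consecutive duplicates (degenerate when h == 0 or d == D)
    keep = np.ones(len(r_all), dtype=bool)
    keep[1:] = (np.abs(np.diff(r_all)) > 1e-12) | (np.abs(np.diff(z_all)) > 1e-12)
    return r_all[keep], z_all[keep]


def build_universal_lv(
    dims: LVDims,
    n_theta: int = 64,
    n_axial: int = 64,
    fillet_radius: float = 0.0,
) -> TriSurface:
    """Mesh the universal ventricle as a watertight axisymmetric surface.

    The generatrix (ellipsoid arc, cylinder wall, optional fillet arc, top
    disc) is revolved through ``n_theta`` angular segments.  Structured
    longitude/latitude triangulation makes the surface watertight by
    construction; orientation is outward (positive enclosed volume).
    Units: mm.
    """
    if n_theta < 8 or n_axial < 8:
        raise ValidationError("resolution must be at least 8 segments per direction")
    r_prof, z_prof = _profile(dims, fillet_radius, n_axial)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)

    # vertex layout: apex, rings for every profile point with r > 0, top centre
    interior = r_prof > 1e-12
    r_in, z_in = r_prof[interior], z_prof[interior]
    n_rings = len(r_in)
    verts = np.empty((1 + n_rings * n_theta + 1, 3))
    verts[0] = (0.0, 0.0, z_prof[0])
    ring0 = 1
    for i in range(n_rings):
        base = ring0 + i * n_theta
        verts[base : base + n_theta, 0] = r_in[i] * ct
        verts[base : base + n_theta, 1] = r_in[i] * st
        verts[base : base + n_theta, 2] = z_in[i]
    top = 1 + n_rings * n_theta
    z_top = z_prof[-1] if r_prof[-1] <= 1e-12 else z_in[-1]
    verts[top] = (0.0, 0.0, z_top)

    faces = []
    j = np.arange(n_theta)
    jn = (j + 1) % n_theta
    # apex fan (outward normals point away from the axis/down at the apex)
    first = ring0
    faces.append(np.stack([np.zeros(n_theta, dtype=np.int64), first + jn, first + j], axis=1))
    # quad strips
    for i in range(n_rings - 1):
        lo = ring0 + i * n_theta
        hi = lo + n_theta
        faces.append(np.stack([lo + j, hi + jn, hi + j], axis=1))
        faces.append(np.stack([lo + j, lo + jn, hi + jn], axis=1))
    # top-centre fan
    last = ring0 + (n_rings - 1) * n_theta
    faces.append(np.stack([np.full(n_theta, top, dtype=np.int64), last + j, last + jn], axis=1))

    surf = TriSurface(verts, np.concatenate(faces), unit="mm")
    if enclosed_volume(surf, validate=False) < 0:
        surf.faces = surf.faces[:, ::-1]
    _check_watertight(surf)
    return surf


def solve_dims_for_volume(
    V_target: float,
    template: LVDims,
    n_theta: int = 64,
    n_axial: int = 64,
    fillet_radius: float = 0.0,
    rel_tol: float = 1e-3,
) -> LVDims:
    """Scale the template's ellipsoid (fixed d, h, aspect D/H) to hit a volume.

    Scalar root-finding on the joint scale of (D, H); the cylinder cap is
    left untouched.  The returned dimensions mesh (at the same resolution)
    to within ``rel_tol`` relative of ``V_target`` (default 0.1%).
    """
    if not V_target > 0:
        raise DomainError(f"V_target must be positive, got {V_target}")

    def vol(scale: float) -> float:
        dims = replace(template, D=template.D * scale, H=template.H * scale)
        return enclosed_volume(build_universal_lv(dims, n_theta, n_axial, fillet_radius),
                               validate=False)

    s_lo = template.d / template.D * (1.0 + 1e-9)
    v_lo = vol(s_lo)
    if V_target <= v_lo:
        raise ConvergenceError(
            f"V_target={V_target:g} mm^3 is below the cylinder-cap floor "
            f"{v_lo:g} mm^3 reachable with d={template.d}, h={template.h}"
        )
    s_hi = max(1.0, s_lo * 2.0)
    for _ in range(60):
        if vol(s_hi) >= V_target:
            break
        s_hi *= 1.5
    else:
        raise ConvergenceError(
            f"could not bracket V_target={V_target:g} mm^3 (last scale {s_hi:g}, "
            f"volume {vol(s_hi):g} mm^3)"
        )
    scale = brentq(lambda s: vol(s) - V_target, s_lo, s_hi, xtol=1e-12, rtol=1e-14)
    dims = replace(template, D=template.D * scale, H=template.H * scale)
    achieved = enclosed_volume(build_universal_lv(dims, n_theta, n_axial, fillet_radius))
    if abs(achieved - V_target) / V_target > rel_tol:
        raise ConvergenceError(
            f"solver finished but |V - V_target|/V_target = "
            f"{abs(achieved - V_target) / V_target:g} exceeds {rel_tol:g}"
        )
    return dims
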