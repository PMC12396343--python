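"""Conformal geometry: mesh ingestion, segmentation, layering and projection.

Soft organ models rarely sit on a flat base, and the anisotropic voxel
lattice only behaves as designed when it follows the natural topography of
the part.  This module turns a surface mesh into a nonplanar *bottom
template* (a regular-grid height field), generates conformal layers as pure
vertical offsets of that template — the kinematics of a 3-axis gantry — and
projects planar toolpaths onto each layer.  The residual error of vertical
offsetting on an incline is compensated by adjusting the nozzle clearance
from the local gradient::

    h = h0 / cos(alpha) +/- (d/2) * tan(alpha)

with "+" when travelling downhill and "-" uphill: the leading edge of the
nozzle sits over the higher side of the substrate, shrinking the effective
clearance.  Accuracy degrades above ~45 degrees of inclination; that is a
documented limitation, not a checked invariant.

Coordinates are millimetres, right-handed, Z up; angles in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.spatial import QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union
from shapely import geometry as shgeo

from .voxel import ValidationError

__all__ = [
    "MeshLoadError",
    "load_mesh",
    "write_mesh",
    "Rotation2Tilt",
    "reorient_min_height",
    "SplitResult",
    "split_top_bottom",
    "HeightField",
    "LayerSurface",
    "heightfield_from_points",
    "conformal_layers",
    "layer_contour",
    "project_to_surface",
    "path_gradient",
    "DepositionParams",
    "adjust_nozzle_height",
    "flow_rate",
    "read_points_csv",
    "write_contour_csv",
]

LAYER_ROLES = ("bottom_cover", "infill", "top_cover", "sacrificial")


class MeshLoadError(ValueError):
    """The STL could not be parsed; the message carries the parser detail."""


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load an ASCII or binary STL into a deduplicated triangle mesh.

    Duplicate vertices are merged within 1e-6 mm; vertex normals are the
    area-weighted average of the incident face normals (trimesh's default).
    """
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl", process=True)
    except Exception as exc:  # trimesh raises a zoo of types on bad input
        raise MeshLoadError(f"failed to parse STL {path!r}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshLoadError(f"STL {path!r} contains no triangles")
    mesh.merge_vertices(digits_vertex=6)
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh as STL (binary for .stl, ASCII via trimesh for .stl_ascii)."""
    mesh.export(str(path))


# ---------------------------------------------------------------------------
# Reorientation for minimal build height
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rotation2Tilt:
    """A rotation reported as two tilt angles about X then Y (degrees)."""

    rx: float
    ry: float
    matrix: np.ndarray  # the full 3x3 rotation actually applied


def _rot_x(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def reorient_min_height(
    mesh: trimesh.Trimesh, step_deg: float = 1.0
) -> tuple[trimesh.Trimesh, Rotation2Tilt]:
    """Rotate the mesh so its Z extent (build height) is minimized.

    Initializes by aligning the least-extended principal direction of the
    vertex cloud with Z, then refines with an exhaustive grid over two tilt
    angles (about X and Y) in +/-45 degrees at ``step_deg`` resolution.
    Deterministic; ties broken toward the smallest tilt magnitudes.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    if len(V) < 3:
        raise ValidationError("mesh must have at least 3 vertices")
    # principal-axis initialization: smallest-variance direction -> Z
    C = np.cov((V - V.mean(axis=0)).T)
    eigval, eigvec = np.linalg.eigh(C)
    n = eigvec[:, 0]  # least variance
    if n[2] < 0:
        n = -n
    # rotation taking n to +Z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s, c = np.linalg.norm(v), float(np.dot(n, z))
    if s < 1e-12:
        R0 = np.eye(3)
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R0 = np.eye(3) + K + K @ K * ((1 - c) / s**2)
    V0 = V @ R0.T

    angles = np.arange(-45.0, 45.0 + 1e-9, step_deg)
    best = (np.inf, np.inf, 0.0, 0.0)  # extent, tilt magnitude, rx, ry
    # z after Rx(rx) then Ry(ry) depends only on the third row of Ry@Rx
    for rx in angles:
        Rx = _rot_x(rx)
        for ry in angles:
            row = (_rot_y(ry) @ Rx)[2]
            zs = V0 @ row
            extent = float(zs.max() - zs.min())
            key = (round(extent, 9), abs(rx) + abs(ry), rx, ry)
            if key < best:
                best = key
    _, _, rx, ry = best
    R = _rot_y(ry) @ _rot_x(rx) @ R0
    out = mesh.copy()
    out.vertices = V @ R.T
    return out, Rotation2Tilt(rx=rx, ry=ry, matrix=R)


# ---------------------------------------------------------------------------
# Top/bottom segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    """Vertex/face partition into bottom (downward-facing) and top sets."""

    bottom_vertices: np.ndarray  # vertex indices
    top_vertices: np.ndarray
    bottom_faces: np.ndarray  # face indices
    top_faces: np.ndarray
    n_ambiguous: int  # vertices with |nz| < 1e-6 (vertical walls), sent to top


def split_top_bottom(mesh: trimesh.Trimesh, nz_threshold: float = 0.0) -> SplitResult:
    """Partition vertices and faces by the sign of the vertex-normal Z component.

    A vertex belongs to the bottom set iff its normal's Z component is below
    ``nz_threshold``.  Faces follow the majority of their three vertices.
    Near-vertical vertices (|nz| < 1e-6) are assigned to the top set and
    counted in ``n_ambiguous`` (a warning is emitted when any exist).
    """
    nz = np.asarray(mesh.vertex_normals, dtype=float)[:, 2]
    ambiguous = np.abs(nz) < 1e-6
    is_bottom = (nz < nz_threshold) & ~ambiguous
    n_amb = int(ambiguous.sum())
    if n_amb:
        warnings.warn(
            f"{n_amb} vertices have near-vertical normals (|nz| < 1e-6); assigned to top",
            stacklevel=2,
        )
    idx = np.arange(len(nz))
    faces = np.asarray(mesh.faces)
    votes = is_bottom[faces].sum(axis=1)
    face_bottom = votes >= 2  # majority of 3; ties cannot occur with 2 classes
    fidx = np.arange(len(faces))
    return SplitResult(
        bottom_vertices=idx[is_bottom],
        top_vertices=idx[~is_bottom],
        bottom_faces=fidx[face_bottom],
        top_faces=fidx[~face_bottom],
        n_ambiguous=n_amb,
    )


# ---------------------------------------------------------------------------
# Height fields and conformal layers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeightField:
    """z(x, y) sampled on a regular XY grid; NaN marks undefined cells.

    ``z`` is indexed ``[iy, ix]``; the cell centre of ``(ix, iy)`` sits at
    ``origin + spacing * (ix, iy)``.
    """

    origin: tuple[float, float]
    spacing: float
    z: np.ndarray

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValidationError("grid spacing must be positive")
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or min(z.shape) < 2:
            raise ValidationError("height field needs at least a 2x2 grid")
        object.__setattr__(self, "z", z)

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.z.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.z.shape[0])

    def sample(self, x, y) -> np.ndarray:
        """Bilinear interpolation; NaN outside the grid or over undefined cells."""
        interp = RegularGridInterpolator(
            (self.y, self.x), self.z, method="linear",
            bounds_error=False, fill_value=np.nan,
        )
        pts = np.column_stack([np.atleast_1d(y).astype(float), np.atleast_1d(x).astype(float)])
        out = interp(pts)
        return out if np.ndim(x) else float(out[0])

    def translated(self, dx: float, dy: float) -> "HeightField":
        return HeightField(origin=(self.origin[0] + dx, self.origin[1] + dy),
                           spacing=self.spacing, z=self.z)


@dataclass(frozen=True)
class LayerSurface:
    """One conformal layer: the bottom template plus a vertical offset."""

    index: int
    base: HeightField
    offset: float  # cumulative vertical offset of the layer's top surface, mm
    thickness: float
    role: Literal["bottom_cover", "infill", "top_cover", "sacrificial"]

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValidationError("layer thickness must be positive")
        if self.role not in LAYER_ROLES:
            raise ValidationError(f"unknown layer role {self.role!r}")

    def sample(self, x, y):
        """Layer surface height at (x, y): base height plus the offset."""
        return self.base.sample(x, y) + self.offset


def heightfield_from_points(points: np.ndarray, spacing: float) -> HeightField:
    """Regular-grid height field from scattered (x, y, z) samples.

    Uses barycentric linear interpolation on the Delaunay triangulation of
    the XY locations (the standard treatment of raw surface-scan data).
    Grid cells outside the convex hull are NaN and excluded downstream.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValidationError("need at least 3 (x, y, z) points")
    try:
        interp = LinearNDInterpolator(P[:, :2], P[:, 2])
    except QhullError as exc:
        raise ValidationError(f"points are collinear or degenerate: {exc}") from exc
    if interp.tri.npoints < 3 or len(interp.tri.simplices) == 0:
        raise ValidationError("points are collinear: no triangulation exists")
    x0, y0 = P[:, 0].min(), P[:, 1].min()
    nx = int(np.floor((P[:, 0].max() - x0) / spacing)) + 1
    ny = int(np.floor((P[:, 1].max() - y0) / spacing)) + 1
    gx = x0 + spacing * np.arange(max(nx, 2))
    gy = y0 + spacing * np.arange(max(ny, 2))
    X, Y = np.meshgrid(gx, gy)
    Z = interp(X, Y)
    return HeightField(origin=(float(x0), float(y0)), spacing=float(spacing), z=Z)


def conformal_layers(
    base: HeightField, plan: Sequence[tuple[str, float]]
) -> list[LayerSurface]:
    """Stack layers as successive vertical offsets of the bottom template.

    ``plan`` is an ordered list of ``(role, thickness_mm)``; layer k's top
    surface sits at the base height plus the cumulative thickness through k.
    """
    if not plan:
        raise ValidationError("layer plan is empty")
    layers, offset = [], 0.0
    for k, (role, t) in enumerate(plan):
        offset += float(t)
        layers.append(LayerSurface(index=k, base=base, offset=offset, thickness=float(t), role=role))
    return layers


# ---------------------------------------------------------------------------
# Contours and projection
# ---------------------------------------------------------------------------


def mesh_footprint(mesh: trimesh.Trimesh) -> list[Polygon]:
    """XY footprint of a mesh: union of projected triangles, oriented CCW."""
    tris = np.asarray(mesh.vertices)[np.asarray(mesh.faces)][:, :, :2]
    polys = []
    for t in tris:
        p = Polygon(t)
        if p.area > 1e-12:
            polys.append(p)
    merged = unary_union(polys).buffer(0)
    if merged.is_empty:
        return []
    geoms = list(merged.geoms) if hasattr(merged, "geoms") else [merged]
    return [shgeo.polygon.orient(g, sign=1.0) for g in geoms if isinstance(g, Polygon)]


def layer_contour(mesh: trimesh.Trimesh, layer: LayerSurface) -> list[Polygon]:
    """Footprint polygon(s) of a solid mesh at a conformal layer.

    Conformal layers are vertical offsets of the bottom template, so where
    the model has material at the layer's height its outline is the XY
    footprint of the mesh.  Returns an empty list when the layer surface
    lies entirely above the mesh top (no material remains at that height) —
    note this applies to solid models; an open shell used purely as a
    bottom template carries its stack above itself by construction, and the
    planner uses :func:`mesh_footprint` directly in that situation.
    """
    zmax = float(np.asarray(mesh.vertices)[:, 2].max())
    z_layer_min = float(np.nanmin(layer.base.z)) + layer.offset
    if z_layer_min > zmax:
        return []
    return mesh_footprint(mesh)


def project_to_surface(path2d: np.ndarray, layer: LayerSurface) -> np.ndarray:
    """Lift a planar waypoint sequence onto a layer surface.

    XY coordinates are unchanged; z is the bilinear sample of the layer.
    A waypoint over an undefined region raises, naming its index.
    """
    P = np.atleast_2d(np.asarray(path2d, dtype=float))[:, :2]
    z = np.atleast_1d(layer.sample(P[:, 0], P[:, 1]))
    bad = np.flatnonzero(np.isnan(z))
    if bad.size:
        raise ValidationError(
            f"waypoint {bad[0]} at ({P[bad[0], 0]:.3f}, {P[bad[0], 1]:.3f}) "
            "lies outside the defined layer region"
        )
    return np.column_stack([P, z])


def path_gradient(path3d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local inclination along a 3D path.

    Returns ``(alpha_deg, sense)`` per waypoint, where ``alpha`` is
    ``atan(|dz/ds|)`` with ``s`` the planar (XY) arc length, computed by
    central differences in the interior and one-sided at the ends, and
    ``sense`` is ``"ascending"`` where dz/ds > 0 else ``"descending"``.
    """
    P = np.asarray(path3d, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2 or P.shape[1] != 3:
        raise ValidationError("path must be an (n>=2, 3) array")
    seg = np.linalg.norm(np.diff(P[:, :2], axis=0), axis=1)
    if np.any(seg < 1e-12):
        raise ValidationError("duplicate consecutive waypoints in path")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    dzds = np.gradient(P[:, 2], s)
    alpha = np.rad2deg(np.arctan(np.abs(dzds)))
    sense = np.where(dzds > 0, "ascending", "descending")
    return alpha, sense


# ---------------------------------------------------------------------------
# Nozzle-height compensation and flow
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepositionParams:
    """Local deposition state used by the nozzle-height compensation."""

    h0: float  # desired layer height, mm
    d: float  # nozzle inner diameter, mm
    alpha: float  # local inclination, degrees
    travel_sense: Literal["ascending", "descending"]
    speed: float = 16.667  # mm/s

    def __post_init__(self):
        if self.h0 <= 0 or self.d <= 0 or self.speed <= 0:
            raise ValidationError("h0, d and speed must be positive")
        if not 0 <= self.alpha < 90:
            raise ValidationError("alpha must be in [0, 90) degrees")
        if self.travel_sense not in ("ascending", "descending"):
            raise ValidationError(f"unknown travel sense {self.travel_sense!r}")


def adjust_nozzle_height(p: DepositionParams) -> float:
    """Adjusted nozzle clearance h = h0/cos(alpha) +/- (d/2) tan(alpha).

    "+" when descending, "-" when ascending: travelling uphill the leading
    nozzle edge overhangs the higher substrate side, so the commanded
    clearance is reduced to keep the deposited height at ``h0``.
    """
    a = np.deg2rad(p.alpha)
    sign = 1.0 if p.travel_sense == "descending" else -1.0
    h = p.h0 / np.cos(a) + sign * (p.d / 2.0) * np.tan(a)
    if h <= 0:
        raise ValidationError(
            f"adjusted height is non-positive at alpha={p.alpha} deg ascending; "
            "inclination too steep for this nozzle/layer combination"
        )
    return float(h)


def flow_rate(speed: float, d: float, h: float) -> float:
    """Volumetric flow (mm^3/s) for a rectangular filament of width d, height h."""
    if speed < 0 or d <= 0 or h <= 0:
        raise ValidationError("speed must be >= 0 and d, h > 0")
    return speed * d * h


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def read_points_csv(path: str | Path) -> np.ndarray:
    """Read scattered surface samples from a headered CSV with x, y, z columns."""
    df = pd.read_csv(path)
    return df[["x", "y", "z"]].to_numpy(float)


def write_contour_csv(polygons: Sequence[Polygon], path: str | Path) -> None:
    """Write closed contour polylines as CSV (contour_id, order, x, y)."""
    rows = []
    for cid, poly in enumerate(polygons):
        xs, ys = poly.exterior.coords.xy
        for k, (x, y) in enumerate(zip(xs, ys)):
            rows.append((cid, k, x, y))
    pd.DataFrame(rows, columns=["contour_id", "order", "x", "y"]).to_csv(path, index=False)
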