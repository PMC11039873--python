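"""Triangle-mesh data model, STL/PLY I/O and planar cross-sections.

The whole pipeline works in a single coordinate convention: the canal's
longitudinal axis is z, the most distal cross-section sits at z = 0 and the
shaft extends toward +z; x is the medio-lateral axis, y the anterior-posterior
axis. All coordinates are millimetres.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from ._geometry import polygon_area
from .errors import (DegenerateSliceError, MeshIOError, MeshValidationError,
                     NoIntersectionError)

log = logging.getLogger(__name__)

#: Tag naming the shared coordinate convention (distal end at z = 0, +z proximal).
DEFAULT_FRAME = "distal-z0"

_FORMATS = ("stl", "ply")


@dataclass
class TriMesh:
    """Triangulated canal surface: vertices (Nn, 3) in mm, faces (Nf, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray
    frame: str = DEFAULT_FRAME

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.validate()

    def validate(self) -> None:
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise MeshValidationError("mesh is empty (no vertices or no faces)")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshValidationError("mesh has non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshValidationError(
                f"face index out of range [0, {len(self.vertices)})")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MeshValidationError("degenerate face: repeated vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def z_range(self) -> tuple[float, float]:
        z = self.vertices[:, 2]
        return float(z.min()), float(z.max())

    @property
    def extent(self) -> float:
        """Longitudinal extent (mm) along the frame's z axis."""
        lo, hi = self.z_range
        return hi - lo

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.frame)

    def transformed(self, transform) -> "TriMesh":
        return TriMesh(transform.apply(self.vertices), self.faces.copy(), self.frame)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh, frame: str = DEFAULT_FRAME) -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=float),
                   np.asarray(tm.faces, dtype=np.int64), frame)


@dataclass
class PlanarPolygon:
    """Closed cross-section loop at longitudinal station `station` (mm).

    Points are an ordered open ring (closure implicit) of (x, y) pairs in the
    slice plane, counter-clockwise viewed from +z.
    """

    station: float
    points: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) >= 2 and np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]
        if len(self.points) < 8:
            raise DegenerateSliceError(
                f"slice at z={self.station:.3f} has only {len(self.points)} points")

    @property
    def area(self) -> float:
        """Enclosed (shoelace) area, positive for CCW loops."""
        return polygon_area(self.points)

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed polygon."""
        p = self.points
        q = np.roll(p, -1, axis=0)
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:
            return p.mean(axis=0)
        cx = np.sum((p[:, 0] + q[:, 0]) * cross) / (6.0 * a)
        cy = np.sum((p[:, 1] + q[:, 1]) * cross) / (6.0 * a)
        return np.array([cx, cy])


def _resolve_format(path, fmt) -> str:
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshIOError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_mesh(path, fmt: str | None = None) -> TriMesh:
    """Read an STL (binary or ASCII) or PLY triangle mesh.

    STL stores loose triangles, so coincident vertices are merged on load to
    recover an indexed topology; PLY is read as stored. Units are assumed mm.
    """
    fmt = _resolve_format(path, fmt)
    if not os.path.exists(path):
        raise MeshIOError(f"no such file: {path}")
    try:
        tm = _trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # parser-level failure
        raise MeshIOError(f"could not parse {path} as {fmt}: {exc}") from exc
    if isinstance(tm, _trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshValidationError(f"{path}: file contains no mesh geometry")
        tm = geoms[0]
    if fmt == "stl":
        tm.merge_vertices()
    return TriMesh.from_trimesh(tm)


def write_mesh(mesh: TriMesh, path, fmt: str | None = None, *, binary: bool = True) -> None:
    """Write a mesh as STL (binary by default, ASCII with binary=False) or ASCII PLY."""
    fmt = _resolve_format(path, fmt)
    mesh.validate()
    tm = mesh.to_trimesh()
    try:
        if fmt == "stl":
            tm.export(str(path), file_type="stl" if binary else "stl_ascii")
        else:
            tm.export(str(path), file_type="ply",
                      encoding="binary" if binary else "ascii")
    except OSError as exc:
        raise MeshIOError(f"could not write {path}: {exc}") from exc


def slice_mesh(mesh: TriMesh, z: float) -> PlanarPolygon:
    """Intersect the surface with the plane normal to z at station `z`.

    Returns the ordered closed loop of the intersection, CCW viewed from +z.
    If the plane cuts several loops the largest-area one is kept and a warning
    logged; the station must lie strictly inside the longitudinal extent.
    """
    lo, hi = mesh.z_range
    if not (lo < z < hi):
        raise NoIntersectionError(
            f"station z={z:.3f} outside the open longitudinal extent ({lo:.3f}, {hi:.3f})")
    section = mesh.to_trimesh().section(plane_origin=[0.0, 0.0, z],
                                        plane_normal=[0.0, 0.0, 1.0])
    if section is None:
        raise NoIntersectionError(f"plane z={z:.3f} does not intersect the mesh")
    loops = [np.asarray(loop) for loop in section.discrete]
    closed = [lp for lp in loops if len(lp) >= 4 and np.allclose(lp[0], lp[-1], atol=1e-9)]
    if not closed:
        raise DegenerateSliceError(
            f"section at z={z:.3f} is an open curve (plane tangent to a boundary?)")
    if len(closed) > 1:
        log.warning("slice at z=%.3f produced %d loops; keeping the largest-area one",
                    z, len(closed))
    areas = [abs(polygon_area(lp[:-1, :2])) for lp in closed]
    loop = closed[int(np.argmax(areas))]
    pts = loop[:-1, :2]
    if polygon_area(pts) < 0:  # enforce CCW from +z
        pts = pts[::-1]
    return PlanarPolygon(station=z, points=pts)
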