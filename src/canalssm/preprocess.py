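"""Mirroring, distal-segment cutting and rigid ICP alignment.

Right-side canals are reflected onto left-side geometry by comparing rigid
Procrustes residuals against a left reference, with and without reflection.
Sixteen nested distal segments (25% L ... 100% L in 5% steps) are cut from
each full-length canal, and every segment is rigidly registered to the
corresponding segment of the reference canal with a point-to-point ICP
stopped at 0.01 mm / 0.05 deg inter-iteration increments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

from ._geometry import RigidTransform, kabsch
from .errors import (FitError, NonConvergenceError, ParameterError,
                     PreprocessError)
from .mesh import TriMesh, slice_mesh

log = logging.getLogger(__name__)

#: The sixteen admissible distal segment fractions (25% L ... 100% L, 5% step).
SEGMENT_FRACTIONS: tuple[float, ...] = tuple(np.round(np.arange(0.25, 1.0001, 0.05), 2))

DEFAULT_ICP_TOL_TRANS_MM = 0.01
DEFAULT_ICP_TOL_ROT_DEG = 0.05


def reflect_mesh(mesh: TriMesh) -> TriMesh:
    """Reflect across the x = 0 (sagittal) plane, keeping outward face orientation."""
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    return TriMesh(v, mesh.faces[:, ::-1].copy(), mesh.frame)


def _canonical_axis_endpoints(ellipse, z: float) -> np.ndarray:
    """Major/minor axis endpoints of a fitted slice ellipse, lifted to 3D.

    Axis directions are canonicalized (positive x, then positive y component)
    so the four endpoints are ordered reproducibly for Procrustes pairing.
    """
    th = np.radians(ellipse.orientation_deg)
    u = np.array([np.cos(th), np.sin(th)])
    if u[0] < 0 or (abs(u[0]) < 1e-12 and u[1] < 0):
        u = -u
    v = np.array([-u[1], u[0]])
    if v[1] < 0 or (abs(v[1]) < 1e-12 and v[0] < 0):
        v = -v
    c = ellipse.centroid
    pts2 = [c + u * ellipse.ax_max / 2.0, c - u * ellipse.ax_max / 2.0,
            c + v * ellipse.ax_min / 2.0, c - v * ellipse.ax_min / 2.0]
    return np.array([[p[0], p[1], z] for p in pts2])


def _robust_slices(mesh: TriMesh, spacing: float) -> list:
    """(station, SliceEllipse) every `spacing` mm, tolerant of tilted poses.

    Mirroring runs before ICP, so canals may still carry a residual pose: the
    slicing grid starts half a spacing inside the extent and stations whose
    plane only clips a rim corner are skipped.
    """
    from .errors import DegenerateSliceError, NoIntersectionError
    from .features import fit_ellipse
    from .mesh import slice_mesh

    lo, hi = mesh.z_range
    out = []
    for z in np.arange(lo + spacing / 2.0, hi - spacing / 4.0, spacing):
        try:
            out.append((float(z), fit_ellipse(slice_mesh(mesh, z))))
        except (DegenerateSliceError, NoIntersectionError, FitError):
            continue
    return out


def mirroring_landmarks(mesh: TriMesh, spacing: float = 10.0,
                        max_slices: int | None = None) -> np.ndarray:
    """Homologous landmark set for mirror detection.

    Slice centroids every `spacing` mm from the distal end (optionally only
    the `max_slices` most distal ones) plus the four axis endpoints of the
    most distal valid slice ellipse.
    """
    slices = _robust_slices(mesh, spacing)
    if len(slices) < 3:
        raise PreprocessError("landmark extraction failed: too few valid slices")
    if max_slices is not None:
        slices = slices[:max_slices]
    centroids = np.array([[e.centroid[0], e.centroid[1], z] for z, e in slices])
    endpoints = _canonical_axis_endpoints(slices[0][1], slices[0][0])
    return np.vstack([centroids, endpoints])


def _procrustes_rms(a: np.ndarray, b: np.ndarray) -> float:
    T = kabsch(a, b)
    d = T.apply(a) - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def mirror_canal(mesh: TriMesh, reference: TriMesh,
                 spacing: float = 10.0) -> tuple[TriMesh, str]:
    """Detect and undo right-sidedness against a left-sided reference.

    The rigid (no scaling) Procrustes residual of the landmark set against the
    reference's is computed for the canal as-is and for its reflection across
    x = 0; the lower-residual variant is kept. Returns (mesh, side_flag) where
    side_flag is "right" iff the reflection won (i.e. the input was
    right-sided relative to the reference).
    """
    n_mesh = len(_robust_slices(mesh, spacing))
    n_ref = len(_robust_slices(reference, spacing))
    m = min(n_mesh, n_ref)
    if m < 3:
        raise PreprocessError("too few valid slices for mirror detection")
    lm_ref = mirroring_landmarks(reference, spacing, max_slices=m)
    lm_direct = mirroring_landmarks(mesh, spacing, max_slices=m)
    reflected = reflect_mesh(mesh)
    lm_mirror = mirroring_landmarks(reflected, spacing, max_slices=m)
    r_direct = _procrustes_rms(lm_direct, lm_ref)
    r_mirror = _procrustes_rms(lm_mirror, lm_ref)
    if r_mirror < r_direct:
        return reflected, "right"
    return mesh.copy(), "left"


def cut_segment(mesh: TriMesh, fraction: float) -> TriMesh:
    """Keep the distal portion z in [0, fraction * L] of the canal.

    `fraction` must be one of the sixteen admissible values; the cut rim is
    left open (no capping) and the distal end is shared by all segments of a
    subject. Fraction 1.0 returns the full canal unchanged.
    """
    if not any(abs(fraction - f) < 1e-9 for f in SEGMENT_FRACTIONS):
        raise ParameterError(
            f"fraction {fraction} not in the admissible set {SEGMENT_FRACTIONS}")
    if abs(fraction - 1.0) < 1e-9:
        return mesh.copy()
    lo, _ = mesh.z_range
    z_cut = lo + fraction * mesh.extent
    cut = _trimesh.intersections.slice_mesh_plane(
        mesh.to_trimesh(), plane_normal=[0.0, 0.0, -1.0],
        plane_origin=[0.0, 0.0, z_cut + 1e-6], cap=False)
    if cut is None or len(cut.faces) == 0:
        raise PreprocessError(f"cut at fraction {fraction} produced an empty mesh")
    out = _trimesh.Trimesh(np.asarray(cut.vertices), np.asarray(cut.faces),
                           process=False)
    out.merge_vertices()        # the plane cut duplicates vertices on the rim
    out.remove_unreferenced_vertices()
    return TriMesh.from_trimesh(out, mesh.frame)


def choose_reference(meshes: list[TriMesh],
                     candidates: list[int] | None = None) -> int:
    """Index of the intermediate-sized canal: the (lower-)median longitudinal extent."""
    idx = list(range(len(meshes))) if candidates is None else list(candidates)
    if not idx:
        raise ParameterError("no candidate meshes for reference selection")
    extents = [(meshes[i].extent, i) for i in idx]
    extents.sort()
    return extents[(len(extents) - 1) // 2][1]


@dataclass
class ICPResult:
    """Outcome of a converged ICP run."""

    mesh: TriMesh
    transform: RigidTransform
    iterations: int
    trans_increment_mm: float
    rot_increment_deg: float
    residual_mm: float          # mean closest-vertex distance at convergence


def icp_align(moving: TriMesh, target: TriMesh,
              tol_trans_mm: float = DEFAULT_ICP_TOL_TRANS_MM,
              tol_rot_deg: float = DEFAULT_ICP_TOL_ROT_DEG,
              max_iter: int = 200,
              principal_axis_init: bool = False) -> ICPResult:
    """Rigid point-to-point ICP of `moving` onto `target`.

    Correspondence is vertex-to-nearest-vertex on the target; each iteration
    solves the optimal rigid transform (Kabsch) for the current pairing.
    Iterations stop when the inter-iteration translation increment falls below
    `tol_trans_mm` AND the inter-iteration rotation increment (axis-angle
    magnitude of the relative rotation) falls below `tol_rot_deg`.
    Initialization superposes centroids; `principal_axis_init` additionally
    aligns the leading principal axes for badly posed inputs.
    """
    tgt = target.vertices
    tree = cKDTree(tgt)
    mov = moving.vertices

    R0 = np.eye(3)
    if principal_axis_init:
        R0 = _principal_axis_rotation(mov, tgt)
    t0 = tgt.mean(axis=0) - R0 @ mov.mean(axis=0)
    T = RigidTransform(R0, t0)

    for it in range(1, max_iter + 1):
        cur = T.apply(mov)
        _, idx = tree.query(cur)
        step = kabsch(cur, tgt[idx])
        T_new = step.compose(T)
        d_trans = float(np.linalg.norm(T_new.translation - T.translation))
        d_rot = RigidTransform(step.rotation, np.zeros(3)).rotation_angle_deg
        T = T_new
        if d_trans < tol_trans_mm and d_rot < tol_rot_deg:
            cur = T.apply(mov)
            dist, _ = tree.query(cur)
            return ICPResult(mesh=TriMesh(cur, moving.faces.copy(), moving.frame),
                             transform=T, iterations=it,
                             trans_increment_mm=d_trans, rot_increment_deg=d_rot,
                             residual_mm=float(dist.mean()))
    raise NonConvergenceError(
        f"ICP did not converge in {max_iter} iterations "
        f"(last increments: {d_trans:.4g} mm, {d_rot:.4g} deg)",
        iterations=max_iter, trans_increment=d_trans, rot_increment_deg=d_rot)


def _principal_axes(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    if np.linalg.det(vt) < 0:
        vt[2] = -vt[2]
    return vt


def _principal_axis_rotation(mov: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Rotation mapping the moving cloud's principal frame onto the target's.

    Principal axes have an inherent sign ambiguity, so the four proper sign
    combinations are tried and the one with the lowest mean closest-vertex
    distance (on a subsample) wins — a pose initialization good enough to put
    ICP in the right convergence basin even for large misalignments.
    """
    A_m, A_t = _principal_axes(mov), _principal_axes(tgt)
    tree = cKDTree(tgt)
    sub = mov[:: max(1, len(mov) // 500)]
    cm, ct = mov.mean(axis=0), tgt.mean(axis=0)
    best, best_cost = np.eye(3), np.inf
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = A_t.T @ (np.diag(signs) @ A_m)
        moved = (sub - cm) @ R.T + ct
        cost = tree.query(moved)[0].mean()
        if cost < best_cost:
            best, best_cost = R, cost
    return best
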