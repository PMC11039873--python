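"""Synthetic medullary-canal surfaces with known ground-truth geometry.

The generator emulates the population structure the downstream analysis
assumes: independent subject-level variation in longitudinal length (La),
centerline radius of curvature (Rc), cross-sectional size (davg), distal
flare (conicity, con) and distal ellipticity (ell), plus random rigid pose
and left/right side.

A canal is a swept tube: the centerline is a circular arc of radius Rc lying
in a plane that contains the z axis and is rotated a small azimuth off the
sagittal (y-z) plane; cross-sections perpendicular to z are ellipses with the
major axis along x. The diameter profile is piecewise linear with an interior
minimum (the isthmus) at fractional station `z_min_frac`, flaring back to the
distal diameter at z = 0, which makes conicity (distal minus minimum
diameter) nonzero and controllable. Ellipticity is maximal at the distal
section and decays linearly to zero proximally. Right-side canals are the
mirror image (across x = 0) of the construction; the small off-sagittal bow
azimuth is what makes left and right geometrically distinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geometry import RigidTransform, random_rigid_transform
from .errors import GenerationError, ParameterError
from .mesh import TriMesh

STRAIGHT = math.inf
"""Sentinel curvature radius for a straight centerline."""


@dataclass
class CanalParams:
    """Ground-truth generative parameters of a single canal."""

    length_mm: float = 200.0
    curvature_radius_mm: float = 1000.0   # STRAIGHT for a straight canal
    diameter_distal_mm: float = 17.0
    diameter_min_mm: float = 11.0
    z_min_frac: float = 0.3
    ellipticity_mm: float = 2.0
    proximal_flare_mm: float = 6.0        # proximal diameter = diameter_min + this
    isthmus_plateau_mm: float = 12.0      # flat stretch at the minimum diameter
    side: str = "left"
    bow_plane_deg: float = 15.0           # bow-plane azimuth off sagittal, toward +x
    pose: RigidTransform | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        p = self
        if not p.length_mm > 0:
            raise ParameterError("length_mm must be positive")
        if p.diameter_min_mm <= 0 or p.diameter_min_mm > p.diameter_distal_mm:
            raise ParameterError("need 0 < diameter_min_mm <= diameter_distal_mm")
        if p.ellipticity_mm < 0:
            raise ParameterError("ellipticity_mm must be >= 0")
        if p.ellipticity_mm >= p.diameter_min_mm:
            raise ParameterError("ellipticity_mm must stay below diameter_min_mm "
                                 "(sections must remain valid ellipses)")
        if p.proximal_flare_mm < 0:
            raise ParameterError("proximal_flare_mm must be >= 0")
        if not 0.0 < p.z_min_frac < 1.0:
            raise ParameterError("z_min_frac must lie in (0, 1)")
        if math.isfinite(p.curvature_radius_mm) and \
                p.curvature_radius_mm <= p.length_mm / 2.0:
            raise ParameterError("curvature_radius_mm must exceed length_mm/2 "
                                 "(arc must remain a function of z)")
        if p.side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")

    @property
    def conicity_mm(self) -> float:
        """Ground-truth conicity: distal diameter minus minimum diameter."""
        return self.diameter_distal_mm - self.diameter_min_mm


@dataclass
class PopulationSpec:
    """Cohort distribution: truncated-normal draws per generative parameter.

    Each (mean, sd) pair describes an independent normal truncated to the
    parameter's valid region (re-drawn up to `max_retries` times). The seed
    fixes the whole cohort, meshes included, bit for bit.
    """

    n_subjects: int = 20
    length_mm: tuple[float, float] = (200.0, 15.0)
    curvature_radius_mm: tuple[float, float] = (1000.0, 150.0)
    diameter_mm: tuple[float, float] = (11.0, 1.0)       # isthmus (minimum) diameter
    flare_mm: tuple[float, float] = (6.0, 0.6)           # distal minus minimum diameter
    ellipticity_mm: tuple[float, float] = (2.0, 0.5)
    z_min_frac: float = 0.3
    bow_plane_deg: float = 15.0
    fraction_right: float = 0.5
    max_rot_deg: float = 5.0
    max_trans_mm: float = 5.0
    n_circumferential: int = 48
    n_longitudinal: int = 101
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ParameterError("n_subjects must be >= 3")
        for name in ("length_mm", "curvature_radius_mm", "diameter_mm",
                     "flare_mm", "ellipticity_mm"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ParameterError(f"{name} SD must be >= 0")
            if not math.isfinite(mean) and sd != 0:
                raise ParameterError(f"{name}: infinite mean requires SD = 0")
        if not 0.0 <= self.fraction_right <= 1.0:
            raise ParameterError("fraction_right must lie in [0, 1]")


@dataclass
class Cohort:
    """A generated cohort: meshes, their generative parameters, and a table."""

    meshes: list[TriMesh]
    params: list[CanalParams]
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.meshes)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _diameter_profile(z: np.ndarray, p: CanalParams) -> np.ndarray:
    """Piecewise-linear diameter: distal (condylar) flare -> isthmus plateau
    -> proximal (metaphyseal) flare. The two flares are independent; the
    minimum is a short flat stretch rather than a sharp vertex, so sampling
    the profile on any coarse longitudinal grid still observes the true
    minimum diameter."""
    zm = p.z_min_frac * p.length_mm
    half = min(p.isthmus_plateau_mm / 2.0, 0.8 * zm,
               0.8 * (p.length_mm - zm))
    lo_edge, hi_edge = zm - half, zm + half
    d_prox = p.diameter_min_mm + p.proximal_flare_mm
    d = np.full_like(z, p.diameter_min_mm)
    distal = z < lo_edge
    d[distal] = p.diameter_distal_mm + \
        (p.diameter_min_mm - p.diameter_distal_mm) * z[distal] / lo_edge
    proximal = z > hi_edge
    d[proximal] = p.diameter_min_mm + (d_prox - p.diameter_min_mm) \
        * (z[proximal] - hi_edge) / (p.length_mm - hi_edge)
    return d


def _centerline_offset(z: np.ndarray, p: CanalParams) -> np.ndarray:
    """Deflection of the centerline from the z axis, along the bow-plane direction."""
    if not math.isfinite(p.curvature_radius_mm):
        return np.zeros_like(z)
    R, L = p.curvature_radius_mm, p.length_mm
    half = L / 2.0
    return np.sqrt(R * R - (z - half) ** 2) - math.sqrt(R * R - half * half)


def generate_canal(params: CanalParams, n_circumferential: int = 48,
                   n_longitudinal: int = 101,
                   theta_offset_deg: float = 0.0) -> TriMesh:
    """Build the swept-tube surface for one set of generative parameters.

    The grid topology (n_circumferential x n_longitudinal, open tube, no end
    caps) is identical for every canal built at the same resolution, so
    cohorts are iso-topological by construction. `theta_offset_deg` rotates
    the circumferential sampling phase — useful to re-mesh the same surface
    with a different discretization.
    """
    params.validate()
    if n_circumferential < 8 or n_longitudinal < 2:
        raise ParameterError("resolution too coarse: need >= 8 x 2 grid")
    p = params
    z = np.linspace(0.0, p.length_mm, n_longitudinal)
    theta = np.radians(theta_offset_deg) + \
        np.linspace(0.0, 2.0 * np.pi, n_circumferential, endpoint=False)

    d = _diameter_profile(z, p)
    e = p.ellipticity_mm * (1.0 - z / p.length_mm)
    a = (d + e / 2.0) / 2.0          # semi-axis along x (major)
    b = (d - e / 2.0) / 2.0          # semi-axis along y (minor)

    g = _centerline_offset(z, p)
    phi = math.radians(p.bow_plane_deg)
    cx = g * math.sin(phi)
    cy = g * math.cos(phi)

    cos_t, sin_t = np.cos(theta), np.sin(theta)
    X = cx[:, None] + a[:, None] * cos_t[None, :]
    Y = cy[:, None] + b[:, None] * sin_t[None, :]
    Z = np.broadcast_to(z[:, None], X.shape)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    nc = n_circumferential
    faces = []
    for j in range(n_longitudinal - 1):
        base, nxt = j * nc, (j + 1) * nc
        for i in range(nc):
            i2 = (i + 1) % nc
            faces.append((base + i, base + i2, nxt + i2))
            faces.append((base + i, nxt + i2, nxt + i))
    faces = np.asarray(faces, dtype=np.int64)

    # right side: mirror vertices only, keeping the face list bit-identical
    # across the whole cohort (iso-topology); no stage relies on face
    # orientation, so the flipped winding of mirrored canals is harmless
    if p.side == "right":
        vertices[:, 0] = -vertices[:, 0]

    mesh = TriMesh(vertices, faces)
    if p.pose is not None:
        mesh = mesh.transformed(p.pose)
    return mesh


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                    ok, retries: int, name: str) -> float:
    if sd == 0:
        if not ok(mean):
            raise GenerationError(f"{name}: mean {mean} violates its invariant")
        return mean
    for _ in range(retries):
        x = rng.normal(mean, sd)
        if ok(x):
            return float(x)
    raise GenerationError(f"{name}: no valid draw in {retries} retries "
                          f"(mean={mean}, sd={sd})")


def draw_params(spec: PopulationSpec, rng: np.random.Generator) -> CanalParams:
    """Draw one subject's CanalParams from the population distributions."""
    r = spec.max_retries
    La = _draw_truncated(rng, *spec.length_mm, lambda x: x > 0, r, "length_mm")
    Rc = _draw_truncated(rng, *spec.curvature_radius_mm,
                         lambda x: (not math.isfinite(x)) or x > La / 2.0,
                         r, "curvature_radius_mm")
    dmin = _draw_truncated(rng, *spec.diameter_mm, lambda x: x > 0, r, "diameter_mm")
    flare = _draw_truncated(rng, *spec.flare_mm, lambda x: x >= 0, r, "flare_mm")
    ell = _draw_truncated(rng, *spec.ellipticity_mm,
                          lambda x: 0 <= x < dmin, r, "ellipticity_mm")
    side = "right" if rng.uniform() < spec.fraction_right else "left"
    pose = random_rigid_transform(rng, spec.max_rot_deg, spec.max_trans_mm)
    return CanalParams(length_mm=La, curvature_radius_mm=Rc,
                       diameter_distal_mm=dmin + flare, diameter_min_mm=dmin,
                       z_min_frac=spec.z_min_frac, ellipticity_mm=ell,
                       side=side, bow_plane_deg=spec.bow_plane_deg, pose=pose)


def generate_population(spec: PopulationSpec) -> Cohort:
    """Generate a deterministic cohort of canal meshes plus its ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    params, meshes, rows = [], [], []
    for sid in range(spec.n_subjects):
        p = draw_params(spec, rng)
        mesh = generate_canal(p, spec.n_circumferential, spec.n_longitudinal)
        params.append(p)
        meshes.append(mesh)
        rotvec = _rotvec_of(p.pose)
        rows.append({
            "subject_id": sid,
            "La": p.length_mm,
            "Rc": p.curvature_radius_mm,
            "d_dist": p.diameter_distal_mm,
            "d_min": p.diameter_min_mm,
            "z_min_frac": p.z_min_frac,
            "ell": p.ellipticity_mm,
            "con": p.conicity_mm,
            "side": p.side,
            "pose_rx": rotvec[0], "pose_ry": rotvec[1], "pose_rz": rotvec[2],
            "pose_tx": p.pose.translation[0],
            "pose_ty": p.pose.translation[1],
            "pose_tz": p.pose.translation[2],
        })
    return Cohort(meshes=meshes, params=params, table=pd.DataFrame(rows))


def _rotvec_of(transform: RigidTransform) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_matrix(transform.rotation).as_rotvec()


def perturb_pose(mesh: TriMesh, max_rot_deg: float, max_trans_mm: float,
                 seed: int | np.random.Generator = 0) -> tuple[TriMesh, RigidTransform]:
    """Apply a random rigid motion within the given bounds; return mesh + transform."""
    if max_rot_deg < 0 or max_trans_mm < 0:
        raise ParameterError("pose-perturbation bounds must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = random_rigid_transform(rng, max_rot_deg, max_trans_mm)
    return mesh.transformed(T), T


def unposed(params: CanalParams) -> CanalParams:
    """Copy of `params` with identity pose (the canal in its canonical frame)."""
    return replace(params, pose=None)
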