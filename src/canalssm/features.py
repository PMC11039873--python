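"""Morphometric parametrization of a canal shape.

Any canal (a subject, a mean shape, or a ±2σ mode shape) is reduced to five
geometric parameters by slicing it every 10 mm perpendicular to the
longitudinal axis, best-fitting each section with an ellipse, and fitting a
circle to the slice centroids:

- La    longitudinal length (mm): the z extent of the mesh;
- Rc    radius of curvature (mm) of the centroid curve (least-squares circle
        in the SVD best-fit plane); radii above a cap are reported as the
        straight sentinel (infinity);
- ell   ellipticity (mm): major minus minor full axis at the most distal slice;
- davg  mean diameter (mm): mean over slices of the area-equivalent diameter
        2*sqrt(Area/pi) of the fitted ellipse;
- con   conicity (mm): distal-slice diameter minus the minimum slice diameter
        within the segment (distal flare past the isthmus; >= 0 by definition).

Note La (and the slicing grid) depends on the shared frame convention with z
longitudinal; all other features are invariant to rotations about z and
in-plane translations up to discretization error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

from .errors import FeatureError, FitError
from .mesh import PlanarPolygon, TriMesh, slice_mesh

log = logging.getLogger(__name__)

#: Fitted radii above this value (mm) are reported as straight (infinite radius).
STRAIGHT_CAP_MM = 50_000.0

#: Longitudinal slice spacing (mm).
DEFAULT_SPACING_MM = 10.0

# Slicing planes are nudged off nominal stations by this much so that planes
# never sit exactly on a vertex ring or on the open distal rim.
_STATION_EPS = 1e-3


@dataclass
class SliceEllipse:
    """Best-fit ellipse of one cross-section. Axes are FULL lengths (mm)."""

    station: float
    ax_max: float
    ax_min: float
    centroid: np.ndarray        # (x0, y0) in the slice plane
    area: float                 # pi * (ax_max/2) * (ax_min/2)
    orientation_deg: float      # major-axis angle from +x, in [0, 180)

    @property
    def diameter(self) -> float:
        """Area-equivalent diameter 2*sqrt(area/pi)."""
        return 2.0 * math.sqrt(self.area / math.pi)


@dataclass
class CanalFeatures:
    """The five geometric parameters of one canal segment."""

    length_mm: float
    curvature_radius_mm: float       # math.inf == straight
    ellipticity_mm: float
    mean_diameter_mm: float
    conicity_mm: float
    n_slices: int

    @property
    def is_straight(self) -> bool:
        return not math.isfinite(self.curvature_radius_mm)

    def as_dict(self) -> dict:
        return {"La": self.length_mm, "Rc": self.curvature_radius_mm,
                "ell": self.ellipticity_mm, "davg": self.mean_diameter_mm,
                "con": self.conicity_mm, "k": self.n_slices}


def fit_ellipse(polygon: PlanarPolygon) -> SliceEllipse:
    """Direct least-squares ellipse fit of a section loop.

    Uses the ellipse-constrained direct conic fit; degenerate or non-elliptical
    point sets raise FitError. The returned axes are full lengths.
    """
    pts = polygon.points
    with np.errstate(divide="ignore", invalid="ignore"):
        model = EllipseModel.from_estimate(pts)
    if not model:
        raise FitError(f"ellipse fit failed at z={polygon.station:.3f} "
                       "(degenerate or non-elliptical section)")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if a < b:
        a, b = b, a
        theta += math.pi / 2.0
    orientation = math.degrees(theta) % 180.0
    area = math.pi * a * b
    poly_area = abs(polygon.area)
    if poly_area > 0 and not 0.8 <= area / poly_area <= 1.2:
        log.warning("ellipse area %.2f deviates >20%% from polygon area %.2f "
                    "at z=%.3f", area, poly_area, polygon.station)
    return SliceEllipse(station=polygon.station, ax_max=2.0 * a, ax_min=2.0 * b,
                        centroid=np.array([xc, yc]), area=area,
                        orientation_deg=orientation)


def extract_slices(mesh: TriMesh, spacing: float = DEFAULT_SPACING_MM) -> list[SliceEllipse]:
    """Slice the canal every `spacing` mm from the distal end and fit ellipses.

    Stations run z = 0, spacing, 2*spacing, ... strictly inside the extent
    (measured from the distal end). The cutting planes are nudged a micron-
    scale epsilon proximally so the distal rim and vertex rings are never hit
    exactly.
    """
    from .errors import DegenerateSliceError, NoIntersectionError

    lo, _ = mesh.z_range
    extent = mesh.extent
    if extent < 2.0 * spacing:
        raise FeatureError(f"extent {extent:.1f} mm too short for spacing {spacing} mm")
    # the distal rim of an aligned (hence slightly tilted) canal is not exactly
    # planar in z: probe inward until the first closed section is found
    first_poly, delta = None, None
    for d in (_STATION_EPS, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0):
        try:
            first_poly = slice_mesh(mesh, lo + d)
            delta = d
            break
        except (DegenerateSliceError, NoIntersectionError):
            continue
    if first_poly is None:
        raise FeatureError("no closed section found near the distal end")
    slices = []
    for s in np.arange(0.0, extent - delta - _STATION_EPS, spacing):
        try:
            poly = first_poly if s == 0.0 else slice_mesh(mesh, lo + delta + s)
            ell = fit_ellipse(poly)
        except (DegenerateSliceError, NoIntersectionError):
            if s > extent - 2.0 * spacing:   # proximal rim corner: stop early
                break
            raise
        ell.station = float(s)
        slices.append(ell)
    if len(slices) < 3:
        raise FeatureError(f"only {len(slices)} valid slices; need >= 3")
    return slices


def radius_of_curvature(centroids, straight_cap: float = STRAIGHT_CAP_MM) -> float:
    """Radius of the least-squares circle through 3D slice centroids.

    The centroid cloud is centered on its mean, SVD gives the best-fit plane,
    the points are rotated into it, and an algebraic (Kåsa) circle fit is
    refined by one Gauss-Newton step on the geometric residuals. Radii above
    `straight_cap` — and exactly collinear clouds — are reported as math.inf.
    """
    P = np.asarray(centroids, dtype=float).reshape(-1, 3)
    if len(P) < 3:
        raise FeatureError("radius_of_curvature needs >= 3 centroids")
    P = P - P.mean(axis=0)
    _, svals, Vt = np.linalg.svd(P, full_matrices=False)
    u = P @ Vt[0]
    v = P @ Vt[1]
    # collinear cloud: no measurable deflection in the second principal direction
    if svals[0] == 0 or svals[1] / svals[0] < 1e-9 or np.ptp(v) < 1e-9:
        return math.inf

    A = np.column_stack([2.0 * u, 2.0 * v, np.ones_like(u)])
    rhs = u * u + v * v
    (uc, vc, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    r2 = c + uc * uc + vc * vc
    if r2 <= 0:
        return math.inf
    radius = math.sqrt(r2)

    # one Gauss-Newton step on the geometric distance
    du, dv = u - uc, v - vc
    rho = np.hypot(du, dv)
    if np.all(rho > 0):
        res = rho - radius
        J = np.column_stack([-du / rho, -dv / rho, -np.ones_like(rho)])
        try:
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
            uc2, vc2, radius2 = uc + step[0], vc + step[1], radius + step[2]
            if radius2 > 0:
                radius = radius2
        except np.linalg.LinAlgError:
            pass

    return radius if radius <= straight_cap else math.inf


def compute_features(slices: list[SliceEllipse], extent: float,
                     straight_cap: float = STRAIGHT_CAP_MM) -> CanalFeatures:
    """Combine per-slice ellipses into the five-parameter description."""
    if len(slices) < 3:
        raise FeatureError("compute_features needs >= 3 slices")
    order = np.argsort([s.station for s in slices])
    slices = [slices[i] for i in order]
    distal = slices[0]
    diameters = np.array([s.diameter for s in slices])
    centroids3d = np.array([[s.centroid[0], s.centroid[1], s.station] for s in slices])
    return CanalFeatures(
        length_mm=float(extent),
        curvature_radius_mm=radius_of_curvature(centroids3d, straight_cap),
        ellipticity_mm=distal.ax_max - distal.ax_min,
        mean_diameter_mm=float(diameters.mean()),
        conicity_mm=float(distal.diameter - diameters.min()),
        n_slices=len(slices),
    )


def canal_features(mesh: TriMesh, spacing: float = DEFAULT_SPACING_MM,
                   straight_cap: float = STRAIGHT_CAP_MM) -> CanalFeatures:
    """Slice a mesh and compute its five geometric parameters in one call."""
    slices = extract_slices(mesh, spacing)
    return compute_features(slices, mesh.extent, straight_cap)
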