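"""The 3D-model tunnel diameter measurements.

Three methods operate on a triangle mesh of the tunnel wall:

* **Best-fit cylinder** (:func:`fit_cylinder`): one analytic cylinder
  minimizing squared orthogonal distance to all wall vertices over the
  entire tunnel length; diameter = 2r.
* **Transverse section** (:func:`fit_centerline` +
  :func:`transverse_section_diameter`): a center axis is fitted through the
  lumen, the mesh is cut by the plane perpendicular to the axis at a chosen
  arc-length station (mid-length by default), and a circle is fitted to the
  cut boundary; diameter = 2r of that circle.
* **Wall thickness** (:func:`wall_thickness`): from each triangle a ray is
  cast along the into-lumen normal to the opposite wall; the mean recorded
  distance is the method's diameter.  On rough (realistically segmented)
  walls the ray directions scatter and chords shorter than the true diameter
  dominate, which biases this method low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .mesh import NormalOrientation, TunnelMesh

__all__ = [
    "Cylinder",
    "Centerline",
    "CrossSection",
    "ThicknessField",
    "CylinderFitError",
    "InvalidGeometryError",
    "fit_cylinder",
    "fit_centerline",
    "transverse_section_diameter",
    "wall_thickness",
]


class InvalidGeometryError(ValueError):
    """Input geometry cannot support the requested measurement."""


class CylinderFitError(RuntimeError):
    """Cylinder fit did not converge; carries the best iterate found."""

    def __init__(self, message: str, best: "Cylinder | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class Cylinder:
    """Analytic cylinder: points at distance ``radius_mm`` from the axis
    line through ``axis_point`` along unit ``axis_direction``; ``extent_mm``
    is the data's [t_min, t_max] range along the axis."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius_mm: float
    extent_mm: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float).reshape(3)
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("degenerate axis direction")
        self.axis_direction = d / n
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not self.extent_mm[0] < self.extent_mm[1]:
            raise ValueError("extent t_min must be < t_max")

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.radius_mm

    def point_distances(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal distances of points to the cylinder surface."""
        rel = np.asarray(points, dtype=float) - self.axis_point
        along = rel @ self.axis_direction
        radial = np.linalg.norm(rel - along[:, None] * self.axis_direction, axis=1)
        return radial - self.radius_mm


@dataclass
class Centerline:
    """Ordered polyline through the tunnel lumen, arc-length parameterized."""

    points: np.ndarray
    arc_length_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centerline needs >= 2 points of dimension 3")
        if self.arc_length_mm is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc_length_mm = np.concatenate([[0.0], np.cumsum(seg)])
        self.arc_length_mm = np.asarray(self.arc_length_mm, dtype=float)
        if np.any(np.diff(self.arc_length_mm) <= 0):
            raise ValueError("arc lengths must be strictly increasing")

    @property
    def length_mm(self) -> float:
        return float(self.arc_length_mm[-1])

    def point_at(self, fraction: float) -> np.ndarray:
        """Point at an arc-length fraction in [0, 1]."""
        s = float(fraction) * self.length_mm
        return np.array([
            np.interp(s, self.arc_length_mm, self.points[:, k]) for k in range(3)
        ])

    def tangent_at(self, fraction: float, window: float = 0.05) -> np.ndarray:
        """Unit tangent at an arc-length fraction (central difference over a
        small arc-length window)."""
        lo = max(0.0, fraction - window)
        hi = min(1.0, fraction + window)
        t = self.point_at(hi) - self.point_at(lo)
        n = np.linalg.norm(t)
        if n < 1e-12:
            raise InvalidGeometryError("degenerate centerline tangent")
        return t / n


@dataclass
class CrossSection:
    """Planar cut of the tunnel wall with a circle fitted to its boundary."""

    plane_point: np.ndarray
    plane_normal: np.ndarray
    boundary_mm: np.ndarray  # (n, 3) closed polyline on the cutting plane
    center_mm: np.ndarray
    radius_mm: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.boundary_mm) < 8:
            raise InvalidGeometryError("cross-section boundary needs >= 8 points")
        if self.radius_mm <= 0:
            raise ValueError("fitted radius must be positive")

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.radius_mm


@dataclass
class ThicknessField:
    """Per-triangle wall thickness with miss bookkeeping.

    ``thickness_mm`` is NaN where the ray escaped through an aperture;
    ``miss_fraction`` reports how often that happened.
    """

    thickness_mm: np.ndarray
    miss_fraction: float
    mean_mm: float
    median_mm: float
    percentiles_mm: dict[int, float]
    area_weighted_mean_mm: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def diameter_mm(self) -> float:
        """Summary diameter: unweighted mean of recorded thicknesses."""
        return self.mean_mm


# ---------------------------------------------------------------------------
# Best-fit cylinder
# ---------------------------------------------------------------------------


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid, principal directions (rows, descending), singular values."""
    centroid = points.mean(axis=0)
    _, svals, vt = np.linalg.svd(points - centroid, full_matrices=False)
    # deterministic sign: largest-magnitude component positive
    for i in range(3):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    return centroid, vt, svals


def fit_cylinder(
    mesh_or_points: TunnelMesh | np.ndarray,
    gtol: float = 1e-10,
    max_iter: int = 200,
    end_trim_mm: float = 0.0,
) -> Cylinder:
    """Orthogonal-distance least-squares cylinder over all wall vertices.

    The residual for a point ``p`` is ``|| (p - c) - ((p - c)·d) d || - r``.
    Initialization: ``d`` = first principal axis, ``c`` = centroid, ``r`` =
    mean radial distance; refined by Levenberg-style least squares to
    gradient tolerance ``gtol`` (default 1e-10) within ``max_iter``
    iterations.

    ``end_trim_mm`` excludes vertices within that distance of the two axial
    extremes (along the initial principal axis) before fitting.  Segmented
    tunnel models are least reliable at the apertures, where partial-volume
    narrowing through the cortical shell would otherwise drag the fitted
    radius down; trimming is a deterministic stand-in for the manual
    aperture cleanup a human analyst performs.  On an ideal cylinder the
    trim is a no-op for the recovered radius.
    """
    pts = mesh_or_points.vertices if isinstance(mesh_or_points, TunnelMesh) else np.asarray(mesh_or_points, float)
    if end_trim_mm > 0 and len(pts):
        c0, axes0, _ = _principal_axes(pts)
        t0_ = (pts - c0) @ axes0[0]
        sel = (t0_ > t0_.min() + end_trim_mm) & (t0_ < t0_.max() - end_trim_mm)
        if sel.sum() >= 50:
            pts = pts[sel]
    if len(pts) < 50:
        raise InvalidGeometryError(f"cylinder fit needs >= 50 vertices, got {len(pts)}")
    centroid, axes, svals = _principal_axes(pts)
    if svals[1] <= 0 or svals[0] / max(svals[1], 1e-30) < 1.2:
        raise InvalidGeometryError(
            "point cloud has no dominant axis (near-spherical); cannot fit a cylinder"
        )
    u0, e1, e2 = axes  # initial axis and a transverse frame

    def unpack(x):
        a, b, c1, c2, r = x
        d = u0 + a * e1 + b * e2
        d = d / np.linalg.norm(d)
        c = centroid + c1 * e1 + c2 * e2
        return c, d, r

    def residuals(x):
        c, d, r = unpack(x)
        rel = pts - c
        along = rel @ d
        radial = np.linalg.norm(rel - along[:, None] * d, axis=1)
        return radial - r

    rel0 = pts - centroid
    along0 = rel0 @ u0
    r0 = float(np.linalg.norm(rel0 - along0[:, None] * u0, axis=1).mean())
    x0 = np.array([0.0, 0.0, 0.0, 0.0, r0])

    sol = least_squares(residuals, x0, method="lm", gtol=gtol, xtol=1e-14, ftol=1e-14,
                        max_nfev=max_iter * 6)
    c, d, r = unpack(sol.x)
    if r <= 0:
        raise InvalidGeometryError("cylinder fit collapsed to non-positive radius")
    rel = pts - c
    along = rel @ d
    cyl = Cylinder(
        axis_point=c,
        axis_direction=d,
        radius_mm=float(r),
        extent_mm=(float(along.min()), float(along.max())),
        diagnostics={
            "diameter_mm": 2.0 * float(r),
            "rms_residual_mm": float(np.sqrt(np.mean(sol.fun**2))),
            "n_points": len(pts),
            "iterations": int(sol.nfev),
            "converged": bool(sol.status > 0),
        },
    )
    if sol.status <= 0:
        raise CylinderFitError(f"cylinder fit did not converge: {sol.message}", best=cyl)
    return cyl


# ---------------------------------------------------------------------------
# Centerline
# ---------------------------------------------------------------------------


def fit_centerline(
    mesh: TunnelMesh,
    n_slabs: int = 20,
    min_vertices_per_slab: int = 10,
    drop_end_slabs: bool = True,
) -> Centerline:
    """Slab-centroid centerline through a tubular mesh.

    Vertices are binned into ``n_slabs`` equal-width slabs along the initial
    principal axis; each well-populated slab contributes its centroid.  For
    tubular meshes with roughly uniform tessellation the centroids track the
    medial axis.

    The two extreme slabs are dropped by default: they cover the tunnel
    apertures, whose slanted rims contribute only part of each ring of
    vertices and so pull the slab centroid off the true axis.
    """
    if n_slabs < 5:
        raise ValueError("n_slabs must be >= 5")
    pts = mesh.vertices
    centroid, axes, _ = _principal_axes(pts)
    t = (pts - centroid) @ axes[0]
    edges = np.linspace(t.min(), t.max(), n_slabs + 1)
    which = np.clip(np.digitize(t, edges) - 1, 0, n_slabs - 1)
    points, order_key = [], []
    first, last = (1, n_slabs - 1) if drop_end_slabs else (0, n_slabs)
    for s in range(first, last):
        sel = which == s
        if sel.sum() < min_vertices_per_slab:
            continue
        points.append(pts[sel].mean(axis=0))
        order_key.append(0.5 * (edges[s] + edges[s + 1]))
    if len(points) < 2:
        raise InvalidGeometryError(
            f"fewer than 2 slabs had >= {min_vertices_per_slab} vertices; mesh too sparse"
        )
    return Centerline(np.asarray(points)[np.argsort(order_key)])


# ---------------------------------------------------------------------------
# Transverse section
# ---------------------------------------------------------------------------


def _kasa_circle(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) circle fit to 2D points."""
    A = np.column_stack([2 * xy[:, 0], 2 * xy[:, 1], np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]
    r2 = sol[2] + center @ center
    if r2 <= 0:
        raise InvalidGeometryError("Kåsa circle fit produced non-positive radius")
    return center, float(np.sqrt(r2))


def fit_circle_2d(xy: np.ndarray, gtol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Geometric circle fit: Kåsa initialization, then minimize
    ``sum((||p - center|| - r)^2)``."""
    xy = np.asarray(xy, dtype=float)
    c0, r0 = _kasa_circle(xy)

    def residuals(x):
        return np.linalg.norm(xy - x[:2], axis=1) - x[2]

    sol = least_squares(residuals, np.array([c0[0], c0[1], r0]), method="lm",
                        gtol=gtol, xtol=1e-14, ftol=1e-14)
    cx, cy, r = sol.x
    if r <= 0:
        raise InvalidGeometryError("circle fit collapsed to non-positive radius")
    return np.array([cx, cy]), float(r)


def _plane_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def _polygon_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def transverse_section_diameter(
    mesh: TunnelMesh,
    centerline: Centerline,
    station: float = 0.5,
) -> CrossSection:
    """Cut the mesh perpendicular to the centerline at an arc-length station
    (0.5 = the tunnel's mid-length) and fit a circle to the cut boundary.

    The boundary loop containing the centerline point is retained; with
    nested loops the innermost is used (with a warning).  A cut through an
    aperture yields no closed loop and raises, suggesting another station.
    """
    if not 0.0 < station < 1.0:
        raise ValueError("station must be strictly inside (0, 1)")
    point = centerline.point_at(station)
    normal = centerline.tangent_at(station)

    section = mesh.to_trimesh().section(plane_origin=point, plane_normal=normal)
    if section is None:
        raise InvalidGeometryError("cutting plane does not intersect the mesh")
    polylines = [np.asarray(d) for d in section.discrete]
    closed = [p for p in polylines if len(p) >= 8 and np.allclose(p[0], p[-1], atol=1e-8)]
    if not closed:
        raise InvalidGeometryError(
            f"open intersection at station {station} (plane passes through an aperture); "
            "try a different station"
        )

    from shapely.geometry import Point as ShPoint, Polygon

    e1, e2 = _plane_frame(normal)
    loops2d = [np.column_stack([(p - point) @ e1, (p - point) @ e2]) for p in closed]
    containing = []
    for i, loop in enumerate(loops2d):
        try:
            if Polygon(loop).contains(ShPoint(0.0, 0.0)):
                containing.append(i)
        except Exception:
            continue
    if containing:
        if len(containing) > 1:
            warnings.warn("nested cross-section loops; keeping the innermost", stacklevel=2)
        idx = min(containing, key=lambda i: _polygon_area(loops2d[i]))
    else:
        # centerline point barely outside every loop (rough walls); take the
        # loop whose centroid is nearest to it
        warnings.warn("no loop contains the centerline point; using the nearest loop", stacklevel=2)
        idx = min(range(len(loops2d)), key=lambda i: float(np.linalg.norm(loops2d[i].mean(axis=0))))

    boundary3d = closed[idx][:-1]  # drop duplicated closing point
    xy = loops2d[idx][:-1]
    center2d, radius = fit_circle_2d(xy)
    center3d = point + center2d[0] * e1 + center2d[1] * e2
    return CrossSection(
        plane_point=point,
        plane_normal=normal,
        boundary_mm=boundary3d,
        center_mm=center3d,
        radius_mm=radius,
        diagnostics={
            "diameter_mm": 2.0 * radius,
            "station": station,
            "n_boundary_points": len(xy),
            "n_loops": len(closed),
        },
    )


# ---------------------------------------------------------------------------
# Wall thickness
# ---------------------------------------------------------------------------


def _ray_mesh_distances(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    tri_centroids: np.ndarray,
    exclusion_radius_mm: float,
    chunk: int = 128,
) -> np.ndarray:
    """Distance from each ray origin to the first triangle hit whose centroid
    lies farther than the exclusion radius from the origin; inf = miss.
    Vectorized Möller-Trumbore over ray chunks."""
    v0 = triangles[:, 0]
    edge1 = triangles[:, 1] - v0
    edge2 = triangles[:, 2] - v0
    eps = 1e-9
    out = np.full(len(origins), np.inf)
    for start in range(0, len(origins), chunk):
        O = origins[start:start + chunk][:, None, :]       # (r,1,3)
        D = directions[start:start + chunk][:, None, :]
        h = np.cross(D, edge2[None, :, :])                  # (r,T,3)
        a = np.einsum("tk,rtk->rt", edge1, h)
        s = O - v0[None, :, :]
        q = np.cross(s, edge1[None, :, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_a = 1.0 / a
            u = np.einsum("rtk,rtk->rt", s, h) * inv_a
            v = np.einsum("rtk,rtk->rt", D, q) * inv_a
            t = np.einsum("tk,rtk->rt", edge2, q) * inv_a
            valid = (np.abs(a) > eps) & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-6)
        # exclude nearby triangles (self and immediate neighbours)
        d2 = ((tri_centroids[None, :, :] - O) ** 2).sum(axis=2)
        valid &= d2 > exclusion_radius_mm**2
        t = np.where(valid, t, np.inf)
        out[start:start + chunk] = t.min(axis=1)
    return out


def wall_thickness(
    mesh: TunnelMesh,
    exclusion_radius_mm: float = 1.0,
    from_vertices: bool = False,
    percentiles: tuple[int, ...] = (5, 25, 75, 95),
) -> ThicknessField:
    """Perpendicular distance from each wall triangle across the lumen to
    the opposite wall.

    A ray starts at each triangle centroid (or each vertex with
    ``from_vertices=True``) along the into-lumen normal; the first hit on a
    triangle whose centroid is farther than ``exclusion_radius_mm`` (to skip
    the source's own neighbourhood) is recorded.  Rays escaping through an
    aperture count as misses and are excluded from the summary mean.
    """
    if mesh.normal_orientation != NormalOrientation.INTO_LUMEN:
        raise ValueError(
            "wall_thickness requires into-lumen normals; call mesh.oriented('into_lumen') first"
        )
    triangles = mesh.vertices[mesh.faces]
    tri_centroids = triangles.mean(axis=1)
    if from_vertices:
        origins = mesh.vertices
        directions = mesh.vertex_normals()
    else:
        origins = tri_centroids
        directions = mesh.face_normals()

    dist = _ray_mesh_distances(origins, directions, triangles, tri_centroids, exclusion_radius_mm)
    hit = np.isfinite(dist)
    if not hit.any():
        raise InvalidGeometryError("wall-thickness ray casting recorded zero hits")
    thick = np.where(hit, dist, np.nan)
    miss_fraction = float(1.0 - hit.mean())
    recorded = dist[hit]
    if miss_fraction > 0.5:
        warnings.warn(f"{miss_fraction:.0%} of wall-thickness rays escaped through apertures",
                      stacklevel=2)
    if from_vertices:
        aw_mean = float(recorded.mean())  # area weights undefined for vertex rays
    else:
        areas = mesh.face_areas()[hit]
        aw_mean = float(np.average(recorded, weights=areas)) if areas.sum() > 0 else float(recorded.mean())
    return ThicknessField(
        thickness_mm=thick,
        miss_fraction=miss_fraction,
        mean_mm=float(recorded.mean()),
        median_mm=float(np.median(recorded)),
        percentiles_mm={p: float(np.percentile(recorded, p)) for p in percentiles},
        area_weighted_mean_mm=aw_mean,
        diagnostics={"n_rays": len(origins), "n_hits": int(hit.sum()),
                     "exclusion_radius_mm": exclusion_radius_mm,
                     "from_vertices": from_vertices},
    )
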