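"""The clinical 2D CT measurement and the combined four-method driver.

The 2D method emulates what a clinician does on the scanner console: at the
tunnel's mid-point, a straight-line diameter is read off in each of the
three canonical image planes (axial, coronal, sagittal) and the three values
are averaged.  Because an oblique tunnel cuts each plane in an elongated
section, the line a clinician draws "across" the tunnel is modeled as the
region's minimum Feret width (the minor caliper diameter); sub-pixel
accuracy comes from contour extraction at the 0.5 level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as skmeasure

from .geometry import (
    InvalidGeometryError,
    fit_centerline,
    fit_cylinder,
    transverse_section_diameter,
    wall_thickness,
)
from .mesh import TunnelMesh
from .phantom import GroundTruth
from .volume import BinaryMask

__all__ = [
    "Method",
    "MeasurementRecord",
    "min_feret_width",
    "max_feret_width",
    "ct2d_diameter",
    "measure_all",
]

_PLANE_NAMES = ("axial", "coronal", "sagittal")


class Method(str, Enum):
    CYLINDER_FIT = "cylinder_fit"
    TRANSVERSE_SECTION = "transverse_section"
    WALL_THICKNESS = "wall_thickness"
    CT2D = "ct2d"


@dataclass
class MeasurementRecord:
    """One tunnel, one method, one diameter (or a recorded failure)."""

    tunnel_id: str
    method: Method
    diameter_mm: float | None
    error_mm: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.method, str):
            self.method = Method(self.method)
        if self.diameter_mm is not None and self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive when present")

    @property
    def ok(self) -> bool:
        return self.diameter_mm is not None


# ---------------------------------------------------------------------------
# Feret widths (caliper diameters) of a 2D point set
# ---------------------------------------------------------------------------


def min_feret_width(points_2d: np.ndarray) -> float:
    """Minimum caliper width: the smallest gap between two parallel lines
    enclosing the points.  Rotating-calipers over the convex hull (the
    minimum is attained with one line flush with a hull edge)."""
    pts = np.asarray(points_2d, dtype=float)
    if len(pts) < 3:
        return 0.0
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:  # collinear points
        c = pts.mean(axis=0)
        _, s, _ = np.linalg.svd(pts - c, full_matrices=False)
        return float(2 * s[-1] / np.sqrt(len(pts)))
    best = np.inf
    n_h = len(hull)
    for i in range(n_h):
        edge = hull[(i + 1) % n_h] - hull[i]
        norm = np.linalg.norm(edge)
        if norm < 1e-12:
            continue
        nvec = np.array([-edge[1], edge[0]]) / norm
        width = np.abs((hull - hull[i]) @ nvec).max()
        best = min(best, width)
    return float(best)


def max_feret_width(points_2d: np.ndarray) -> float:
    """Maximum caliper width (longest point-to-point distance)."""
    pts = np.asarray(points_2d, dtype=float)
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:
        hull = pts
    d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def _plane_slice(mask: np.ndarray, plane: str, idx: tuple[int, int, int]):
    """2D slice through the midpoint for one canonical plane, plus the
    midpoint's in-slice pixel coordinates and the two in-plane axis ids."""
    ix, iy, iz = idx
    if plane == "axial":  # z fixed
        return mask[:, :, iz], (ix, iy), (0, 1)
    if plane == "coronal":  # y fixed
        return mask[:, iy, :], (ix, iz), (0, 2)
    if plane == "sagittal":  # x fixed
        return mask[ix, :, :], (iy, iz), (1, 2)
    raise ValueError(plane)


def _component_width(
    slice2d: np.ndarray,
    pixel: tuple[int, int],
    spacings: np.ndarray,
    mode: str,
    smooth_sigma_px: float = 1.0,
) -> tuple[float, dict]:
    """Sub-pixel width (mm) of the in-slice component containing `pixel`.

    The binary slice is lightly Gaussian-smoothed before the 0.5-level
    contour is traced: caliper widths are set by the outermost contour
    points, and on a raw binary grid the staircase corners stick out by up
    to half a pixel, biasing Feret widths high.
    """
    labels, _ = ndimage.label(slice2d, structure=np.ones((3, 3), dtype=bool))
    lab = labels[pixel]
    if lab == 0:
        raise InvalidGeometryError("tunnel mid-point lies outside the mask in this plane")
    comp = labels == lab
    touches_edge = bool(comp[0].any() or comp[-1].any() or comp[:, 0].any() or comp[:, -1].any())
    if touches_edge:
        warnings.warn("in-slice tunnel component touches the slice edge", stacklevel=3)
    pad = 3
    field = np.pad(comp.astype(float), pad)
    if smooth_sigma_px > 0:
        smoothed = ndimage.gaussian_filter(field, sigma=smooth_sigma_px)
        if smoothed.max() > 0.5:
            field = smoothed
    contours = skmeasure.find_contours(field, 0.5)
    if not contours:
        raise InvalidGeometryError("no contour found for in-slice component")
    contour = max(contours, key=len) - float(pad)  # undo padding offset
    pts_mm = contour * spacings[None, :]
    width = min_feret_width(pts_mm) if mode == "min_feret" else max_feret_width(pts_mm)
    if width <= 0:
        raise InvalidGeometryError("degenerate in-slice component (zero width)")
    return width, {"n_contour_points": len(contour), "touches_edge": touches_edge,
                   "component_pixels": int(comp.sum())}


def ct2d_diameter(
    tunnel_mask: BinaryMask,
    midpoint_mm,
    tunnel_id: str = "tunnel",
    width_mode: str = "min_feret",
) -> MeasurementRecord:
    """Clinical 2D CT measurement: per-plane width at the tunnel mid-point,
    averaged over the axial, coronal and sagittal planes.

    ``width_mode`` selects the in-slice width definition: ``"min_feret"``
    (default; the minor caliper width a straight-line measurement across an
    oblique tunnel approximates) or ``"max_feret"`` for sensitivity analysis.
    """
    if width_mode not in ("min_feret", "max_feret"):
        raise ValueError(f"unknown width_mode {width_mode!r}")
    idx = tunnel_mask.world_to_voxel(midpoint_mm)
    if not tunnel_mask.voxels[idx]:
        raise InvalidGeometryError(
            f"midpoint {np.asarray(midpoint_mm)} (voxel {idx}) is outside the tunnel mask"
        )
    widths: dict[str, float] = {}
    diag: dict = {"width_mode": width_mode, "midpoint_voxel": list(idx)}
    for plane in _PLANE_NAMES:
        slice2d, pixel, axes = _plane_slice(tunnel_mask.voxels, plane, idx)
        spacings = tunnel_mask.spacing_mm[list(axes)]
        w, info = _component_width(slice2d, pixel, spacings, width_mode)
        widths[plane] = w
        diag[plane] = {"width_mm": w, **info}
    mean_width = float(np.mean(list(widths.values())))
    diag["per_plane_mm"] = widths
    return MeasurementRecord(tunnel_id, Method.CT2D, mean_width, diagnostics=diag)


# ---------------------------------------------------------------------------
# All four methods on one tunnel
# ---------------------------------------------------------------------------


def measure_all(
    mesh: TunnelMesh,
    mask: BinaryMask | None = None,
    truth: GroundTruth | None = None,
    tunnel_id: str | None = None,
    station: float = 0.5,
    exclusion_radius_mm: float = 1.0,
    n_slabs: int = 20,
    width_mode: str = "min_feret",
    cylinder_end_trim_mm: float = 4.0,
) -> list[MeasurementRecord]:
    """Run every applicable method on one tunnel; failures become per-record
    entries (``diameter_mm=None`` with the error message) and never abort
    the remaining methods.  With ``truth`` given, each record carries the
    signed error (measured − truth).

    ``cylinder_end_trim_mm`` (default 4.0) excludes the aperture rim from
    the cylinder fit, where segmented models are unreliable; see
    :func:`tunnelmetrics.geometry.fit_cylinder`."""
    tid = tunnel_id or (truth.tunnel_id if truth is not None else "tunnel")
    records: list[MeasurementRecord] = []

    def _attach(method: Method, fn):
        try:
            diameter, diag = fn()
            err = None if truth is None else float(diameter - truth.true_diameter_mm)
            records.append(MeasurementRecord(tid, method, float(diameter), err, diag))
        except Exception as exc:
            records.append(MeasurementRecord(tid, method, None,
                                             diagnostics={"error": f"{type(exc).__name__}: {exc}"}))

    def _cyl():
        cyl = fit_cylinder(mesh, end_trim_mm=cylinder_end_trim_mm)
        return cyl.diameter_mm, dict(cyl.diagnostics)

    def _section():
        centerline = fit_centerline(mesh, n_slabs=n_slabs)
        xs = transverse_section_diameter(mesh, centerline, station=station)
        return xs.diameter_mm, dict(xs.diagnostics)

    def _thickness():
        tf = wall_thickness(mesh.oriented("into_lumen"), exclusion_radius_mm=exclusion_radius_mm)
        d = dict(tf.diagnostics)
        d.update({"miss_fraction": tf.miss_fraction, "median_mm": tf.median_mm})
        return tf.diameter_mm, d

    _attach(Method.CYLINDER_FIT, _cyl)
    _attach(Method.TRANSVERSE_SECTION, _section)
    _attach(Method.WALL_THICKNESS, _thickness)

    if mask is not None:
        def _ct2d():
            centerline = fit_centerline(mesh, n_slabs=n_slabs)
            rec = ct2d_diameter(mask, centerline.point_at(station), tid, width_mode)
            return rec.diameter_mm, dict(rec.diagnostics)

        _attach(Method.CT2D, _ct2d)
    return records


def records_to_frame(records: list[MeasurementRecord]):
    """Flatten records into a tidy DataFrame (diagnostics JSON-encoded)."""
    import json

    import pandas as pd

    rows = []
    for r in records:
        rows.append({
            "tunnel_id": r.tunnel_id,
            "method": r.method.value,
            "diameter_mm": r.diameter_mm,
            "error_mm": r.error_mm,
            "diagnostics_json": json.dumps(r.diagnostics, default=_json_default, sort_keys=True),
        })
    frame = pd.DataFrame(rows)
    for col in ("diameter_mm", "error_mm"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return frame


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
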