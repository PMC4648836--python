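"""CT volume -> bone mask -> tunnel cavity -> wall mesh.

Bone is segmented by a density window (the clinical workflow: "adjust a
density range to highlight bone").  The drilled tunnel then appears as a
cavity in the bone mask; it is recovered by morphological closing with a
ball larger than the tunnel radius, subtracting the bone, and keeping the
connected component around a user-supplied seed point.  The cavity wall is
surfaced by marching cubes with vertices in world millimetres.

Morphological radii are specified in millimetres and converted per-axis to
voxels via Euclidean distance transforms, so anisotropic slice spacing does
not bias the morphology.  Connected components use 26-connectivity.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage import measure

from .mesh import NormalOrientation, TunnelMesh
from .volume import BinaryMask, CTVolume

__all__ = [
    "threshold_segment",
    "extract_tunnel_cavity",
    "mask_to_mesh",
    "NoCavityError",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class NoCavityError(ValueError):
    """Raised when no tunnel cavity exists at the requested seed point."""


def threshold_segment(volume: CTVolume, low: float, high: float = np.inf) -> BinaryMask:
    """Mask of voxels with density in ``[low, high]``.  No morphology.

    An empty result is allowed (a warning is emitted); the caller decides
    whether that is an error.
    """
    if not low < high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    sel = (volume.voxels >= low) & (volume.voxels <= high)
    if not sel.any():
        warnings.warn(f"threshold [{low}, {high}] selected no voxels", stacklevel=2)
    return BinaryMask(sel, volume.spacing_mm.copy(), volume.origin_mm.copy())


def _dilate_mm(mask: np.ndarray, radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= radius_mm


def _erode_mm(mask: np.ndarray, radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    return dist > radius_mm


def close_mm(mask: np.ndarray, radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Morphological closing with a Euclidean ball of ``radius_mm``,
    computed via distance transforms (exact in mm, anisotropy-aware).

    The array is padded by the ball radius first so the dilation never
    saturates at the array boundary (which would leave an un-eroded crust).
    """
    pad = tuple(int(np.ceil(radius_mm / s)) + 2 for s in spacing)
    padded = np.pad(mask, [(p, p) for p in pad], constant_values=False)
    closed = _erode_mm(_dilate_mm(padded, radius_mm, spacing), radius_mm, spacing)
    sl = tuple(slice(p, dim - p) for p, dim in zip(pad, closed.shape))
    return closed[sl]


def extract_tunnel_cavity(
    bone_mask: BinaryMask,
    closing_radius_mm: float,
    seed_point_mm,
) -> BinaryMask:
    """Isolate the tunnel cavity containing ``seed_point_mm``.

    The bone mask is closed with a ball whose radius must exceed the
    expected tunnel radius (so the closing bridges the tunnel); the closed
    mask minus the bone is candidate cavity; the 26-connected component
    containing the seed point is returned.

    Raises :class:`NoCavityError` when the seed lands outside any cavity.
    """
    if closing_radius_mm <= 0:
        raise ValueError("closing_radius_mm must be positive")
    spacing = bone_mask.spacing_mm
    closed = close_mm(bone_mask.voxels, closing_radius_mm, spacing)
    cavity = closed & ~bone_mask.voxels
    labels, _ = ndimage.label(cavity, structure=_CONN26)
    seed_idx = bone_mask.world_to_voxel(seed_point_mm)
    lab = labels[seed_idx]
    if lab == 0:
        raise NoCavityError(
            f"no cavity at seed point {np.asarray(seed_point_mm)} (voxel {seed_idx}); "
            "check the seed location and that closing_radius_mm exceeds the tunnel radius"
        )
    return BinaryMask(labels == lab, spacing.copy(), bone_mask.origin_mm.copy())


def mask_to_mesh(
    mask: BinaryMask,
    iso_level: float = 0.5,
    smooth_sigma_voxels: float = 0.5,
    orientation: NormalOrientation = NormalOrientation.INTO_LUMEN,
) -> TunnelMesh:
    """Surface a binary mask by marching cubes at ``iso_level``.

    By default the boolean field is Gaussian-smoothed (sigma in voxels)
    before iso-surfacing, which places vertices at sub-voxel positions and
    removes staircase artifacts; pass ``smooth_sigma_voxels=0`` for raw-mask
    surfacing.  The default sigma of 0.5 voxel is deliberately small:
    smoothing moves a curved 0.5-level set inward by roughly sigma^2/(2R)
    (curvature flow), so a large sigma systematically shrinks small tunnels.

    Vertices are returned in world mm; normals are normalized to the
    requested orientation (``into_lumen`` for cavity meshes).
    """
    vox = mask.voxels
    if not vox.any():
        raise ValueError("cannot mesh an empty mask")
    field = vox.astype(np.float32)
    if smooth_sigma_voxels > 0:
        field = ndimage.gaussian_filter(field, sigma=smooth_sigma_voxels)
        # smoothing can pull the field below the iso level everywhere for
        # very thin masks; fall back to the raw field in that case
        if field.max() <= iso_level:
            field = vox.astype(np.float32)

    touches_boundary = bool(
        vox[0].any() or vox[-1].any() or vox[:, 0].any() or vox[:, -1].any()
        or vox[:, :, 0].any() or vox[:, :, -1].any()
    )
    if touches_boundary:
        warnings.warn("mask touches the array boundary; mesh will have open apertures", stacklevel=2)

    verts_idx, faces, normals, _ = measure.marching_cubes(field, level=iso_level)
    verts_mm = mask.origin_mm + verts_idx * mask.spacing_mm

    # Orient normals by majority vote: a short step along the face normal
    # should leave the mask (mask=1 is the cavity; into-lumen normals point
    # toward higher field values).
    mesh = TunnelMesh(verts_mm, faces, NormalOrientation.INTO_LUMEN, has_apertures=touches_boundary)
    centroids_idx = (verts_idx[faces].mean(axis=1))
    fn = mesh.face_normals() / mask.spacing_mm  # to index space, then renormalize
    fn /= np.linalg.norm(fn, axis=1, keepdims=True)
    probe = centroids_idx + 0.75 * fn
    vals = ndimage.map_coordinates(field, probe.T, order=1, mode="nearest")
    base = ndimage.map_coordinates(field, centroids_idx.T, order=1, mode="nearest")
    into_lumen_votes = (vals > base).mean()
    currently_into = into_lumen_votes >= 0.5
    if currently_into:
        mesh.normal_orientation = NormalOrientation.INTO_LUMEN
    else:
        mesh.normal_orientation = NormalOrientation.OUT_OF_LUMEN
    return mesh.oriented(orientation)
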