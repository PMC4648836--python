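"""CT volume and binary mask containers with physical-coordinate bookkeeping.

Axis convention used throughout the package: voxel arrays are indexed
``(x, y, z)`` with 0-based indices, and world coordinates (mm) are

    world = origin + index * spacing

i.e. voxel ``(0, 0, 0)`` has its *center* at ``origin``.  All readers and
writers normalize to this convention so that downstream geometry never has
to guess about axial/sagittal flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CTVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "write_mask",
]


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.size != 3:
        raise ValueError(f"{name} must have 3 components, got {a.size}")
    return a


@dataclass
class _Grid:
    """Shared spatial bookkeeping for voxel grids."""

    voxels: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_world(self, index) -> np.ndarray:
        """Voxel index (may be fractional) -> world mm."""
        return self.origin_mm + np.asarray(index, dtype=float) * self.spacing_mm

    def world_to_index(self, world_mm) -> np.ndarray:
        """World mm -> fractional voxel index."""
        return (np.asarray(world_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def world_to_voxel(self, world_mm) -> tuple[int, int, int]:
        """World mm -> nearest integer voxel index (clipped to the grid)."""
        idx = np.rint(self.world_to_index(world_mm)).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)


@dataclass
class CTVolume(_Grid):
    """A CT scan (or synthetic phantom) as a density grid in HU-like units."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if min(self.shape) < 8:
            raise ValueError(f"volume needs >= 8 voxels per axis, got shape {self.shape}")
        self.voxels = self.voxels.astype(np.float32, copy=False)


@dataclass
class BinaryMask(_Grid):
    """Boolean voxel mask sharing the grid of its source volume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.voxels = self.voxels.astype(bool, copy=False)

    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


# ---------------------------------------------------------------------------
# I/O.  NIfTI goes through nibabel; NRRD and DICOM series through SimpleITK.
# Both are normalized to the (x, y, z) voxel order documented above.
# ---------------------------------------------------------------------------


def _from_nifti(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    origin = affine[:3, 3].copy()
    # nibabel data is already (x, y, z) for plain 3D images
    return np.asarray(data), spacing, origin


def _from_sitk(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    return data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from NIfTI (.nii/.nii.gz) or NRRD (.nrrd/.nhdr).

    Raises a ``FileNotFoundError``/``ValueError`` naming the file on failure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            data, spacing, origin = _from_nifti(path)
        elif name.endswith((".nrrd", ".nhdr")):
            data, spacing, origin = _from_sitk(path)
        else:
            raise ValueError(f"unrecognized volume format: {path} (expected NIfTI or NRRD)")
    except Exception as exc:  # re-raise with filename context
        raise ValueError(f"could not read volume {path}: {exc}") from exc
    return CTVolume(data.astype(np.float32), spacing, origin)


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Read a DICOM series from a directory (optional convenience reader)."""
    import SimpleITK as sitk

    directory = Path(directory)
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return CTVolume(data.astype(np.float32), np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()))


def _nifti_affine(grid: _Grid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing_mm)
    affine[:3, 3] = grid.origin_mm
    return affine


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI with spacing/origin in the affine."""
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _nifti_affine(volume))
    nib.save(img, str(path))
    return path


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask as NIfTI (uint8)."""
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _nifti_affine(mask))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.voxels > 0.5, vol.spacing_mm, vol.origin_mm)
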