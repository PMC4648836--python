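"""Triangle-mesh container for tunnel cavity walls.

A :class:`TunnelMesh` is a triangulated surface of the drilled tunnel's wall
in world millimetre coordinates.  Meshes may be open at the tunnel apertures
(the openings at the bone surface); ``normal_orientation`` records whether
face normals point into the tunnel lumen or outward into bone.  Wall
thickness measurement requires ``into_lumen`` normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import trimesh


class NormalOrientation(str, Enum):
    INTO_LUMEN = "into_lumen"
    OUT_OF_LUMEN = "out_of_lumen"


@dataclass
class TunnelMesh:
    """Closed or aperture-open triangle mesh of a tunnel wall (mm units).

    Parameters
    ----------
    vertices : (n, 3) float array, world mm.
    faces : (m, 3) int array of 0-based vertex indices, consistently wound.
    normal_orientation : whether face normals point into the lumen (toward
        the tunnel axis) or outward.
    has_apertures : True when the surface is open at the tunnel end(s).
    """

    vertices: np.ndarray
    faces: np.ndarray
    normal_orientation: NormalOrientation = NormalOrientation.INTO_LUMEN
    has_apertures: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if isinstance(self.normal_orientation, str):
            self.normal_orientation = NormalOrientation(self.normal_orientation)

    # -- derived geometry ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        """Unit face normals following the winding order."""
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted unit vertex normals (same orientation as faces)."""
        tm = self.to_trimesh(process=False)
        vn = np.array(tm.vertex_normals, dtype=float)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def oriented(self, orientation: NormalOrientation) -> "TunnelMesh":
        """Return a copy with the requested normal orientation (flips winding
        if needed)."""
        orientation = NormalOrientation(orientation)
        if orientation == self.normal_orientation:
            return self
        return TunnelMesh(
            self.vertices.copy(),
            self.faces[:, ::-1].copy(),
            orientation,
            self.has_apertures,
            dict(self.metadata),
        )

    def transformed(self, rotation: np.ndarray | None = None, translation=None) -> "TunnelMesh":
        """Rigidly transform (rotate then translate) the mesh."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TunnelMesh(v, self.faces.copy(), self.normal_orientation, self.has_apertures, dict(self.metadata))

    # -- interop / I/O ------------------------------------------------------

    def to_trimesh(self, process: bool = False) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=process)

    @classmethod
    def from_trimesh(
        cls,
        tm: trimesh.Trimesh,
        normal_orientation: NormalOrientation = NormalOrientation.INTO_LUMEN,
        has_apertures: bool | None = None,
    ) -> "TunnelMesh":
        if has_apertures is None:
            has_apertures = not tm.is_watertight
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), normal_orientation, has_apertures)

    def save(self, path: str | Path) -> Path:
        """Write as STL (binary) or PLY, by extension."""
        path = Path(path)
        self.to_trimesh().export(str(path))
        return path

    @classmethod
    def load(
        cls,
        path: str | Path,
        normal_orientation: NormalOrientation = NormalOrientation.INTO_LUMEN,
    ) -> "TunnelMesh":
        """Read an STL/PLY mesh.  The file format does not record which way
        normals face relative to the lumen, so the caller declares it."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"mesh file not found: {path}")
        tm = trimesh.load_mesh(str(path), process=False)
        return cls.from_trimesh(tm, normal_orientation)
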