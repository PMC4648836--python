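"""Synthetic ground-truth geometry and CT phantoms for drilled bone tunnels.

Patient scans from tunnel-widening studies are not public, so every
measurement method in this package is validated on phantoms whose tunnel
diameter is known exactly — mirroring the clinical situation where the drill
(reamer) size serves as the ground-truth diameter immediately after surgery.

Two kinds of ground truth are produced:

* **Analytic meshes** (:func:`make_cylinder_mesh`, :func:`make_frustum_mesh`)
  whose vertices lie exactly on the ideal surface; optionally roughened by
  :func:`perturb_mesh` to emulate segmentation noise.
* **Voxel phantoms** (:func:`make_phantom_volume`): a two-density bone block
  (cancellous interior + cortical shell) pierced by a cylindrical tunnel,
  voxelized at CT-like anisotropic spacing with partial-volume blur and
  additive noise.

All randomness flows through explicit seeds; no global random state is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .mesh import NormalOrientation, TunnelMesh
from .volume import CTVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "DIAMETER_GRID_MM",
    "tilted_axis",
    "make_cylinder_mesh",
    "make_frustum_mesh",
    "make_plates_mesh",
    "perturb_mesh",
    "make_phantom_volume",
    "make_cohort",
]

#: Drill diameters available on a 0.5 mm graft-ruler scale, 5.0-9.0 mm —
#: the clinically used range for hamstring ACL grafts.
DIAMETER_GRID_MM: tuple[float, ...] = tuple(np.arange(5.0, 9.01, 0.5).round(1))

#: In-plane spacing of a 500 mm field of view on a 512x512 matrix, and a
#: 0.75 mm slice increment — the acquisition geometry the phantoms emulate.
DEFAULT_SPACING_MM: tuple[float, float, float] = (500.0 / 512.0, 500.0 / 512.0, 0.75)


def tilted_axis(polar_deg: float, azimuth_deg: float = 0.0) -> np.ndarray:
    """Unit vector tilted ``polar_deg`` from the scan (z) axis."""
    th = np.deg2rad(polar_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _unit(v, name: str = "axis") -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"degenerate {name}: zero vector")
    return v / n


def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing a right-handed frame with `direction`."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


@dataclass
class PhantomSpec:
    """Parameters of one voxel phantom: a bone block pierced by a tunnel.

    Densities are HU-like but uncalibrated: any three well-separated levels
    suffice because segmentation is threshold-based.  ``blur_sigma_voxels``
    models partial-volume averaging; ``noise_sd`` is additive Gaussian noise
    in density units.
    """

    drill_diameter_mm: float = 6.0
    tunnel_axis: np.ndarray = field(default_factory=lambda: tilted_axis(30.0))
    tunnel_length_mm: float = 30.0
    bone_extent_mm: np.ndarray = field(default_factory=lambda: np.array([40.0, 40.0, 22.0]))
    cortical_density: float = 1200.0
    cancellous_density: float = 300.0
    background_density: float = 0.0
    voxel_spacing_mm: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_SPACING_MM))
    blur_sigma_voxels: float = 0.6
    noise_sd: float = 20.0
    seed: int = 0
    cortical_thickness_mm: float = 3.0
    margin_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.drill_diameter_mm <= 0:
            raise ValueError("drill_diameter_mm must be positive")
        if self.tunnel_length_mm <= 0:
            raise ValueError("tunnel_length_mm must be positive")
        if self.blur_sigma_voxels < 0 or self.noise_sd < 0:
            raise ValueError("blur and noise must be non-negative")
        self.tunnel_axis = _unit(self.tunnel_axis, "tunnel_axis")
        self.bone_extent_mm = np.asarray(self.bone_extent_mm, dtype=float).reshape(3)
        self.voxel_spacing_mm = np.asarray(self.voxel_spacing_mm, dtype=float).reshape(3)
        if np.any(self.voxel_spacing_mm <= 0) or np.any(self.bone_extent_mm <= 0):
            raise ValueError("spacing and bone extent must be positive")
        self._check_tunnel_inside()

    def _check_tunnel_inside(self) -> None:
        """The tunnel wall must stay inside the block laterally.

        The tunnel passes through the block center; its ends may pierce the
        block faces (real tunnels are open at the bone surface).
        """
        r = self.drill_diameter_mm / 2.0
        half = self.bone_extent_mm / 2.0
        t = np.linspace(-self.tunnel_length_mm / 2, self.tunnel_length_mm / 2, 64)
        pts = t[:, None] * self.tunnel_axis[None, :]
        inside_slab = np.abs(pts[:, 2]) <= half[2]
        if np.any(np.abs(pts[inside_slab, :2]) + r > half[:2]):
            raise ValueError(
                "tunnel not fully inside bone: wall exits the block laterally "
                f"(diameter {self.drill_diameter_mm} mm, axis {self.tunnel_axis})"
            )


@dataclass
class GroundTruth:
    """Known tunnel geometry serialized alongside every generated phantom."""

    tunnel_id: str
    true_diameter_mm: float
    axis_point_mm: np.ndarray
    axis_direction: np.ndarray
    length_mm: float
    profile: str = "cylinder"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_diameter_mm <= 0:
            raise ValueError("true_diameter_mm must be positive")
        self.axis_point_mm = np.asarray(self.axis_point_mm, dtype=float).reshape(3)
        self.axis_direction = _unit(self.axis_direction, "axis_direction")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["axis_point_mm"] = list(self.axis_point_mm)
        d["axis_direction"] = list(self.axis_direction)
        path.write_text(json.dumps(d, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


# ---------------------------------------------------------------------------
# Analytic meshes
# ---------------------------------------------------------------------------


def _tube_mesh(
    radii: np.ndarray,
    length_mm: float,
    axis_direction,
    axis_point,
    n_circumferential: int,
    capped: bool,
    orientation: NormalOrientation,
) -> TunnelMesh:
    """Triangulated tube with per-ring radii; rings from the entry end
    (arc-length fraction 0) to the exit end (fraction 1)."""
    d = _unit(axis_direction)
    p0 = np.asarray(axis_point, dtype=float).reshape(3)
    e1, e2 = _frame(d)
    n_axial = len(radii)
    nc = n_circumferential

    theta = 2 * np.pi * np.arange(nc) / nc
    circ = np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2  # (nc, 3)
    t = np.linspace(0.0, length_mm, n_axial)
    verts = (p0[None, None, :] + t[:, None, None] * d[None, None, :]
             + radii[:, None, None] * circ[None, :, :]).reshape(-1, 3)

    faces = []
    for i in range(n_axial - 1):
        for j in range(nc):
            a = i * nc + j
            b = i * nc + (j + 1) % nc
            c = (i + 1) * nc + (j + 1) % nc
            dd = (i + 1) * nc + j
            faces.append((a, b, c))
            faces.append((a, c, dd))
    verts_list = [verts]
    if capped:
        base = len(verts)
        verts_list.append(p0[None, :])
        verts_list.append((p0 + length_mm * d)[None, :])
        for j in range(nc):
            faces.append((base, (j + 1) % nc, j))
            top = (n_axial - 1) * nc
            faces.append((base + 1, top + j, top + (j + 1) % nc))
    mesh = TunnelMesh(
        np.concatenate(verts_list, axis=0),
        np.asarray(faces),
        NormalOrientation.OUT_OF_LUMEN,  # provisional; fixed below
        has_apertures=not capped,
    )
    # Make winding consistent with the requested orientation: test one side
    # face's normal against the local radial direction.
    centroid0 = mesh.vertices[mesh.faces[0]].mean(axis=0)
    rel = centroid0 - p0
    radial = rel - (rel @ d) * d
    outward = mesh.face_normals()[0] @ radial > 0
    want_outward = orientation == NormalOrientation.OUT_OF_LUMEN
    if outward != want_outward:
        mesh = TunnelMesh(mesh.vertices, mesh.faces[:, ::-1], orientation, mesh.has_apertures)
    else:
        mesh.normal_orientation = orientation
    mesh.metadata.update({"axis_point": p0, "axis_direction": d, "length_mm": length_mm})
    return mesh


def make_cylinder_mesh(
    radius_mm: float,
    length_mm: float = 30.0,
    axis_direction=(0.0, 0.0, 1.0),
    axis_point=(0.0, 0.0, 0.0),
    n_circumferential: int = 64,
    n_axial: int = 40,
    capped: bool = False,
    orientation: NormalOrientation = NormalOrientation.INTO_LUMEN,
) -> TunnelMesh:
    """Exact triangulated cylinder: every vertex at distance ``radius_mm``
    from the axis.  Default normals face into the lumen (like a tunnel wall).
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if n_circumferential < 8 or n_axial < 2:
        raise ValueError("need n_circumferential >= 8 and n_axial >= 2")
    radii = np.full(n_axial, float(radius_mm))
    return _tube_mesh(radii, length_mm, axis_direction, axis_point, n_circumferential, capped, orientation)


def make_frustum_mesh(
    r_entry_mm: float,
    r_exit_mm: float,
    length_mm: float = 30.0,
    axis_direction=(0.0, 0.0, 1.0),
    axis_point=(0.0, 0.0, 0.0),
    n_circumferential: int = 64,
    n_axial: int = 40,
    capped: bool = False,
    orientation: NormalOrientation = NormalOrientation.INTO_LUMEN,
) -> TunnelMesh:
    """Linearly tapered tube: ring radius at arc-length fraction ``t`` is
    ``r_entry + t * (r_exit - r_entry)``.  Exercises the "mid-length"
    semantics of the transverse-section method.
    """
    if r_entry_mm <= 0 or r_exit_mm <= 0:
        raise ValueError("both radii must be positive")
    if n_circumferential < 8 or n_axial < 2:
        raise ValueError("need n_circumferential >= 8 and n_axial >= 2")
    t = np.linspace(0.0, 1.0, n_axial)
    radii = r_entry_mm + t * (r_exit_mm - r_entry_mm)
    return _tube_mesh(radii, length_mm, axis_direction, axis_point, n_circumferential, capped, orientation)


def make_plates_mesh(gap_mm: float, side_mm: float = 20.0, n: int = 20) -> TunnelMesh:
    """Two parallel square plates facing each other across ``gap_mm`` —
    the degenerate geometry whose wall thickness is exactly the gap."""
    if gap_mm <= 0:
        raise ValueError("gap_mm must be positive")
    xs = np.linspace(-side_mm / 2, side_mm / 2, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    grid = np.stack([xx.ravel(), yy.ravel()], axis=1)
    verts, faces = [], []
    for z, flip in ((-gap_mm / 2, True), (gap_mm / 2, False)):
        base = sum(v.shape[0] for v in verts)
        plate = np.column_stack([grid, np.full(len(grid), z)])
        verts.append(plate)
        for i in range(n - 1):
            for j in range(n - 1):
                a = base + i * n + j
                b = base + i * n + j + 1
                c = base + (i + 1) * n + j + 1
                d = base + (i + 1) * n + j
                if flip:  # normals face each other (into the gap)
                    faces.append((a, c, b))
                    faces.append((a, d, c))
                else:
                    faces.append((a, b, c))
                    faces.append((a, c, d))
    return TunnelMesh(np.concatenate(verts), np.asarray(faces), NormalOrientation.INTO_LUMEN, True)


def perturb_mesh(mesh: TunnelMesh, vertex_noise_sd_mm: float, seed: int = 0) -> TunnelMesh:
    """Displace each vertex along its normal by an independent N(0, sd) draw.

    Emulates the surface roughness that manual CT segmentation leaves on real
    tunnel models; topology is unchanged and output is reproducible per seed.
    """
    if vertex_noise_sd_mm < 0:
        raise ValueError("vertex_noise_sd_mm must be non-negative")
    if vertex_noise_sd_mm == 0:
        return TunnelMesh(mesh.vertices.copy(), mesh.faces.copy(), mesh.normal_orientation,
                          mesh.has_apertures, dict(mesh.metadata))
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, vertex_noise_sd_mm, size=mesh.n_vertices)
    verts = mesh.vertices + offsets[:, None] * mesh.vertex_normals()
    return TunnelMesh(verts, mesh.faces.copy(), mesh.normal_orientation, mesh.has_apertures, dict(mesh.metadata))


# ---------------------------------------------------------------------------
# Voxel phantoms
# ---------------------------------------------------------------------------


def _phantom_grids(spec: PhantomSpec):
    """World coordinates of all voxel centers plus grid origin."""
    extent = spec.bone_extent_mm + 2 * spec.margin_mm
    shape = np.maximum(np.ceil(extent / spec.voxel_spacing_mm).astype(int), 8)
    origin = -(shape - 1) * spec.voxel_spacing_mm / 2.0  # block centered at 0
    ax = [origin[k] + spec.voxel_spacing_mm[k] * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return X, Y, Z, origin, shape


def tunnel_true_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean array of voxels whose centers fall inside the ideal tunnel
    cylinder (clipped to the bone block) — the pre-blur ground truth."""
    X, Y, Z, _, _ = _phantom_grids(spec)
    pts = np.stack([X, Y, Z], axis=-1)
    along = pts @ spec.tunnel_axis
    radial2 = (pts * pts).sum(axis=-1) - along**2
    r = spec.drill_diameter_mm / 2.0
    in_tunnel = (radial2 <= r * r) & (np.abs(along) <= spec.tunnel_length_mm / 2.0)
    half = spec.bone_extent_mm / 2.0
    in_block = (np.abs(X) <= half[0]) & (np.abs(Y) <= half[1]) & (np.abs(Z) <= half[2])
    return in_tunnel & in_block


def make_phantom_volume(spec: PhantomSpec, tunnel_id: str = "t00") -> tuple[CTVolume, GroundTruth]:
    """Voxelize one phantom: cancellous block, cortical shell, tunnel carved
    out at background density; then isotropic Gaussian blur (partial volume)
    and additive noise.  Deterministic for a fixed ``spec.seed``."""
    X, Y, Z, origin, shape = _phantom_grids(spec)
    half = spec.bone_extent_mm / 2.0

    vox = np.full(shape, spec.background_density, dtype=np.float32)
    in_block = (np.abs(X) <= half[0]) & (np.abs(Y) <= half[1]) & (np.abs(Z) <= half[2])
    # distance from the block boundary, inward; shell where small
    depth = np.minimum.reduce([half[0] - np.abs(X), half[1] - np.abs(Y), half[2] - np.abs(Z)])
    shell = in_block & (depth <= spec.cortical_thickness_mm)
    vox[in_block] = spec.cancellous_density
    vox[shell] = spec.cortical_density

    pts = np.stack([X, Y, Z], axis=-1)
    along = pts @ spec.tunnel_axis
    radial2 = (pts * pts).sum(axis=-1) - along**2
    r = spec.drill_diameter_mm / 2.0
    in_tunnel = (radial2 <= r * r) & (np.abs(along) <= spec.tunnel_length_mm / 2.0)
    vox[in_tunnel] = spec.background_density

    if spec.blur_sigma_voxels > 0:
        vox = ndimage.gaussian_filter(vox, sigma=spec.blur_sigma_voxels)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox = vox + rng.normal(0.0, spec.noise_sd, size=vox.shape).astype(np.float32)

    volume = CTVolume(vox.astype(np.float32), spec.voxel_spacing_mm.copy(), origin)
    truth = GroundTruth(
        tunnel_id=tunnel_id,
        true_diameter_mm=spec.drill_diameter_mm,
        axis_point_mm=np.zeros(3),
        axis_direction=spec.tunnel_axis.copy(),
        length_mm=spec.tunnel_length_mm,
        profile="cylinder",
        seed=spec.seed,
    )
    return volume, truth


def make_cohort(
    n_tunnels: int = 24,
    diameter_grid=DIAMETER_GRID_MM,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
    obliquity_deg: tuple[float, float] = (20.0, 40.0),
) -> tuple[list[tuple[CTVolume, GroundTruth]], pd.DataFrame]:
    """Simulated study cohort: ``n_tunnels`` phantoms with drill diameters
    sampled (with replacement) from the 0.5 mm grid and randomized tunnel
    obliquity.  Returns the phantoms plus a manifest DataFrame.
    """
    if n_tunnels < 2:
        raise ValueError("n_tunnels must be >= 2")
    grid = [float(d) for d in diameter_grid]
    if not grid:
        raise ValueError("diameter_grid must not be empty")
    base = spec_template or PhantomSpec()
    rng = np.random.default_rng(seed)

    phantoms: list[tuple[CTVolume, GroundTruth]] = []
    rows = []
    for i in range(n_tunnels):
        d = float(rng.choice(grid))
        polar = float(rng.uniform(*obliquity_deg))
        azimuth = float(rng.uniform(0.0, 360.0))
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            drill_diameter_mm=d,
            tunnel_axis=tilted_axis(polar, azimuth),
            tunnel_length_mm=base.tunnel_length_mm,
            bone_extent_mm=base.bone_extent_mm.copy(),
            cortical_density=base.cortical_density,
            cancellous_density=base.cancellous_density,
            background_density=base.background_density,
            voxel_spacing_mm=base.voxel_spacing_mm.copy(),
            blur_sigma_voxels=base.blur_sigma_voxels,
            noise_sd=base.noise_sd,
            seed=child_seed,
            cortical_thickness_mm=base.cortical_thickness_mm,
            margin_mm=base.margin_mm,
        )
        tid = f"t{i:02d}"
        vol, truth = make_phantom_volume(spec, tunnel_id=tid)
        phantoms.append((vol, truth))
        rows.append({
            "id": tid,
            "true_diameter_mm": d,
            "axis_x": truth.axis_direction[0],
            "axis_y": truth.axis_direction[1],
            "axis_z": truth.axis_direction[2],
            "length_mm": spec.tunnel_length_mm,
            "seed": child_seed,
        })
    manifest = pd.DataFrame(rows)
    return phantoms, manifest
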