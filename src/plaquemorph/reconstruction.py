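"""Surface reconstruction of binary components and exact mesh metrics.

A component mask is converted to a watertight triangle mesh by marching
cubes at isovalue 0.5 on the zero-padded binary grid (padding guarantees the
surface closes at grid borders). Volume is the sum of signed tetrahedron
volumes over faces; area is the sum of triangle areas. No smoothing is
applied by default because smoothing changes both metrics; an optional
Laplacian pass is available for visual output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

from .image import BinaryMask

__all__ = ["TriSurface", "extract_surface", "mesh_volume", "mesh_area"]


@dataclass
class TriSurface:
    """A consistently outward-oriented triangle mesh in mm coordinates.

    Invariants for closed surfaces: every edge is shared by exactly two
    faces, no degenerate faces, positive signed volume.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _mesh: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) vertex-index triples")

    @property
    def mesh(self) -> trimesh.Trimesh:
        if self._mesh is None:
            self._mesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._mesh

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    @property
    def volume(self) -> float:
        """Enclosed volume in mm^3 (requires watertightness)."""
        return mesh_volume(self)

    @property
    def area(self) -> float:
        """Total surface area in mm^2."""
        return mesh_area(self)

    def transformed(self, matrix: np.ndarray) -> "TriSurface":
        """Apply a 4x4 homogeneous transform, returning a new surface."""
        matrix = np.asarray(matrix, dtype=np.float64)
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        return TriSurface(v, self.faces.copy())

    def scaled(self, factor: float, center: np.ndarray | None = None) -> "TriSurface":
        """Exact similarity scaling about *center* (default: vertex centroid)."""
        if factor <= 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        c = self.vertices.mean(axis=0) if center is None else np.asarray(center, float)
        return TriSurface(c + factor * (self.vertices - c), self.faces.copy())

    def save(self, path) -> None:
        """Export as STL or PLY depending on the file extension."""
        self.mesh.export(str(path))

    @classmethod
    def load(cls, path) -> "TriSurface":
        m = trimesh.load_mesh(str(path))
        return cls(np.asarray(m.vertices), np.asarray(m.faces))


def _clean(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    # merge near-duplicate vertices and drop zero-area faces before metrics
    mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    mesh.fix_normals()
    return mesh


def extract_surface(
    mask: BinaryMask,
    level: float = 0.5,
    antialias_sigma: float = 1.0,
    smooth_iterations: int = 0,
) -> TriSurface:
    """Marching-cubes isosurface of a binary component mask.

    The mask is zero-padded so the surface always closes, anti-aliased with
    a Gaussian of ``antialias_sigma`` voxels, and contoured at *level*.
    Anti-aliasing removes the voxel staircase that otherwise inflates the
    measured surface area by a resolution-independent ~8 %; because the
    filter also shrinks convex surfaces by ~sigma^2 x curvature, the mesh is
    then rescaled about its centroid so that its enclosed volume matches the
    (nearly unbiased) raw binary-contour volume of the same mask. The field
    operations replace mesh smoothing; no mesh-level smoothing is performed
    unless ``smooth_iterations`` > 0. Components too small to survive the
    filter fall back to an upsampled voxel-boundary contour. Vertex
    coordinates are scaled by the grid spacing and offset by the grid
    origin, i.e. returned in world mm.
    """
    if not mask.voxels.any():
        raise ValueError("cannot extract a surface from an empty mask")
    pad = max(2, int(np.ceil(2 * antialias_sigma)))
    padded = np.pad(mask.voxels, pad).astype(np.float32)
    spacing = np.asarray(mask.spacing, dtype=np.float64)
    shift = float(pad)
    field = padded
    calibrate = False
    if antialias_sigma > 0:
        from scipy.ndimage import gaussian_filter

        smoothed = gaussian_filter(padded, antialias_sigma)
        if smoothed.max() > level:
            field = smoothed
            calibrate = True
        else:
            # component thinner than the filter support: approximate the
            # voxel-boundary surface via 4x nearest-neighbour upsampling so
            # the enclosed volume stays close to the voxel-count volume
            up = 4
            fine = np.repeat(np.repeat(np.repeat(padded, up, 0), up, 1), up, 2)
            field = fine
            spacing = spacing / up
            shift = pad * up + (up - 1) / 2.0
    verts, faces, _, _ = measure.marching_cubes(field, level=level)
    # undo padding/upsampling; voxel centre i sits at origin + i*spacing
    verts = (verts - shift) * spacing + np.asarray(mask.origin)
    mesh = _clean(trimesh.Trimesh(vertices=verts, faces=faces, process=False))
    if calibrate and mesh.is_watertight and mesh.volume != 0:
        rv, rf, _, _ = measure.marching_cubes(padded, level=level)
        raw = trimesh.Trimesh((rv - pad) * spacing, rf, process=False)
        factor = float(abs(raw.volume) / abs(mesh.volume)) ** (1.0 / 3.0)
        centroid = mesh.center_mass
        mesh.apply_translation(-centroid)
        mesh.apply_scale(factor)
        mesh.apply_translation(centroid)
    if smooth_iterations > 0:
        trimesh.smoothing.filter_laplacian(mesh, iterations=smooth_iterations)
    if not mesh.is_watertight:
        raise ValueError("isosurface did not close into a watertight mesh")
    if mesh.volume < 0:
        mesh.invert()
    return TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces), mesh)


def mesh_volume(m: TriSurface) -> float:
    """Signed-tetrahedron volume of a watertight mesh, in mm^3.

    Translation- and rotation-invariant; raises on non-watertight input
    because the divergence-theorem sum is meaningless there.
    """
    if not m.is_watertight:
        raise ValueError("mesh volume requires a watertight mesh")
    return float(abs(m.mesh.volume))


def mesh_area(m: TriSurface) -> float:
    """Sum of triangle areas in mm^2."""
    return float(m.mesh.area)
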