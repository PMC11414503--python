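import numpy as np
import pytest

from plaquemorph.image import BinaryMask
from plaquemorph.reconstruction import TriSurface


def digital_ball(radius: float, spacing: float, pad_voxels: int = 6) -> BinaryMask:
    """Binary voxelization of a solid ball centred on the grid."""
    n = int(np.ceil(2 * radius / spacing)) + 2 * pad_voxels
    ax = np.arange(n) * spacing
    c = ax[n // 2]
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vox = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= radius**2
    return BinaryMask(vox, (spacing, spacing, spacing))


def unit_cube_mesh() -> TriSurface:
    """Hand-built axis-aligned unit cube (12 triangles, outward normals)."""
    v = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    f = np.array(
        [[0, 2, 1], [0, 3, 2],  # bottom (z=0)
         [4, 5, 6], [4, 6, 7],  # top
         [0, 1, 5], [0, 5, 4],  # y=0
         [1, 2, 6], [1, 6, 5],  # x=1
         [2, 3, 7], [2, 7, 6],  # y=1
         [3, 0, 4], [3, 4, 7]]  # x=0
    )
    return TriSurface(v, f)


def half_cylinder_mesh(radius: float, height: float, nt: int = 60, nz: int = 60) -> TriSurface:
    """Open half-cylinder shell; unrolled geodesic is sqrt((pi*r)^2 + h^2)."""
    th = np.linspace(0, np.pi, nt)
    z = np.linspace(0, height, nz)
    T, Z = np.meshgrid(th, z, indexing="ij")
    verts = np.column_stack(
        [radius * np.cos(T).ravel(), radius * np.sin(T).ravel(), Z.ravel()]
    )
    faces = []
    for i in range(nt - 1):
        for j in range(nz - 1):
            a = i * nz + j
            b = (i + 1) * nz + j
            faces += [[a, b, a + 1], [b, b + 1, a + 1]]
    return TriSurface(verts, np.array(faces))


def icosphere_mesh(radius: float, center=(0.0, 0.0, 0.0), subdivisions: int = 4) -> TriSurface:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface(np.asarray(ico.vertices) + np.asarray(center), np.asarray(ico.faces))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
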