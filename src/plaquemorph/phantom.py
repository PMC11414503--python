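"""Synthetic vessel phantoms with analytic ground truth.

The phantom emulates the imaging substrate of a contrast-enhanced carotid
CTA: a curved tubular lumen at high HU, eccentric ellipsoidal wall plaques
at soft-tissue HU (0-150), ellipsoidal calcifications embedded in plaques
at calcific HU (>150), and near-zero background, plus optional additive
Gaussian noise. Plaques are ellipsoids rather than image-derived shapes so
that every downstream measurement has a closed-form oracle: volume
(4/3)*pi*a*b*c, exact surface area via Legendre incomplete elliptic
integrals, and support-function axial extents.

The default lumen intensity (1500 HU) sits above the calcified window's
1334 HU upper bound, so threshold segmentation separates plaque components
from the contrast-filled lumen without a manual region of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .image import BinaryMask, ImageVolume
from .reconstruction import TriSurface

__all__ = [
    "PlaqueSpec",
    "PhantomSpec",
    "GroundTruth",
    "ellipsoid_volume",
    "ellipsoid_area",
    "ellipsoid_mesh",
    "make_vessel_phantom",
    "make_scaled_family",
]


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """(4/3)*pi*a*b*c for semi-axes a, b, c in mm."""
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Exact ellipsoid surface area in mm^2.

    Uses the Legendre form with incomplete elliptic integrals for semi-axes
    sorted a >= b >= c; degenerate (near-spherical or near-prolate) cases
    fall back to their closed forms to avoid 0/0.
    """
    a, b, c = sorted((float(a), float(b), float(c)), reverse=True)
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("semi-axes must be positive")
    if np.isclose(a, c, rtol=1e-12):  # sphere
        return 4.0 * np.pi * a * a
    phi = np.arccos(np.clip(c / a, -1.0, 1.0))
    m = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))  # k^2
    F = special.ellipkinc(phi, m)
    E = special.ellipeinc(phi, m)
    s = np.sin(phi)
    return float(
        2.0 * np.pi * c * c
        + (2.0 * np.pi * a * b / s) * (E * s * s + F * np.cos(phi) ** 2)
    )


def _as_rotation(orientation) -> np.ndarray:
    if orientation is None:
        return np.eye(3)
    R = np.asarray(orientation, dtype=np.float64)
    if R.shape != (3, 3):
        raise ValueError("orientation must be a 3x3 rotation matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-8
    ):
        raise ValueError("orientation must be a proper rotation (orthonormal, det=1)")
    return R


@dataclass
class PlaqueSpec:
    """An ellipsoidal plaque body attached to the lumen wall.

    ``calcifications`` is a list of ``(center, semi_axes)`` ellipsoids
    (axis-aligned in the plaque's rotated frame) that must lie fully inside
    the plaque body.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    orientation: np.ndarray | None = None
    calcifications: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.semi_axes = np.asarray(self.semi_axes, dtype=np.float64)
        if np.any(self.semi_axes <= 0):
            raise ValueError(f"plaque semi-axes must be positive, got {self.semi_axes}")
        self.orientation = _as_rotation(self.orientation)
        calcs = []
        for ctr, ax in self.calcifications:
            ctr = np.asarray(ctr, dtype=np.float64)
            ax = np.asarray(ax, dtype=np.float64)
            if np.any(ax <= 0):
                raise ValueError("calcification semi-axes must be positive")
            calcs.append((ctr, ax))
        self.calcifications = calcs
        for i, (ctr, ax) in enumerate(self.calcifications):
            if not self._contains_ellipsoid(ctr, ax):
                raise ValueError(
                    f"calcification {i} (center {ctr}, semi-axes {ax}) is not "
                    f"contained in the plaque ellipsoid"
                )

    def _local(self, points: np.ndarray) -> np.ndarray:
        """World points -> plaque-frame coordinates scaled by semi-axes."""
        return ((points - self.center) @ self.orientation) / self.semi_axes

    def contains(self, points: np.ndarray) -> np.ndarray:
        q = self._local(np.atleast_2d(points))
        return (q * q).sum(axis=1) <= 1.0

    def calc_contains(self, idx: int, points: np.ndarray) -> np.ndarray:
        ctr, ax = self.calcifications[idx]
        local = (np.atleast_2d(points) - self.center) @ self.orientation
        q = (local - ctr) / ax
        return (q * q).sum(axis=1) <= 1.0

    def _contains_ellipsoid(self, ctr: np.ndarray, ax: np.ndarray, n: int = 512) -> bool:
        # sample the calcification surface; containment of an ellipsoid in an
        # ellipsoid has no convenient closed form
        rng = np.random.default_rng(0)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts_local = ctr + u * ax
        q = pts_local / self.semi_axes
        return bool(np.all((q * q).sum(axis=1) <= 1.0 + 1e-12))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box (min, max) of the ellipsoid."""
        # support function of an ellipsoid along each world axis
        M = self.orientation * self.semi_axes  # columns scaled
        half = np.sqrt((M * M).sum(axis=1))
        return self.center - half, self.center + half

    def extent_along(self, direction: np.ndarray) -> float:
        """Full extent (mm) of the ellipsoid along a unit direction."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        w = (d @ self.orientation) * self.semi_axes
        return float(2.0 * np.linalg.norm(w))


@dataclass
class PhantomSpec:
    """Everything needed to voxelize a single-vessel phantom."""

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    lumen_axis: np.ndarray  # (n, 3) polyline in mm
    lumen_radius: float
    plaques: list[PlaqueSpec] = field(default_factory=list)
    lumen_hu: float = 1500.0
    plaque_hu: float = 75.0
    calc_hu: float = 600.0
    background_hu: float = -50.0
    noise_sd: float = 0.0
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        self.lumen_axis = np.asarray(self.lumen_axis, dtype=np.float64)
        if self.lumen_axis.ndim != 2 or self.lumen_axis.shape[1] != 3:
            raise ValueError("lumen_axis must be an (n, 3) polyline")
        if self.lumen_radius <= 0:
            raise ValueError("lumen_radius must be positive")
        if not self.lumen_hu > 150:
            raise ValueError("lumen_hu must exceed 150 HU (contrast-enhanced)")
        if not (0 <= self.plaque_hu <= 150):
            raise ValueError("plaque_hu must lie in the soft window [0, 150] HU")
        if not self.calc_hu > 150:
            raise ValueError("calc_hu must exceed 150 HU")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Analytic per-component truth for a voxelized phantom."""

    plaque_volumes: list[float]  # mm^3, pre-voxelization solids
    plaque_areas: list[float]  # mm^2
    plaque_extents: list[float]  # mm along the local lumen-axis tangent
    calc_volumes: list[list[float]]  # per plaque, mm^3
    lumen_axis: np.ndarray
    labels: np.ndarray  # 0 bg, 1 lumen, 2+i plaque i (incl. its calcifications)
    calc_labels: np.ndarray  # 0 none, global 1-based calcification index

    def to_json(self) -> str:
        payload = {
            "plaque_volumes_mm3": self.plaque_volumes,
            "plaque_areas_mm2": self.plaque_areas,
            "plaque_extents_mm": self.plaque_extents,
            "calc_volumes_mm3": self.calc_volumes,
            "lumen_axis_mm": self.lumen_axis.tolist(),
        }
        return json.dumps(payload, indent=2)


def _voxel_centers(shape, spacing, origin):
    axes = [o + np.arange(n) * s for n, s, o in zip(shape, spacing, origin)]
    return axes


def _polyline_distance(points: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline (vectorized per segment)."""
    d = np.full(points.shape[0], np.inf)
    for p0, p1 in zip(axis[:-1], axis[1:]):
        seg = p1 - p0
        L2 = float(seg @ seg)
        if L2 == 0.0:
            dist = np.linalg.norm(points - p0, axis=1)
        else:
            t = np.clip(((points - p0) @ seg) / L2, 0.0, 1.0)
            proj = p0 + t[:, None] * seg
            dist = np.linalg.norm(points - proj, axis=1)
        np.minimum(d, dist, out=d)
    if axis.shape[0] == 1:
        d = np.linalg.norm(points - axis[0], axis=1)
    return d


def _axis_tangent_at(axis: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Unit tangent of the polyline segment nearest to *point*."""
    if axis.shape[0] < 2:
        return np.array([0.0, 0.0, 1.0])
    best, best_d = 0, np.inf
    for i, (p0, p1) in enumerate(zip(axis[:-1], axis[1:])):
        seg = p1 - p0
        L2 = float(seg @ seg)
        t = 0.0 if L2 == 0 else np.clip((point - p0) @ seg / L2, 0.0, 1.0)
        d = np.linalg.norm(point - (p0 + t * seg))
        if d < best_d:
            best, best_d = i, d
    seg = axis[best + 1] - axis[best]
    return seg / np.linalg.norm(seg)


def make_vessel_phantom(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Voxelize the phantom and return the HU volume plus analytic truth.

    Voxels take the lumen / plaque / calcification / background plateau of
    whichever analytic solid contains their centre (plaque overrides lumen,
    calcification overrides plaque), plus Gaussian noise at ``noise_sd``.
    Deterministic for a fixed ``seed``.

    Raises if a plaque ellipsoid extends outside the grid or if two plaque
    ellipsoids overlap on the voxel grid (overlap would make per-plaque
    ground truth ambiguous).
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing)
    origin = np.asarray(spec.origin)
    grid_min = origin
    grid_max = origin + (np.asarray(shape) - 1) * spacing

    for i, pl in enumerate(spec.plaques):
        lo, hi = pl.bounds()
        if np.any(lo < grid_min - 1e-9) or np.any(hi > grid_max + 1e-9):
            raise ValueError(
                f"plaque {i} (center {pl.center}, semi-axes {pl.semi_axes}) "
                f"extends outside the grid [{grid_min}, {grid_max}] mm"
            )

    ax0, ax1, ax2 = _voxel_centers(shape, spacing, origin)
    labels = np.zeros(shape, dtype=np.int32)
    calc_labels = np.zeros(shape, dtype=np.int32)

    # lumen: tube of lumen_radius around the axis polyline
    II, JJ, KK = np.meshgrid(ax0, ax1, ax2, indexing="ij")
    centers = np.column_stack([II.ravel(), JJ.ravel(), KK.ravel()])
    lumen = _polyline_distance(centers, spec.lumen_axis) <= spec.lumen_radius
    labels.ravel()[lumen] = 1

    calc_counter = 0
    calc_volumes: list[list[float]] = []
    for i, pl in enumerate(spec.plaques):
        inside = pl.contains(centers)
        prev = labels.ravel()[inside]
        if np.any(prev >= 2):
            other = int(prev[prev >= 2].min()) - 2
            raise ValueError(f"plaques {other} and {i} overlap on the voxel grid")
        labels.ravel()[inside] = 2 + i
        vols = []
        for j, (_ctr, ax) in enumerate(pl.calcifications):
            calc_counter += 1
            cin = pl.calc_contains(j, centers)
            calc_labels.ravel()[cin] = calc_counter
            vols.append(ellipsoid_volume(*ax))
        calc_volumes.append(vols)

    hu = np.full(shape, spec.background_hu, dtype=np.float64)
    hu[labels == 1] = spec.lumen_hu
    hu[labels >= 2] = spec.plaque_hu
    hu[calc_labels > 0] = spec.calc_hu
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd, size=shape)

    truth = GroundTruth(
        plaque_volumes=[ellipsoid_volume(*pl.semi_axes) for pl in spec.plaques],
        plaque_areas=[ellipsoid_area(*pl.semi_axes) for pl in spec.plaques],
        plaque_extents=[
            pl.extent_along(_axis_tangent_at(spec.lumen_axis, pl.center))
            for pl in spec.plaques
        ],
        calc_volumes=calc_volumes,
        lumen_axis=spec.lumen_axis.copy(),
        labels=labels,
        calc_labels=calc_labels,
    )
    return ImageVolume(hu, spec.spacing, spec.origin), truth


def ellipsoid_mesh(pl: PlaqueSpec, subdivisions: int = 4) -> TriSurface:
    """Triangulated ellipsoid surface for a plaque spec (icosphere mapped)."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(ico.vertices) * pl.semi_axes  # stretch in plaque frame
    v = v @ pl.orientation.T + pl.center
    return TriSurface(v, np.asarray(ico.faces))


def make_scaled_family(base: PlaqueSpec, scales) -> list[TriSurface]:
    """Exact similarity family of the base plaque mesh.

    For a scale ``s`` the mesh is the base mesh with vertices scaled by
    ``s`` about the plaque centre, so area multiplies by ``s**2`` and
    volume by ``s**3`` exactly.
    """
    scales = [float(s) for s in scales]
    if any(s <= 0 for s in scales):
        raise ValueError(f"all scale factors must be positive, got {scales}")
    base_mesh = ellipsoid_mesh(base)
    return [base_mesh.scaled(s, center=base.center) for s in scales]
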