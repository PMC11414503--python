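"""Voxel-grid containers for CT-angiography-like volumes.

All grids are indexed ``(i, j, k)`` with world coordinates
``origin + index * spacing`` in millimetres (right-handed, 0-based).
Intensities are in Hounsfield units (HU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "BinaryMask", "LabelMap", "HuWindow"]


@dataclass(frozen=True)
class HuWindow:
    """An attenuation window [low, high] in Hounsfield units.

    ``low_open``/``high_open`` make the corresponding bound exclusive; the
    calcified window is conventionally open at its lower bound so that the
    soft-tissue window [0, 150] and the calcified window (150, 1334] form a
    partition with no voxel in both.
    """

    low: float
    high: float
    low_open: bool = False
    high_open: bool = False

    def __post_init__(self) -> None:
        if not (self.low <= self.high):
            raise ValueError(f"window low ({self.low}) must be <= high ({self.high})")

    def contains(self, values: np.ndarray) -> np.ndarray:
        lo = values > self.low if self.low_open else values >= self.low
        hi = values < self.high if self.high_open else values <= self.high
        return lo & hi


# the windows used for carotid plaque components: soft (non-calcified)
# tissue at 0-150 HU, calcification above 150 up to 1334 HU
SOFT_WINDOW = HuWindow(0.0, 150.0)
CALC_WINDOW = HuWindow(150.0, 1334.0, low_open=True)


@dataclass
class ImageVolume:
    """A 3D HU grid with anisotropic mm spacing."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(self.intensities.astype(np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
        origin = tuple(affine[:3, 3])
        return cls(np.asanyarray(img.dataobj), spacing, origin)


@dataclass
class BinaryMask:
    """A boolean voxel mask on the grid of a parent :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume(self) -> float:
        """Voxel-count volume in mm^3."""
        return float(self.voxels.sum()) * self.voxel_volume

    def same_grid(self, other: "BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def save(self, path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), affine), str(path))


@dataclass
class LabelMap:
    """Connected components labelled 1..K (0 = background), largest first."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_components(self) -> int:
        return int(self.labels.max())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def component_mask(self, label: int) -> BinaryMask:
        if not (1 <= label <= self.n_components):
            raise ValueError(f"label {label} out of range 1..{self.n_components}")
        return BinaryMask(self.labels == label, self.spacing, self.origin)

    def component_volumes(self) -> np.ndarray:
        """mm^3 per label, index 0 -> label 1."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_components + 1)[1:]
        return counts * self.voxel_volume

    def save(self, path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), affine), str(path))
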