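"""Lightweight volumetric containers shared by the whole pipeline.

Conventions
-----------
* Arrays are indexed ``(x, y, z)`` and live on an axis-aligned grid:
  ``world = origin + index * spacing`` (mm), identity direction matrix.
* Displacement fields are stored on the *fixed* grid and map fixed-domain
  physical points into the moving domain (pull-back convention):
  ``x_moving = x_fixed + u(x_fixed)``.
* Affine transforms likewise map fixed physical points to moving physical
  points, matching the resampling direction used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "LabelMap",
    "DisplacementField",
    "AffineTransform",
    "LOBE_LABELS",
    "UPPER_LOBES",
    "MID_LOWER_LOBES",
]

#: Integer labels for the five lobes. 0 is background (not lung).
LOBE_LABELS = {"LUL": 1, "LLL": 2, "RUL": 3, "RML": 4, "RLL": 5}
UPPER_LOBES = frozenset({"LUL", "RUL"})
MID_LOWER_LOBES = frozenset({"LLL", "RML", "RLL"})


@dataclass
class ImageVolume:
    """A 3-D scalar grid (HU or tracer counts) with physical geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid of physical (mm) coordinates of every voxel centre."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert (..., 3) physical points to fractional index coordinates."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid_as(self, other: "ImageVolume | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=np.asarray(data))

    # -- interchange --------------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T).astype(np.float64))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        return cls(
            data=sitk.GetArrayFromImage(img).T,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
        )

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        return cls(
            data=np.asanyarray(img.dataobj).astype(np.float64),
            spacing=spacing,
            origin=tuple(float(v) for v in affine[:3, 3]),
        )


@dataclass
class LabelMap(ImageVolume):
    """Integer lobe labels (``LOBE_LABELS``) on an ImageVolume grid; 0 = not lung."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.int16, copy=False)

    @property
    def lung_mask(self) -> np.ndarray:
        return self.data > 0

    def lobe_mask(self, lobe: str) -> np.ndarray:
        return self.data == LOBE_LABELS[lobe]

    def lobe_names(self) -> list[str]:
        present = set(np.unique(self.data)) - {0}
        return [name for name, lab in LOBE_LABELS.items() if lab in present]


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on the fixed grid, fixed→moving."""

    vectors: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def grid_like(self) -> ImageVolume:
        """An empty ImageVolume describing the fixed grid."""
        return ImageVolume(np.zeros(self.shape), self.spacing, self.origin)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.vectors.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "DisplacementField":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        return cls(
            vectors=np.asanyarray(img.dataobj).astype(np.float64),
            spacing=spacing,
            origin=tuple(float(v) for v in affine[:3, 3]),
        )


@dataclass
class AffineTransform:
    """Affine map of fixed physical points into the moving domain."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-9:
            raise ValueError("affine matrix is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def to_text(self, path: str | Path) -> None:
        m = np.eye(4)
        m[:3, :3] = self.matrix
        m[:3, 3] = self.translation
        np.savetxt(str(path), m, fmt="%.10g")

    @classmethod
    def from_text(cls, path: str | Path) -> "AffineTransform":
        m = np.loadtxt(str(path))
        return cls(m[:3, :3], m[:3, 3])
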