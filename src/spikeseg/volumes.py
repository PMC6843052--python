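"""In-memory containers for intensity and label volumes.

A :class:`Volume` is a 3D scalar grid with an affine carrying voxel spacing
and orientation (the NIfTI convention, voxel index -> world mm).  A
:class:`LabelVolume` is the integer-valued counterpart holding class ids
``0..n_classes-1`` where 0 is the background/"unknown" label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LabelVolume", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class Volume:
    """3D scalar intensity grid plus spacing/orientation metadata."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel size in mm along each axis (column norms of the affine)."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj, dtype=np.float32), img.affine)


@dataclass
class LabelVolume:
    """3D integer grid of class ids; 0 is background/unknown."""

    data: np.ndarray
    n_classes: int
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValidationError("label data must be integer-valued")
        self.data = self.data.astype(np.int32)
        if self.data.ndim != 3:
            raise ValidationError(f"label data must be 3D, got {self.data.ndim}D")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2 (background plus one class)")
        if self.data.min() < 0 or self.data.max() >= self.n_classes:
            raise ValidationError(
                f"label values must lie in [0, {self.n_classes - 1}]"
            )
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path, n_classes: int | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.int32)
        if n_classes is None:
            n_classes = int(data.max()) + 1 if data.size else 2
            n_classes = max(n_classes, 2)
        return cls(data, n_classes, img.affine)
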