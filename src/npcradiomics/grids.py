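"""Volume and mask containers with NIfTI round-tripping.

Axis order is array index order (axis 0, 1, 2); ``spacing_mm`` follows the
same order. NIfTI affines are diagonal: axis i of the array maps to world
axis i scaled by ``spacing_mm[i]`` and shifted by ``origin_mm[i]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "RoiMask", "check_congruent"]


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(x))
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected 3 per-axis values, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3-D scalar grid (MR intensity in arbitrary units, or dose in Gy)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = _as_tuple3(self.spacing_mm)
        self.origin_mm = _as_tuple3(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


@dataclass
class RoiMask:
    """Binary 3-D mask congruent with its parent :class:`ImageVolume`."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "GTV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={self.values.ndim}")
        self.spacing_mm = _as_tuple3(self.spacing_mm)
        self.origin_mm = _as_tuple3(self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def with_values(self, values: np.ndarray, label: str | None = None) -> "RoiMask":
        return replace(self, values=values, label=self.label if label is None else label)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.uint8), self.affine())
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, label: str = "GTV") -> "RoiMask":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(np.asarray(img.dataobj) > 0, spacing, origin, label=label)


def check_congruent(vol: ImageVolume, mask: RoiMask) -> None:
    """Raise if ``mask`` is not on the same grid as ``vol``."""
    if vol.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {vol.shape} vs mask {mask.shape}")
    if not np.allclose(vol.spacing_mm, mask.spacing_mm):
        raise ValueError(
            f"spacing mismatch: volume {vol.spacing_mm} vs mask {mask.spacing_mm}"
        )
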