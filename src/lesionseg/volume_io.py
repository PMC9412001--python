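"""NIfTI volume and mask I/O with geometry bookkeeping.

All volumes are reoriented to the canonical RAS+ axis order at load so that
"axial / coronal / sagittal" have a fixed meaning downstream: axis 0 runs
left→right (sagittal slicing), axis 1 posterior→anterior (coronal slicing),
axis 2 inferior→superior (axial slicing). Voxel indices are 0-based; world
coordinates are only ever reached through the affine.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryMask3D",
    "VolumePair",
    "GeometryError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


class GeometryError(ValueError):
    """Grid shape / spacing / affine disagreement between related files."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and a voxel→world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be 3 positive finite values, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class BinaryMask3D:
    """A {0,1} mask sharing the grid of a reference :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) != 0).astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @classmethod
    def from_reference(cls, data: np.ndarray, reference: "Volume | BinaryMask3D",
                       id: str = "") -> "BinaryMask3D":
        if tuple(data.shape) != tuple(reference.shape):
            raise GeometryError(
                f"mask shape {tuple(data.shape)} != reference {tuple(reference.shape)}"
            )
        return cls(data=data, spacing=reference.spacing,
                   affine=reference.affine.copy(), id=id)


@dataclasses.dataclass
class VolumePair:
    """Baseline + follow-up scan of one subject on a common grid."""

    baseline: Volume
    followup: Volume

    def __post_init__(self) -> None:
        if self.baseline.shape != self.followup.shape:
            raise GeometryError(
                f"time points differ in shape: {self.baseline.shape} vs "
                f"{self.followup.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.baseline.shape


def _load_canonical(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    return nib.as_closest_canonical(img)


def read_volume(path: str | Path, id: str = "") -> Volume:
    """Read a 3D NIfTI file, reorienting to canonical RAS+ axis order.

    Raises ``ValueError`` for non-3D images; no resampling is performed.
    """
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=np.asarray(data, dtype=np.float32), spacing=spacing,
                  affine=np.asarray(img.affine), id=id or Path(path).stem)


def write_volume(volume: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, reference: Volume, id: str = "") -> BinaryMask3D:
    """Read a mask, binarize (nonzero → 1) and adopt the reference geometry."""
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    if tuple(data.shape) != tuple(reference.shape):
        raise GeometryError(
            f"{path}: mask shape {tuple(data.shape)} does not match reference "
            f"{tuple(reference.shape)}"
        )
    return BinaryMask3D.from_reference(data, reference, id=id or Path(path).stem)


def write_mask(mask: BinaryMask3D, path: str | Path) -> None:
    # uint8 on disk: compact and lossless for binary labels
    img = nib.Nifti1Image(np.asarray(mask.data, dtype=np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
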