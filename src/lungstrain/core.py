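"""Core image containers and NIfTI I/O.

Conventions used throughout the package
---------------------------------------
* Array axes are ordered (AB, DV, LR): apical-basal, dorsal-ventral,
  left-right.  The DV axis runs dorsal -> ventral with increasing index.
* All physical coordinates are in millimetres.  Voxel ``i`` is centred at
  ``i * spacing`` and occupies the cube ``[(i - 1/2) h, (i + 1/2) h]``.
* Images are scalar Hounsfield-unit volumes; masks are boolean; aeration
  maps are small-integer label volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np

AXIS_LABELS = ("AB", "DV", "LR")
AB, DV, LR = 0, 1, 2

#: HU value used for soft tissue surrounding the lung in phantoms.
SOFT_TISSUE_HU = 40.0


class Compartment(IntEnum):
    """Aeration compartment labels (also used as voxel labels on disk)."""

    BACKGROUND = 0
    NON_AERATED = 1
    POORLY_AERATED = 2
    NORMALLY_AERATED = 3
    HYPER_AERATED = 4


@dataclass
class CTImage:
    """A 3D CT volume in Hounsfield units with isotropic spacing (mm)."""

    data: np.ndarray
    spacing: float
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"CTImage expects a 3D array, got shape {self.data.shape}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.spacing**3)


@dataclass
class BinaryMask:
    """Voxel-wise membership mask sharing the CT grid."""

    data: np.ndarray
    spacing: float
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"BinaryMask expects a 3D array, got shape {self.data.shape}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count * self.spacing**3


@dataclass
class AerationMap:
    """Per-voxel compartment labels over a lung mask.

    ``labels`` holds :class:`Compartment` values; voxels outside the lung
    are ``BACKGROUND``.  ``n_clamped`` counts voxels whose HU fell outside
    the nominal classification range and were clamped to the nearest
    compartment (QC figure).
    """

    labels: np.ndarray
    spacing: float
    n_clamped: int = 0
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("AerationMap expects a 3D label array")

    @property
    def lung_mask(self) -> BinaryMask:
        return BinaryMask(self.labels != Compartment.BACKGROUND, self.spacing)


def _affine(spacing: float) -> np.ndarray:
    aff = np.diag([spacing, spacing, spacing, 1.0])
    return aff


def save_nifti(volume: np.ndarray, spacing: float, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with isotropic spacing in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(volume)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, _affine(spacing))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    """Load a NIfTI volume; returns (array, isotropic spacing in mm).

    Raises ``ValueError`` for anisotropic spacing (the pipeline assumes
    isotropic voxels) or a corrupt header.
    """
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(f"anisotropic spacing {zooms} in {path}; isotropic voxels required")
    # pixdim is float32 in the header; strip the representation noise
    # (0.1 stored as 0.10000000149...) so round-trips are exact
    return np.asarray(img.dataobj), float(f"{float(zooms[0]):.7g}")


def load_ct(path: str | Path) -> CTImage:
    data, spacing = load_nifti(path)
    return CTImage(np.asarray(data, dtype=np.float32), spacing)


def load_mask(path: str | Path) -> BinaryMask:
    data, spacing = load_nifti(path)
    return BinaryMask(data > 0, spacing)
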