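"""NIfTI volume and mask containers with strict grid compatibility checks.

All downstream stages (masking, SUVR normalization, the two-point
correlation) assume that the PET volume and every mask live on the
identical voxel grid: same array shape and same voxel-to-world affine.
This module is the single place where that contract is enforced.

Physical distances are always derived from index offsets multiplied by
the voxel spacing (the column norms of the affine).  Oblique affines are
tolerated for I/O but intervoxel distances then refer to the axis-aligned
approximation; rotations that change column norms are not corrected for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: Elementwise absolute tolerance (mm) when comparing affines for grid equality.
#: Chosen to absorb header round-off between tools, not genuine misregistration.
AFFINE_ATOL_MM = 1e-3


class VolumeFormatError(ValueError):
    """Raised when an image on disk violates the 3-D single-frame contract."""


class GridMismatchError(ValueError):
    """Raised when two objects expected to share a voxel grid do not."""


@dataclass
class Volume:
    """A 3-D scalar field (PET activity or SUVR) on a voxel grid.

    Parameters
    ----------
    data
        3-D array of voxel values.  NaN voxels are allowed in memory and
        are treated as lying outside every mask by downstream code.
    affine
        4x4 voxel-to-world transform in mm.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"Volume data must be 3-D, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise VolumeFormatError(
                f"affine must be 4x4, got shape {self.affine.shape}"
            )
        if not np.all(self.spacing > 0):
            raise VolumeFormatError(
                f"voxel spacing must be positive in all axes, got {self.spacing}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray) -> "Volume":
        """Return a new Volume on the same grid carrying ``data``."""
        data = np.asarray(data)
        if data.shape != self.data.shape:
            raise GridMismatchError(
                f"replacement data shape {data.shape} != {self.data.shape}"
            )
        return Volume(data=data, affine=self.affine.copy())


@dataclass
class MaskSet:
    """Named binary masks sharing one voxel grid.

    Typical contents: ``target_gm`` plus the candidate reference regions
    ``cereb_gm``, ``wm10``, ``wm100``, ``brainstem``, ``corpus_callosum``.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    masks: dict[str, np.ndarray]

    @classmethod
    def empty(cls, like: Volume) -> "MaskSet":
        return cls(shape=like.shape, affine=like.affine.copy(), masks={})

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask)
        if mask.shape != tuple(self.shape):
            raise GridMismatchError(
                f"mask {name!r} shape {mask.shape} != grid shape {tuple(self.shape)}"
            )
        if mask.dtype != bool:
            values = np.unique(mask[np.isfinite(mask)] if np.issubdtype(
                mask.dtype, np.floating) else mask)
            if not np.all(np.isin(values, (0, 1))):
                raise ValueError(
                    f"mask {name!r} is not binary (values outside {{0,1}} found)"
                )
            mask = mask.astype(bool)
        self.masks[name] = mask

    def get(self, name: str, *, require_nonempty: bool = True) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"no mask named {name!r}; have {sorted(self.masks)}")
        mask = self.masks[name]
        if require_nonempty and not mask.any():
            raise ValueError(f"mask {name!r} is empty")
        return mask

    def __contains__(self, name: str) -> bool:
        return name in self.masks


def load_volume(path: str | Path) -> Volume:
    """Load a 3-D NIfTI image; 4-D single-frame inputs are squeezed to 3-D.

    NaN voxels are kept but a warning reports their count; masks built
    elsewhere treat them as background.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise VolumeFormatError(
                f"{path}: expected a single 3-D frame, got 4-D with "
                f"{data.shape[3]} frames"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D data, got {data.ndim}-D")
    data = np.asarray(data, dtype=np.float64) if np.issubdtype(
        data.dtype, np.floating) else data
    if np.issubdtype(data.dtype, np.floating):
        n_nan = int(np.isnan(data).sum())
        if n_nan:
            warnings.warn(
                f"{path.name}: {n_nan} NaN voxels; they are treated as "
                "outside every mask",
                stacklevel=2,
            )
    return Volume(data=data, affine=np.asarray(img.affine, dtype=float))


def save_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1 (.nii or .nii.gz by extension)."""
    img = nib.Nifti1Image(volume.data, volume.affine)
    nib.save(img, str(path))


def check_same_grid(a: Volume | MaskSet, b: Volume | MaskSet,
                    atol: float = AFFINE_ATOL_MM) -> bool:
    """True iff shapes match and affines agree elementwise within ``atol`` mm."""
    if tuple(a.shape) != tuple(b.shape):
        return False
    return bool(np.allclose(a.affine, b.affine, rtol=0.0, atol=atol))


def require_same_grid(a: Volume | MaskSet, b: Volume | MaskSet,
                      what: str = "inputs") -> None:
    if not check_same_grid(a, b):
        raise GridMismatchError(
            f"{what} do not share a voxel grid "
            f"(shapes {tuple(a.shape)} vs {tuple(b.shape)})"
        )
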