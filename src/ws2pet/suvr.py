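"""SUVR normalization of PET activity against a reference region.

SUVR(v) = PET(v) / <PET over reference mask>, with the reference summary
being the arithmetic mean by convention (median available behind a flag
for sensitivity analyses).  Summaries over the target gray matter are the
plain mean and median of the normalized voxel values.

NaN or nonpositive activity inside the reference is excluded from the
reference statistic with a warning; such voxels usually come from
resampling margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Volume


class SUVRError(ValueError):
    """Raised when a reference or target region cannot support normalization."""


@dataclass
class SUVRResult:
    """Per-scheme SUVR outcome for one PET volume."""

    scheme: str
    suvr_volume: Volume
    suvr_mean: float
    suvr_median: float
    ref_mean: float
    n_target_voxels: int
    n_ref_voxels: int


def normalize(pet: Volume, reference: np.ndarray, *, scheme: str = "reference",
              statistic: str = "mean") -> tuple[Volume, float, int]:
    """Divide the PET volume by the reference-region activity summary.

    Returns ``(suvr_volume, ref_value, n_ref_used)`` where ``ref_value``
    is the mean (or median) reference activity actually used, kept for
    audit trails.
    """
    reference = np.asarray(reference).astype(bool)
    if reference.shape != pet.shape:
        raise SUVRError(
            f"reference mask shape {reference.shape} != PET shape {pet.shape} "
            f"(scheme {scheme!r})"
        )
    if not reference.any():
        raise SUVRError(f"reference region {scheme!r} is empty")
    vals = pet.data[reference]
    good = np.isfinite(vals) & (vals > 0)
    n_dropped = int(vals.size - good.sum())
    if n_dropped:
        warnings.warn(
            f"scheme {scheme!r}: excluded {n_dropped} NaN/nonpositive "
            f"reference voxels from the reference statistic",
            stacklevel=2,
        )
    if not good.any():
        raise SUVRError(
            f"reference region {scheme!r} has no positive finite activity"
        )
    if statistic == "mean":
        ref_value = float(np.mean(vals[good]))
    elif statistic == "median":
        ref_value = float(np.median(vals[good]))
    else:
        raise ValueError(f"unknown reference statistic {statistic!r}")
    if ref_value <= 0:
        raise SUVRError(
            f"reference region {scheme!r} has nonpositive {statistic} activity"
        )
    return pet.with_data(pet.data / ref_value), ref_value, int(good.sum())


def summarize(suvr_volume: Volume, target: np.ndarray) -> tuple[float, float]:
    """Mean and median SUVR over the target mask (nonfinite voxels dropped).

    The median of an even count is the midpoint of the two central order
    statistics (numpy convention).
    """
    target = np.asarray(target).astype(bool)
    if target.shape != suvr_volume.shape:
        raise SUVRError(
            f"target mask shape {target.shape} != volume shape "
            f"{suvr_volume.shape}"
        )
    if not target.any():
        raise SUVRError("target region is empty")
    vals = suvr_volume.data[target]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise SUVRError("target region has no finite voxels")
    return float(np.mean(vals)), float(np.median(vals))


def compute_suvr(pet: Volume, target: np.ndarray, reference: np.ndarray,
                 scheme: str, *, statistic: str = "mean") -> SUVRResult:
    """Full SUVR computation for one (volume, target, reference) triple."""
    suvr_vol, ref_value, n_ref = normalize(
        pet, reference, scheme=scheme, statistic=statistic
    )
    suvr_mean, suvr_median = summarize(suvr_vol, target)
    return SUVRResult(
        scheme=scheme,
        suvr_volume=suvr_vol,
        suvr_mean=suvr_mean,
        suvr_median=suvr_median,
        ref_mean=ref_value,
        n_target_voxels=int(np.asarray(target).astype(bool).sum()),
        n_ref_voxels=n_ref,
    )
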