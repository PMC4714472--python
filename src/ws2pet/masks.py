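"""Construction of the target gray-matter mask and candidate reference masks.

Reference regions for SUVR normalization of amyloid PET:

* ``cereb_gm``          cerebellar gray matter (atlas labels)
* ``wm10``              white matter at a 10 % probability threshold, which
                        keeps WM border voxels adjacent to gray matter
* ``wm100``             white matter at a 100 % threshold (border voxels
                        removed; implemented as prob >= 1 - 1e-6 so float
                        probability maps round-trip safely)
* ``brainstem``         atlas labels
* ``corpus_callosum``   atlas labels, or a user-drawn splenium mask

The target is cerebral gray matter thresholded from the GM probability map,
minus cerebellar/brainstem labels so reference tissue never leaks into the
target statistics.

Tissue segmentation itself (producing the probability maps) and atlas
deformation into native space are upstream of this package; inputs must
already share the PET grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import MaskSet, Volume, require_same_grid

#: "100 %" probability is matched as >= 1 - WM_FULL_PROB_EPS.
WM_FULL_PROB_EPS = 1e-6

#: Default atlas label ids; match the synthetic phantom atlas and can be
#: overridden by a YAML config for real atlases (e.g. Neuromorphometrics).
DEFAULT_REGION_IDS: dict[str, list[int]] = {
    "cereb_gm": [2],
    "brainstem": [4],
    "corpus_callosum": [5],
}

#: Default GM probability threshold for the target mask.
DEFAULT_GM_LEVEL = 0.5


class MaskError(ValueError):
    """Raised when a requested mask would be empty or is otherwise invalid."""


@dataclass
class TissueProbabilityMap:
    """Per-voxel gray/white matter probabilities on the PET grid."""

    gm_prob: np.ndarray
    wm_prob: np.ndarray

    def __post_init__(self) -> None:
        self.gm_prob = np.asarray(self.gm_prob, dtype=float)
        self.wm_prob = np.asarray(self.wm_prob, dtype=float)
        if self.gm_prob.shape != self.wm_prob.shape:
            raise MaskError(
                f"gm_prob shape {self.gm_prob.shape} != wm_prob shape "
                f"{self.wm_prob.shape}"
            )
        for name, arr in (("gm_prob", self.gm_prob), ("wm_prob", self.wm_prob)):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise MaskError(f"{name} has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm_prob.shape


def _check_level(level: float) -> None:
    if not (0 < level <= 1):
        raise MaskError(f"probability threshold must be in (0, 1], got {level}")


def threshold_wm_mask(tpm: TissueProbabilityMap, level: float) -> np.ndarray:
    """Binary white-matter mask at a probability threshold.

    ``level=0.1`` reproduces the 10 % mask (WM voxels bordering gray
    matter included); ``level=1.0`` the 100 % mask (border voxels
    removed).  NaN probabilities never enter a mask.
    """
    _check_level(level)
    thr = min(level, 1.0 - WM_FULL_PROB_EPS)
    mask = tpm.wm_prob >= thr
    if not mask.any():
        raise MaskError(f"white-matter mask at level {level:g} is empty")
    return mask


def target_gm_mask(tpm: TissueProbabilityMap, level: float = DEFAULT_GM_LEVEL,
                   exclude: np.ndarray | None = None) -> np.ndarray:
    """Cerebral gray-matter target mask: gm_prob >= level, minus ``exclude``."""
    _check_level(level)
    mask = tpm.gm_prob >= min(level, 1.0 - WM_FULL_PROB_EPS)
    if exclude is not None:
        exclude = np.asarray(exclude).astype(bool)
        if exclude.shape != mask.shape:
            raise MaskError(
                f"exclusion shape {exclude.shape} != grid {mask.shape}"
            )
        mask &= ~exclude
    if not mask.any():
        raise MaskError(f"target gray-matter mask at level {level:g} is empty")
    return mask


def atlas_region_mask(labels: Volume | np.ndarray, ids) -> np.ndarray:
    """Union of the requested integer atlas labels as a binary mask."""
    arr = labels.data if isinstance(labels, Volume) else np.asarray(labels)
    ids = sorted(set(int(i) for i in ids))
    if not ids:
        raise MaskError("no atlas label ids requested")
    mask = np.isin(arr, ids)
    if not mask.any():
        raise MaskError(f"no voxel carries any of atlas labels {ids}")
    return mask


def load_region_ids(path: str | Path) -> dict[str, list[int]]:
    """Read a region-name -> label-id-list mapping from a small YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise MaskError(f"{path}: expected a mapping of region name to id list")
    return {str(k): [int(i) for i in np.atleast_1d(v)] for k, v in raw.items()}


def reference_mask(
    scheme: str,
    tpm: TissueProbabilityMap,
    labels: Volume,
    *,
    region_ids: dict[str, list[int]] | None = None,
    splenium: np.ndarray | None = None,
) -> np.ndarray:
    """Build a single named reference mask (lets callers isolate failures)."""
    ids = dict(DEFAULT_REGION_IDS)
    if region_ids:
        ids.update(region_ids)
    if scheme == "wm10":
        return threshold_wm_mask(tpm, 0.1)
    if scheme == "wm100":
        return threshold_wm_mask(tpm, 1.0)
    if scheme == "corpus_callosum" and splenium is not None:
        spl = np.asarray(splenium).astype(bool)
        if not spl.any():
            raise MaskError("supplied splenium mask is empty")
        return spl
    if scheme in ids:
        return atlas_region_mask(labels, ids[scheme])
    raise MaskError(f"unknown reference scheme {scheme!r}")


def exclusion_mask(labels: Volume,
                   region_ids: dict[str, list[int]] | None = None
                   ) -> np.ndarray:
    """Cerebellum + brainstem label voxels to exclude from the target.

    Tolerant of absent labels: an exclusion that matches nothing is
    simply empty, unlike a reference region.
    """
    ids = dict(DEFAULT_REGION_IDS)
    if region_ids:
        ids.update(region_ids)
    wanted = sorted(set(ids["cereb_gm"]) | set(ids["brainstem"]))
    arr = labels.data if isinstance(labels, Volume) else np.asarray(labels)
    return np.isin(arr, wanted)


def build_mask_set(
    pet: Volume,
    tpm: TissueProbabilityMap,
    labels: Volume,
    *,
    region_ids: dict[str, list[int]] | None = None,
    gm_level: float = DEFAULT_GM_LEVEL,
    splenium: np.ndarray | None = None,
) -> MaskSet:
    """Assemble target + all five candidate reference masks on the PET grid.

    ``splenium`` optionally overrides the atlas-derived corpus callosum
    with a user-drawn splenium ROI.
    """
    require_same_grid(pet, labels, "PET and atlas labels")
    if tpm.shape != pet.shape:
        raise MaskError(
            f"probability maps shape {tpm.shape} != PET shape {pet.shape}"
        )
    ids = dict(DEFAULT_REGION_IDS)
    if region_ids:
        ids.update(region_ids)

    ms = MaskSet.empty(pet)
    cereb = atlas_region_mask(labels, ids["cereb_gm"])
    brainstem = atlas_region_mask(labels, ids["brainstem"])
    ms.add("cereb_gm", cereb)
    ms.add("brainstem", brainstem)
    ms.add("wm10", threshold_wm_mask(tpm, 0.1))
    ms.add("wm100", threshold_wm_mask(tpm, 1.0))
    if splenium is not None:
        ms.add("corpus_callosum", splenium)
        if not ms.get("corpus_callosum").any():  # pragma: no cover - guarded in add
            raise MaskError("supplied splenium mask is empty")
    else:
        ms.add("corpus_callosum", atlas_region_mask(labels, ids["corpus_callosum"]))
    ms.add("target_gm", target_gm_mask(tpm, gm_level, exclude=cereb | brainstem))
    return ms
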