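"""Weighted two-point correlation function (wS2) over gray-matter voxel pairs.

The statistic characterizes spatial clustering ("flocculence") of tracer
uptake.  For a pair of in-mask voxels with values ``v1, v2`` separated by
Euclidean distance ``d`` (index offset times voxel spacing, mm), the pair
weight is

    w = (v1 + v2) / 2 * exp(-|v1 - v2| / lambda_diff)

i.e. large when both voxels are hot *and* similar.  Pairs are binned by
distance into half-open bins of width ``bin_width`` over [0, r_max]; the
per-bin mean weight plotted against distance is the wS2 curve.  Scalar
summaries are the trapezoidal area under the curve (AUC, the primary
outcome) and the ordinary-least-squares slope.

Two evaluation routes are provided:

``ws2_curve``
    Monte-Carlo estimate from ``n_pairs`` random pairs (default 50,000),
    drawn uniformly over the set of unordered in-mask pairs with
    ``d <= r_max``.  Uniformity over pairs is achieved by drawing the
    first voxel proportional to its in-ball neighbour count and the
    second uniformly from that ball; this makes the estimator unbiased
    for the exhaustive curve (a uniform first draw would over-weight
    pairs touching low-degree boundary voxels).

``ws2_exhaustive``
    Deterministic enumeration of *all* in-mask pairs with ``d <= r_max``
    (guarded to small masks); serves as the validation oracle for the
    sampler.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .io import Volume, require_same_grid

#: ws2_exhaustive refuses masks larger than this many voxels.
EXHAUSTIVE_MAX_VOXELS = 5000

#: Rounds of offset redraws before the rejection sampler gives up.
_MAX_REJECTION_ROUNDS = 10_000


class WS2Error(ValueError):
    """Raised for unusable masks, empty curves, or sampler failure."""


@dataclass(frozen=True)
class WS2Config:
    """Tunable parameters of the Monte-Carlo wS2 estimator.

    ``lambda_diff`` is the exponential decay scale of the difference term,
    in image-value units (SUVR units when run on normalized images).
    """

    n_pairs: int = 50_000
    r_max: float = 10.0
    bin_width: float = 1.0
    lambda_diff: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise WS2Error(f"n_pairs must be >= 1, got {self.n_pairs}")
        if self.r_max <= 0:
            raise WS2Error(f"r_max must be > 0, got {self.r_max}")
        if not (0 < self.bin_width <= self.r_max):
            raise WS2Error(
                f"bin_width must be in (0, r_max], got {self.bin_width}"
            )
        if self.lambda_diff <= 0:
            raise WS2Error(
                f"lambda_diff must be > 0, got {self.lambda_diff}"
            )


@dataclass
class WS2Curve:
    """Distance-binned wS2 values with AUC and slope summaries.

    ``values`` is NaN at empty bins; ``filled_values`` carries the
    linearly interpolated curve actually integrated for the AUC.
    ``stderr`` is the per-bin standard error of the mean weight (NaN for
    bins with fewer than two pairs).
    """

    bin_centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    stderr: np.ndarray
    filled_values: np.ndarray
    empty_bins: np.ndarray
    auc: float
    slope: float
    lambda_diff: float
    n_pairs: int

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


def pair_weight(v1, v2, lambda_diff: float = 1.0):
    """Weight of a voxel pair: pair mean times exponential difference decay.

    Symmetric in its arguments; equals the common value when v1 == v2.
    """
    if lambda_diff <= 0:
        raise WS2Error(f"lambda_diff must be > 0, got {lambda_diff}")
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    return 0.5 * (v1 + v2) * np.exp(-np.abs(v1 - v2) / lambda_diff)


def ball_offsets(spacing, r_max: float) -> np.ndarray:
    """Integer index offsets (excluding zero) within r_max mm, as (K, 3)."""
    spacing = np.asarray(spacing, dtype=float)
    reach = np.floor(r_max / spacing).astype(int)
    axes = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(grid * spacing, axis=1)
    keep = (d > 0) & (d <= r_max)
    return grid[keep]


def neighbor_counts(mask: np.ndarray, spacing, r_max: float) -> np.ndarray:
    """Per-voxel count of in-mask voxels within r_max mm (self excluded).

    Computed by FFT convolution with the ball footprint and rounded back
    to exact integers; zero outside the mask.
    """
    mask = np.asarray(mask).astype(bool)
    offs = ball_offsets(spacing, r_max)
    reach = np.abs(offs).max(axis=0)
    kernel = np.zeros(2 * reach + 1)
    kernel[tuple((offs + reach).T)] = 1.0
    conv = fftconvolve(mask.astype(np.float64), kernel, mode="same")
    counts = np.rint(conv).astype(np.int64)
    counts[~mask] = 0
    return counts


def sample_pairs(
    mask: np.ndarray,
    spacing,
    config: WS2Config,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n_pairs`` pairs uniformly over valid in-mask pairs.

    Returns ``(idx1, idx2, dist)`` with ``idx*`` of shape (n_pairs, 3)
    and ``dist`` in mm, all within (0, r_max].  Sampling is with
    replacement across instances and reproducible from ``config.seed``
    (or an explicit ``rng``).
    """
    mask = np.asarray(mask).astype(bool)
    spacing = np.asarray(spacing, dtype=float)
    coords = np.argwhere(mask)
    if len(coords) < 2:
        raise WS2Error(
            f"mask has {len(coords)} voxels; at least 2 required for pairs"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    offsets = ball_offsets(spacing, config.r_max)
    deg = neighbor_counts(mask, spacing, config.r_max)
    deg_in = deg[tuple(coords.T)]
    total = deg_in.sum()
    if total == 0:
        raise WS2Error(
            f"no in-mask voxel pair lies within r_max = {config.r_max:g} mm"
        )
    # first voxel ~ degree => unordered pairs are uniform
    p = deg_in / total
    n = config.n_pairs
    first = rng.choice(len(coords), size=n, p=p)
    idx1 = coords[first]
    idx2 = np.empty_like(idx1)
    done = np.zeros(n, dtype=bool)
    shape = np.asarray(mask.shape)
    for _round in range(_MAX_REJECTION_ROUNDS):
        todo = np.flatnonzero(~done)
        if todo.size == 0:
            break
        off = offsets[rng.integers(0, len(offsets), size=todo.size)]
        cand = idx1[todo] + off
        inside = np.all((cand >= 0) & (cand < shape), axis=1)
        ok = inside.copy()
        ok[inside] = mask[tuple(cand[inside].T)]
        hit = todo[ok]
        idx2[hit] = cand[ok]
        done[hit] = True
    else:  # pragma: no cover - requires pathological acceptance rate
        raise WS2Error(
            f"pair rejection sampling did not converge after "
            f"{_MAX_REJECTION_ROUNDS} rounds; "
            f"{int((~done).sum())}/{n} pairs unresolved "
            f"(mask voxels={len(coords)}, r_max={config.r_max:g} mm)"
        )
    dist = np.linalg.norm((idx1 - idx2) * spacing, axis=1)
    return idx1, idx2, dist


def _bin_curve(dist: np.ndarray, weights: np.ndarray, r_max: float,
               bin_width: float, lambda_diff: float) -> WS2Curve:
    """Bin pair weights by distance and summarize (shared by both routes)."""
    n_bins = int(np.ceil(r_max / bin_width - 1e-9))
    centers = (np.arange(n_bins) + 0.5) * bin_width
    idx = np.minimum((dist / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=weights, minlength=n_bins)
    sumsq = np.bincount(idx, weights=weights * weights, minlength=n_bins)

    values = np.full(n_bins, np.nan)
    stderr = np.full(n_bins, np.nan)
    occ = counts > 0
    values[occ] = sums[occ] / counts[occ]
    multi = counts > 1
    with np.errstate(invalid="ignore"):
        var = (sumsq[multi] / counts[multi] - values[multi] ** 2)
        var *= counts[multi] / (counts[multi] - 1)
        stderr[multi] = np.sqrt(np.maximum(var, 0.0) / counts[multi])

    if not occ.any():
        raise WS2Error("all distance bins are empty")
    empty = ~occ
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} of {n_bins} distance bins are empty; "
            "their curve values are linearly interpolated for the AUC",
            stacklevel=3,
        )
    filled = np.interp(centers, centers[occ], values[occ])

    auc = float(np.trapezoid(filled, centers))
    if occ.sum() >= 2:
        slope = float(np.polyfit(centers[occ], values[occ], 1)[0])
    else:
        slope = float("nan")
    return WS2Curve(
        bin_centers=centers,
        values=values,
        counts=counts,
        stderr=stderr,
        filled_values=filled,
        empty_bins=empty,
        auc=auc,
        slope=slope,
        lambda_diff=lambda_diff,
        n_pairs=int(counts.sum()),
    )


def ws2_from_pairs(image: Volume, idx1: np.ndarray, idx2: np.ndarray,
                   dist: np.ndarray, config: WS2Config) -> WS2Curve:
    """Curve from an explicit pair sample (lets one sample serve many images)."""
    v1 = image.data[tuple(idx1.T)]
    v2 = image.data[tuple(idx2.T)]
    w = pair_weight(v1, v2, config.lambda_diff)
    return _bin_curve(dist, w, config.r_max, config.bin_width,
                      config.lambda_diff)


def ws2_curve(image: Volume, mask: np.ndarray, config: WS2Config,
              rng: np.random.Generator | None = None) -> WS2Curve:
    """Monte-Carlo wS2 curve of ``image`` over ``mask``."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape:
        raise WS2Error(
            f"mask shape {mask.shape} != image shape {image.shape}"
        )
    work = mask & np.isfinite(image.data)
    idx1, idx2, dist = sample_pairs(work, image.spacing, config, rng=rng)
    return ws2_from_pairs(image, idx1, idx2, dist, config)


def ws2_exhaustive(image: Volume, mask: np.ndarray, r_max: float = 10.0,
                   bin_width: float = 1.0, lambda_diff: float = 1.0,
                   max_voxels: int = EXHAUSTIVE_MAX_VOXELS) -> WS2Curve:
    """Deterministic wS2 over all in-mask pairs with d <= r_max.

    The independent oracle for :func:`ws2_curve`; restricted to masks of
    at most ``max_voxels`` voxels so the pair enumeration stays tractable.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape:
        raise WS2Error(
            f"mask shape {mask.shape} != image shape {image.shape}"
        )
    work = mask & np.isfinite(image.data)
    coords = np.argwhere(work)
    if len(coords) > max_voxels:
        raise WS2Error(
            f"exhaustive enumeration limited to {max_voxels} voxels, "
            f"mask has {len(coords)}"
        )
    if len(coords) < 2:
        raise WS2Error(
            f"mask has {len(coords)} voxels; at least 2 required for pairs"
        )
    xyz = coords * np.asarray(image.spacing, dtype=float)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if len(pairs) == 0:
        raise WS2Error(
            f"no in-mask voxel pair lies within r_max = {r_max:g} mm"
        )
    dist = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
    vals = image.data[tuple(coords.T)]
    w = pair_weight(vals[pairs[:, 0]], vals[pairs[:, 1]], lambda_diff)
    return _bin_curve(dist, w, r_max, bin_width, lambda_diff)


def subject_seed(seed: int, subject_id: str, timepoint: str) -> int:
    """Stable per-(subject, timepoint) RNG seed derived from the run seed."""
    digest = hashlib.sha256(
        f"{seed}|{subject_id}|{timepoint}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
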