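"""Spatial structure statistics for masked intensity maps.

Two rank-based statistics quantify how spatially organized a fluorescence
intensity map is:

* **cluster size** — each non-background pixel follows the steepest 4-neighbor
  ascent path to a local intensity peak; pixels sharing a terminal peak form a
  cluster (a discrete gradient-ascent basin), and the statistic is the average
  basin size in pixels.
* **peak size** — pixels above the 95th percentile of the masked intensity
  distribution are grouped into 4-connected components; the statistic is the
  average component size.

Both depend only on the ordering of intensity values, so they are insensitive
to monotone intensity transforms, but both also depend on the mask geometry.
They are therefore normalized by a shuffle null model: intensity values are
permuted uniformly among non-background pixels (destroying spatial structure
while preserving the value distribution and the mask), the statistic is
recomputed for many shuffles, and the observed value is divided by the null
mean.  A normalized value near 1 means no spatial structure beyond chance;
values above 1 indicate spatially clustered intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .traces import IntensityMap

__all__ = [
    "ClusterLabeling",
    "SpatialMeasureResult",
    "PeakSizeParams",
    "steepest_ascent_clustering",
    "average_cluster_size",
    "shuffle_map",
    "null_average_cluster_size",
    "normalized_cluster_size",
    "peak_size",
    "null_peak_size",
    "normalized_peak_size",
]

# 4-neighborhood scan order used for steepest-ascent moves and tie-breaking:
# up, down, left, right (row-major, 0-based coordinates).
_NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ClusterLabeling:
    """Partition of non-background pixels into steepest-ascent basins.

    Attributes
    ----------
    label_map : ndarray of int
        Cluster id per pixel, ``-1`` on background.
    peaks : ndarray of shape (n_clusters, 2)
        (row, col) of the local peak anchoring each cluster, ordered by label.
    sizes : ndarray of int
        Pixel count per cluster, ordered by label.
    """

    label_map: np.ndarray
    peaks: np.ndarray
    sizes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass
class SpatialMeasureResult:
    """An observed spatial statistic with its shuffle-null normalization."""

    observed: float
    null_mean: float
    normalized: float
    n_shuffles: int
    frames_used: int
    seed: int | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class PeakSizeParams:
    """Parameters of the percentile peak-size statistic."""

    percentile: float = 95.0

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie strictly between 0 and 100")


def _neighbor_stack(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Stack of the 4 neighbor values at each pixel; -inf where the neighbor
    is out of bounds or background (it then never wins the ascent move)."""
    h, w = values.shape
    stack = np.full((4, h, w), -np.inf)
    masked = np.where(valid, values, -np.inf)
    stack[0, 1:, :] = masked[:-1, :]   # up neighbor
    stack[1, :-1, :] = masked[1:, :]   # down neighbor
    stack[2, :, 1:] = masked[:, :-1]   # left neighbor
    stack[3, :, :-1] = masked[:, 1:]   # right neighbor
    return stack


def steepest_ascent_clustering(imap: IntensityMap) -> ClusterLabeling:
    """Partition non-background pixels into basins of steepest 4-neighbor ascent.

    Each pixel moves to its largest 4-neighbor as long as that neighbor is
    strictly larger than the pixel itself; a pixel with no strictly larger
    neighbor is a local peak.  Clusters are the sets of pixels whose ascent
    paths terminate at the same peak.  Background pixels are neither traversed
    nor counted, and neighbors outside the mask or the image simply do not
    participate.

    Ties between neighbors sharing the maximal value are broken toward the
    first in the fixed scan order up, down, left, right.  On a plateau every
    pixel is its own peak (strict comparison), so a constant map yields
    size-1 clusters.
    """
    values = np.asarray(imap.grid, dtype=float)
    valid = ~np.asarray(imap.background_mask, dtype=bool)
    if values.shape != valid.shape or values.ndim != 2:
        raise ValueError("grid and background_mask must be equal-shape 2-D arrays")
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("empty mask: no non-background pixels to cluster")

    h, w = values.shape
    stack = _neighbor_stack(values, valid)
    best_dir = stack.argmax(axis=0)          # argmax takes the first maximum
    best_val = np.take_along_axis(stack, best_dir[None], axis=0)[0]

    flat_idx = np.arange(h * w).reshape(h, w)
    row_off = np.array([o[0] for o in _NEIGHBOR_OFFSETS])
    col_off = np.array([o[1] for o in _NEIGHBOR_OFFSETS])
    neighbor_idx = flat_idx + row_off[best_dir] * w + col_off[best_dir]

    self_val = np.where(valid, values, -np.inf)
    pointer = np.where(valid & (best_val > self_val), neighbor_idx, flat_idx)
    pointer = pointer.ravel()

    # Pointer jumping: each round doubles the resolved path length.
    while True:
        nxt = pointer[pointer]
        if np.array_equal(nxt, pointer):
            break
        pointer = nxt

    roots = pointer.reshape(h, w)
    valid_roots = roots[valid]
    unique_roots, labels_flat = np.unique(valid_roots, return_inverse=True)

    label_map = np.full((h, w), -1, dtype=np.int64)
    label_map[valid] = labels_flat
    sizes = np.bincount(labels_flat, minlength=len(unique_roots))
    peaks = np.column_stack(np.unravel_index(unique_roots, (h, w)))
    return ClusterLabeling(label_map=label_map, peaks=peaks, sizes=sizes)


def average_cluster_size(labeling: ClusterLabeling) -> float:
    """Mean basin size: non-background pixel count / number of clusters."""
    if labeling.n_clusters == 0:
        raise ValueError("labeling has no clusters")
    return float(labeling.sizes.sum()) / labeling.n_clusters


def shuffle_map(imap: IntensityMap, rng: np.random.Generator) -> IntensityMap:
    """Permute intensity values uniformly among non-background pixels.

    The mask geometry and the multiset of values are preserved; only the
    spatial arrangement is destroyed.
    """
    valid = ~imap.background_mask
    grid = imap.grid.copy()
    vals = grid[valid]
    grid[valid] = vals[rng.permutation(len(vals))]
    return IntensityMap(grid=grid, background_mask=imap.background_mask.copy(),
                        frame_index=imap.frame_index)


def null_average_cluster_size(
    imap: IntensityMap, n_shuffles: int = 1000, rng: np.random.Generator | None = None
) -> float:
    """Mean average cluster size over value-shuffled copies of the map."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    acc = 0.0
    for _ in range(n_shuffles):
        acc += average_cluster_size(steepest_ascent_clustering(shuffle_map(imap, rng)))
    return acc / n_shuffles


def _check_phase(n_frames: int, phase: Literal["baseline", "stimulation"] | None) -> None:
    expected = {"baseline": 9, "stimulation": 3}
    if phase is not None:
        if phase not in expected:
            raise ValueError(f"unknown phase {phase!r}")
        if n_frames != expected[phase]:
            raise ValueError(
                f"phase {phase!r} requires {expected[phase]} frames, got {n_frames}"
            )


def normalized_cluster_size(
    frames: Sequence[IntensityMap],
    phase: Literal["baseline", "stimulation"] | None = None,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SpatialMeasureResult:
    """Frame-averaged cluster size divided by its shuffle-null mean.

    The observed value is the mean over frames of the per-frame average
    cluster size; the null mean averages over both frames and shuffle runs
    (ratio of averages, not average of per-frame ratios).  ``phase`` enforces
    the 9-frame pre-stimulus / 3-frame stimulation frame counts of the
    recording protocol; ``None`` accepts any number of frames.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    _check_phase(len(frames), phase)
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = float(np.mean([
        average_cluster_size(steepest_ascent_clustering(f)) for f in frames
    ]))
    null_mean = float(np.mean([
        null_average_cluster_size(f, n_shuffles=n_shuffles, rng=rng) for f in frames
    ]))
    return SpatialMeasureResult(
        observed=observed, null_mean=null_mean, normalized=observed / null_mean,
        n_shuffles=n_shuffles, frames_used=len(frames), seed=seed,
    )


def _super_threshold(imap: IntensityMap, params: PeakSizeParams) -> np.ndarray:
    valid = ~imap.background_mask
    vals = imap.grid[valid]
    if vals.size == 0:
        raise ValueError("empty mask")
    threshold = np.percentile(vals, params.percentile)  # linear interpolation
    return valid & (imap.grid > threshold)


def peak_size(imap: IntensityMap, params: PeakSizeParams | None = None) -> float:
    """Average 4-connected component size of super-percentile pixels.

    Pixels with intensity strictly above the given percentile of the
    non-background distribution are grouped by 4-adjacency (top, bottom,
    left, right); the returned value is the mean component size in pixels.
    """
    params = params or PeakSizeParams()
    above = _super_threshold(imap, params)
    labels, n_comp = ndimage.label(above, structure=_FOUR_CONN)
    if n_comp == 0:
        raise ValueError("no pixels above the percentile threshold")
    return float(above.sum()) / n_comp


def null_peak_size(
    imap: IntensityMap,
    params: PeakSizeParams | None = None,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean peak size over value-shuffled copies of the map."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    params = params or PeakSizeParams()
    rng = np.random.default_rng() if rng is None else rng
    return float(np.mean([
        peak_size(shuffle_map(imap, rng), params) for _ in range(n_shuffles)
    ]))


def normalized_peak_size(
    imap: IntensityMap,
    params: PeakSizeParams | None = None,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SpatialMeasureResult:
    """Observed peak size divided by its mean over shuffled images."""
    params = params or PeakSizeParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = peak_size(imap, params)
    null_mean = null_peak_size(imap, params, n_shuffles=n_shuffles, rng=rng)
    return SpatialMeasureResult(
        observed=observed, null_mean=null_mean, normalized=observed / null_mean,
        n_shuffles=n_shuffles, frames_used=1, seed=seed,
        extras={"percentile": params.percentile},
    )
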