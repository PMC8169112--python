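"""Ground-truth-bearing synthetic inputs for every pipeline stage.

The generator emulates, at a deliberately simple level, the data this
package analyzes:

* masked two-channel images in which the calcium channel is a field of
  isotropic Gaussian bumps ("active-zone calcium" puncta) over a baseline
  with iid pixel noise, and the reference channel (mCherry) is flat inside
  the mask — it models sensor abundance only as a mask and denominator;
* stimulus-response stacks in which either all bumps (global mode, the
  signature of sugar-reward ingestion) or a seeded subset of bumps (local
  mode, the signature of odor responses) brighten during a stimulus window;
* behavioral acquisition datasets drawn from the saturating hyperbola
  LI = A·t/(B+t) plus Gaussian noise, clipped to the valid learning-index
  range [−1, 1].

Every generator is a pure function of its spec (including the seed), so
identical specs produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticImageSpec",
    "SyntheticImageTruth",
    "SyntheticResponseSpec",
    "SyntheticAcquisitionSpec",
    "AcquisitionDataset",
    "generate_terminal_image",
    "generate_response_stack",
    "generate_acquisition_data",
]


@dataclass
class SyntheticImageSpec:
    """Parameters of a masked two-channel terminal image.

    Defaults represent a densely innervated terminal field: many narrow
    bumps tiling an elliptical compartment, pixel noise well below the
    structural contrast, and no residual additive background (images are
    assumed background-subtracted upstream).  With ``footprint_radius`` set
    (the default, 1.5·sigma), the mask is further restricted to pixels near
    some bump center: the reference channel marks only regions containing
    active zones, so deep voids carry no mCherry and are censored.
    """

    height: int = 64
    width: int = 64
    mask_shape: Literal["full", "ellipse", "custom"] = "ellipse"
    custom_mask: np.ndarray | None = None
    n_peaks: int = 90
    peak_sigma: float = 2.0
    peak_amplitude: float = 1.0
    baseline_level: float = 0.0
    noise_sd: float = 0.05
    mcherry_level: float = 1.0
    min_separation: float | None = None  # defaults to 2 * peak_sigma
    footprint_radius: float | None = 3.0  # restrict mask to bump coverage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mcherry_level <= 0:
            raise ValueError("mcherry_level must be > 0 inside the mask")
        if self.mask_shape == "custom" and self.custom_mask is None:
            raise ValueError("custom mask_shape requires custom_mask")

    def mask(self) -> np.ndarray:
        """Boolean array, True inside the imaged region."""
        if self.mask_shape == "full":
            return np.ones((self.height, self.width), dtype=bool)
        if self.mask_shape == "ellipse":
            r = (np.arange(self.height) - (self.height - 1) / 2) / (self.height / 2)
            c = (np.arange(self.width) - (self.width - 1) / 2) / (self.width / 2)
            return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0
        m = np.asarray(self.custom_mask, dtype=bool)
        if m.shape != (self.height, self.width):
            raise ValueError("custom_mask shape mismatch")
        return m


@dataclass
class SyntheticImageTruth:
    """Ground truth of a generated image: bump centers, the nearest-center
    label of every in-mask pixel, per-bump pixel counts, and (for response
    stacks) which bumps respond to the stimulus."""

    peak_centers: np.ndarray          # (n_peaks, 2) float (row, col)
    true_label_map: np.ndarray        # int, -1 outside mask (or if no peaks)
    per_bump_size: np.ndarray         # pixels assigned to each bump
    responsive: np.ndarray | None = None  # bool per bump (response stacks)


@dataclass
class SyntheticResponseSpec:
    """A response stack: re-noised copies of a base image, with bump
    amplitudes multiplied by ``response_gain`` during the stimulus window —
    for all bumps (global) or a seeded fraction of bumps (local)."""

    base: SyntheticImageSpec = field(default_factory=SyntheticImageSpec)
    n_frames: int = 12
    stim_onset_frame: int = 9
    stim_n_frames: int = 3
    response_mode: Literal["global", "local"] = "global"
    response_gain: float = 3.0
    local_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0 <= self.stim_onset_frame and
                self.stim_onset_frame + self.stim_n_frames <= self.n_frames):
            raise ValueError("stimulus window does not fit within n_frames")
        if not 0 < self.local_fraction <= 1:
            raise ValueError("local_fraction must be in (0, 1]")
        if self.response_mode not in ("global", "local"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")


@dataclass
class SyntheticAcquisitionSpec:
    """Learning-index data from LI = A·t/(B+t) + Normal(0, noise_sd),
    clipped to [−1, 1], at the stated training durations (seconds)."""

    A_true: float = 0.4
    B_true: float = 20.0
    durations: Sequence[float] = (10.0, 20.0, 40.0, 80.0, 120.0)
    n_reps: int = 12
    noise_sd: float = 0.05
    group: str = "wt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B_true <= 0:
            raise ValueError("B_true must be > 0")
        if len(self.durations) == 0:
            raise ValueError("durations must be non-empty")
        if any(t <= 0 for t in self.durations):
            raise ValueError("durations must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class AcquisitionDataset:
    """Tidy learning-index records: one row per replicate."""

    table: pd.DataFrame  # columns: group, duration_s, replicate, li

    def __post_init__(self) -> None:
        required = {"group", "duration_s", "replicate", "li"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")

    def for_group(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[self.table["group"] == group]
        if sub.empty:
            raise ValueError(f"no records for group {group!r}")
        return sub["duration_s"].to_numpy(float), sub["li"].to_numpy(float)

    @classmethod
    def from_csv(cls, path) -> "AcquisitionDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _place_centers(spec: SyntheticImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement of bump centers inside the mask with a
    minimum pairwise distance (default 2σ) so ground-truth basins are
    identifiable.  Raises if the requested count cannot be placed."""
    mask = spec.mask()
    rows, cols = np.nonzero(mask)
    if spec.n_peaks == 0:
        return np.empty((0, 2))
    if rows.size == 0:
        raise ValueError("mask has no interior pixels to place peaks in")
    min_sep = 2.0 * spec.peak_sigma if spec.min_separation is None else spec.min_separation
    centers: list[np.ndarray] = []
    # bail once a long run of candidates is rejected: the packing is jammed
    max_consecutive_rejects = 3000
    rejects = 0
    while rejects < max_consecutive_rejects:
        i = rng.integers(rows.size)
        cand = np.array([rows[i], cols[i]]) + rng.uniform(-0.5, 0.5, size=2)
        if centers:
            d2 = np.sum((np.array(centers) - cand) ** 2, axis=1)
            if d2.min() < min_sep ** 2:
                rejects += 1
                continue
        rejects = 0
        centers.append(cand)
        if len(centers) == spec.n_peaks:
            return np.array(centers)
    raise ValueError(
        f"could not place {spec.n_peaks} peaks at separation {min_sep:.1f} "
        f"inside the mask ({rows.size} pixels)"
    )


def _bump_field(shape: tuple[int, int], centers: np.ndarray,
                amplitudes: np.ndarray, sigma: float) -> np.ndarray:
    """Sum of isotropic Gaussian bumps, evaluated over the full grid."""
    h, w = shape
    out = np.zeros((h, w))
    if len(centers) == 0:
        return out
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    for (r0, c0), a in zip(centers, amplitudes):
        out += a * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma ** 2))
    return out


def _effective_mask(spec: SyntheticImageSpec, mask: np.ndarray,
                    centers: np.ndarray) -> np.ndarray:
    """Optionally restrict the mask to the terminal footprint: pixels within
    ``footprint_radius`` of some bump center.  Models the reference channel
    marking only regions that contain active zones, so deep voids carry no
    mCherry and are censored."""
    if spec.footprint_radius is None or len(centers) == 0:
        return mask
    rows, cols = np.nonzero(mask)
    d2 = ((rows[:, None] - centers[None, :, 0]) ** 2
          + (cols[:, None] - centers[None, :, 1]) ** 2).min(axis=1)
    out = np.zeros_like(mask)
    out[rows, cols] = d2 <= spec.footprint_radius ** 2
    return out


def _truth_from_centers(mask: np.ndarray, centers: np.ndarray) -> SyntheticImageTruth:
    h, w = mask.shape
    label_map = np.full((h, w), -1, dtype=np.int64)
    if len(centers):
        rows, cols = np.nonzero(mask)
        d2 = ((rows[:, None] - centers[None, :, 0]) ** 2
              + (cols[:, None] - centers[None, :, 1]) ** 2)
        nearest = d2.argmin(axis=1)
        label_map[rows, cols] = nearest
        per_bump = np.bincount(nearest, minlength=len(centers))
    else:
        per_bump = np.zeros(0, dtype=np.int64)
    return SyntheticImageTruth(
        peak_centers=centers, true_label_map=label_map, per_bump_size=per_bump
    )


def _render_frame(spec: SyntheticImageSpec, mask: np.ndarray, signal: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    frame = spec.baseline_level + signal
    if spec.noise_sd > 0:
        frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
    frame = np.clip(frame, 0.0, None)
    frame[~mask] = 0.0
    return frame


def generate_terminal_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, SyntheticImageTruth]:
    """Render one two-channel frame.

    Returns an array of shape (2, H, W): channel 0 is baseline + Gaussian
    bumps + iid noise (zeroed outside the mask, clipped at 0); channel 1 is
    the flat mCherry reference, ``mcherry_level`` inside the mask and 0
    outside.  The truth records the bump centers, nearest-center labels of
    in-mask pixels, and per-bump pixel counts.
    """
    rng = np.random.default_rng(spec.seed)
    mask = spec.mask()
    centers = _place_centers(spec, rng)
    mask = _effective_mask(spec, mask, centers)
    amplitudes = np.full(len(centers), spec.peak_amplitude)
    signal = _bump_field((spec.height, spec.width), centers, amplitudes, spec.peak_sigma)
    gcamp = _render_frame(spec, mask, signal, rng)
    mcherry = np.where(mask, spec.mcherry_level, 0.0)
    frame = np.stack([gcamp, mcherry]).astype(np.float32)
    return frame, _truth_from_centers(mask, centers)


def generate_response_stack(
    spec: SyntheticResponseSpec,
) -> tuple[np.ndarray, SyntheticImageTruth]:
    """Render a (n_frames, 2, H, W) stimulus-response stack.

    Pre/post-stimulus frames are independent re-noisings of the base bump
    field.  During the stimulus window, bump amplitudes are multiplied by
    ``response_gain`` — all of them in global mode, or a seeded random
    subset of round(local_fraction · n_peaks) bumps in local mode.  The
    truth flags which bumps respond.
    """
    base = spec.base
    rng = np.random.default_rng(spec.seed)
    center_rng = np.random.default_rng(base.seed)
    mask = base.mask()
    centers = _place_centers(base, center_rng)
    mask = _effective_mask(base, mask, centers)
    n = len(centers)

    responsive = np.ones(n, dtype=bool)
    if spec.response_mode == "local" and n > 0:
        k = int(round(spec.local_fraction * n))
        k = max(k, 1)
        responsive = np.zeros(n, dtype=bool)
        responsive[rng.choice(n, size=k, replace=False)] = True

    amp0 = np.full(n, base.peak_amplitude)
    amp_stim = amp0.copy()
    amp_stim[responsive] *= spec.response_gain

    signal0 = _bump_field((base.height, base.width), centers, amp0, base.peak_sigma)
    signal1 = _bump_field((base.height, base.width), centers, amp_stim, base.peak_sigma)

    stim = range(spec.stim_onset_frame, spec.stim_onset_frame + spec.stim_n_frames)
    mcherry = np.where(mask, base.mcherry_level, 0.0)
    frames = []
    for f in range(spec.n_frames):
        signal = signal1 if f in stim else signal0
        gcamp = _render_frame(base, mask, signal, rng)
        frames.append(np.stack([gcamp, mcherry]))
    truth = _truth_from_centers(mask, centers)
    truth.responsive = responsive
    return np.array(frames, dtype=np.float32), truth


def generate_acquisition_data(spec: SyntheticAcquisitionSpec) -> AcquisitionDataset:
    """Draw replicate learning indices from the hyperbola plus noise.

    For each duration t, ``n_reps`` values A·t/(B+t) + Normal(0, noise_sd)
    are drawn and clipped to [−1, 1].
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for t in spec.durations:
        mu = spec.A_true * t / (spec.B_true + t)
        li = mu + rng.normal(0.0, spec.noise_sd, size=spec.n_reps)
        li = np.clip(li, -1.0, 1.0)
        for rep, v in enumerate(li):
            rows.append((spec.group, float(t), rep, float(v)))
    return AcquisitionDataset(
        pd.DataFrame(rows, columns=["group", "duration_s", "replicate", "li"])
    )


def structure_free_map_spec(seed: int, size: int = 64,
                            noise_sd: float = 0.3) -> SyntheticImageSpec:
    """A spec with no bumps: pure iid noise on a flat baseline — the
    structure-free control for null-model calibration."""
    return SyntheticImageSpec(
        height=size, width=size, mask_shape="ellipse", n_peaks=0,
        baseline_level=1.0, noise_sd=noise_sd, seed=seed,
    )
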