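"""Trace- and map-level preprocessing for ratiometric calcium imaging.

Covers the standard quantities derived from a two-channel (GCaMP / mCherry)
recording after registration:

* ΔF/F₀ of a single-ROI fluorescence trace, with F₀ the mean of a window of
  pre-stimulus frames;
* the ratiometric log-intensity map log₁₀(GCaMP/mCherry), with censoring of
  pixels that carry no usable mCherry (or GCaMP) value;
* pixel-distribution summaries (mean, SD, Gaussian diagnostic) of a masked
  map, the temporal variance of spatially averaged intensities, and the
  across-individual correlation between map means and SDs.

Conventions: within-map pixel SD is the population SD (ddof=0); temporal
variance across frames is the sample variance (ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "IntensityMap",
    "DistributionSummary",
    "TemporalVarianceResult",
    "compute_dff",
    "peak_transient",
    "ratiometric_log_map",
    "map_distribution_stats",
    "temporal_variance",
    "population_mean_sd_correlation",
]


@dataclass
class FluorescenceTrace:
    """A single-ROI fluorescence time series with its stimulus window.

    ``stim_onset`` is the 0-based index of the first stimulated frame;
    ``stim_duration`` is the stimulation length in frames (3 s of
    stimulation at the recording frame rate in the original protocol).
    """

    values: np.ndarray
    frame_period: float = 1.0
    stim_onset: int = 0
    stim_duration: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if not 0 <= self.stim_onset < len(self.values):
            raise ValueError("stim_onset outside trace")
        if self.stim_onset + self.stim_duration > len(self.values):
            raise ValueError("stimulus window extends past end of trace")


@dataclass
class DffTrace:
    """ΔF/F₀ per frame plus the baseline it was computed against."""

    values: np.ndarray
    f0: float
    baseline_n: int
    stim_onset: int
    stim_duration: int


@dataclass
class IntensityMap:
    """Masked 2-D map of log₁₀(GCaMP/mCherry) intensities.

    ``background_mask`` is True on background / censored pixels; values are
    finite exactly on non-background pixels.
    """

    grid: np.ndarray
    background_mask: np.ndarray
    frame_index: int | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.grid.shape != self.background_mask.shape:
            raise ValueError("grid and background_mask shapes differ")
        if not np.all(np.isfinite(self.grid[~self.background_mask])):
            raise ValueError("non-background pixels must be finite")

    @property
    def n_pixels(self) -> int:
        return int((~self.background_mask).sum())

    def values(self) -> np.ndarray:
        """Non-background pixel values, row-major order."""
        return self.grid[~self.background_mask]


@dataclass
class DistributionSummary:
    mean: float
    sd: float
    n_pixels: int
    gaussian_fit_ok: bool | None = None
    gaussian_pvalue: float | None = None
    pearson_r: float | None = None


@dataclass
class TemporalVarianceResult:
    spatial_means: np.ndarray
    variance: float
    n_frames: int


def compute_dff(trace: FluorescenceTrace, baseline_n: int = 7) -> DffTrace:
    """ΔF/F₀ = (F_t − F₀)/F₀ with F₀ the mean of ``baseline_n`` frames
    immediately preceding stimulus onset.

    Raises if fewer than ``baseline_n`` pre-stimulus frames exist, or if the
    baseline is non-positive (an empty or censored ROI).
    """
    if baseline_n < 1:
        raise ValueError("baseline_n must be >= 1")
    if trace.stim_onset < baseline_n:
        raise ValueError(
            f"need {baseline_n} pre-stimulus frames, trace has {trace.stim_onset}"
        )
    f0 = float(trace.values[trace.stim_onset - baseline_n:trace.stim_onset].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0={f0}: censored or empty ROI")
    return DffTrace(
        values=(trace.values - f0) / f0,
        f0=f0,
        baseline_n=baseline_n,
        stim_onset=trace.stim_onset,
        stim_duration=trace.stim_duration,
    )


def peak_transient(dff: DffTrace, window: tuple[int, int] | None = None) -> float:
    """Maximum ΔF/F₀ within a frame window ``[start, stop)``.

    Defaults to the stimulus onset through twice the stimulus duration past
    onset, a conventional search extent for a stimulus-evoked transient.
    """
    if window is None:
        window = (dff.stim_onset, dff.stim_onset + 2 * dff.stim_duration)
    start, stop = window
    start = max(start, 0)
    stop = min(stop, len(dff.values))
    if stop <= start:
        raise ValueError("empty peak-search window")
    return float(dff.values[start:stop].max())


def ratiometric_log_map(
    gcamp_frame: np.ndarray,
    mcherry_frame: np.ndarray,
    censor_threshold: float = 0.0,
    frame_index: int | None = None,
) -> IntensityMap:
    """log₁₀(GCaMP/mCherry) with censoring of unusable pixels.

    Pixels whose mCherry value is at or below ``censor_threshold`` are
    devoid of a reference signal and marked background.  Pixels with a
    non-positive GCaMP value are likewise censored, as their log-ratio is
    undefined.
    """
    gcamp = np.asarray(gcamp_frame, dtype=float)
    mcherry = np.asarray(mcherry_frame, dtype=float)
    if gcamp.shape != mcherry.shape:
        raise ValueError("channel frames must have the same shape")
    if censor_threshold < 0:
        raise ValueError("censor_threshold must be >= 0")
    background = (mcherry <= censor_threshold) | (gcamp <= 0)
    if background.all():
        raise ValueError("all pixels censored")
    grid = np.zeros_like(gcamp)
    keep = ~background
    grid[keep] = np.log10(gcamp[keep] / mcherry[keep])
    grid[background] = np.nan
    return IntensityMap(grid=grid, background_mask=background, frame_index=frame_index)


def map_distribution_stats(
    imap: IntensityMap, gaussian_test: bool = False, alpha: float = 0.05
) -> DistributionSummary:
    """Mean and population SD of the non-background pixel distribution.

    With ``gaussian_test=True`` a D'Agostino K² normality test is run and
    its p-value reported (``gaussian_fit_ok`` is True when the test does not
    reject at ``alpha``).
    """
    vals = imap.values()
    if vals.size < 2:
        raise ValueError("need at least 2 non-background pixels")
    ok = pval = None
    if gaussian_test:
        if vals.size >= 20 and np.std(vals) > 0:
            _, pval = stats.normaltest(vals)
            pval = float(pval)
            ok = bool(pval > alpha)
        else:
            ok = False
    return DistributionSummary(
        mean=float(vals.mean()), sd=float(vals.std(ddof=0)),
        n_pixels=int(vals.size), gaussian_fit_ok=ok, gaussian_pvalue=pval,
    )


def temporal_variance(maps: Sequence[IntensityMap]) -> TemporalVarianceResult:
    """Variance across frames of the per-frame spatial mean intensity.

    All frames must share the same background mask; the spatial mean is over
    non-background pixels and the across-frame variance uses ddof=1.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 frames")
    mask0 = maps[0].background_mask
    for m in maps[1:]:
        if not np.array_equal(m.background_mask, mask0):
            raise ValueError("background masks differ across frames")
    means = np.array([m.values().mean() for m in maps])
    return TemporalVarianceResult(
        spatial_means=means, variance=float(means.var(ddof=1)), n_frames=len(maps)
    )


def population_mean_sd_correlation(summaries: Sequence[DistributionSummary]) -> float:
    """Pearson correlation between per-individual map means and SDs.

    A strong negative value indicates that individuals with brighter
    (higher-mean) log-ratio maps have more spatially uniform signal.
    """
    summaries = list(summaries)
    if len(summaries) < 3:
        raise ValueError("need at least 3 individuals")
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    if means.std() == 0 or sds.std() == 0:
        raise ValueError("zero-variance inputs: correlation undefined")
    r, _ = stats.pearsonr(means, sds)
    return float(r)
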