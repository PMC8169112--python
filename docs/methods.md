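# Methods

This note documents the models, conventions and design choices behind
`azcalcium`, in the order data flow through the package.

## Ratiometric preprocessing

The sensor couples a calcium indicator (GCaMP6s) to a calcium-insensitive
reference (mCherry) at presynaptic active zones, so the pixelwise ratio
GCaMP/mCherry normalizes for local sensor abundance. `ratiometric_log_map`
computes `log10(gcamp / mcherry)` and censors two kinds of pixels:

- mCherry ≤ `censor_threshold` (default 0): no reference signal, so the
  ratio is meaningless. Real recordings typically need a small positive
  threshold; the default treats only strictly signal-free pixels as
  "devoid" of a value.
- GCaMP ≤ 0: the log-ratio is undefined. This second rule is ours; it
  keeps the map finite exactly on non-background pixels, which every
  downstream statistic assumes.

Base-10 logs are used throughout so map units read directly as orders of
magnitude of the ratio.

ΔF/F₀ uses F₀ = mean of exactly `baseline_n = 7` frames immediately before
stimulus onset (configurable). The peak-transient search window defaults to
[onset, onset + 2·stim_duration]; the appropriate extent depends on
indicator kinetics and is exposed as an argument.

Variance conventions are fixed so tests can be exact: **population** SD
(ddof = 0) for within-map pixel distributions, **sample** variance
(ddof = 1) for the temporal variance of spatially averaged intensities.

## Steepest-ascent cluster size

Each non-background pixel inspects its 4-neighbors (up, down, left, right;
0-based row-major coordinates). If the largest neighbor is strictly greater
than the pixel, the pixel points to it; otherwise the pixel is a local
peak. Following pointers partitions the mask into discrete gradient-ascent
basins; the statistic is the mean basin size in pixels. Conventions for
cases the mathematics leaves open:

- *Ties* between equally valued best neighbors resolve to the first in the
  fixed scan order up, down, left, right. Float-valued data make ties
  rare, but a deterministic rule keeps runs reproducible and lets an
  independent brute-force oracle reproduce the partition exactly.
- *Plateaus*: a pixel with no strictly greater neighbor is a peak, so a
  constant map decomposes into size-1 clusters (average size 1).
- *Background*: censored pixels are neither traversed nor counted, and
  neighbors outside the mask or image simply do not participate.

The implementation computes all pointers vectorially and resolves them by
pointer jumping; the test suite checks it against a per-pixel path-following
oracle on hundreds of random maps.

## Percentile peak size

The threshold is the linearly interpolated percentile (default 95) of the
non-background values; "above" is strict. Super-threshold pixels are
grouped by 4-connectivity (`scipy.ndimage.label`) and the statistic is the
mean component size. Both statistics are *rank statistics*: any strictly
increasing transform of the map leaves them unchanged.

## Shuffle null normalization

Observed cluster/peak sizes depend on the mask's area and shape. Each
statistic is therefore divided by its mean over images in which the
intensity values were permuted uniformly **among non-background pixels**
(default 1000 shuffles; tests and the acceptance script use 40–200, which
the convergence checks show is ample at 64×64). Permuting into the
background would alter the statistic's support, so background stays fixed;
`shuffle_map` is the single primitive behind both null models. For framed
recordings the observed value is averaged over frames (9 pre-stimulus or 3
stimulation frames, enforced via `phase`) and divided by the null mean
averaged over frames and shuffles — a ratio of averages, not an average of
per-frame ratios.

Calibration: on structure-free maps the normalized value is 1 within
Monte-Carlo error (acceptance checks require the mean over 30 maps to lie
in [0.9, 1.1]).

## Synthetic data

The generator emulates what the statistics need to see, not microscope
physics (no PSF, bleaching, or motion; stacks are "pre-registered"):

- **Images**: isotropic Gaussian bumps (amplitude 1, σ = 2 px by default)
  at centers dart-thrown inside an elliptical mask with minimum pairwise
  distance 2σ, over baseline 0 with iid N(0, 0.05²) pixel noise, clipped
  at 0. The mCherry channel is flat and noiseless — it models sensor
  abundance only as a mask and denominator (heterogeneous mCherry is a
  config option, off by default).
- **Footprint mask** (default radius 1.5σ): the mask is restricted to
  pixels within that distance of some bump center. The reference channel
  marks Brp-containing regions only, so coverage voids carry no mCherry
  and are censored. Besides realism this bounds the log-ratio's left tail,
  which otherwise is dominated by near-zero-signal pixels.
- **Response stacks**: 9 pre-stimulus + 3 stimulus frames, each an
  independent re-noising of the bump field. During the stimulus, bump
  amplitudes are multiplied by `response_gain` (default 3) — all bumps in
  *global* mode, a seeded random half in *local* mode. With zero additive
  baseline a global gain is a pure scaling, so the log-map's structural
  spread is invariant while relative noise shrinks: within-map SD falls,
  the signature of a uniform (reward-like) calcium rise. In local mode the
  boosted bumps' flanks override their dimmer neighbors' own gradients, so
  ascent basins merge and normalized cluster size rises above the global
  case — the signature of a spatially restricted (odor-like) response.
  These defaults were chosen by analyzing that generative physics; with
  noise comparable to structural contrast the noise-compression effect
  would dominate both signatures, which is a property of additive-noise
  imaging, not of the statistics.
- **Acquisition data**: LI = A·t/(B+t) + N(0, noise_sd), clipped to
  [−1, 1], defaults A = 0.4, B = 20 s, 12 replicates per duration at
  t ∈ {10, 20, 40, 80, 120} s, noise SD 0.05 — a plateau, time scale,
  replicate count and scatter typical of appetitive conditioning
  experiments over 10–120 s training.

What passing on these synthetics does **not** show: robustness to motion,
bleaching, non-flat mCherry, anisotropic or non-Gaussian puncta, or
correlated noise. The statistics themselves are rank-based and
mask-normalized, which is exactly the design that should transfer, but the
generator cannot certify it.

## Hyperbola fitting

`fit_hyperbola` minimizes Σ(LI − A·t/(B+t))² with bounds A ∈ [−1, 1]
(the LI range) and B ∈ (0, 10·max t]. For fixed B the optimal A is linear
(then clamped), so A is profiled out and the fit reduces to a 1-D search
over B: a 60-point log-spaced scan brackets the minimum of the profiled
RSS and golden-section iterations refine it to ~1e-9 relative. The fit is
therefore deterministic, needs no starting values, and vectorizes over
thousands of permutation refits; `scipy.optimize.curve_fit` on the raw
2-parameter problem serves as an independent cross-check in the tests.
A fit is flagged non-converged when B lands at the upper bound — the data
never saturate, so the plateau is unidentified.

## Permutation test on ΔA, ΔB

The permutation unit is the individual replicate LI, reshuffled between
groups **within each duration stratum** so every permuted group keeps the
original design (same n per duration) — the conservative reading of
"reassigning the group labels" when the design is shared. P-values are
two-sided with the add-one correction, p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) /
(n_valid + 1), so p is never 0 and identical groups give p = 1.
Non-converged refits are dropped from the null and counted (warning above
5%); stratum pools are sorted before permuting, which leaves the null's
law unchanged but makes the realized p exactly invariant to which group is
labeled first when group sizes match. Simulation places the empirical
type-I rate at α = 0.05 within [0.03, 0.07] and the power to detect a
plateau ratio of 2 (A = 0.3 vs 0.6, 12 replicates/duration, noise 0.05)
near 100%.

## Problem sizes

The test suite and acceptance script size their simulations for a
single-CPU run: 64×64 maps, 40–200 shuffles per null, 100-simulation
recovery studies, and 200–500×300–500 permutation calibrations. These are
the smallest sizes at which the Monte-Carlo error is comfortably below
each property's acceptance band; production analyses should use the 1000
shuffles / 2000 permutations defaults.

## Known limitations

- 2-D only (per-slice); no 26-neighbor volumetric clustering.
- The cluster statistic is sensitive to pixel noise: heavy noise
  fragments basins toward the null. Normalization removes bias but not
  variance; average over frames.
- The hyperbola's (A, B) are strongly correlated when the largest training
  duration is ≲ B; the permutation test inherits that uncertainty in ΔB.
- `AcquisitionDataset` assumes replicate independence; within-session
  correlation would invalidate the stratified permutation null.
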