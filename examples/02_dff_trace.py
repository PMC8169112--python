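"""Compute ΔF/F₀ and the stimulus-evoked peak transient of an ROI trace.

ΔF/F₀ = (F_t − F₀)/F₀ with F₀ the mean of the 7 frames preceding stimulus
onset; the peak transient is the maximum ΔF/F₀ in a window from onset to
twice the stimulus duration.
"""

import numpy as np

from azcalcium import FluorescenceTrace, compute_dff, peak_transient

rng = np.random.default_rng(0)
# 30-frame trace: baseline 100 a.u., a transient rising to 180 during
# a 3-frame stimulus, plus measurement noise
values = np.full(30, 100.0)
values[10:16] = [120.0, 165.0, 180.0, 160.0, 135.0, 112.0]
values += rng.normal(0, 1.0, 30)

trace = FluorescenceTrace(values=values, stim_onset=10, stim_duration=3)
dff = compute_dff(trace, baseline_n=7)
print(f"baseline F0 = {dff.f0:.1f} a.u.")
print(f"peak dF/F0 = {peak_transient(dff):.3f}")
# ~0.8: the fluorescence rose 80% above baseline at the transient's apex.
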