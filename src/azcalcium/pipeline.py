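"""Pipeline orchestration: seeded end-to-end runs with a manifest.

A run executes the selected stages in order — simulate (synthetic inputs),
traces (ΔF/F and map summaries), spatial (normalized cluster / peak size),
acquisition (hyperbola fits and the permutation test) — writing every
output file plus a JSON manifest that echoes the configuration, records
content hashes of inputs and outputs, and collects warnings.  Identical
configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as azio
from .acquisition import fit_hyperbola, permutation_test_fit
from .spatial import (
    PeakSizeParams,
    normalized_cluster_size,
    normalized_peak_size,
)
from .synthetic import (
    SyntheticAcquisitionSpec,
    SyntheticImageSpec,
    SyntheticResponseSpec,
    generate_acquisition_data,
    generate_response_stack,
)
from .traces import (
    FluorescenceTrace,
    compute_dff,
    map_distribution_stats,
    peak_transient,
    ratiometric_log_map,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "compare_groups"]

ALL_STAGES = ("simulate", "traces", "spatial", "acquisition")


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    output_dir: str
    seed: int
    stages: Sequence[str] = ALL_STAGES
    stack_path: str | None = None          # existing input; simulated if None
    behavior_csv: str | None = None
    n_shuffles: int = 200
    n_perm: int = 1000
    percentile: float = 95.0
    baseline_n: int = 7
    baseline_frames: int = 9
    stim_frames: int = 3
    censor_threshold: float = 0.0
    response_mode: str = "global"

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.baseline_n < 1:
            raise ValueError("baseline_n must be >= 1")
        if self.censor_threshold < 0:
            raise ValueError("censor_threshold must be >= 0")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    version: str
    stages_run: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)      # path -> sha256
    warnings: list = field(default_factory=list)
    wall_time_s: float = 0.0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages and write outputs plus a manifest."""
    from . import __version__

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    t0 = time.perf_counter()

    stack = None
    behavior = None
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "simulate":
                stack, behavior = _stage_simulate(config, out, manifest)
            elif stage == "traces":
                stack = _require_stack(config, stack)
                _stage_traces(config, stack, out, manifest)
            elif stage == "spatial":
                stack = _require_stack(config, stack)
                _stage_spatial(config, stack, out, manifest)
            elif stage == "acquisition":
                behavior = _require_behavior(config, behavior)
                _stage_acquisition(config, behavior, out, manifest)
            manifest.stages_run.append(stage)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, exc) from exc

    manifest.wall_time_s = round(time.perf_counter() - t0, 3)
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest.outputs[p.name] = _sha256(p)
    azio.write_json(out / "manifest.json", asdict(manifest))
    return manifest


def _require_stack(config: RunConfig, stack):
    if stack is not None:
        return stack
    if config.stack_path is None:
        raise ValueError("no image stack: run the simulate stage or set stack_path")
    return azio.read_stack(config.stack_path)


def _require_behavior(config: RunConfig, behavior):
    if behavior is not None:
        return behavior
    if config.behavior_csv is None:
        raise ValueError("no behavior table: run simulate or set behavior_csv")
    from .synthetic import AcquisitionDataset

    return AcquisitionDataset.from_csv(config.behavior_csv)


def _stage_simulate(config: RunConfig, out: Path, manifest: RunManifest):
    base = SyntheticImageSpec(seed=config.seed)
    rspec = SyntheticResponseSpec(
        base=base,
        n_frames=config.baseline_frames + config.stim_frames,
        stim_onset_frame=config.baseline_frames,
        stim_n_frames=config.stim_frames,
        response_mode=config.response_mode,
        seed=config.seed,
    )
    stack, truth = generate_response_stack(rspec)
    azio.write_stack(out / "stack.tif", stack)
    azio.write_mask(out / "mask.tif", base.mask())
    azio.write_json(out / "truth.json", {
        "peak_centers": truth.peak_centers,
        "per_bump_size": truth.per_bump_size,
        "responsive": truth.responsive,
    })
    g1 = generate_acquisition_data(
        SyntheticAcquisitionSpec(group="g1", seed=config.seed)
    )
    g2 = generate_acquisition_data(
        SyntheticAcquisitionSpec(A_true=0.6, group="g2", seed=config.seed + 1)
    )
    behavior_tbl = pd.concat([g1.table, g2.table], ignore_index=True)
    behavior_tbl.to_csv(out / "behavior.csv", index=False)
    from .synthetic import AcquisitionDataset

    return stack, AcquisitionDataset(behavior_tbl)


def _log_maps(config: RunConfig, stack: np.ndarray):
    return [
        ratiometric_log_map(frame[0], frame[1], config.censor_threshold,
                            frame_index=i)
        for i, frame in enumerate(stack)
    ]


def _stage_traces(config: RunConfig, stack: np.ndarray, out: Path,
                  manifest: RunManifest) -> None:
    n_frames = stack.shape[0]
    masks = stack[:, 1] > config.censor_threshold
    roi_trace = np.array([
        stack[f, 0][masks[f]].mean() for f in range(n_frames)
    ])
    trace = FluorescenceTrace(
        values=roi_trace,
        stim_onset=config.baseline_frames,
        stim_duration=config.stim_frames,
    )
    dff = compute_dff(trace, baseline_n=min(config.baseline_n, config.baseline_frames))
    peak = peak_transient(dff)
    maps = _log_maps(config, stack)
    per_frame = [map_distribution_stats(m) for m in maps]
    censored = [float(m.background_mask.mean()) for m in maps]
    if max(censored) > 0.5:
        manifest.warnings.append(
            f"high censored-pixel fraction (max {max(censored):.2f})"
        )
    pd.DataFrame({
        "frame": np.arange(n_frames),
        "dff": dff.values,
        "map_mean": [s.mean for s in per_frame],
        "map_sd": [s.sd for s in per_frame],
        "censored_fraction": censored,
    }).to_csv(out / "traces.csv", index=False)
    azio.write_json(out / "trace_summary.json", {
        "f0": dff.f0, "peak_dff": peak, "n_frames": n_frames,
    })


def _stage_spatial(config: RunConfig, stack: np.ndarray, out: Path,
                   manifest: RunManifest) -> None:
    maps = _log_maps(config, stack)
    nb, ns = config.baseline_frames, config.stim_frames
    results = {}
    for phase, sel in (("baseline", maps[:nb]), ("stimulation", maps[nb:nb + ns])):
        rng = np.random.default_rng(config.seed)
        res = normalized_cluster_size(sel, phase=phase,
                                      n_shuffles=config.n_shuffles, rng=rng)
        res.seed = config.seed
        pk = normalized_peak_size(
            sel[0], PeakSizeParams(percentile=config.percentile),
            n_shuffles=config.n_shuffles,
            rng=np.random.default_rng(config.seed),
        )
        pk.seed = config.seed
        results[phase] = {"cluster_size": res, "peak_size": pk}
    azio.write_json(out / "spatial.json", results)


def _stage_acquisition(config: RunConfig, behavior, out: Path,
                       manifest: RunManifest) -> None:
    groups = list(behavior.table["group"].unique())
    fits = {g: fit_hyperbola(behavior, g) for g in groups}
    result = {"fits": fits}
    if len(groups) == 2:
        perm = permutation_test_fit(
            behavior, behavior, group1=groups[0], group2=groups[1],
            n_perm=config.n_perm, seed=config.seed,
        )
        if perm.n_failed:
            manifest.warnings.append(
                f"{perm.n_failed}/{perm.n_perm} permutation refits failed"
            )
        result["permutation"] = {
            "dA_obs": perm.dA_obs, "dB_obs": perm.dB_obs,
            "p_A": perm.p_A, "p_B": perm.p_B,
            "n_perm": perm.n_perm, "n_failed": perm.n_failed,
            "seed": perm.seed,
            "null_dA_sd": float(np.std(perm.null_dA)),
            "null_dB_sd": float(np.std(perm.null_dB)),
        }
    azio.write_json(out / "acquisition.json", result)


def compare_groups(values_a, values_b, test: str = "mann_whitney") -> dict:
    """Two-sample comparison via standard routines (two-sided).

    ``test`` is ``"mann_whitney"`` or ``"t_test"``.  Returns the statistic,
    p-value and per-group sample sizes.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "t_test":
        res = stats.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"test": test, "statistic": float(res.statistic),
            "p_value": float(res.pvalue), "n_a": len(a), "n_b": len(b)}
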