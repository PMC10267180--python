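"""End-to-end orchestration of the workflow: conditioning, training,
prediction, fusion, evaluation and onset detection.

Shared by the CLI and by the evaluation suites so both run exactly the same
code path.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .config import ExperimentConfig
from .evaluation import EvaluationReport, evaluate_split, split_by_plant
from .fusion import OnsetResult, PredictionTrace, combine_predictions, detect_stress_onset
from .io import Recording
from .models import ArchitectureSpec, TrainedClassifier, predict_trace
from .preprocessing import (
    WindowSet,
    compute_plant_extrema,
    label_windows,
    make_windows,
    normalize,
    notch_filter,
    simplify,
)

log = logging.getLogger(__name__)

__all__ = ["prepare_windows", "PipelineResult", "run_pipeline"]


def prepare_windows(
    recordings: list[Recording],
    config: ExperimentConfig,
    apply_notch: bool = True,
    use_simplify: bool = True,
) -> WindowSet:
    """Conditioning chain: notch -> simplify (or raw windowing) -> label ->
    normalize, concatenated over plants.

    Plant order cannot matter: every step is plant-wise independent (per-plant
    min-max extrema are computed from labelled windows only).
    """
    parts = []
    for rec in recordings:
        samples = rec.samples
        if apply_notch and config.notch_freqs:
            if max(config.notch_freqs) < rec.fs / 2.0:
                samples = notch_filter(samples, rec.fs, config.notch_freqs)
            else:
                log.info(
                    "skipping notch for %s: %s Hz not below Nyquist (%s Hz)",
                    rec.plant_id, max(config.notch_freqs), rec.fs / 2.0,
                )
        filtered = dataclasses.replace(rec, samples=samples)
        if use_simplify:
            ws = simplify(filtered, config.simplify.S, config.simplify.N, config.simplify.F)
        else:
            ws = make_windows(filtered, config.window_length_s)
        ws = label_windows(ws, filtered, config.protocol)
        parts.append(ws)
    combined = WindowSet.concatenate(parts)
    extrema = None
    if config.normalization == "per_plant_minmax":
        extrema = compute_plant_extrema(combined)
    return normalize(combined, config.normalization, extrema)


@dataclasses.dataclass
class PipelineResult:
    config: ExperimentConfig
    classifier: TrainedClassifier
    report: EvaluationReport
    raw_traces: dict[str, PredictionTrace]
    fused_traces: dict[str, PredictionTrace]
    onsets: dict[str, OnsetResult]


def run_pipeline(
    recordings: list[Recording],
    config: ExperimentConfig,
    spec: ArchitectureSpec | None = None,
    apply_notch: bool = True,
) -> PipelineResult:
    """simulate/load -> preprocess -> train -> predict -> fuse -> evaluate ->
    detect-onset, on a held-out plant-wise split from the config protocol."""
    windows = prepare_windows(recordings, config, apply_notch=apply_notch)
    cohort_ids = [r.plant_id for r in recordings]
    split = split_by_plant(cohort_ids, config.protocol.test_plants)
    clf, report = evaluate_split(windows, split, config, config.seed, spec)

    by_id = {r.plant_id: r for r in recordings}
    raw_traces: dict[str, PredictionTrace] = {}
    fused_traces: dict[str, PredictionTrace] = {}
    onsets: dict[str, OnsetResult] = {}
    for pid in split.test_plants:
        trace = predict_trace(clf, windows.for_plants([pid]))
        fusedt = combine_predictions(trace, config.fusion.L, config.fusion.method)
        raw_traces[pid] = trace
        fused_traces[pid] = fusedt
        onsets[pid] = detect_stress_onset(
            fusedt, config.onset_threshold, search_from=by_id[pid].stimulus_time
        )
    return PipelineResult(
        config=config,
        classifier=clf,
        report=report,
        raw_traces=raw_traces,
        fused_traces=fused_traces,
        onsets=onsets,
    )
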