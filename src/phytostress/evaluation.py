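"""Plant-wise evaluation: splits, accuracy, leave-one-plant-out
cross-validation and the inference-timing report.

All data separation is done with respect to plants, never windows, so no
plant's data can appear on both sides of a split.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Callable, Sequence

import numpy as np

from .config import ExperimentConfig
from .fusion import PredictionTrace
from .models import ArchitectureSpec, TrainedClassifier, predict_confidences, train
from .preprocessing import WindowSet
from .utils import stable_seed

__all__ = [
    "SplitError",
    "SplitPlan",
    "EvaluationReport",
    "split_by_plant",
    "accuracy",
    "evaluate_split",
    "loocv",
    "inference_timing",
    "default_spec_for",
]


class SplitError(ValueError):
    """Raised for invalid plant-wise splits."""


@dataclasses.dataclass
class SplitPlan:
    test_plants: list[str]
    train_plants: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.test_plants) & set(self.train_plants)
        if overlap:
            raise SplitError(f"plants on both sides of the split: {sorted(overlap)}")
        if not self.test_plants:
            raise SplitError("test set must be non-empty")
        if not self.train_plants:
            raise SplitError("train set must be non-empty")


@dataclasses.dataclass
class EvaluationReport:
    per_plant_accuracy: dict[str, float]
    average_accuracy: float
    training_accuracy: float
    std_dev: float
    n_windows: dict[str, int] = dataclasses.field(default_factory=dict)

    @staticmethod
    def from_per_plant(per_plant: dict[str, float], training_accuracy: float,
                       n_windows: dict[str, int] | None = None) -> "EvaluationReport":
        vals = np.array(list(per_plant.values()))
        return EvaluationReport(
            per_plant_accuracy=dict(per_plant),
            average_accuracy=float(vals.mean()),
            training_accuracy=float(training_accuracy),
            std_dev=float(vals.std(ddof=0)),
            n_windows=dict(n_windows or {}),
        )


def split_by_plant(cohort_ids: Sequence[str], test_ids: Sequence[str]) -> SplitPlan:
    """Partition a cohort by plant id; every id stays on exactly one side."""
    cohort = list(dict.fromkeys(str(i) for i in cohort_ids))
    test = [str(i) for i in test_ids]
    unknown = set(test) - set(cohort)
    if unknown:
        raise SplitError(f"unknown plant id(s) in test set: {sorted(unknown)}")
    if len(set(test)) != len(test):
        raise SplitError("duplicate plant id in test set")
    train = [pid for pid in cohort if pid not in set(test)]
    return SplitPlan(test_plants=test, train_plants=train)


def accuracy(
    trace: PredictionTrace | np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> float:
    """Fraction of windows where (confidence >= threshold) equals the label.

    Windows labelled -1 (transition/unlabelled) are excluded; ties at the
    threshold are assigned to the stressed class.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    conf = trace.confidences if isinstance(trace, PredictionTrace) else np.asarray(trace)
    labels = np.asarray(labels)
    if len(conf) != len(labels):
        raise ValueError(f"trace length {len(conf)} != labels length {len(labels)}")
    keep = labels != -1
    if not np.any(keep):
        raise ValueError("accuracy is undefined: every window is labelled -1")
    pred = (conf[keep] >= threshold).astype(np.int64)
    return float((pred == labels[keep]).mean())


def default_spec_for(config: ExperimentConfig, input_length: int) -> ArchitectureSpec:
    return ArchitectureSpec(kind=config.architecture, input_length=input_length)


def _default_train_fn(
    train_ws: WindowSet, config: ExperimentConfig, seed: int, spec: ArchitectureSpec | None
) -> TrainedClassifier:
    spec = spec or default_spec_for(config, train_ws.window_samples)
    return train(
        spec,
        train_ws,
        epochs=config.train_budget.epochs,
        seed=seed,
        max_seconds=config.train_budget.max_seconds,
    )


def evaluate_split(
    windows: WindowSet,
    split: SplitPlan,
    config: ExperimentConfig,
    seed: int,
    spec: ArchitectureSpec | None = None,
    train_fn: Callable[..., TrainedClassifier] | None = None,
) -> tuple[TrainedClassifier, EvaluationReport]:
    """Train on the labelled windows of the train plants, score each test
    plant on its labelled windows."""
    assert not (set(split.train_plants) & set(split.test_plants))
    train_ws = windows.for_plants(split.train_plants).labelled()
    fn = train_fn or _default_train_fn
    clf = fn(train_ws, config, seed, spec)
    train_conf = predict_confidences(clf, train_ws)
    train_acc = accuracy(train_conf, train_ws.labels, config.decision_threshold)
    per_plant: dict[str, float] = {}
    n_win: dict[str, int] = {}
    for pid in split.test_plants:
        test_ws = windows.for_plants([pid]).labelled()
        if test_ws.n_windows == 0:
            raise SplitError(f"test plant {pid} has no labelled windows")
        conf = predict_confidences(clf, test_ws)
        per_plant[pid] = accuracy(conf, test_ws.labels, config.decision_threshold)
        n_win[pid] = test_ws.n_windows
    return clf, EvaluationReport.from_per_plant(per_plant, train_acc, n_win)


@dataclasses.dataclass
class LoocvResult:
    folds: dict[str, EvaluationReport]
    fold_seeds: dict[str, int]
    mean_test_accuracy: float
    std_test_accuracy: float
    mean_train_accuracy: float

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def loocv(
    windows: WindowSet,
    config: ExperimentConfig,
    spec: ArchitectureSpec | None = None,
    train_fn: Callable[..., TrainedClassifier] | None = None,
) -> LoocvResult:
    """Leave-one-plant-out CV: one model per plant, trained on all others.

    Per-fold seeds derive from hash(master seed, plant id), so adding a plant
    leaves the other folds' randomness untouched.
    """
    plant_list = sorted(str(p) for p in np.unique(windows.plant_ids))
    if len(plant_list) < 2:
        raise SplitError(f"LOOCV needs at least 2 plants, got {len(plant_list)}")
    folds: dict[str, EvaluationReport] = {}
    fold_seeds: dict[str, int] = {}
    for pid in plant_list:
        split = split_by_plant(plant_list, [pid])
        fold_seed = stable_seed(config.seed, pid)
        fold_seeds[pid] = fold_seed
        _, report = evaluate_split(windows, split, config, fold_seed, spec, train_fn)
        folds[pid] = report
    test_accs = np.array([folds[p].per_plant_accuracy[p] for p in plant_list])
    train_accs = np.array([folds[p].training_accuracy for p in plant_list])
    return LoocvResult(
        folds=folds,
        fold_seeds=fold_seeds,
        mean_test_accuracy=float(test_accs.mean()),
        std_test_accuracy=float(test_accs.std(ddof=0)),
        mean_train_accuracy=float(train_accs.mean()),
    )


def inference_timing(
    clf: TrainedClassifier,
    windows: WindowSet,
    batch_sizes: Sequence[int] = (1, 64),
    repetitions: int = 30,
) -> dict:
    """Median wall-time per window for each batch size (report-only; never a
    test assertion — timings are hardware-dependent)."""
    rows = []
    for bs in batch_sizes:
        x = windows.windows[:bs]
        if len(x) < bs:
            x = np.tile(windows.windows, (int(np.ceil(bs / max(1, len(windows.windows)))), 1))[:bs]
        clf.net.predict_proba(x, batch_size=bs)  # warm-up
        times = []
        for _ in range(repetitions):
            t0 = time.perf_counter()
            clf.net.predict_proba(x, batch_size=bs)
            times.append((time.perf_counter() - t0) / bs)
        rows.append(
            {
                "batch_size": int(bs),
                "median_seconds_per_window": float(np.median(times)),
                "repetitions": int(repetitions),
            }
        )
    return {"rows": rows, "architecture": clf.spec.kind}
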