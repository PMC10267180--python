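"""Causal fusion of consecutive prediction confidences and stress-onset
detection.

Because plant state changes slowly, the confidence for the current window can
be replaced by the mean or median of the previous L confidences; the price is
a decision delay of L x window-length.  Onset is the first local maximum of
the fused trace exceeding a threshold above 0.5.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from .config import ConfigError

__all__ = [
    "PredictionTrace",
    "OnsetResult",
    "OnsetError",
    "combine_predictions",
    "prediction_delay",
    "delay_hours",
    "delay_minutes",
    "threshold_trace",
    "detect_stress_onset",
    "write_trace_csv",
    "read_trace_csv",
]


class OnsetError(ValueError):
    """Raised when onset detection is asked for an empty trace."""


@dataclasses.dataclass
class PredictionTrace:
    """Time-ordered per-window stressed-state confidences for one plant."""

    plant_id: str
    start_times: np.ndarray
    confidences: np.ndarray
    window_length_s: float
    fused: bool = False
    fusion_params: dict | None = None

    def __post_init__(self) -> None:
        self.start_times = np.asarray(self.start_times, dtype=np.float64)
        self.confidences = np.asarray(self.confidences, dtype=np.float64)
        if len(self.start_times) != len(self.confidences):
            raise ValueError(
                f"start_times ({len(self.start_times)}) and confidences "
                f"({len(self.confidences)}) differ in length"
            )
        if len(self.start_times) > 1 and not np.all(np.diff(self.start_times) > 0):
            raise ValueError("start_times must be strictly increasing")
        if len(self.confidences) and (
            self.confidences.min() < 0.0 or self.confidences.max() > 1.0
        ):
            raise ValueError("confidences must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.confidences)


@dataclasses.dataclass
class OnsetResult:
    onset_time: float | None
    threshold: float
    rule: str = "first local maximum of the fused confidence >= threshold"


def combine_predictions(trace: PredictionTrace, l: int, method: str) -> PredictionTrace:
    """Causal fusion: value at i = mean/median of raw confidences over
    [max(0, i-L+1) .. i].  The warm-up prefix shrinks rather than being
    dropped, so the fused trace keeps full length.
    """
    if l < 1:
        raise ConfigError(f"fusion length L must be >= 1, got {l}")
    if method not in ("mean", "median"):
        raise ConfigError(f"fusion method must be 'mean' or 'median', got {method!r}")
    if trace.fused:
        raise ValueError("trace is already fused; combine raw confidences only")
    c = trace.confidences
    n = len(c)
    fused = np.empty(n)
    if method == "mean":
        csum = np.concatenate([[0.0], np.cumsum(c)])
        for i in range(n):
            lo = max(0, i - l + 1)
            fused[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    else:
        for i in range(n):
            fused[i] = np.median(c[max(0, i - l + 1) : i + 1])
    return PredictionTrace(
        plant_id=trace.plant_id,
        start_times=trace.start_times.copy(),
        confidences=fused,
        window_length_s=trace.window_length_s,
        fused=True,
        fusion_params={"L": l, "method": method},
    )


def prediction_delay(l: int, window_length_s: float) -> float:
    """Decision delay in seconds: L x window length."""
    if l < 1:
        raise ConfigError(f"L must be >= 1, got {l}")
    if window_length_s <= 0:
        raise ConfigError(f"window_length_s must be positive, got {window_length_s}")
    return l * window_length_s


def _trunc2(x: float) -> float:
    """Truncate (not round) to two decimals, matching the printed convention
    for delay figures (16000 s -> 4.44 h, 160 s -> 2.66 min)."""
    return math.floor(x * 100.0) / 100.0


def delay_hours(l: int, window_length_s: float) -> float:
    return _trunc2(prediction_delay(l, window_length_s) / 3600.0)


def delay_minutes(l: int, window_length_s: float) -> float:
    return _trunc2(prediction_delay(l, window_length_s) / 60.0)


def threshold_trace(trace: PredictionTrace, threshold: float) -> np.ndarray:
    """Binary labels: 1 where confidence >= threshold (ties go to stressed)."""
    if not (0.0 < threshold < 1.0):
        raise ConfigError(f"threshold must lie in (0, 1), got {threshold}")
    return (trace.confidences >= threshold).astype(np.int64)


def detect_stress_onset(
    trace: PredictionTrace,
    onset_threshold: float = 0.65,
    search_from: float | None = None,
) -> OnsetResult:
    """First local maximum of the fused confidence that reaches the threshold.

    A local maximum is strictly greater than its predecessor and >= its
    successor; the final index qualifies when it exceeds its predecessor, so a
    trace still rising at its end yields an onset.  ``search_from`` restricts
    the search to start times >= that value (e.g. the stimulus time).
    """
    if not (0.5 < onset_threshold < 1.0):
        raise ConfigError(f"onset_threshold must lie in (0.5, 1), got {onset_threshold}")
    c = trace.confidences
    if len(c) == 0:
        raise OnsetError("cannot detect an onset on an empty trace")
    first = 0
    if search_from is not None:
        eligible = np.nonzero(trace.start_times >= search_from)[0]
        if len(eligible) == 0:
            return OnsetResult(onset_time=None, threshold=onset_threshold)
        first = int(eligible[0])
    n = len(c)
    for i in range(first, n):
        if c[i] < onset_threshold:
            continue
        up = i == 0 or c[i] > c[i - 1]
        down = i == n - 1 or c[i] >= c[i + 1]
        if i == 0:
            up = True
            down = n == 1 or c[0] >= c[1]
        if up and down:
            return OnsetResult(onset_time=float(trace.start_times[i]), threshold=onset_threshold)
    return OnsetResult(onset_time=None, threshold=onset_threshold)


def write_trace_csv(trace: PredictionTrace, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# plant_id={trace.plant_id}\n")
        fh.write(f"# window_length_s={trace.window_length_s}\n")
        fh.write(f"# fused={trace.fused}\n")
        if trace.fusion_params:
            fh.write(f"# L={trace.fusion_params['L']}\n")
            fh.write(f"# method={trace.fusion_params['method']}\n")
        fh.write("start_time_s,confidence\n")
        for t, c in zip(trace.start_times, trace.confidences):
            fh.write(f"{t:.6f},{c:.9f}\n")
    return path


def read_trace_csv(path: str | Path) -> PredictionTrace:
    meta: dict[str, str] = {}
    times: list[float] = []
    confs: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("start_time_s"):
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            else:
                t, _, c = line.partition(",")
                times.append(float(t))
                confs.append(float(c))
    fused = meta.get("fused", "False") == "True"
    fusion_params = None
    if fused and "L" in meta:
        fusion_params = {"L": int(meta["L"]), "method": meta.get("method", "mean")}
    return PredictionTrace(
        plant_id=meta.get("plant_id", "unknown"),
        start_times=np.asarray(times),
        confidences=np.asarray(confs),
        window_length_s=float(meta.get("window_length_s", 16.0)),
        fused=fused,
        fusion_params=fusion_params,
    )
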