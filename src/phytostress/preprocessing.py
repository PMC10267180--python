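"""Signal conditioning: notch filtering, simplification, windowing, labelling
and normalization.

The simplification transform reduces a raw trace to a low-granularity
envelope: cut non-overlapping S-second windows, apply an N-sample rolling
median inside each window, then keep every F-th sample.  Windows never
overlap (stride = length), so no information leaks between adjacent training
samples.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .config import ConfigError, ProtocolParams
from .io import Recording

__all__ = [
    "WindowSet",
    "LabelError",
    "notch_filter",
    "rolling_median",
    "downsample",
    "simplify",
    "make_windows",
    "label_windows",
    "normalize",
    "compute_plant_extrema",
    "write_windows",
    "read_windows",
]

log = logging.getLogger(__name__)


class LabelError(ValueError):
    """Raised when a labelling protocol does not fit the recording."""


@dataclasses.dataclass
class WindowSet:
    """A batch of fixed-length signal windows with per-window metadata.

    ``labels``: 0 = normal, 1 = stressed, -1 = transition/unlabelled.
    """

    windows: np.ndarray
    plant_ids: np.ndarray
    start_times: np.ndarray
    labels: np.ndarray
    fs_effective: float
    window_length_s: float

    def __post_init__(self) -> None:
        self.windows = np.atleast_2d(np.asarray(self.windows, dtype=np.float64))
        self.plant_ids = np.asarray(self.plant_ids)
        self.start_times = np.asarray(self.start_times, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = self.windows.shape[0]
        if self.windows.size == 0:
            self.windows = self.windows.reshape(0, self.windows.shape[1] if self.windows.ndim == 2 else 0)
            n = 0
        for name, arr in (("plant_ids", self.plant_ids),
                          ("start_times", self.start_times),
                          ("labels", self.labels)):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        bad = set(np.unique(self.labels)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"labels must be in {{-1, 0, 1}}, got extraneous {sorted(bad)}")
        for pid in np.unique(self.plant_ids):
            st = self.start_times[self.plant_ids == pid]
            if len(st) > 1 and not np.all(np.diff(st) > 0):
                raise ValueError(f"start_times must be strictly increasing within plant {pid}")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_samples(self) -> int:
        return self.windows.shape[1]

    def select(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            windows=self.windows[mask],
            plant_ids=self.plant_ids[mask],
            start_times=self.start_times[mask],
            labels=self.labels[mask],
            fs_effective=self.fs_effective,
            window_length_s=self.window_length_s,
        )

    def for_plants(self, plant_ids: list[str]) -> "WindowSet":
        return self.select(np.isin(self.plant_ids, plant_ids))

    def labelled(self) -> "WindowSet":
        return self.select(self.labels != -1)

    @staticmethod
    def concatenate(parts: list["WindowSet"]) -> "WindowSet":
        if not parts:
            raise ValueError("cannot concatenate an empty list of WindowSets")
        fs = {p.fs_effective for p in parts}
        wl = {p.window_length_s for p in parts}
        if len(fs) != 1 or len(wl) != 1:
            raise ValueError("WindowSets disagree on fs_effective/window_length_s")
        return WindowSet(
            windows=np.concatenate([p.windows for p in parts]),
            plant_ids=np.concatenate([p.plant_ids for p in parts]),
            start_times=np.concatenate([p.start_times for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            fs_effective=parts[0].fs_effective,
            window_length_s=parts[0].window_length_s,
        )


def notch_filter(samples: np.ndarray, fs: float, freqs: list[float], q: float = 30.0) -> np.ndarray:
    """Zero-phase band-stop at each frequency (second-order IIR notch, Q=30).

    Forward-backward application keeps window timestamps unaffected.
    """
    samples = np.asarray(samples, dtype=np.float64)
    out = samples
    for f0 in freqs:
        if f0 >= fs / 2.0:
            raise ConfigError(f"notch frequency {f0} Hz >= Nyquist ({fs / 2.0} Hz)")
        b, a = sps.iirnotch(f0, q, fs=fs)
        out = sps.filtfilt(b, a, out)
    return out


def _rolling_median_rows(rows: np.ndarray, n: int, max_bytes: int = 1 << 26) -> np.ndarray:
    """Exact centered rolling median along axis 1, windows truncated at edges.

    The centered window for position i spans [i - (n-1)//2, i + n//2]; even
    counts take the arithmetic mean of the two middle order statistics
    (numpy's median).
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    n_rows, t = rows.shape
    hl = (n - 1) // 2
    hr = n // 2
    out = np.empty_like(rows)
    if t >= n:
        chunk = max(1, max_bytes // max(1, (t - n + 1) * n * 8))
        for s in range(0, n_rows, chunk):
            sw = sliding_window_view(rows[s : s + chunk], n, axis=1)
            out[s : s + chunk, hl : t - hr] = np.median(sw, axis=2)
        edge_cols = list(range(hl)) + list(range(t - hr, t))
    else:
        edge_cols = list(range(t))
    for i in edge_cols:
        a, b = max(0, i - hl), min(t, i + hr + 1)
        out[:, i] = np.median(rows[:, a:b], axis=1)
    return out


def rolling_median(samples: np.ndarray, n: int) -> np.ndarray:
    """Length-preserving rolling median with centered, edge-truncated windows."""
    if n < 1:
        raise ConfigError(f"rolling-median width must be >= 1, got {n}")
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1:
        raise ValueError("rolling_median expects a 1-D array")
    if n == 1:
        return samples.copy()
    return _rolling_median_rows(samples[None, :], n)[0]


def downsample(samples: np.ndarray, f: int) -> np.ndarray:
    """Keep every ``f``-th sample starting at index 0 (no extra anti-aliasing;
    the rolling median is the smoother)."""
    if f < 1:
        raise ConfigError(f"downsample factor must be >= 1, got {f}")
    return np.asarray(samples)[::f].copy()


def _cut_windows(rec: Recording, window_length_s: float) -> tuple[np.ndarray, np.ndarray]:
    win_samples = int(round(window_length_s * rec.fs))
    if win_samples < 1:
        raise ConfigError(f"window of {window_length_s}s is shorter than one sample at {rec.fs} Hz")
    n_win = len(rec.samples) // win_samples
    if n_win == 0:
        warnings.warn(
            f"recording {rec.plant_id} ({rec.duration_s:.1f}s) is shorter than one "
            f"{window_length_s}s window; returning an empty WindowSet",
            stacklevel=3,
        )
        return np.empty((0, win_samples)), np.empty(0)
    rows = rec.samples[: n_win * win_samples].reshape(n_win, win_samples)
    starts = rec.t0 + np.arange(n_win) * window_length_s
    return rows, starts


def simplify(rec: Recording, s: float = 16.0, n: int = 50, f: int = 10) -> WindowSet:
    """Cut S-second windows, rolling-median (N) each, then decimate by F.

    Trailing partial windows are discarded; labels start unassigned (-1).
    """
    if n < 1 or f < 1:
        raise ConfigError(f"simplify requires N >= 1 and F >= 1, got N={n}, F={f}")
    rows, starts = _cut_windows(rec, s)
    if rows.shape[0] > 0:
        if n > 1:
            rows = _rolling_median_rows(rows, n)
        rows = rows[:, ::f]
    else:
        rows = rows[:, ::f]
    return WindowSet(
        windows=rows,
        plant_ids=np.full(rows.shape[0], rec.plant_id),
        start_times=starts,
        labels=np.full(rows.shape[0], -1),
        fs_effective=rec.fs / f,
        window_length_s=s,
    )


def make_windows(rec: Recording, window_length_s: float, extra_downsample: int = 1) -> WindowSet:
    """Non-overlapping raw windows, optionally decimated (e.g. 30 s / factor 3)."""
    if window_length_s <= 0:
        raise ConfigError(f"window_length_s must be positive, got {window_length_s}")
    if extra_downsample < 1:
        raise ConfigError(f"extra_downsample must be >= 1, got {extra_downsample}")
    rows, starts = _cut_windows(rec, window_length_s)
    rows = rows[:, ::extra_downsample]
    return WindowSet(
        windows=rows,
        plant_ids=np.full(rows.shape[0], rec.plant_id),
        start_times=starts,
        labels=np.full(rows.shape[0], -1),
        fs_effective=rec.fs / extra_downsample,
        window_length_s=window_length_s,
    )


def label_windows(ws: WindowSet, rec: Recording, protocol: ProtocolParams) -> WindowSet:
    """Assign state labels from the training protocol.

    Windows fully inside ``[t0, t0 + span]`` are normal (0).  Stressed (1)
    windows lie fully inside ``[symptom_time, symptom_time + span]`` under the
    post-symptom protocol, or inside the final ``span`` hours under the
    extended protocol.  Everything else — including the whole transition
    period — is -1: excluded from training, retained for full-trace scoring.
    """
    span = protocol.train_hours_per_state * 3600.0
    end = rec.t0 + rec.duration_s
    if rec.t0 + span > end:
        raise LabelError(
            f"normal span of {span}s exceeds recording length {rec.duration_s}s"
        )
    if rec.t0 + span > rec.stimulus_time:
        raise LabelError(
            f"normal span of {span}s crosses the stimulus at {rec.stimulus_time}s"
        )
    if protocol.mode == "post_symptom":
        s_start, s_end = rec.symptom_time, rec.symptom_time + span
        if s_end > end:
            raise LabelError(
                f"stressed span [{s_start}, {s_end}]s exceeds recording end {end}s"
            )
    else:  # extended: final `span` hours
        s_start, s_end = end - span, end
        if s_start < rec.stimulus_time:
            raise LabelError(
                f"extended stressed span of {span}s reaches before the stimulus "
                f"at {rec.stimulus_time}s"
            )
    mask = ws.plant_ids == rec.plant_id
    w_start = ws.start_times
    w_end = ws.start_times + ws.window_length_s
    labels = ws.labels.copy()
    normal = mask & (w_start >= rec.t0) & (w_end <= rec.t0 + span)
    stressed = mask & (w_start >= s_start) & (w_end <= s_end)
    labels[mask] = -1
    labels[normal] = 0
    labels[stressed] = 1
    return dataclasses.replace(ws, labels=labels)


def compute_plant_extrema(ws: WindowSet, use_labelled_only: bool = True) -> dict[str, tuple[float, float]]:
    """Per-plant (min, max) from training-visible windows only (labelled != -1
    when available), so test-period extrema never leak into normalization."""
    extrema: dict[str, tuple[float, float]] = {}
    for pid in np.unique(ws.plant_ids):
        mask = ws.plant_ids == pid
        if use_labelled_only and np.any(mask & (ws.labels != -1)):
            mask = mask & (ws.labels != -1)
        vals = ws.windows[mask]
        extrema[str(pid)] = (float(vals.min()), float(vals.max()))
    return extrema


def normalize(
    ws: WindowSet,
    method: str,
    per_plant_extrema: dict[str, tuple[float, float]] | None = None,
) -> WindowSet:
    """Apply one of the four normalization variants.

    ``per_window_minmax`` maps each non-constant window onto [0, 1]; constant
    windows map to all-zeros (logged, no division by zero).
    """
    w = ws.windows
    if method == "none":
        out = w.copy()
    elif method == "per_window_minmax":
        mn = w.min(axis=1, keepdims=True)
        mx = w.max(axis=1, keepdims=True)
        span = mx - mn
        flat = span[:, 0] == 0
        if np.any(flat):
            log.info("per_window_minmax: %d constant window(s) mapped to zeros", int(flat.sum()))
        span[flat] = 1.0
        out = (w - mn) / span
        out[flat] = 0.0
    elif method == "per_window_demean":
        out = w - w.mean(axis=1, keepdims=True)
    elif method == "per_plant_minmax":
        if per_plant_extrema is None:
            per_plant_extrema = compute_plant_extrema(ws)
        out = np.empty_like(w)
        for pid in np.unique(ws.plant_ids):
            if str(pid) not in per_plant_extrema:
                raise ConfigError(f"no extrema provided for plant {pid}")
            mn, mx = per_plant_extrema[str(pid)]
            mask = ws.plant_ids == pid
            span = (mx - mn) or 1.0
            out[mask] = (w[mask] - mn) / span
    else:
        raise ConfigError(f"unknown normalization method {method!r}")
    return dataclasses.replace(ws, windows=out)


def write_windows(ws: WindowSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=ws.windows)
        f.create_dataset("labels", data=ws.labels)
        f.create_dataset("plant_ids", data=np.asarray(ws.plant_ids, dtype="S16"))
        f.create_dataset("start_times", data=ws.start_times)
        f.attrs["fs_effective"] = ws.fs_effective
        f.attrs["window_length_s"] = ws.window_length_s
    return path


def read_windows(path: str | Path) -> WindowSet:
    with h5py.File(path, "r") as f:
        return WindowSet(
            windows=f["windows"][()],
            plant_ids=np.array([p.decode() for p in f["plant_ids"][()]]),
            start_times=f["start_times"][()],
            labels=f["labels"][()],
            fs_effective=float(f.attrs["fs_effective"]),
            window_length_s=float(f.attrs["window_length_s"]),
        )
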