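"""Feature-based comparison approach: 34 handcrafted features per 60 s window
(temporal, frequency and time-frequency families), a causal multi-window
context, and a gradient-boosted-tree classifier tuned with leave-one-plant-out
folds.

The concrete feature formulas are this module's own documented set (the three
families are fixed; the set is versioned and swappable).  The time-frequency
family uses a Daubechies-4 discrete wavelet decomposition implemented here
directly.  Gradient boosting uses scikit-learn's implementation; the ranking
is its impurity-gain feature importance.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from sklearn.ensemble import GradientBoostingClassifier

from .config import ConfigError, ProtocolParams
from .io import Recording

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "ExtractionError",
    "TuningError",
    "FEATURE_NAMES",
    "window_features",
    "extract_features",
    "label_features",
    "build_context_matrix",
    "train_baseline",
]

FEATURE_SET_VERSION = "v1"


class ExtractionError(ValueError):
    """Raised when a recording is too short for the requested extraction."""


class TuningError(ValueError):
    """Raised when plant-wise hyperparameter tuning is impossible."""


# ---------------------------------------------------------------- wavelets
# Daubechies-4 decomposition low-pass filter (8 taps); the high-pass is its
# quadrature mirror.  Symmetric padding, stride-2 decimation.
_DB4_LO = np.array(
    [
        -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
        -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
        0.7148465705525415, 0.23037781330885523,
    ]
)
_DB4_HI = np.array([(-1) ** k * _DB4_LO[len(_DB4_LO) - 1 - k] for k in range(len(_DB4_LO))])


def _dwt_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pad = len(_DB4_LO) - 1
    xp = np.pad(x, pad, mode="symmetric")
    approx = np.convolve(xp, _DB4_LO[::-1], mode="valid")[::2]
    detail = np.convolve(xp, _DB4_HI[::-1], mode="valid")[::2]
    return approx, detail


def wavelet_energies(x: np.ndarray, levels: int = 5) -> tuple[np.ndarray, float]:
    """Per-level detail energies d1..dL and the final approximation energy."""
    energies = np.zeros(levels)
    approx = np.asarray(x, dtype=np.float64)
    for lev in range(levels):
        if len(approx) < 2:
            break
        approx, detail = _dwt_step(approx)
        energies[lev] = float(np.sum(detail**2))
    return energies, float(np.sum(approx**2))


# ---------------------------------------------------------------- features
_TEMPORAL = [
    "mean", "std", "variance", "skewness", "kurtosis", "min", "max", "ptp",
    "median", "rms", "iqr", "mad", "mean_abs_diff", "zero_crossings",
    "hjorth_mobility", "hjorth_complexity",
]
_FREQUENCY = [
    "total_power", "bandpower_0.0_0.5", "bandpower_0.5_2.0",
    "bandpower_2.0_10.0", "bandpower_10.0_nyq", "spectral_centroid",
    "spectral_bandwidth", "spectral_entropy", "spectral_edge95",
    "peak_frequency",
]
_WAVELET = [
    "wavelet_energy_d1", "wavelet_energy_d2", "wavelet_energy_d3",
    "wavelet_energy_d4", "wavelet_energy_d5", "wavelet_energy_a5",
    "wavelet_entropy", "wavelet_detail_ratio",
]
FEATURE_NAMES: tuple[str, ...] = tuple(_TEMPORAL + _FREQUENCY + _WAVELET)

_BANDS = ((0.0, 0.5), (0.5, 2.0), (2.0, 10.0), (10.0, np.inf))


def _hjorth(x: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0.0:
        return 0.0, 0.0
    v0 = float(np.var(x))
    if v0 == 0.0:
        return 0.0, 0.0
    d1 = np.diff(x)
    v1 = float(np.var(d1))
    mobility = float(np.sqrt(v1 / v0))
    if v1 == 0.0:
        return mobility, 0.0
    v2 = float(np.var(np.diff(d1)))
    mob_d = np.sqrt(v2 / v1)
    return mobility, float(mob_d / mobility) if mobility > 0 else 0.0


def window_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """All 34 features for one window; deterministic, no missing values."""
    x = np.asarray(x, dtype=np.float64)
    out: dict[str, float] = {}
    constant = bool(np.ptp(x) == 0.0)
    sd = 0.0 if constant else float(np.std(x))
    out["mean"] = float(np.mean(x))
    out["std"] = sd
    out["variance"] = 0.0 if constant else float(np.var(x))
    out["skewness"] = float(stats.skew(x)) if sd > 0 else 0.0
    out["kurtosis"] = float(stats.kurtosis(x)) if sd > 0 else 0.0
    out["min"] = float(np.min(x))
    out["max"] = float(np.max(x))
    out["ptp"] = float(np.ptp(x))
    out["median"] = float(np.median(x))
    out["rms"] = float(np.sqrt(np.mean(x**2)))
    q75, q25 = np.percentile(x, [75, 25])
    out["iqr"] = float(q75 - q25)
    out["mad"] = float(np.median(np.abs(x - np.median(x))))
    out["mean_abs_diff"] = float(np.mean(np.abs(np.diff(x)))) if len(x) > 1 else 0.0
    xc = x - out["mean"]
    out["zero_crossings"] = float(np.sum(xc[:-1] * xc[1:] < 0))
    out["hjorth_mobility"], out["hjorth_complexity"] = _hjorth(x)

    freqs, psd = sps.periodogram(x, fs=fs)
    total = float(np.sum(psd))
    out["total_power"] = total
    nyq = fs / 2.0
    for lo, hi in _BANDS:
        hi_eff = min(hi, nyq)
        name = f"bandpower_{lo}_{'nyq' if np.isinf(hi) else hi}"
        if total > 0 and hi_eff > lo:
            band = float(np.sum(psd[(freqs >= lo) & (freqs < hi_eff)]))
            out[name] = band / total
        else:
            out[name] = 0.0
    if total > 0:
        p = psd / total
        centroid = float(np.sum(freqs * p))
        out["spectral_centroid"] = centroid
        out["spectral_bandwidth"] = float(np.sqrt(np.sum((freqs - centroid) ** 2 * p)))
        nz = p[p > 0]
        out["spectral_entropy"] = float(-np.sum(nz * np.log(nz)) / np.log(len(p))) if len(p) > 1 else 0.0
        cum = np.cumsum(p)
        out["spectral_edge95"] = float(freqs[int(np.searchsorted(cum, 0.95))] if cum[-1] >= 0.95 else freqs[-1])
        out["peak_frequency"] = float(freqs[int(np.argmax(psd))])
    else:
        for name in ("spectral_centroid", "spectral_bandwidth", "spectral_entropy",
                     "spectral_edge95", "peak_frequency"):
            out[name] = 0.0

    det, approx = wavelet_energies(x, levels=5)
    for i, e in enumerate(det, start=1):
        out[f"wavelet_energy_d{i}"] = e
    out["wavelet_energy_a5"] = approx
    total_w = float(det.sum() + approx)
    if total_w > 0:
        rel = np.append(det, approx) / total_w
        nz = rel[rel > 0]
        out["wavelet_entropy"] = float(-np.sum(nz * np.log(nz)))
        out["wavelet_detail_ratio"] = float(det.sum() / total_w)
    else:
        out["wavelet_entropy"] = 0.0
        out["wavelet_detail_ratio"] = 0.0
    return out


@dataclasses.dataclass
class FeatureConfig:
    context_windows: int = 15
    window_length_s: float = 60.0
    feature_set: tuple[str, ...] = FEATURE_NAMES

    def validate(self) -> "FeatureConfig":
        if self.context_windows < 1:
            raise ConfigError(f"context_windows must be >= 1, got {self.context_windows}")
        if self.window_length_s <= 0:
            raise ConfigError(f"window_length_s must be positive, got {self.window_length_s}")
        unknown = set(self.feature_set) - set(FEATURE_NAMES)
        if unknown:
            raise ConfigError(f"unknown feature(s): {sorted(unknown)}")
        if len(set(self.feature_set)) != len(self.feature_set):
            raise ConfigError("feature_set contains duplicates")
        return self


@dataclasses.dataclass
class FeatureMatrix:
    values: np.ndarray
    columns: list[str]
    plant_ids: np.ndarray
    start_times: np.ndarray
    labels: np.ndarray
    window_length_s: float

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("feature column names must be unique")
        if self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"{self.values.shape[1]} columns of values vs {len(self.columns)} names"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "plant_id", self.plant_ids)
        df.insert(1, "start_time_s", self.start_times)
        df.insert(2, "label", self.labels)
        return df


def extract_features(rec: Recording, config: FeatureConfig | None = None) -> FeatureMatrix:
    """One feature vector per non-overlapping window of the recording."""
    config = (config or FeatureConfig()).validate()
    win = int(round(config.window_length_s * rec.fs))
    needed = config.context_windows * config.window_length_s
    if rec.duration_s < needed:
        raise ExtractionError(
            f"recording of {rec.duration_s:.1f}s is shorter than "
            f"context_windows x window_length = {needed:.1f}s"
        )
    n_win = len(rec.samples) // win
    rows = np.empty((n_win, len(config.feature_set)))
    for i in range(n_win):
        feats = window_features(rec.samples[i * win : (i + 1) * win], rec.fs)
        rows[i] = [feats[name] for name in config.feature_set]
    return FeatureMatrix(
        values=rows,
        columns=list(config.feature_set),
        plant_ids=np.full(n_win, rec.plant_id),
        start_times=rec.t0 + np.arange(n_win) * config.window_length_s,
        labels=np.full(n_win, -1, dtype=np.int64),
        window_length_s=config.window_length_s,
    )


def label_features(fm: FeatureMatrix, rec: Recording, protocol: ProtocolParams) -> FeatureMatrix:
    """Same labelling rule as the window pipeline, applied to feature rows."""
    span = protocol.train_hours_per_state * 3600.0
    end = rec.t0 + rec.duration_s
    if protocol.mode == "post_symptom":
        s_start, s_end = rec.symptom_time, rec.symptom_time + span
    else:
        s_start, s_end = end - span, end
    w_start = fm.start_times
    w_end = fm.start_times + fm.window_length_s
    mask = fm.plant_ids == rec.plant_id
    labels = fm.labels.copy()
    labels[mask] = -1
    labels[mask & (w_start >= rec.t0) & (w_end <= rec.t0 + span)] = 0
    labels[mask & (w_start >= s_start) & (w_end <= s_end)] = 1
    return dataclasses.replace(fm, labels=labels)


def build_context_matrix(fm: FeatureMatrix, context_windows: int) -> FeatureMatrix:
    """Concatenate the features of the previous ``context_windows`` windows
    (causal context) into one row per eligible window, per plant."""
    if context_windows < 1:
        raise ConfigError(f"context_windows must be >= 1, got {context_windows}")
    k = context_windows
    cols = [f"ctx{j}_{name}" for j in range(k) for name in fm.columns]
    blocks, pids, starts, labels = [], [], [], []
    for pid in np.unique(fm.plant_ids):
        mask = fm.plant_ids == pid
        vals = fm.values[mask]
        st = fm.start_times[mask]
        lab = fm.labels[mask]
        if len(vals) < k:
            continue
        for i in range(k - 1, len(vals)):
            blocks.append(vals[i - k + 1 : i + 1].reshape(-1))
            pids.append(pid)
            starts.append(st[i])
            labels.append(lab[i])
    if not blocks:
        raise ExtractionError(
            f"no plant has {k} consecutive windows to build a context from"
        )
    return FeatureMatrix(
        values=np.vstack(blocks),
        columns=cols,
        plant_ids=np.asarray(pids),
        start_times=np.asarray(starts),
        labels=np.asarray(labels, dtype=np.int64),
        window_length_s=fm.window_length_s,
    )


_DEFAULT_GRID: dict[str, Sequence] = {
    "n_estimators": (50,),
    "max_depth": (2, 3),
    "learning_rate": (0.1,),
    "subsample": (1.0, 0.8),
}


def _grid_points(grid: dict[str, Sequence]) -> list[dict]:
    points = [{}]
    for key, values in grid.items():
        points = [{**p, key: v} for p in points for v in values]
    return points


def train_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    plant_ids: np.ndarray,
    tuning_grid: dict[str, Sequence] | None = None,
    feature_names: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[GradientBoostingClassifier, pd.DataFrame]:
    """Grid search scored by leave-one-plant-out mean accuracy, then refit on
    everything; returns the fitted ensemble and a gain-based feature ranking."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    plant_ids = np.asarray(plant_ids)
    plants = sorted(str(p) for p in np.unique(plant_ids))
    if len(plants) < 2:
        raise TuningError(f"plant-wise tuning needs >= 2 plants, got {len(plants)}")
    grid = tuning_grid or _DEFAULT_GRID
    best_score, best_params = -np.inf, None
    for params in _grid_points(grid):
        fold_accs = []
        for pid in plants:
            held = plant_ids == pid
            assert set(np.unique(plant_ids[held])).isdisjoint(
                np.unique(plant_ids[~held])
            ), "tuning folds must not mix plants"
            model = GradientBoostingClassifier(random_state=seed, **params)
            model.fit(features[~held], labels[~held])
            fold_accs.append(float((model.predict(features[held]) == labels[held]).mean()))
        score = float(np.mean(fold_accs))
        if score > best_score:
            best_score, best_params = score, params
    final = GradientBoostingClassifier(random_state=seed, **best_params)
    final.fit(features, labels)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(features.shape[1])
    ]
    ranking = (
        pd.DataFrame({"feature": names, "gain": final.feature_importances_})
        .sort_values("gain", ascending=False)
        .reset_index(drop=True)
    )
    ranking.attrs["cv_accuracy"] = best_score
    ranking.attrs["best_params"] = best_params
    ranking.attrs["n_folds"] = len(plants)
    return final, ranking
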