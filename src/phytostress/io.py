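"""Recording container and HDF5/CSV readers and writers.

The canonical on-disk container is HDF5: one group per plant holding a
``samples`` dataset plus ``fs``, ``plant_id``, ``stimulus_time`` and
``symptom_time`` attributes.  CSV (``time_s,value`` with ``# key=value``
header comments for metadata) is a convenience dialect for small extracts.
All timestamps are seconds since recording start.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np

__all__ = [
    "Recording",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_cohort",
    "write_cohort",
    "read_recording_csv",
    "write_recording_csv",
    "write_manifest",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the recording contract."""


@dataclasses.dataclass
class Recording:
    """One plant's univariate voltage trace with stress-timeline metadata.

    Attributes
    ----------
    plant_id : str
        Cohort-unique identifier (e.g. ``"B0"``).
    fs : float
        Sampling rate in Hz.
    samples : numpy.ndarray
        1-D float array, arbitrary voltage units.
    stimulus_time : float
        Seconds since start when the stressor was applied.
    symptom_time : float
        Seconds since start when visual symptoms appeared.
    t0 : float
        Start time, seconds (0 by convention).
    """

    plant_id: str
    fs: float
    samples: np.ndarray
    stimulus_time: float
    symptom_time: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        end = self.t0 + len(self.samples) / self.fs
        if not (self.t0 <= self.stimulus_time <= self.symptom_time <= end):
            raise ValueError(
                "timeline must satisfy t0 <= stimulus_time <= symptom_time <= end "
                f"(got t0={self.t0}, stimulus={self.stimulus_time}, "
                f"symptom={self.symptom_time}, end={end})"
            )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


_REQUIRED_ATTRS = ("fs", "plant_id", "stimulus_time", "symptom_time")


def _group_to_recording(grp: h5py.Group) -> Recording:
    for attr in _REQUIRED_ATTRS:
        if attr not in grp.attrs:
            raise FormatError(f"missing required attribute {attr!r} in {grp.name}")
    if "samples" not in grp:
        raise FormatError(f"missing 'samples' dataset in {grp.name}")
    plant_id = grp.attrs["plant_id"]
    if isinstance(plant_id, bytes):
        plant_id = plant_id.decode()
    return Recording(
        plant_id=str(plant_id),
        fs=float(grp.attrs["fs"]),
        samples=grp["samples"][()],
        stimulus_time=float(grp.attrs["stimulus_time"]),
        symptom_time=float(grp.attrs["symptom_time"]),
        t0=float(grp.attrs.get("t0", 0.0)),
    )


def _write_group(grp: h5py.Group, rec: Recording) -> None:
    grp.create_dataset("samples", data=rec.samples)
    grp.attrs["fs"] = rec.fs
    grp.attrs["plant_id"] = rec.plant_id
    grp.attrs["stimulus_time"] = rec.stimulus_time
    grp.attrs["symptom_time"] = rec.symptom_time
    grp.attrs["t0"] = rec.t0


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a single recording to an HDF5 file (group named by plant id)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        _write_group(f.create_group(rec.plant_id), rec)
    return path


def read_recording(path: str | Path, plant_id: str | None = None) -> Recording:
    """Read one recording; if ``plant_id`` is None the file must hold exactly one."""
    with h5py.File(path, "r") as f:
        names = sorted(f.keys())
        if plant_id is None:
            if len(names) != 1:
                raise FormatError(
                    f"{path} holds {len(names)} plants; pass plant_id to choose one"
                )
            plant_id = names[0]
        if plant_id not in f:
            raise FormatError(f"plant {plant_id!r} not found in {path}")
        return _group_to_recording(f[plant_id])


def write_cohort(recordings: list[Recording], path: str | Path) -> Path:
    path = Path(path)
    ids = [r.plant_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate plant_id in cohort")
    with h5py.File(path, "w") as f:
        for rec in recordings:
            _write_group(f.create_group(rec.plant_id), rec)
    return path


def read_cohort(path: str | Path) -> list[Recording]:
    with h5py.File(path, "r") as f:
        return [_group_to_recording(f[name]) for name in sorted(f.keys())]


def iter_cohort(path: str | Path) -> Iterator[Recording]:
    yield from read_cohort(path)


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# plant_id={rec.plant_id}\n")
        fh.write(f"# fs={rec.fs}\n")
        fh.write(f"# stimulus_time={rec.stimulus_time}\n")
        fh.write(f"# symptom_time={rec.symptom_time}\n")
        fh.write("time_s,value\n")
        times = rec.times
        for t, v in zip(times, rec.samples):
            fh.write(f"{t:.6f},{v:.9g}\n")
    return path


def read_recording_csv(path: str | Path) -> Recording:
    meta: dict[str, str] = {}
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            elif line.startswith("time_s"):
                continue
            else:
                t, _, v = line.partition(",")
                times.append(float(t))
                values.append(float(v))
    t_arr = np.asarray(times)
    if len(t_arr) >= 2:
        dt = np.diff(t_arr)
        if np.any(dt <= 0):
            raise FormatError("time column must be strictly increasing")
    for attr in _REQUIRED_ATTRS:
        if attr != "fs" and attr not in meta and attr != "plant_id":
            raise FormatError(f"missing required attribute {attr!r}")
    if "fs" in meta:
        fs = float(meta["fs"])
    elif len(t_arr) >= 2:
        fs = 1.0 / float(np.median(np.diff(t_arr)))
    else:
        raise FormatError("missing required attribute 'fs'")
    return Recording(
        plant_id=meta.get("plant_id", "unknown"),
        fs=fs,
        samples=np.asarray(values),
        stimulus_time=float(meta["stimulus_time"]),
        symptom_time=float(meta["symptom_time"]),
        t0=float(meta.get("t0", t_arr[0] if len(t_arr) else 0.0)),
    )


def write_manifest(path: str | Path, config: object, seed: int, **extra: object) -> Path:
    """Write a JSON manifest (config snapshot + seed + version) for a run."""
    from . import __version__

    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        cfg = dataclasses.asdict(config)
    else:
        cfg = config
    payload = {
        "package": "phytostress",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": cfg,
        **extra,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
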