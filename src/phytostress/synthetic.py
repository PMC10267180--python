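"""Synthetic multi-plant electrophysiology cohorts.

The real recordings behind this pipeline are proprietary, so this module
produces surrogate cohorts carrying the statistical structure the analysis
assumes: per-plant amplitude ranges spanning orders of magnitude, a slow
baseline drift, a seconds-scale signal texture whose character changes
between the normal and the stressed state, optional 50 Hz powerline
contamination, and white measurement noise.  The stressed texture is blended
in with a weight that ramps linearly from 0 at the stimulus time to the
plant's ``responsiveness`` at the visual-symptom time and stays constant
afterwards.

This is an emulation chosen to reproduce the qualitative multi-scale
appearance of greenhouse recordings — it is not a biophysical model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .config import ConfigError
from .utils import stable_seed

__all__ = [
    "TextureSpec",
    "DriftSpec",
    "PlantProfile",
    "CohortConfig",
    "default_profile",
    "generate_plant_recording",
    "generate_cohort",
]


@dataclasses.dataclass
class TextureSpec:
    """Seconds-scale oscillation + burst process for one plant state."""

    osc_low_hz: float
    osc_high_hz: float
    osc_amp: float
    burst_rate_per_min: float = 0.0
    burst_amp: float = 0.0
    burst_tau_s: float = 1.0


@dataclasses.dataclass
class DriftSpec:
    """Slow baseline wander: AR(1) knot process linearly interpolated."""

    corner_hz: float = 0.002
    amplitude: float = 0.5


@dataclasses.dataclass
class PlantProfile:
    plant_id: str
    amplitude_scale: float = 1.0
    drift_spec: DriftSpec = dataclasses.field(default_factory=DriftSpec)
    # Equal-amplitude textures in different bands: the state difference is
    # spectral (fast vs slow oscillation), not amplitude — per-plant range
    # stays independent of state, as the normalization experiments assume.
    texture_normal: TextureSpec = dataclasses.field(
        default_factory=lambda: TextureSpec(1.5, 5.0, 0.5, 2.0, 0.3, 0.3)
    )
    texture_stressed: TextureSpec = dataclasses.field(
        default_factory=lambda: TextureSpec(0.05, 0.4, 0.5, 2.0, 0.3, 2.0)
    )
    powerline_amp: float = 0.0
    noise_sd: float = 0.1
    responsiveness: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ConfigError(f"amplitude_scale must be positive, got {self.amplitude_scale}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.powerline_amp < 0:
            raise ConfigError(f"powerline_amp must be >= 0, got {self.powerline_amp}")
        if not (0.0 <= self.responsiveness <= 1.0):
            raise ConfigError(f"responsiveness must lie in [0, 1], got {self.responsiveness}")


@dataclasses.dataclass
class CohortConfig:
    n_plants: int = 16
    fs: float = 500.0
    duration_days: float = 15.0
    stimulus_day: float = 6.0
    symptom_lag_days: float = 5.0
    seed: int = 0
    # hyper-distribution knobs for generate_cohort
    amplitude_scale_range: tuple[float, float] = (0.1, 10.0)  # log-uniform
    responsive_fraction: float = 0.8
    responsiveness_floor: float = 0.8
    powerline_amp: float = 0.0

    def validate(self) -> "CohortConfig":
        if self.n_plants < 1:
            raise ConfigError(f"n_plants must be >= 1, got {self.n_plants}")
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if self.duration_days <= 0:
            raise ConfigError(f"duration_days must be positive, got {self.duration_days}")
        if not (0 < self.stimulus_day < self.stimulus_day + self.symptom_lag_days < self.duration_days):
            raise ConfigError(
                "timeline must satisfy 0 < stimulus_day < stimulus_day + symptom_lag_days "
                f"< duration_days (got stimulus_day={self.stimulus_day}, "
                f"symptom_lag_days={self.symptom_lag_days}, duration_days={self.duration_days})"
            )
        if not (0.0 <= self.responsive_fraction <= 1.0):
            raise ConfigError(
                f"responsive_fraction must lie in [0, 1], got {self.responsive_fraction}"
            )
        return self

    @property
    def duration_s(self) -> float:
        return self.duration_days * 86400.0

    @property
    def stimulus_s(self) -> float:
        return self.stimulus_day * 86400.0

    @property
    def symptom_s(self) -> float:
        return (self.stimulus_day + self.symptom_lag_days) * 86400.0


def default_profile(plant_id: str = "B0", **overrides: object) -> PlantProfile:
    """A reference profile with every generator process at its default level."""
    return PlantProfile(plant_id=plant_id, **overrides)  # type: ignore[arg-type]


def plant_ids(n: int) -> list[str]:
    """Device-letter/channel-number identifiers: B0..B7, C0..C7, D0.."""
    return [f"{chr(ord('B') + i // 8)}{i % 8}" for i in range(n)]


def _band_oscillation(rng: np.random.Generator, n: int, fs: float, spec: TextureSpec) -> np.ndarray:
    """Unit-variance band-limited noise in [osc_low, osc_high] Hz.

    Generated at a coarse rate (8 x upper band edge) where the Butterworth
    band-pass is numerically well conditioned, then linearly interpolated to
    the full rate; avoids filter instability for very low bands at 500 Hz.
    """
    if spec.osc_amp == 0:
        return np.zeros(n)
    fs_coarse = min(fs, max(8.0 * spec.osc_high_hz, 16.0 * spec.osc_low_hz, 1.0))
    n_coarse = max(int(np.ceil(n * fs_coarse / fs)) + 1, 16)
    white = rng.standard_normal(n_coarse)
    nyq = fs_coarse / 2.0
    lo = max(spec.osc_low_hz / nyq, 1e-5)
    hi = min(spec.osc_high_hz / nyq, 0.99)
    sos = sps.butter(2, [lo, hi], btype="bandpass", output="sos")
    osc = sps.sosfilt(sos, white)
    sd = osc.std()
    if sd > 0:
        osc = osc / sd
    t_coarse = np.arange(n_coarse) / fs_coarse
    t_fine = np.arange(n) / fs
    return np.interp(t_fine, t_coarse, osc)


def _bursts(rng: np.random.Generator, n: int, fs: float, spec: TextureSpec) -> np.ndarray:
    """Poisson train of exponentially decaying pulses with Laplace amplitudes."""
    if spec.burst_rate_per_min <= 0 or spec.burst_amp == 0:
        return np.zeros(n)
    rate_hz = spec.burst_rate_per_min / 60.0
    n_events = rng.poisson(rate_hz * n / fs)
    out = np.zeros(n)
    if n_events == 0:
        return out
    idx = rng.integers(0, n, size=n_events)
    amps = rng.laplace(0.0, spec.burst_amp, size=n_events)
    np.add.at(out, idx, amps)
    decay = np.exp(-1.0 / (spec.burst_tau_s * fs))
    return sps.lfilter([1.0], [1.0, -decay], out)


def _drift(rng: np.random.Generator, n: int, fs: float, spec: DriftSpec) -> np.ndarray:
    """Stationary AR(1) knot process, knots at 1/(5*corner_hz) spacing."""
    if spec.amplitude == 0:
        return np.zeros(n)
    knot_dt = 1.0 / (5.0 * spec.corner_hz)
    n_knots = max(int(np.ceil(n / fs / knot_dt)) + 2, 4)
    phi = 0.9
    innov = rng.standard_normal(n_knots)
    knots = np.empty(n_knots)
    knots[0] = innov[0]
    c = np.sqrt(1.0 - phi * phi)
    for k in range(1, n_knots):
        knots[k] = phi * knots[k - 1] + c * innov[k]
    t_knots = np.arange(n_knots) * knot_dt
    t = np.arange(n) / fs
    return spec.amplitude * np.interp(t, t_knots, knots)


def stress_weight(t: np.ndarray, stimulus_s: float, symptom_s: float, responsiveness: float) -> np.ndarray:
    """Blend weight: 0 before stimulus, linear ramp to ``responsiveness`` at
    symptom onset, constant after."""
    if symptom_s <= stimulus_s:
        return np.where(t >= stimulus_s, responsiveness, 0.0)
    ramp = (t - stimulus_s) / (symptom_s - stimulus_s)
    return responsiveness * np.clip(ramp, 0.0, 1.0)


def generate_plant_recording(profile: PlantProfile, config: CohortConfig, seed: int):
    """Synthesize one plant's full recording. Deterministic given ``seed``."""
    from .io import Recording

    config.validate()
    rng = np.random.default_rng(seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    tex_n = _band_oscillation(rng, n, fs, profile.texture_normal) * profile.texture_normal.osc_amp
    tex_n += _bursts(rng, n, fs, profile.texture_normal)
    tex_s = _band_oscillation(rng, n, fs, profile.texture_stressed) * profile.texture_stressed.osc_amp
    tex_s += _bursts(rng, n, fs, profile.texture_stressed)
    drift = _drift(rng, n, fs, profile.drift_spec)
    noise = profile.noise_sd * rng.standard_normal(n) if profile.noise_sd > 0 else np.zeros(n)

    w = stress_weight(t, config.stimulus_s, config.symptom_s, profile.responsiveness)
    texture = (1.0 - w) * tex_n + w * tex_s

    x = drift + texture + noise
    if profile.powerline_amp > 0:
        x = x + profile.powerline_amp * np.sin(2.0 * np.pi * 50.0 * t)
    x = profile.amplitude_scale * x

    return Recording(
        plant_id=profile.plant_id,
        fs=fs,
        samples=x,
        stimulus_time=config.stimulus_s,
        symptom_time=config.symptom_s,
    )


def cohort_profiles(config: CohortConfig) -> list[PlantProfile]:
    """Draw per-plant profiles from the cohort hyper-distributions.

    At least ``responsive_fraction`` of plants receive a responsiveness above
    ``responsiveness_floor``; the rest are weak responders, mirroring the
    resilient minority seen in real cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = plant_ids(config.n_plants)
    n_resp = int(np.ceil(config.responsive_fraction * config.n_plants))
    responsive = np.zeros(config.n_plants, dtype=bool)
    responsive[rng.permutation(config.n_plants)[:n_resp]] = True

    lo, hi = config.amplitude_scale_range
    profiles = []
    for i, pid in enumerate(ids):
        prng = np.random.default_rng(stable_seed(config.seed, "profile", pid))
        amp = float(np.exp(prng.uniform(np.log(lo), np.log(hi))))
        if responsive[i]:
            resp = float(prng.uniform(config.responsiveness_floor, 1.0))
        else:
            resp = float(prng.uniform(0.0, 0.3))
        profiles.append(
            PlantProfile(
                plant_id=pid,
                amplitude_scale=amp,
                powerline_amp=config.powerline_amp,
                responsiveness=resp,
            )
        )
    return profiles


def generate_cohort(config: CohortConfig):
    """Generate ``n_plants`` recordings with distinct ids; seeded per plant."""
    config.validate()
    if config.n_plants < 2:
        raise ConfigError(f"a cohort needs at least 2 plants, got {config.n_plants}")
    profiles = cohort_profiles(config)
    ids = [p.plant_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate plant_id in cohort")
    return [
        generate_plant_recording(p, config, stable_seed(config.seed, "recording", p.plant_id))
        for p in profiles
    ]
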