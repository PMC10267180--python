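"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from phytostress.config import ExperimentConfig, ProtocolParams, TrainBudget
from phytostress.io import Recording
from phytostress.models import ArchitectureSpec
from phytostress.synthetic import CohortConfig, generate_cohort


def tiny_encoder_spec(input_length: int) -> ArchitectureSpec:
    """Desk-scale encoder: same topology as the default, smaller filters."""
    return ArchitectureSpec(
        kind="encoder",
        input_length=input_length,
        encoder_filters=(8, 16, 16),
        encoder_kernels=(3, 5, 7),
        encoder_dropout=0.1,
    )


def desk_cohort_config(**overrides) -> CohortConfig:
    """Scaled-down cohort (lower fs, hours instead of days) used throughout
    the suite; the generator itself is scale-free."""
    defaults = dict(
        n_plants=8,
        fs=50.0,
        duration_days=0.4,
        stimulus_day=0.1,
        symptom_lag_days=0.05,
        seed=7,
        responsive_fraction=1.0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def desk_experiment_config(**overrides) -> ExperimentConfig:
    cfg = ExperimentConfig(seed=7)
    cfg.protocol = ProtocolParams(train_hours_per_state=1.5, mode="post_symptom",
                                  test_plants=["B6", "B7"])
    cfg.train_budget = TrainBudget(epochs=6)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def desk_cohort():
    """8 responsive plants at desk scale; shared (read-only) across tests."""
    return generate_cohort(desk_cohort_config())


@pytest.fixture(scope="session")
def desk_recording(desk_cohort):
    return desk_cohort[0]


@pytest.fixture()
def toy_recording():
    """Short deterministic recording for structural tests."""
    rng = np.random.default_rng(0)
    fs = 50.0
    n = int(120 * fs)
    return Recording(
        plant_id="B0",
        fs=fs,
        samples=rng.standard_normal(n),
        stimulus_time=40.0,
        symptom_time=80.0,
    )


@pytest.fixture(scope="session")
def toy_separable_windows():
    """Linearly separable windows (class means +-1, sd 0.1) over 4 plants."""
    from phytostress.preprocessing import WindowSet

    rng = np.random.default_rng(0)
    n, t = 400, 80
    x = np.concatenate([rng.normal(-1, 0.1, (n // 2, t)), rng.normal(1, 0.1, (n // 2, t))])
    y = np.concatenate([np.zeros(n // 2, int), np.ones(n // 2, int)])
    perm = rng.permutation(n)
    return WindowSet(
        windows=x[perm],
        plant_ids=np.array([f"P{i % 4}" for i in range(n)]),
        start_times=np.arange(n) * 16.0,
        labels=y[perm],
        fs_effective=5.0,
        window_length_s=16.0,
    )
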