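"""The four window-classifier architectures and their training surface.

The attention encoder is the canonical model: three blocks of
[1-D convolution -> instance normalization -> PReLU -> dropout] with
max-pooling after the first two, then a channel split where a time-wise
softmax on one half weights the other half, instance normalization, and a
dense softmax head.  MLP, FCN and ResNet are the comparison architectures.

Exact filter counts / dense widths are configurable in ``ArchitectureSpec``;
the defaults follow common reference conventions for these architectures.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .config import ConfigError
from .nnet import (
    AttentionSplit,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool,
    InstanceNorm1d,
    MaxPool1d,
    Network,
    PReLU,
    ReLU,
    ResidualBlock,
    train_network,
)
from .preprocessing import WindowSet

__all__ = [
    "ArchitectureSpec",
    "TrainedClassifier",
    "TrainingError",
    "build_model",
    "train",
    "predict_confidences",
    "predict_trace",
    "save_classifier",
    "load_classifier",
]


class TrainingError(ValueError):
    """Raised when the training set violates the contract (e.g. one class)."""


@dataclasses.dataclass
class ArchitectureSpec:
    kind: str = "encoder"
    input_length: int = 800
    n_classes: int = 2
    # encoder
    encoder_filters: tuple[int, ...] = (128, 256, 512)
    encoder_kernels: tuple[int, ...] = (5, 11, 21)
    encoder_dropout: float = 0.2
    pool: int = 2
    # mlp
    mlp_hidden: tuple[int, ...] = (500, 500, 500)
    mlp_dropout: tuple[float, ...] = (0.1, 0.2, 0.2, 0.3)
    # fcn / resnet
    fcn_filters: tuple[int, ...] = (128, 256, 128)
    fcn_kernels: tuple[int, ...] = (8, 5, 3)
    resnet_filters: tuple[int, ...] = (64, 128, 128)
    resnet_kernels: tuple[int, int, int] = (8, 5, 3)

    def validate(self) -> "ArchitectureSpec":
        if self.kind not in ("mlp", "fcn", "resnet", "encoder"):
            raise ConfigError(f"unknown architecture kind {self.kind!r}")
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.input_length < 1:
            raise ConfigError(f"input_length must be positive, got {self.input_length}")
        kernels = {
            "encoder": self.encoder_kernels,
            "fcn": self.fcn_kernels,
            "resnet": self.resnet_kernels,
            "mlp": (1,),
        }[self.kind]
        if self.input_length <= max(kernels):
            raise ConfigError(
                f"input_length {self.input_length} must exceed the largest kernel {max(kernels)}"
            )
        if self.kind == "encoder":
            if len(self.encoder_filters) != len(self.encoder_kernels):
                raise ConfigError("encoder_filters and encoder_kernels must have equal length")
            if self.encoder_filters[-1] % 2:
                raise ConfigError(
                    "the encoder's final filter count must be even (it is split in "
                    f"half by the attention), got {self.encoder_filters[-1]}"
                )
        if self.kind == "mlp" and len(self.mlp_dropout) != len(self.mlp_hidden) + 1:
            raise ConfigError("mlp_dropout must list one rate per hidden layer plus one")
        return self


@dataclasses.dataclass
class TrainedClassifier:
    spec: ArchitectureSpec
    net: Network
    training_manifest: dict

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def _build_encoder(spec: ArchitectureSpec, rng: np.random.Generator) -> Network:
    layers: list = []
    c_in = 1
    t = spec.input_length
    n_blocks = len(spec.encoder_filters)
    for i, (c_out, k) in enumerate(zip(spec.encoder_filters, spec.encoder_kernels)):
        layers += [
            Conv1d(c_in, c_out, k, rng),
            InstanceNorm1d(c_out),
            PReLU(c_out),
            Dropout(spec.encoder_dropout),
        ]
        c_in = c_out
        if i < n_blocks - 1:  # max-pool between blocks, not after the last
            layers.append(MaxPool1d(spec.pool))
            t = t // spec.pool
    half = spec.encoder_filters[-1] // 2
    layers += [
        AttentionSplit(),
        InstanceNorm1d(half),
        Flatten(),
        Dense(half * t, spec.n_classes, rng),
    ]
    return Network(layers, spec.input_length, spec.n_classes)


def _build_mlp(spec: ArchitectureSpec, rng: np.random.Generator) -> Network:
    layers: list = [Flatten()]
    n_in = spec.input_length
    for width, p in zip(spec.mlp_hidden, spec.mlp_dropout):
        layers += [Dropout(p), Dense(n_in, width, rng), ReLU()]
        n_in = width
    layers += [Dropout(spec.mlp_dropout[-1]), Dense(n_in, spec.n_classes, rng)]
    return Network(layers, spec.input_length, spec.n_classes)


def _build_fcn(spec: ArchitectureSpec, rng: np.random.Generator) -> Network:
    layers: list = []
    c_in = 1
    for c_out, k in zip(spec.fcn_filters, spec.fcn_kernels):
        layers += [Conv1d(c_in, c_out, k, rng), BatchNorm1d(c_out), ReLU()]
        c_in = c_out
    layers += [GlobalAvgPool(), Dense(c_in, spec.n_classes, rng)]
    return Network(layers, spec.input_length, spec.n_classes)


def _build_resnet(spec: ArchitectureSpec, rng: np.random.Generator) -> Network:
    layers: list = []
    c_in = 1
    for c_out in spec.resnet_filters:
        layers.append(ResidualBlock(c_in, c_out, spec.resnet_kernels, rng))
        c_in = c_out
    layers += [GlobalAvgPool(), Dense(c_in, spec.n_classes, rng)]
    return Network(layers, spec.input_length, spec.n_classes)


_BUILDERS = {
    "encoder": _build_encoder,
    "mlp": _build_mlp,
    "fcn": _build_fcn,
    "resnet": _build_resnet,
}


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """Instantiate an untrained classifier with seeded initialization."""
    spec.validate()
    rng = np.random.default_rng(seed)
    return _BUILDERS[spec.kind](spec, rng)


def train(
    spec: ArchitectureSpec,
    train_windows: WindowSet,
    epochs: int,
    seed: int,
    batch_size: int = 64,
    lr: float = 1e-3,
    max_seconds: float | None = None,
) -> TrainedClassifier:
    """Fit a window classifier; deterministic given (spec, data, seed).

    Class imbalance is handled with inverse-frequency class weights.
    """
    labels = train_windows.labels
    if np.any(labels == -1):
        raise TrainingError("training windows must be labelled 0/1 (found -1)")
    classes, counts = np.unique(labels, return_counts=True)
    if epochs > 0 and len(classes) < 2:
        raise TrainingError(f"training set contains a single class {classes.tolist()}")
    if train_windows.window_samples != spec.input_length:
        raise ValueError(
            f"windows have {train_windows.window_samples} samples, "
            f"spec.input_length is {spec.input_length}"
        )
    net = build_model(spec, seed=seed)
    weights = None
    if len(classes) == 2:
        weights = np.zeros(2)
        weights[classes] = counts.sum() / (2.0 * counts)
    manifest = train_network(
        net,
        train_windows.windows,
        labels,
        epochs=epochs,
        seed=seed,
        batch_size=batch_size,
        lr=lr,
        class_weights=weights,
        max_seconds=max_seconds,
    )
    manifest.update(
        architecture=spec.kind,
        n_parameters=net.n_parameters(),
        n_train_windows=train_windows.n_windows,
        optimizer="adam",
        loss="weighted cross-entropy",
    )
    return TrainedClassifier(spec=spec, net=net, training_manifest=manifest)


def predict_confidences(clf: TrainedClassifier, windows: WindowSet, batch_size: int = 64) -> np.ndarray:
    """Stressed-class probability per window, order-preserving.

    Inference is deterministic (dropout off) and batching-invariant.
    """
    if windows.window_samples != clf.spec.input_length:
        raise ValueError(
            f"windows have {windows.window_samples} samples, "
            f"model expects {clf.spec.input_length}"
        )
    proba = clf.net.predict_proba(windows.windows, batch_size=batch_size)
    return proba[:, 1]


def predict_trace(clf: TrainedClassifier, windows: WindowSet, batch_size: int = 64):
    """Per-window confidences for a single plant as a time-ordered trace."""
    from .fusion import PredictionTrace

    pids = np.unique(windows.plant_ids)
    if len(pids) != 1:
        raise ValueError(f"predict_trace expects windows from one plant, got {pids.tolist()}")
    conf = predict_confidences(clf, windows, batch_size=batch_size)
    return PredictionTrace(
        plant_id=str(pids[0]),
        start_times=windows.start_times.copy(),
        confidences=conf,
        window_length_s=windows.window_length_s,
    )


def save_classifier(clf: TrainedClassifier, path: str | Path) -> Path:
    """Checkpoint: npz of parameters + JSON sidecar with spec and manifest."""
    path = Path(path)
    state = {f"p{i}": v for i, v in enumerate(clf.net.get_state())}
    np.savez(path.with_suffix(".npz"), **state)
    meta = {
        "spec": dataclasses.asdict(clf.spec),
        "training_manifest": clf.training_manifest,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return path.with_suffix(".npz")


def load_classifier(path: str | Path) -> TrainedClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_d = meta["spec"]
    for key in ("encoder_filters", "encoder_kernels", "mlp_hidden", "mlp_dropout",
                "fcn_filters", "fcn_kernels", "resnet_filters", "resnet_kernels"):
        spec_d[key] = tuple(spec_d[key])
    spec = ArchitectureSpec(**spec_d)
    net = build_model(spec, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        net.set_state([data[f"p{i}"] for i in range(len(data.files))])
    return TrainedClassifier(spec=spec, net=net, training_manifest=meta["training_manifest"])
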