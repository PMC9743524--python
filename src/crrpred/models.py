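"""Meta-model builders and the training contract.

Two model families are built: dense networks (FFNN) consuming
epigenomic feature vectors, and convolutional networks (CNN) consuming
one-hot 200-nt sequence windows, each in a fixed variant and a
Bayesian-optimizable variant whose configuration is a point in the
corresponding search space. A convolutional comparator architecture
(4conv2pool4norm) is included for sequence-model benchmarking.

Convolutions use same-padding and stride 1; the hg19 CNN treats the
one-hot input as a length-200 sequence with 4 channels, while the hg38
CNN treats it as a 200x4 single-channel 2-D array so kernels can span
both sequence positions and nucleotide channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn.network import bce_loss  # noqa: F401  (re-exported: the training loss)
from .spaces import SearchSpace, meta_model_space

__all__ = [
    "TrainingSettings", "ModelConfig", "bce_loss",
    "build_fixed_ffnn", "build_bayesian_ffnn",
    "build_fixed_cnn", "build_bayesian_cnn", "build_deepenhancer",
    "build_model", "train",
]


@dataclass(frozen=True)
class TrainingSettings:
    optimizer: str = "sgd"
    learning_rate: float = 0.5
    decay: float = 0.0
    l1: float = 0.0
    l2: float = 0.0
    batch_size: int = 32
    max_epochs: int = 64
    patience: int = 5


@dataclass(frozen=True)
class ModelConfig:
    """A concrete point in a meta-model's hyperparameter space."""

    kind: str  # fixed_ffnn | bayes_ffnn_hg19 | bayes_ffnn_hg38 | fixed_cnn |
    #            bayes_cnn_hg19 | bayes_cnn_hg38 | deepenhancer
    params: dict = field(default_factory=dict)
    seed: int = 0


def _seq_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def build_fixed_ffnn(input_dim: int, seed: int = 0) -> tuple[nn.Sequential, TrainingSettings]:
    """Baseline dense net: 16-4-2 ReLU pyramid with a sigmoid output."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = _seq_rng(seed)
    layers: list[nn.Layer] = []
    prev = input_dim
    for width in (16, 4, 2):
        layers += [nn.Dense(prev, width, rng), nn.ReLU()]
        prev = width
    layers += [nn.Dense(prev, 1, rng), nn.Sigmoid()]
    settings = TrainingSettings(
        optimizer="sgd", learning_rate=0.5, decay=0.1, l2=0.0,
        batch_size=32, max_epochs=64,
    )
    return nn.Sequential(layers, (input_dim,)), settings


def _sgd_settings(params: dict, max_epochs_cap: int | None = None) -> TrainingSettings:
    epochs = int(round(params["epochs"]))
    if max_epochs_cap is not None:
        epochs = min(epochs, max_epochs_cap)
    return TrainingSettings(
        optimizer="sgd",
        learning_rate=float(params["learning_rate"]),
        decay=float(params["decay"]),
        l2=float(params["l2"]),
        batch_size=int(round(params["batch_size"])),
        max_epochs=epochs,
    )


def build_bayesian_ffnn(
    config: ModelConfig,
    input_dim: int,
    space: SearchSpace | None = None,
) -> tuple[nn.Sequential, TrainingSettings]:
    """Instantiate a dense meta-model configuration.

    hg19 variant: 0-3 plain ReLU layers with nested width choices.
    hg38 variant: 4 groups of 0-3 Dense+BatchNorm+ReLU layers (width 0
    omits the layer) each closed by a dropout (rate 0 omits it). The
    all-empty hg38 configuration degenerates to logistic regression.
    """
    version = {"bayes_ffnn_hg19": "hg19", "bayes_ffnn_hg38": "hg38"}.get(config.kind)
    if version is None:
        raise ValueError(f"not a Bayesian FFNN config: {config.kind!r}")
    space = space or meta_model_space(config.kind)
    space.validate(config.params)
    p = config.params
    rng = _seq_rng(config.seed)
    layers: list[nn.Layer] = []
    prev = input_dim
    if version == "hg19":
        for i in range(1, p["n_dense"] + 1):
            width = p[f"units_{i}"]
            layers += [nn.Dense(prev, width, rng), nn.ReLU()]
            prev = width
    else:
        for g in range(1, 5):
            for i in range(1, p[f"group{g}_layers"] + 1):
                width = p[f"group{g}_units_{i}"]
                if width == 0:
                    continue
                layers += [nn.Dense(prev, width, rng), nn.BatchNorm(width), nn.ReLU()]
                prev = width
            rate = p[f"group{g}_dropout"]
            if rate > 0:
                layers.append(nn.Dropout(rate, rng))
    layers += [nn.Dense(prev, 1, rng), nn.Sigmoid()]
    return nn.Sequential(layers, (input_dim,)), _sgd_settings(p)


_NADAM = TrainingSettings(
    optimizer="nadam", learning_rate=0.002, batch_size=256, max_epochs=100
)


def build_fixed_cnn(
    window_length: int = 200, seed: int = 0
) -> tuple[nn.Sequential, TrainingSettings]:
    """Baseline sequence CNN: three conv blocks, then a small dense head.

    Blocks: 3x conv(64, k5) + max-pool 2; 3x conv(128, k3) + max-pool 2;
    3x conv(128, k3) + average-pool 2. Head: dropout 0.5, two dense
    layers of 10 (ReLU), dropout 0.5, sigmoid output. Nadam, lr 0.002,
    batch 256, 100 epochs.
    """
    if window_length < 16:
        raise ValueError("window_length must be >= 16")
    rng = _seq_rng(seed)
    layers: list[nn.Layer] = []
    ch = 4
    for filters, kernel, pool in ((64, 5, "max"), (128, 3, "max"), (128, 3, "avg")):
        for _ in range(3):
            layers += [nn.Conv1D(ch, filters, kernel, rng), nn.ReLU()]
            ch = filters
        layers.append(nn.MaxPool1D(2) if pool == "max" else nn.AvgPool1D(2))
    length = window_length // 2 // 2 // 2
    layers += [nn.Dropout(0.5, rng), nn.Flatten()]
    prev = length * ch
    for _ in range(2):
        layers += [nn.Dense(prev, 10, rng), nn.ReLU()]
        prev = 10
    layers += [nn.Dropout(0.5, rng), nn.Dense(prev, 1, rng), nn.Sigmoid()]
    return nn.Sequential(layers, (window_length, 4)), _NADAM


def build_bayesian_cnn(
    config: ModelConfig,
    window_length: int = 200,
    space: SearchSpace | None = None,
) -> tuple[nn.Sequential, TrainingSettings]:
    """Instantiate a convolutional meta-model configuration.

    hg19 variant: fixed topology (4 conv+BN layers, two max-pools, two
    dense layers with 0.1 dropout) searched over filter counts, the
    fourth kernel size, and dense widths; 1-D input (length, 4 ch).
    hg38 variant: 0-2 conv groups and 0-2 dense groups over the 200x4
    single-channel 2-D input; zero-valued counts omit components, so the
    empty configuration is flatten -> sigmoid.
    """
    version = {"bayes_cnn_hg19": "hg19", "bayes_cnn_hg38": "hg38"}.get(config.kind)
    if version is None:
        raise ValueError(f"not a Bayesian CNN config: {config.kind!r}")
    space = space or meta_model_space(config.kind)
    space.validate(config.params)
    p = config.params
    rng = _seq_rng(config.seed)
    layers: list[nn.Layer] = []
    if version == "hg19":
        ch = 4
        for i in (1, 2, 3):
            f = p[f"filters_{i}"]
            layers += [nn.Conv1D(ch, f, 5, rng), nn.BatchNorm(f), nn.ReLU()]
            ch = f
        layers.append(nn.MaxPool1D(2))
        f = p["filters_4"]
        layers += [nn.Conv1D(ch, f, p["kernel_4"], rng), nn.BatchNorm(f), nn.ReLU()]
        layers.append(nn.MaxPool1D(2))
        layers.append(nn.Flatten())
        prev = (window_length // 2 // 2) * f
        for name in ("dense_1", "dense_2"):
            layers += [nn.Dense(prev, p[name], rng), nn.ReLU(), nn.Dropout(0.1, rng)]
            prev = p[name]
        layers += [nn.Dense(prev, 1, rng), nn.Sigmoid()]
        settings = _NADAM
        return nn.Sequential(layers, (window_length, 4)), settings
    # hg38: (window, 4, 1) single-channel 2-D input
    h, w, ch = window_length, 4, 1
    for g in range(1, p["n_conv_groups"] + 1):
        kernel = (p[f"conv{g}_kernel_h"], p[f"conv{g}_kernel_w"])
        built = False
        for i in range(1, p[f"conv{g}_layers"] + 1):
            f = p[f"conv{g}_filters_{i}"]
            if f == 0:
                continue
            layers += [nn.Conv2D(ch, f, kernel, rng), nn.BatchNorm(f), nn.ReLU()]
            ch = f
            built = True
        if built:
            pool = (p[f"conv{g}_pool_h"], p[f"conv{g}_pool_w"])
            layers.append(nn.MaxPool2D(pool))
            h, w = max(h // pool[0], 1), max(w // pool[1], 1)
            rate = p[f"conv{g}_dropout"]
            if rate > 0:
                layers.append(nn.Dropout(rate, rng))
    layers.append(nn.Flatten())
    prev = h * w * ch
    for g in range(1, p["n_dense_groups"] + 1):
        for i in range(1, p[f"dense{g}_layers"] + 1):
            units = p[f"dense{g}_units_{i}"]
            if units == 0:
                continue
            layers += [nn.Dense(prev, units, rng), nn.BatchNorm(units), nn.ReLU()]
            prev = units
        rate = p[f"dense{g}_dropout"]
        if rate > 0:
            layers.append(nn.Dropout(rate, rng))
    layers += [nn.Dense(prev, 1, rng), nn.Sigmoid()]
    settings = replace(_NADAM, l1=1e-4, l2=1e-4)
    return nn.Sequential(layers, (window_length, 4, 1)), settings


def build_deepenhancer(
    window_length: int = 200, seed: int = 0
) -> tuple[nn.Sequential, TrainingSettings]:
    """The 4conv2pool4norm comparator network with a sigmoid head.

    Two conv(128, k8)+BN blocks and a max-pool, two conv(64, k3)+BN
    blocks and a max-pool, then dense 256 (ReLU), dropout 0.5, dense 128
    (ReLU) and a single sigmoid output replacing the original two-way
    softmax. Adam, lr 1e-4 with decay, at most 30 epochs with early
    stopping. The original 300-nt window is parameterized; the default
    matches the 200-nt dataset windows.
    """
    if window_length < 16:
        raise ValueError("window_length must be >= 16")
    rng = _seq_rng(seed)
    layers: list[nn.Layer] = []
    ch = 4
    for filters, kernel in ((128, 8), (128, 8)):
        layers += [nn.Conv1D(ch, filters, kernel, rng), nn.BatchNorm(filters), nn.ReLU()]
        ch = filters
    layers.append(nn.MaxPool1D(2))
    for filters, kernel in ((64, 3), (64, 3)):
        layers += [nn.Conv1D(ch, filters, kernel, rng), nn.BatchNorm(filters), nn.ReLU()]
        ch = filters
    layers.append(nn.MaxPool1D(2))
    layers.append(nn.Flatten())
    prev = (window_length // 2 // 2) * ch
    layers += [nn.Dense(prev, 256, rng), nn.ReLU(), nn.Dropout(0.5, rng)]
    layers += [nn.Dense(256, 128, rng), nn.ReLU()]
    layers += [nn.Dense(128, 1, rng), nn.Sigmoid()]
    settings = TrainingSettings(
        optimizer="adam", learning_rate=1e-4, decay=0.01,
        batch_size=256, max_epochs=30, patience=5,
    )
    return nn.Sequential(layers, (window_length, 4)), settings


def build_model(
    config: ModelConfig,
    input_shape: tuple[int, ...],
    space: SearchSpace | None = None,
) -> tuple[nn.Sequential, TrainingSettings]:
    """Dispatch on the architecture kind. Construction is pure: the same
    config always yields a structurally identical, identically
    initialized model."""
    kind = config.kind
    if kind == "fixed_ffnn":
        (dim,) = input_shape
        return build_fixed_ffnn(dim, config.seed)
    if kind in ("bayes_ffnn_hg19", "bayes_ffnn_hg38"):
        (dim,) = input_shape
        return build_bayesian_ffnn(config, dim, space)
    if kind == "fixed_cnn":
        return build_fixed_cnn(input_shape[0], config.seed)
    if kind in ("bayes_cnn_hg19", "bayes_cnn_hg38"):
        return build_bayesian_cnn(config, input_shape[0], space)
    if kind == "deepenhancer":
        return build_deepenhancer(input_shape[0], config.seed)
    raise ValueError(f"unknown architecture kind {config.kind!r}")


def train(
    model: nn.Sequential,
    settings: TrainingSettings,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    seed: int = 0,
    max_epochs: int | None = None,
) -> nn.TrainingHistory:
    """Train on the BCE loss under the architecture's settings.

    ``max_epochs`` optionally caps the configured epoch count (used by
    desk-scale profiles). Deterministic given the seed in
    single-threaded execution.
    """
    y = np.asarray(y_train)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    optimizer = nn.make_optimizer(
        settings.optimizer, settings.learning_rate,
        decay=settings.decay, l1=settings.l1, l2=settings.l2,
    )
    epochs = settings.max_epochs if max_epochs is None else min(settings.max_epochs, max_epochs)
    return nn.train_network(
        model, optimizer, x_train, y_train, x_val, y_val,
        batch_size=settings.batch_size, max_epochs=epochs,
        patience=settings.patience, seed=seed,
    )
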