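"""Hyperparameter search spaces with tree-structured conditionality.

A space is an ordered list of named dimensions — discrete choice sets,
integer ranges, or continuous intervals. A dimension may be conditional
on earlier dimensions (e.g. the width of dense layer 3 only exists when
the layer count is at least 3); inactive dimensions are absent from a
configuration, not zeroed.

The concrete spaces mirror the published meta-model definitions: the
hg19 spaces are small and mostly discrete, the hg38 spaces are group-
structured and much wider, with zero-valued widths/filter counts
denoting omitted layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Choice", "IntRange", "FloatRange", "SearchSpace", "ConfigError",
    "ffnn_hg19_space", "ffnn_hg38_space", "cnn_hg19_space", "cnn_hg38_space",
    "meta_model_space",
]


class ConfigError(ValueError):
    """A configuration lies outside its declared space."""

    def __init__(self, dimension: str, message: str):
        super().__init__(f"dimension {dimension!r}: {message}")
        self.dimension = dimension


@dataclass(frozen=True)
class _Dim:
    name: str
    active_when: Callable[[dict], bool] | None = None

    def is_active(self, partial: dict) -> bool:
        return self.active_when is None or self.active_when(partial)


@dataclass(frozen=True)
class Choice(_Dim):
    options: tuple = ()

    def __post_init__(self):
        if not self.options:
            raise ValueError(f"{self.name}: empty choice set")

    def sample(self, rng: np.random.Generator):
        return self.options[int(rng.integers(len(self.options)))]

    def check(self, value):
        if value not in self.options:
            raise ConfigError(self.name, f"{value!r} not in {self.options}")


@dataclass(frozen=True)
class IntRange(_Dim):
    lo: int = 0
    hi: int = 0  # inclusive

    def sample(self, rng: np.random.Generator):
        return int(rng.integers(self.lo, self.hi + 1))

    def check(self, value):
        if not (isinstance(value, (int, np.integer)) and self.lo <= value <= self.hi):
            raise ConfigError(self.name, f"{value!r} outside [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class FloatRange(_Dim):
    lo: float = 0.0
    hi: float = 1.0

    def sample(self, rng: np.random.Generator):
        return float(rng.uniform(self.lo, self.hi))

    def check(self, value):
        if not (np.isfinite(value) and self.lo <= value <= self.hi):
            raise ConfigError(self.name, f"{value!r} outside [{self.lo}, {self.hi}]")


@dataclass
class SearchSpace:
    name: str
    dimensions: list = field(default_factory=list)

    def __post_init__(self):
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dimension names")
        self._by_name = {d.name: d for d in self.dimensions}

    def sample(self, rng: np.random.Generator) -> dict:
        """Uniform draw over active dimensions, in declaration order."""
        config: dict = {}
        for dim in self.dimensions:
            if dim.is_active(config):
                config[dim.name] = dim.sample(rng)
        return config

    def active_dimensions(self, config: dict) -> list:
        out = []
        partial: dict = {}
        for dim in self.dimensions:
            if dim.is_active(partial):
                out.append(dim)
                if dim.name in config:
                    partial[dim.name] = config[dim.name]
        return out

    def validate(self, config: dict) -> None:
        """Check values and the activity pattern; name the offender."""
        partial: dict = {}
        for dim in self.dimensions:
            if dim.is_active(partial):
                if dim.name not in config:
                    raise ConfigError(dim.name, "active dimension missing")
                dim.check(config[dim.name])
                partial[dim.name] = config[dim.name]
            elif dim.name in config:
                raise ConfigError(dim.name, "inactive dimension present")
        extra = set(config) - set(partial)
        if extra:
            raise ConfigError(sorted(extra)[0], "not a dimension of this space")

    def __contains__(self, config: dict) -> bool:
        try:
            self.validate(config)
        except ConfigError:
            return False
        return True


def _sgd_learning_dims(epochs: tuple[int, int]) -> list:
    return [
        FloatRange("learning_rate", lo=0.1, hi=0.5),
        FloatRange("decay", lo=0.01, hi=0.2),
        FloatRange("l2", lo=0.0, hi=0.1),
        FloatRange("batch_size", lo=32, hi=256),
        FloatRange("epochs", lo=epochs[0], hi=epochs[1]),
    ]


def ffnn_hg19_space(epochs: tuple[int, int] = (32, 1000)) -> SearchSpace:
    """Pyramidal dense meta-model: up to 3 ReLU layers with nested width sets.

    ``epochs`` narrows the trained-epoch interval for desk-scale runs;
    the full protocol uses (32, 1000).
    """
    def at_least(k):
        return lambda c, k=k: c.get("n_dense", 0) >= k

    dims = [
        Choice("n_dense", options=(0, 1, 2, 3)),
        Choice("units_1", active_when=at_least(1), options=(256, 128, 64, 32, 16, 8, 4, 2)),
        Choice("units_2", active_when=at_least(2), options=(128, 64, 32, 16, 8, 4, 2)),
        Choice("units_3", active_when=at_least(3), options=(64, 32, 16, 8, 4, 2)),
    ]
    return SearchSpace("ffnn_hg19", dims + _sgd_learning_dims(epochs))


FFNN_HG38_GROUPS = 4


def ffnn_hg38_space(epochs: tuple[int, int] = (32, 1000)) -> SearchSpace:
    """Group-structured dense meta-model: 4 groups of 0-3 BN+ReLU layers.

    Widths are searched in {0..256} with 0 meaning the layer is omitted;
    each group ends in a dropout whose rate 0 removes it. Rectangular
    architectures (equal consecutive widths) are allowed.
    """
    dims: list = []
    for g in range(1, FFNN_HG38_GROUPS + 1):
        dims.append(Choice(f"group{g}_layers", options=(0, 1, 2, 3)))
        for i in range(1, 4):
            dims.append(
                IntRange(
                    f"group{g}_units_{i}",
                    active_when=lambda c, g=g, i=i: c.get(f"group{g}_layers", 0) >= i,
                    lo=0, hi=256,
                )
            )
        dims.append(FloatRange(f"group{g}_dropout", lo=0.0, hi=0.5))
    return SearchSpace("ffnn_hg38", dims + _sgd_learning_dims(epochs))


def cnn_hg19_space() -> SearchSpace:
    """Fixed-topology convolutional meta-model searched over filter counts.

    Three conv+BN layers (kernel 5) with a max-pool, one conv+BN layer
    with kernel in {5, 10} and a max-pool, then two dense layers with
    fixed 0.1 dropout. Learning parameters are fixed (Nadam, lr 0.002,
    batch 256, 100 epochs) and therefore not dimensions.
    """
    f = (32, 64, 128)
    dims = [
        Choice("filters_1", options=f),
        Choice("filters_2", options=f),
        Choice("filters_3", options=f),
        Choice("filters_4", options=f),
        Choice("kernel_4", options=(5, 10)),
        Choice("dense_1", options=(10, 32, 64)),
        Choice("dense_2", options=(10, 32, 64)),
    ]
    return SearchSpace("cnn_hg19", dims)


def cnn_hg38_space() -> SearchSpace:
    """Wide 2-D convolutional meta-model over the 200x4 one-hot array.

    0-2 convolutional groups (each 0-3 conv+BN+ReLU layers, a 2-D
    max-pool and a dropout) followed by 0-2 dense groups. Kernels span
    2-8 sequence positions by 1-2 channel rows. Zero filter/unit counts
    omit the layer.
    """
    dims: list = [Choice("n_conv_groups", options=(0, 1, 2))]
    for g in (1, 2):
        def grp_on(c, g=g):
            return c.get("n_conv_groups", 0) >= g

        dims.append(Choice(f"conv{g}_layers", active_when=grp_on, options=(0, 1, 2, 3)))
        for i in range(1, 4):
            dims.append(
                IntRange(
                    f"conv{g}_filters_{i}",
                    active_when=lambda c, g=g, i=i: c.get("n_conv_groups", 0) >= g
                    and c.get(f"conv{g}_layers", 0) >= i,
                    lo=0, hi=128,
                )
            )
        dims.append(IntRange(f"conv{g}_kernel_h", active_when=grp_on, lo=2, hi=8))
        dims.append(Choice(f"conv{g}_kernel_w", active_when=grp_on, options=(1, 2)))
        dims.append(IntRange(f"conv{g}_pool_h", active_when=grp_on, lo=1, hi=8))
        dims.append(Choice(f"conv{g}_pool_w", active_when=grp_on, options=(1, 2)))
        dims.append(FloatRange(f"conv{g}_dropout", active_when=grp_on, lo=0.0, hi=0.5))
    dims.append(Choice("n_dense_groups", options=(0, 1, 2)))
    for g in (1, 2):
        def dgrp_on(c, g=g):
            return c.get("n_dense_groups", 0) >= g

        dims.append(Choice(f"dense{g}_layers", active_when=dgrp_on, options=(0, 1, 2, 3)))
        for i in range(1, 4):
            dims.append(
                IntRange(
                    f"dense{g}_units_{i}",
                    active_when=lambda c, g=g, i=i: c.get("n_dense_groups", 0) >= g
                    and c.get(f"dense{g}_layers", 0) >= i,
                    lo=0, hi=64,
                )
            )
        dims.append(FloatRange(f"dense{g}_dropout", active_when=dgrp_on, lo=0.0, hi=0.5))
    return SearchSpace("cnn_hg38", dims)


def meta_model_space(kind: str, **kwargs) -> SearchSpace:
    factories = {
        "bayes_ffnn_hg19": ffnn_hg19_space,
        "bayes_ffnn_hg38": ffnn_hg38_space,
        "bayes_cnn_hg19": cnn_hg19_space,
        "bayes_cnn_hg38": cnn_hg38_space,
    }
    try:
        return factories[kind](**kwargs)
    except KeyError:
        raise ValueError(f"no search space for architecture kind {kind!r}") from None
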