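"""Sequential model-based hyperparameter optimization.

The optimizer maximizes a black-box objective over a (possibly
conditional) search space with a density-ratio surrogate in the spirit
of the tree-structured Parzen estimator: after an initial block of
random trials, observed configurations are split into a good fraction
and the rest, per-dimension densities l(x) and g(x) are estimated for
each group, and the next trial is the candidate maximizing the
acquisition log l(x) - log g(x) among draws from l. Conditional
dimensions are modelled only where they were active.

The model-selection objective is the mean validation AUPRC over k
stratified internal 80/20 holdouts of the training split; the outer
test split is never touched during optimization.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .balancing import HoldoutPlan, stratified_holdouts
from .evaluation import UndefinedMetricError, auprc
from .models import ModelConfig, build_model, train
from .nn import DivergenceError
from .spaces import Choice, FloatRange, IntRange, SearchSpace

__all__ = [
    "Trial", "OptimizationTrace", "OptimizationAbort",
    "sample_config", "objective_mean_val_auprc", "make_auprc_objective", "optimize",
]


def sample_config(space: SearchSpace, rng: np.random.Generator) -> dict:
    """Uniform random configuration; conditional dimensions only when active."""
    return space.sample(rng)


@dataclass(frozen=True)
class Trial:
    index: int
    config: dict
    value: float
    timestamp: float
    failed: bool = False


@dataclass
class OptimizationTrace:
    trials: list = field(default_factory=list)
    seed: int = 0

    def best(self) -> Trial:
        """Stable argmax: the earliest trial achieving the best value."""
        finite = [t for t in self.trials if np.isfinite(t.value)]
        if not finite:
            raise ValueError("no successful trials")
        return max(finite, key=lambda t: (t.value, -t.index))

    def best_so_far(self) -> list[float]:
        out, cur = [], -np.inf
        for t in self.trials:
            if np.isfinite(t.value):
                cur = max(cur, t.value)
            out.append(cur)
        return out


class OptimizationAbort(RuntimeError):
    def __init__(self, trace: OptimizationTrace):
        super().__init__("objective repeatedly non-finite")
        self.trace = trace


# -- Parzen densities per dimension kind -----------------------------------

def _cat_options(dim) -> tuple:
    if isinstance(dim, Choice):
        return dim.options
    return tuple(range(dim.lo, dim.hi + 1))


def _cat_weights(dim, values) -> np.ndarray:
    opts = _cat_options(dim)
    counts = np.ones(len(opts))  # Laplace prior keeps every option reachable
    index = {v: i for i, v in enumerate(opts)}
    for v in values:
        counts[index[v]] += 1
    return counts / counts.sum()


def _float_sigma(dim, values) -> float:
    span = dim.hi - dim.lo
    return max(span / np.sqrt(len(values) + 1), 1e-3 * span) if span > 0 else 1.0


def _dim_sample(dim, values, rng: np.random.Generator):
    """Draw from the Parzen estimate built on ``values`` (may be empty)."""
    if isinstance(dim, (Choice, IntRange)):
        opts = _cat_options(dim)
        return opts[int(rng.choice(len(opts), p=_cat_weights(dim, values)))]
    # continuous: mixture of a uniform prior and Gaussians at observations
    k = len(values)
    if k == 0 or rng.random() < 1.0 / (k + 1):
        return float(rng.uniform(dim.lo, dim.hi))
    center = values[int(rng.integers(k))]
    draw = rng.normal(center, _float_sigma(dim, values))
    return float(np.clip(draw, dim.lo, dim.hi))


def _dim_logpdf(dim, value, values) -> float:
    if isinstance(dim, (Choice, IntRange)):
        opts = _cat_options(dim)
        w = _cat_weights(dim, values)
        return float(np.log(w[opts.index(value)]))
    span = max(dim.hi - dim.lo, 1e-12)
    uniform = 1.0 / span
    k = len(values)
    if k == 0:
        return float(np.log(uniform))
    sigma = _float_sigma(dim, values)
    comps = np.exp(-0.5 * ((value - np.asarray(values)) / sigma) ** 2) / (
        sigma * np.sqrt(2 * np.pi)
    )
    dens = (uniform + comps.sum()) / (k + 1)
    return float(np.log(max(dens, 1e-300)))


def _propose_tpe(
    space: SearchSpace,
    trials: list[Trial],
    rng: np.random.Generator,
    gamma: float,
    n_candidates: int,
) -> dict:
    ranked = sorted(
        (t for t in trials if np.isfinite(t.value)),
        key=lambda t: t.value, reverse=True,
    )
    if not ranked:
        return space.sample(rng)
    n_good = max(1, int(np.ceil(gamma * len(ranked))))
    good = [t.config for t in ranked[:n_good]]
    bad = [t.config for t in ranked[n_good:]]

    def values_for(dim, configs):
        return [c[dim.name] for c in configs if dim.name in c]

    best_score, best_config = -np.inf, None
    for _ in range(n_candidates):
        config: dict = {}
        score = 0.0
        for dim in space.dimensions:
            if not dim.is_active(config):
                continue
            gv = values_for(dim, good)
            value = _dim_sample(dim, gv, rng)
            config[dim.name] = value
            score += _dim_logpdf(dim, value, gv)
            score -= _dim_logpdf(dim, value, values_for(dim, bad))
        if score > best_score:
            best_score, best_config = score, config
    return best_config


def optimize(
    space: SearchSpace,
    objective,
    budget: int = 100,
    n_initial: int = 10,
    seed: int = 0,
    gamma: float = 0.25,
    n_candidates: int = 24,
    max_consecutive_failures: int = 5,
) -> tuple[dict, OptimizationTrace]:
    """Maximize ``objective(config)`` over the space within ``budget`` trials.

    The first ``n_initial`` trials are uniform random; later trials come
    from the density-ratio proposal. Non-finite objective values are
    recorded as failed trials; after ``max_consecutive_failures`` in a
    row the search aborts with the trace preserved. Bit-reproducible
    under the seed.
    """
    if not 1 <= n_initial <= budget:
        raise ValueError("need budget >= n_initial >= 1")
    rng = np.random.default_rng(seed)
    trace = OptimizationTrace(seed=seed)
    consecutive_failures = 0
    for i in range(budget):
        if i < n_initial:
            config = space.sample(rng)
        else:
            config = _propose_tpe(space, trace.trials, rng, gamma, n_candidates)
        try:
            value = float(objective(config))
        except DivergenceError:
            value = np.nan
        failed = not np.isfinite(value)
        trace.trials.append(
            Trial(i, config, value if not failed else -np.inf, time.time(), failed)
        )
        consecutive_failures = consecutive_failures + 1 if failed else 0
        if consecutive_failures >= max_consecutive_failures:
            raise OptimizationAbort(trace)
    return trace.best().config, trace


# -- Model-selection objective ----------------------------------------------

def objective_mean_val_auprc(
    params: dict,
    kind: str,
    x: np.ndarray,
    y: np.ndarray,
    k_internal: int = 10,
    seed: int = 0,
    max_epochs: int | None = None,
    space: SearchSpace | None = None,
) -> float:
    """Mean validation AUPRC of one configuration over internal holdouts.

    Builds and trains the architecture on k stratified 80/20 internal
    train/validation splits of the supplied (training) data and averages
    the validation AUPRC. Training divergence on any split scores the
    configuration 0, the worst possible value.
    """
    y = np.asarray(y)
    splits = stratified_holdouts(y, HoldoutPlan(k_internal, 0.8, seed))
    scores = []
    for j, (tr, va) in enumerate(splits):
        config = ModelConfig(kind, params, seed=seed + j)
        model, settings = build_model(config, np.shape(x)[1:], space)
        try:
            train(
                model, settings, x[tr], y[tr], x[va], y[va],
                seed=seed + j, max_epochs=max_epochs,
            )
            scores.append(auprc(y[va], model.predict(x[va])))
        except DivergenceError:
            return 0.0
        except UndefinedMetricError:
            raise ValueError("internal validation split lost all positives")
    return float(np.mean(scores))


def make_auprc_objective(
    kind: str,
    x: np.ndarray,
    y: np.ndarray,
    k_internal: int = 10,
    seed: int = 0,
    max_epochs: int | None = None,
    space: SearchSpace | None = None,
):
    """Close the data and protocol over ``objective_mean_val_auprc``."""
    def objective(params: dict) -> float:
        return objective_mean_val_auprc(
            params, kind, x, y, k_internal=k_internal, seed=seed,
            max_epochs=max_epochs, space=space,
        )
    return objective
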