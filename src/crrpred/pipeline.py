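"""End-to-end experiment orchestration.

An experiment is: stratified 80/20 holdouts -> optional balancing of
the splits -> optional Bayesian model selection on the training split
of the first holdout (internal holdouts only; the outer test split is
never touched) -> training on every holdout -> per-holdout AUPRC and
AUROC collected into a MetricReport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balancing import BalancingSpec, HoldoutPlan, apply_balancing, stratified_holdouts
from .evaluation import MetricReport, auprc, auroc
from .models import ModelConfig, build_model, train
from .optimization import OptimizationTrace, make_auprc_objective, optimize
from .seeding import derive_seed
from .spaces import SearchSpace

__all__ = ["ExperimentResult", "select_model", "evaluate_model", "run_experiment"]


@dataclass
class ExperimentResult:
    report: MetricReport
    best_params: dict | None = None
    trace: OptimizationTrace | None = None


def select_model(
    kind: str,
    x: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    space: SearchSpace,
    budget: int = 100,
    n_initial: int = 10,
    k_internal: int = 10,
    seed: int = 0,
    max_epochs: int | None = None,
) -> tuple[dict, OptimizationTrace]:
    """Bayesian model selection on a training split.

    Maximizes the mean validation AUPRC over k stratified internal
    80/20 holdouts of the training rows.
    """
    objective = make_auprc_objective(
        kind, np.asarray(x)[train_idx], np.asarray(y)[train_idx],
        k_internal=k_internal, seed=derive_seed(seed, "objective"),
        max_epochs=max_epochs, space=space,
    )
    return optimize(
        space, objective, budget=budget, n_initial=n_initial,
        seed=derive_seed(seed, "optimize"),
    )


def evaluate_model(
    kind: str,
    params: dict | None,
    x: np.ndarray,
    y: np.ndarray,
    splits,
    balancing: BalancingSpec | None = None,
    seed: int = 0,
    max_epochs: int | None = None,
    space: SearchSpace | None = None,
    task: str = "task",
    cell_line: str = "synthetic",
    model_name: str | None = None,
) -> MetricReport:
    """Train and score one architecture on every holdout."""
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    balancing = balancing or BalancingSpec("unbalanced")
    if balancing.mode != "unbalanced" and not (
        set(np.unique(y).tolist()) & set(balancing.class_ratios)
    ):
        # binary 0/1 task: active class keeps ratio 1, inactive 2, mirroring
        # the enhancer pair of the seven-class proportion scheme
        balancing = BalancingSpec(
            balancing.mode, balancing.cap, {1: 1, 0: 2}, balancing.seed
        )
    rows = []
    for h, (tr, te) in enumerate(splits):
        h_seed = derive_seed(seed, f"holdout-{h}")
        tr_b, te_b = apply_balancing(
            tr, te, y, BalancingSpec(
                balancing.mode, balancing.cap, dict(balancing.class_ratios), h_seed
            ),
        )
        config = ModelConfig(kind, params or {}, seed=h_seed)
        model, settings = build_model(config, x.shape[1:], space)
        train(model, settings, x[tr_b], y[tr_b], seed=h_seed, max_epochs=max_epochs)
        scores = model.predict(x[te_b])
        rows.append(
            {
                "task": task, "cell_line": cell_line, "mode": balancing.mode,
                "holdout": h, "auprc": auprc(y[te_b], scores),
                "auroc": auroc(y[te_b], scores),
            }
        )
    return MetricReport(
        model=model_name or kind,
        records=pd.DataFrame(rows),
        metadata={"seed": seed, "n_holdouts": len(splits), "max_epochs": max_epochs},
    )


def run_experiment(
    x: np.ndarray,
    y: np.ndarray,
    kind: str,
    n_holdouts: int = 10,
    balancing_mode: str = "unbalanced",
    seed: int = 0,
    space: SearchSpace | None = None,
    budget: int = 0,
    n_initial: int = 5,
    k_internal: int = 10,
    max_epochs: int | None = None,
    task: str = "task",
    cell_line: str = "synthetic",
) -> ExperimentResult:
    """Holdouts, optional model selection, training, and evaluation.

    With ``budget > 0`` (requires a search space) the configuration is
    selected by Bayesian optimization on the first holdout's training
    split, then evaluated on all holdouts; with budget 0 the fixed
    architecture is used as-is.
    """
    y = np.asarray(y)
    plan = HoldoutPlan(n_holdouts, 0.8, derive_seed(seed, "holdouts"))
    splits = stratified_holdouts(y, plan)
    best_params, trace = None, None
    if budget > 0:
        if space is None:
            raise ValueError("model selection requires a search space")
        best_params, trace = select_model(
            kind, x, y, splits[0][0], space, budget=budget, n_initial=n_initial,
            k_internal=k_internal, seed=seed, max_epochs=max_epochs,
        )
    report = evaluate_model(
        kind, best_params, x, y, splits,
        balancing=BalancingSpec(balancing_mode), seed=seed,
        max_epochs=max_epochs, space=space, task=task, cell_line=cell_line,
    )
    return ExperimentResult(report, best_params, trace)
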