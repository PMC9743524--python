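"""Stratified holdouts and the three dataset-balancing setups.

The protocol evaluates every model over repeated random stratified
holdouts (80/20 by default). Three rebalancing modes are compared:

* ``unbalanced`` — no resampling; the natural class distribution is kept.
* ``balanced`` — only the training split is downsampled so every class
  has equal cardinality (capped, 3000 by default); the test split is
  untouched.
* ``full_balanced`` — both splits are downsampled to enforced class
  proportions (AE:AP:AX:IE:IP:IX:UK = 1:1:1:2:2:1:10 by default) with a
  per-class cap. Rebalancing the test split this way yields
  over-optimistic performance estimates, which is precisely the effect
  the evaluation protocol is designed to expose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import ClassCountSummary, TaskSpec, predefined_tasks, unbalancing_ratio

__all__ = [
    "HoldoutPlan",
    "BalancingSpec",
    "DEFAULT_CLASS_RATIOS",
    "stratified_holdouts",
    "apply_balancing",
    "full_balanced_sizes",
    "full_balanced_task_ratio",
    "ratio_report_tasks",
    "balancing_report",
]

#: Enforced class proportions of the full-balanced setup.
DEFAULT_CLASS_RATIOS: dict[str, int] = {
    "AE": 1, "AP": 1, "AX": 1, "IE": 2, "IP": 2, "IX": 1, "UK": 10,
}
DEFAULT_CAP = 3000


@dataclass(frozen=True)
class HoldoutPlan:
    n_holdouts: int = 10
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_holdouts < 1:
            raise ValueError("need at least one holdout")


@dataclass(frozen=True)
class BalancingSpec:
    mode: str = "unbalanced"  # unbalanced | balanced | full_balanced
    cap: int = DEFAULT_CAP
    class_ratios: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_RATIOS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("unbalanced", "balanced", "full_balanced"):
            raise ValueError(f"unknown balancing mode {self.mode!r}")
        if self.cap < 1 or any(r < 1 for r in self.class_ratios.values()):
            raise ValueError("cap and class ratios must be positive")


def stratified_holdouts(labels: Sequence, plan: HoldoutPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated random stratified train/test splits.

    Per class c, floor(train_fraction * n_c) samples go to the training
    split; the remainder forms the test split. Deterministic under the
    plan's seed; successive holdouts use fresh draws from the same
    generator.
    """
    y = np.asarray(labels)
    classes, class_counts = np.unique(y, return_counts=True)
    if (class_counts < 2).any():
        bad = classes[class_counts < 2]
        raise ValueError(f"cannot stratify: class(es) {bad.tolist()} have < 2 samples")
    rng = np.random.default_rng(plan.seed)
    splits = []
    for _ in range(plan.n_holdouts):
        train_parts, test_parts = [], []
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n_train = int(np.floor(plan.train_fraction * len(idx)))
            train_parts.append(idx[:n_train])
            test_parts.append(idx[n_train:])
        splits.append((np.sort(np.concatenate(train_parts)),
                       np.sort(np.concatenate(test_parts))))
    return splits


def _downsample(idx: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    if size >= len(idx):
        return idx
    return np.sort(rng.choice(idx, size=size, replace=False))


def full_balanced_sizes(
    class_counts: dict[str, int],
    cap: int = DEFAULT_CAP,
    class_ratios: dict[str, int] | None = None,
) -> dict[str, int]:
    """Per-class target sizes of the full-balanced setup.

    Sizes are r_c * u with a single unit u chosen so that every class is
    available in its required proportion and no class exceeds the cap:
    u = min(min_c floor(n_c / r_c), floor(cap / max_c r_c)).
    """
    ratios = dict(DEFAULT_CLASS_RATIOS if class_ratios is None else class_ratios)
    active = {c: r for c, r in ratios.items() if c in class_counts}
    missing = set(ratios) - set(active)
    if missing:
        warnings.warn(f"classes absent from data skipped in balancing: {sorted(missing)}")
    if not active:
        return {}
    u = min(
        min(class_counts[c] // r for c, r in active.items()),
        cap // max(active.values()),
    )
    return {c: r * u for c, r in active.items()}


def apply_balancing(
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    labels: Sequence,
    spec: BalancingSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a holdout according to the balancing mode.

    Outputs are always subsets of the inputs (downsampling without
    replacement, no duplicates), deterministic under the spec's seed.
    """
    y = np.asarray(labels)
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if spec.mode == "unbalanced":
        return train_idx, test_idx
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "balanced":
        classes = np.unique(y[train_idx])
        target = min(spec.cap, min((y[train_idx] == c).sum() for c in classes))
        parts = [
            _downsample(train_idx[y[train_idx] == c], target, rng) for c in classes
        ]
        return np.sort(np.concatenate(parts)), test_idx
    # full_balanced: both splits, independently, to the ratio scheme
    out = []
    for idx in (train_idx, test_idx):
        counts = {c: int((y[idx] == c).sum()) for c in np.unique(y[idx]).tolist()}
        sizes = full_balanced_sizes(counts, spec.cap, spec.class_ratios)
        parts = [
            _downsample(idx[y[idx] == c], size, rng) for c, size in sizes.items()
        ]
        out.append(np.sort(np.concatenate(parts)) if parts else idx[:0])
    return out[0], out[1]


def full_balanced_task_ratio(
    task: TaskSpec, class_ratios: dict[str, int] | None = None
) -> float:
    """Task unbalancing ratio implied by the full-balanced proportions.

    Identical for every cell line by construction.
    """
    ratios = dict(DEFAULT_CLASS_RATIOS if class_ratios is None else class_ratios)
    pos = sum(ratios.get(l.value, 0) for l in task.positive_labels)
    neg = sum(ratios.get(l.value, 0) for l in task.negative_labels)
    return unbalancing_ratio(pos, neg)


def ratio_report_tasks(genome_version: str) -> tuple[TaskSpec, ...]:
    """Tasks tabulated in the unbalancing-ratio report.

    The hg38 count table covers CRR classes only, and its reference ratio
    report lists the four single-class tasks; the combined AE+AP task is
    still part of the hg38 experimental protocol.
    """
    tasks = predefined_tasks(genome_version)
    return tasks if genome_version == "hg19" else tasks[:4]


def balancing_report(
    summary: ClassCountSummary,
    mode: str = "unbalanced",
    tasks: Sequence[TaskSpec] | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-task, per-cell-line unbalancing ratios with averages.

    Ratios are rounded to ``decimals`` places for display; row and
    column averages are computed on unrounded values and then rounded,
    matching the reference-table convention. For the full-balanced mode
    the ratio is a pure function of the class proportions and is shown
    under a single ``all_cell_lines`` column.
    """
    if tasks is None:
        tasks = ratio_report_tasks(summary.genome_version)
    if mode == "full_balanced":
        col = {t.name: full_balanced_task_ratio(t) for t in tasks}
        df = pd.DataFrame({"all_cell_lines": col})
        df.loc["avg_per_cell_line"] = df["all_cell_lines"].mean()
        return df.round(decimals)
    if mode != "unbalanced":
        raise ValueError("report supports the unbalanced and full_balanced modes")
    cells = list(summary.total_cell_lines) + [
        c for c in summary.counts.index if c not in summary.total_cell_lines
    ]
    raw = pd.DataFrame(index=[t.name for t in tasks], columns=cells, dtype=float)
    for t in tasks:
        for cell in cells:
            pos = sum(summary.count(cell, l) for l in t.positive_labels)
            neg = sum(summary.count(cell, l) for l in t.negative_labels)
            raw.loc[t.name, cell] = unbalancing_ratio(pos, neg)
    raw["average"] = raw[cells].mean(axis=1)
    raw.loc["avg_per_cell_line"] = raw.mean(axis=0)
    return raw.round(decimals)
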