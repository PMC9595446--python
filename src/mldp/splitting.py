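"""Train/validation split plans (Monte-Carlo and dual-center)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CohortError, LabeledCohort
from .rng import derive_rng

__all__ = ["SplitPlan", "make_splits", "stratified_split_indices"]


@dataclass(frozen=True)
class SplitPlan:
    mode: str = "monte_carlo"  # "monte_carlo" | "dual_center"
    folds: int = 100
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("monte_carlo", "dual_center"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "dual_center" and self.folds != 1:
            raise ValueError("dual_center mode implies exactly 1 fold")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def stratified_split_indices(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-proportional random split with at least one sample of each
    class on both sides."""
    y = np.asarray(y)
    train_parts, val_parts = [], []
    for label in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == label))
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_parts.append(idx[:n_train])
        val_parts.append(idx[n_train:])
    train = np.sort(np.concatenate(train_parts))
    val = np.sort(np.concatenate(val_parts))
    return train, val


def make_splits(cohort: LabeledCohort, plan: SplitPlan):
    """List of (train_indices, validation_indices) pairs.

    Per-fold RNGs derive from plan.seed + fold index, so growing the fold
    count never reshuffles earlier folds.
    """
    if plan.mode != "monte_carlo":
        raise ValueError("make_splits only handles monte_carlo plans")
    if cohort.n_samples < 10:
        raise CohortError("Monte-Carlo splitting needs at least 10 samples")
    cohort.require_both_classes()
    splits = []
    for fold in range(plan.folds):
        rng = derive_rng(plan.seed, "fold", fold)
        if plan.stratified:
            train, val = stratified_split_indices(cohort.y, plan.train_fraction, rng)
        else:
            for _ in range(100):  # redraw folds whose training side is single-class
                perm = rng.permutation(cohort.n_samples)
                n_train = int(round(plan.train_fraction * cohort.n_samples))
                train, val = np.sort(perm[:n_train]), np.sort(perm[n_train:])
                if len(np.unique(cohort.y[train])) == 2:
                    break
            else:
                raise CohortError("could not draw a two-class training split")
        splits.append((train, val))
    return splits
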