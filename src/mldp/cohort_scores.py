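"""Cohort characteristic diagnostics: outlier score and borderline score.

The outlier score is the percentage of samples the isolation forest flags
above a score threshold; the borderline score is the percentage of samples
(over the whole cohort) that are minority-class members of at least one
Tomek link. Both can be computed on the whole cohort or averaged over the
training subsets of a Monte-Carlo split plan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CohortError, LabeledCohort
from .prep_ops import isolation_forest_scores, tomek_links

__all__ = ["CohortScores", "outlier_score", "borderline_score", "cohort_scores",
           "fold_averaged_scores"]


@dataclass(frozen=True)
class CohortScores:
    outlier_score: float  # percent of samples flagged as outliers
    borderline_score: float  # percent of samples that are minority link members

    def __post_init__(self) -> None:
        for v in (self.outlier_score, self.borderline_score):
            if not 0.0 <= v <= 100.0:
                raise ValueError("scores are percentages in [0, 100]")


def outlier_score(
    cohort: LabeledCohort,
    n_trees: int = 100,
    subsample_size: int = 256,
    score_threshold: float = 0.55,
    seed: int = 0,
) -> float:
    """Percentage of isolation-forest-flagged samples (nothing is removed)."""
    scores = isolation_forest_scores(cohort, n_trees, subsample_size, seed)
    return 100.0 * float((scores > score_threshold).sum()) / cohort.n_samples


def borderline_score(cohort: LabeledCohort) -> float:
    """Percentage of minority samples participating in >= 1 Tomek link,
    relative to total sample count. Deterministic."""
    cohort.require_both_classes()
    n1 = int(cohort.y.sum())
    minority_label = 1 if n1 <= cohort.n_samples - n1 else 0
    links = tomek_links(cohort)
    members = {i for a, b in links for i in (a, b) if cohort.y[i] == minority_label}
    return 100.0 * len(members) / cohort.n_samples


def cohort_scores(cohort: LabeledCohort, seed: int = 0, **if_params) -> CohortScores:
    return CohortScores(
        outlier_score=outlier_score(cohort, seed=seed, **if_params),
        borderline_score=borderline_score(cohort),
    )


def fold_averaged_scores(cohort: LabeledCohort, splits, seed: int = 0,
                         **if_params) -> CohortScores:
    """Mean of per-fold training-subset scores over a list of
    (train_idx, val_idx) splits — the cross-validation reporting mode."""
    o, b = [], []
    for train_idx, _ in splits:
        sub = cohort.subset_samples(np.asarray(train_idx))
        o.append(outlier_score(sub, seed=seed, **if_params))
        b.append(borderline_score(sub))
    if not o:
        raise CohortError("no splits supplied")
    return CohortScores(float(np.mean(o)), float(np.mean(b)))
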