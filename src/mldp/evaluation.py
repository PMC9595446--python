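"""Experiment harness: Monte-Carlo / dual-center evaluation of the three
comparison arms (no preparation, searched pipeline, fixed manual pipeline)
with confusion-matrix analytics, ANOVA, confidence intervals and
pipeline-occurrence tallies.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classifiers import SCHEMES, ClassifierSpec, predict_scores, train
from .data_model import CohortError, LabeledCohort
from .mldp_search import SearchConfig, run_mldp
from .pipeline_space import Pipeline, RestrictionTable, default_restrictions
from .prep_ops import METHOD_IDS, PrepStepSpec, fit_pipeline
from .rng import derive_seed
from .splitting import SplitPlan, make_splits

__all__ = [
    "SplitPlan",
    "make_splits",
    "MetricSet",
    "CVReport",
    "confusion_metrics",
    "auc",
    "anova_p",
    "ci95",
    "manual_pipeline",
    "run_experiment",
    "ARMS",
]

ARMS = ("none", "mldp", "manual")


@dataclass(frozen=True)
class MetricSet:
    """Confusion-matrix analytics; NaN marks an undefined (zero-denominator)
    metric, with the flag recorded in ``undefined``."""

    ACC: float
    SNS: float
    SPC: float
    PPV: float
    NPV: float
    AUC: float = float("nan")
    undefined: tuple = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("ACC", "SNS", "SPC", "PPV", "NPV", "AUC")}


def _ratio(num: int, den: int, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def confusion_metrics(TP: int, FP: int, TN: int, FN: int) -> MetricSet:
    """ACC/SNS/SPC/PPV/NPV from raw counts; zero denominators are flagged."""
    for c in (TP, FP, TN, FN):
        if c < 0:
            raise ValueError("counts must be non-negative")
    n = TP + FP + TN + FN
    undefined: list = []
    return MetricSet(
        ACC=_ratio(TP + TN, n, "ACC", undefined),
        SNS=_ratio(TP, TP + FN, "SNS", undefined),
        SPC=_ratio(TN, TN + FP, "SPC", undefined),
        PPV=_ratio(TP, TP + FP, "PPV", undefined),
        NPV=_ratio(TN, TN + FN, "NPV", undefined),
        undefined=tuple(undefined),
    )


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise CohortError("AUC needs both classes among the labels")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def anova_p(group_a, group_b) -> float:
    """One-way fixed-effects ANOVA p across two groups of fold values.

    Zero pooled variance (all values identical) returns p = 1 by convention.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 finite values")
    if np.var(np.concatenate([a, b])) < 1e-30:
        return 1.0
    f, p = stats.f_oneway(a, b)
    if math.isnan(p):
        return 1.0
    return float(p)


def ci95(values) -> tuple[float, float]:
    """t-based 95% confidence interval for the mean."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("CI95 needs at least 2 values")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    half = stats.t.ppf(0.975, len(v) - 1) * sd / math.sqrt(len(v))
    return (m - half, m + half)


_MANUAL = Pipeline((PrepStepSpec.make("SFS"), PrepStepSpec.make("SMOTE")))


def manual_pipeline() -> Pipeline:
    """The fixed manual-preparation arm: feature selection then SMOTE."""
    return _MANUAL


@dataclass
class CVReport:
    """Aggregated cross-validation results per (scheme, arm)."""

    mode: str
    folds: int
    fold_metrics: dict = field(default_factory=dict)  # (scheme, arm) -> [MetricSet]
    aggregates: dict = field(default_factory=dict)  # (scheme, arm) -> {metric: stats}
    anova: dict = field(default_factory=dict)  # scheme -> {metric: p}
    occurrence: dict = field(default_factory=dict)  # method_id -> percent of folds
    fold_pipelines: list = field(default_factory=list)  # str per fold (mldp arm)
    pooled: dict = field(default_factory=dict)  # (scheme, arm) -> MetricSet

    def mean(self, scheme: str, arm: str, metric: str) -> float:
        return self.aggregates[(scheme, arm)][metric]["mean"]

    def to_dict(self) -> dict:
        def k(t):
            return f"{t[0]}|{t[1]}"

        return {
            "mode": self.mode,
            "folds": self.folds,
            "aggregates": {k(key): v for key, v in self.aggregates.items()},
            "anova": self.anova,
            "occurrence": self.occurrence,
            "fold_pipelines": self.fold_pipelines,
            "pooled": {k(key): m.as_dict() for key, m in self.pooled.items()},
            "fold_metrics": {
                k(key): [m.as_dict() for m in ms]
                for key, ms in self.fold_metrics.items()
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def _score_fold(model, val_cohort: LabeledCohort) -> tuple[MetricSet, np.ndarray]:
    scores = predict_scores(model, val_cohort)
    pred = scores >= 0.5
    yv = val_cohort.y == 1
    tp = int((pred & yv).sum())
    fp = int((pred & ~yv).sum())
    tn = int((~pred & ~yv).sum())
    fn = int((~pred & yv).sum())
    ms = confusion_metrics(tp, fp, tn, fn)
    try:
        a = auc(scores, val_cohort.y)
    except CohortError:
        a = float("nan")
    return (
        MetricSet(ms.ACC, ms.SNS, ms.SPC, ms.PPV, ms.NPV, a, ms.undefined),
        scores,
    )


def run_experiment(
    cohort: LabeledCohort,
    plan: SplitPlan,
    restrictions: RestrictionTable | None = None,
    search_config: SearchConfig | None = None,
    schemes=("RF", "MG", "SVM", "XGB", "NN"),
    arms=ARMS,
    validation_cohort: LabeledCohort | None = None,
    seed: int = 0,
) -> CVReport:
    """Run the full comparison experiment.

    Monte-Carlo mode splits ``cohort`` per the plan; dual-center mode
    trains on ``cohort`` and validates once on ``validation_cohort``.
    Per fold and arm the pipeline (if any) is fitted on the training split
    only, its feature-space transforms are replayed on the validation
    split, and each classifier scheme is trained and scored. A leakage
    audit asserts that the search never touched a validation sample.
    """
    restrictions = restrictions or default_restrictions()
    search_config = search_config or SearchConfig(seed=seed)
    for s in schemes:
        if s not in SCHEMES:
            raise ValueError(f"unknown scheme {s!r}")
    for a in arms:
        if a not in ARMS:
            raise ValueError(f"unknown arm {a!r}")

    if plan.mode == "dual_center":
        if validation_cohort is None:
            raise ValueError("dual_center mode needs a validation cohort")
        if validation_cohort.feature_names != cohort.feature_names:
            raise CohortError("train/validation feature names differ")
        if set(validation_cohort.sample_ids) & set(cohort.sample_ids):
            raise CohortError(
                "train and validation cohorts share sample ids; the leakage "
                "audit needs disjoint id namespaces")
        fold_cohorts = [(cohort, validation_cohort)]
    else:
        splits = make_splits(cohort, plan)
        fold_cohorts = [
            (cohort.subset_samples(tr), cohort.subset_samples(va)) for tr, va in splits
        ]

    report = CVReport(mode=plan.mode, folds=len(fold_cohorts))
    fold_metrics: dict = {(s, a): [] for s in schemes for a in arms}
    pooled_scores: dict = {(s, a): ([], []) for s in schemes for a in arms}
    method_hits = {m: 0 for m in METHOD_IDS}

    for fold, (train_cohort, val_cohort) in enumerate(fold_cohorts):
        fold_seed = derive_seed(seed, "fold", fold)
        val_ids = set(val_cohort.sample_ids)
        arm_pipelines: dict = {}
        if "none" in arms:
            arm_pipelines["none"] = Pipeline(())
        if "manual" in arms:
            arm_pipelines["manual"] = manual_pipeline()
        if "mldp" in arms:
            cfg_fold = SearchConfig(**{**search_config.__dict__, "seed": fold_seed})
            best, trace = run_mldp(train_cohort, restrictions, cfg_fold)
            leaked = trace.audit_ids & val_ids
            if leaked:
                raise RuntimeError(
                    f"leakage: validation ids {sorted(leaked)[:5]} touched by search")
            arm_pipelines["mldp"] = best
            report.fold_pipelines.append(str(best))
            for m in set(best.method_ids):
                method_hits[m] += 1

        for arm in arms:
            pipeline = arm_pipelines[arm]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    prepared, fitted = fit_pipeline(train_cohort, pipeline,
                                                    seed=fold_seed)
                    if len(np.unique(prepared.y)) < 2:
                        raise CohortError("pipeline emptied a class")
                except (CohortError, ValueError):
                    prepared, fitted = fit_pipeline(train_cohort, Pipeline(()),
                                                    seed=fold_seed)
                val_t = fitted.transform_validation(val_cohort)
                assert val_t.n_samples == val_cohort.n_samples
                for scheme in schemes:
                    model = train(ClassifierSpec(scheme, derive_seed(fold_seed, scheme)),
                                  prepared)
                    ms, scores = _score_fold(model, val_t)
                    fold_metrics[(scheme, arm)].append(ms)
                    pooled_scores[(scheme, arm)][0].extend(scores)
                    pooled_scores[(scheme, arm)][1].extend(val_t.y)

    report.fold_metrics = fold_metrics
    n_folds = len(fold_cohorts)
    if "mldp" in arms:
        report.occurrence = {
            m: 100.0 * method_hits[m] / n_folds for m in METHOD_IDS
        }

    for key, metric_list in fold_metrics.items():
        agg: dict = {}
        for name in ("ACC", "SNS", "SPC", "PPV", "NPV", "AUC"):
            vals = np.array([getattr(m, name) for m in metric_list], float)
            vals = vals[np.isfinite(vals)]
            entry: dict = {"mean": float(vals.mean()) if len(vals) else float("nan"),
                           "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
            if len(vals) > 1:
                entry["ci95"] = ci95(vals)
            agg[name] = entry
        report.aggregates[key] = agg
        sc, yv = pooled_scores[key]
        sc, yv = np.asarray(sc), np.asarray(yv, int)
        if len(sc):
            pred = sc >= 0.5
            tp = int((pred & (yv == 1)).sum())
            fp = int((pred & (yv == 0)).sum())
            tn = int((~pred & (yv == 0)).sum())
            fn = int((~pred & (yv == 1)).sum())
            ms = confusion_metrics(tp, fp, tn, fn)
            pooled_auc = auc(sc, yv) if 0 < yv.sum() < len(yv) else float("nan")
            report.pooled[key] = MetricSet(ms.ACC, ms.SNS, ms.SPC, ms.PPV, ms.NPV,
                                           pooled_auc, ms.undefined)

    if "mldp" in arms and "none" in arms and n_folds >= 2:
        for scheme in schemes:
            ps: dict = {}
            for name in ("ACC", "SNS", "SPC", "PPV", "NPV", "AUC"):
                a = [getattr(m, name) for m in fold_metrics[(scheme, "mldp")]]
                b = [getattr(m, name) for m in fold_metrics[(scheme, "none")]]
                a = [x for x in a if math.isfinite(x)]
                b = [x for x in b if math.isfinite(x)]
                if len(a) >= 2 and len(b) >= 2:
                    ps[name] = anova_p(a, b)
            report.anova[scheme] = ps
    return report
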