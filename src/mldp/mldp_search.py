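"""Evolutionary search for the best preparation pipeline.

The optimizer maintains a population of restriction-valid pipelines,
scores each by ROC-distance fitness measured on internal splits of the
TRAINING cohort only (the held-out validation set is never consulted), and
evolves the population by tournament selection, one-point crossover with
restriction repair, structural mutation and hyperparameter mutation.
Every sample id touched during fitness evaluation is recorded in an audit
log so leakage can be asserted downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .classifiers import ClassifierSpec, predict_scores, train
from .data_model import CohortError, LabeledCohort
from .pipeline_space import (Pipeline, PipelineTree, RestrictionTable,
                             is_valid, sample_pipeline)
from .prep_ops import (HYPERPARAM_REGISTRY, PrepStepSpec, fit_pipeline)
from .rng import derive_rng, derive_seed
from .splitting import stratified_split_indices

__all__ = [
    "SearchConfig",
    "FitnessRecord",
    "SearchTrace",
    "roc_distance",
    "FitnessEvaluator",
    "evaluate_fitness",
    "select_parents",
    "make_offspring",
    "run_mldp",
    "run_random_search",
]

WORST_FITNESS = math.sqrt(2.0)


def roc_distance(sens: float, spec: float) -> float:
    """Euclidean distance of the operating point (sens, spec) from the
    perfect corner (1, 1); 0 is perfect, sqrt(2) the worst corner."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return math.hypot(1.0 - sens, 1.0 - spec)


@dataclass(frozen=True)
class SearchConfig:
    population_size: int = 24
    generations: int = 20
    plateau_patience: int = 5
    crossover_rate: float = 0.9
    mutation_rate: float = 0.3
    hyperparam_mutation_rate: float = 0.3
    elitism_count: int = 2
    inner_splits: int = 5
    inner_split_ratio: float = 0.8
    surrogate: str = "RF"
    surrogate_trees: int = 100  # RF surrogate size; smaller = faster search
    include_empty: bool = False
    # operating point for the sens/spec pair: a fixed score threshold, or
    # None to use the ROC point closest to the perfect corner
    fitness_threshold: float | None = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.crossover_rate, self.mutation_rate, self.hyperparam_mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be < population_size")
        if not 0.5 < self.inner_split_ratio < 0.95:
            raise ValueError("inner_split_ratio must lie in (0.5, 0.95)")


@dataclass
class FitnessRecord:
    pipeline: Pipeline
    fitness: float  # mean ROC distance over inner splits; lower is better
    per_split: list = field(default_factory=list)  # (sens, spec) pairs
    evaluation_count: int = 1


@dataclass
class SearchTrace:
    generations: list = field(default_factory=list)
    best: FitnessRecord | None = None
    total_evaluations: int = 0
    audit_ids: set = field(default_factory=set)  # every sample id ever touched

    def to_dict(self) -> dict:
        return {
            "generations": self.generations,
            "best_pipeline": str(self.best.pipeline) if self.best else None,
            "best_fitness": self.best.fitness if self.best else None,
            "total_evaluations": self.total_evaluations,
        }


def _operating_point(
    scores: np.ndarray, y: np.ndarray, threshold: float | None
) -> tuple[float, float]:
    """(sensitivity, specificity) at a fixed score threshold, or at the ROC
    point closest to the perfect (1, 1) corner when threshold is None."""
    yv = np.asarray(y) == 1
    n_pos = int(yv.sum())
    n_neg = len(yv) - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.0, 0.0
    if threshold is not None:
        pred = scores >= threshold
        sens = float((pred & yv).sum()) / n_pos
        spec = float((~pred & ~yv).sum()) / n_neg
        return sens, spec
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate([[0], np.cumsum(yv[order])])
    fp = np.concatenate([[0], np.cumsum(~yv[order])])
    sens_curve = tp / n_pos
    spec_curve = 1.0 - fp / n_neg
    d2 = (1.0 - sens_curve) ** 2 + (1.0 - spec_curve) ** 2
    i = int(np.argmin(d2))
    return float(sens_curve[i]), float(spec_curve[i])


class FitnessEvaluator:
    """ROC-distance fitness over stratified internal splits of the
    training cohort, with a cache keyed by pipeline identity + seed."""

    def __init__(self, cohort: LabeledCohort, config: SearchConfig):
        cohort.require_both_classes()
        self.cohort = cohort
        self.config = config
        self.cache: dict = {}
        self.audit_ids: set = set()
        self.evaluations = 0
        self._splits = []
        for i in range(config.inner_splits):
            rng = derive_rng(config.seed, "inner", i)
            self._splits.append(
                stratified_split_indices(cohort.y, config.inner_split_ratio, rng))

    def _surrogate_model(self, cohort: LabeledCohort):
        seed = derive_seed(self.config.seed, "surrogate")
        if self.config.surrogate == "RF":
            est = RandomForestClassifier(
                n_estimators=self.config.surrogate_trees, random_state=seed)
            est.fit(cohort.X, cohort.y)
            return ("raw", est)
        return ("scheme", train(ClassifierSpec(self.config.surrogate, seed), cohort))

    def _score(self, model, cohort: LabeledCohort) -> np.ndarray:
        kind, est = model
        if kind == "raw":
            return est.predict_proba(cohort.X)[:, 1]
        return predict_scores(est, cohort)

    def evaluate(self, pipeline: Pipeline) -> FitnessRecord:
        key = (pipeline.key(), self.config.seed)
        if key in self.cache:
            rec = self.cache[key]
            rec.evaluation_count += 1
            return rec
        per_split = []
        distances = []
        for i, (tr, va) in enumerate(self._splits):
            inner_train = self.cohort.subset_samples(tr)
            inner_val = self.cohort.subset_samples(va)
            self.audit_ids.update(inner_train.sample_ids)
            self.audit_ids.update(inner_val.sample_ids)
            step_seed = derive_seed(self.config.seed, "fit", i)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    prepared, fitted = fit_pipeline(inner_train, pipeline, seed=step_seed)
                    if len(np.unique(prepared.y)) < 2:
                        raise CohortError("pipeline emptied a class")
                    val_t = fitted.transform_validation(inner_val)
                    model = self._surrogate_model(prepared)
                    scores = self._score(model, val_t)
            except (CohortError, ValueError) as exc:
                warnings.warn(f"pipeline {pipeline} failed on inner split {i}: {exc}; "
                              "assigning worst fitness for this split")
                distances.append(WORST_FITNESS)
                per_split.append((0.0, 0.0))
                continue
            sens, spec = _operating_point(scores, inner_val.y,
                                          self.config.fitness_threshold)
            per_split.append((sens, spec))
            distances.append(roc_distance(sens, spec))
        self.evaluations += 1
        rec = FitnessRecord(pipeline, float(np.mean(distances)), per_split)
        self.cache[key] = rec
        return rec


def evaluate_fitness(
    pipeline: Pipeline, training_cohort: LabeledCohort, config: SearchConfig
) -> FitnessRecord:
    return FitnessEvaluator(training_cohort, config).evaluate(pipeline)


def _fitness_sort_key(rec: FitnessRecord):
    return (rec.fitness, len(rec.pipeline), rec.pipeline.method_ids)


def select_parents(population: list, seed: int) -> tuple:
    """Tournament selection (size 3) by lower fitness; returns two records."""
    if not population:
        raise ValueError("empty population")
    if len(population) < 2:
        raise ValueError("need at least 2 individuals")
    rng = derive_rng(seed, "select")
    distinct = {rec.pipeline.key() for rec in population}
    if len(population) == 2:
        return population[0], population[1]

    def tournament():
        contenders = [population[i] for i in rng.choice(len(population), 3, replace=False)]
        return min(contenders, key=_fitness_sort_key)

    p1 = tournament()
    p2 = tournament()
    if len(distinct) >= 2:
        for _ in range(50):
            if p2.pipeline.key() != p1.pipeline.key():
                break
            p2 = tournament()
    return p1, p2


def _repair(method_seq: list, restrictions: RestrictionTable) -> list:
    """Make a method sequence restriction-valid: keep first occurrence of
    each method, drop forbidden-pair/adjacency violators, truncate."""
    out: list = []
    for m in method_seq:
        cand = out + [m]
        counts = {x: cand.count(x) for x in set(cand)}
        if counts[m] > restrictions.max_repetitions:
            continue
        present = set(cand)
        if any(pair <= present for pair in restrictions.forbidden_pairs):
            continue
        if out and (out[-1], m) in restrictions.forbidden_adjacencies:
            continue
        out.append(m)
        if len(out) == restrictions.max_length:
            break
    return out


def _mutate_hyperparam(step: PrepStepSpec, rng: np.random.Generator) -> PrepStepSpec:
    registry = HYPERPARAM_REGISTRY[step.method_id]
    if not registry:
        return step
    name = str(rng.choice(sorted(registry)))
    lo, hi = registry[name]["bounds"]
    if registry[name]["int"]:
        value = int(rng.integers(lo, hi + 1))
    else:
        value = float(rng.uniform(lo, hi))
    hp = step.params
    hp[name] = value
    return PrepStepSpec.make(step.method_id, **hp)


def make_offspring(
    p1: Pipeline,
    p2: Pipeline,
    restrictions: RestrictionTable,
    seed: int,
    crossover_rate: float = 0.9,
    mutation_rate: float = 0.3,
    hyperparam_mutation_rate: float = 0.3,
) -> Pipeline:
    """One-point crossover + repair, then optional structural and
    hyperparameter mutation; the result is always restriction-valid."""
    rng = derive_rng(seed, "offspring")
    hp_of = {s.method_id: s.params for s in tuple(p1.steps) + tuple(p2.steps)}

    if rng.random() < crossover_rate and (len(p1) or len(p2)):
        cut1 = int(rng.integers(0, len(p1) + 1))
        cut2 = int(rng.integers(0, len(p2) + 1))
        seq = list(p1.method_ids[:cut1]) + list(p2.method_ids[cut2:])
    else:
        seq = list(p1.method_ids)
    seq = _repair(seq, restrictions)

    if rng.random() < mutation_rate:
        ops = ["swap", "delete", "insert"]
        op = str(rng.choice(ops))
        if op == "swap" and len(seq) >= 2:
            i, j = rng.choice(len(seq), 2, replace=False)
            seq[i], seq[j] = seq[j], seq[i]
            if not is_valid(seq, restrictions):  # adjacency clauses may break
                seq[i], seq[j] = seq[j], seq[i]
        elif op == "delete" and seq:
            del seq[int(rng.integers(len(seq)))]
        elif op == "insert":
            unused = sorted(restrictions.method_pool - set(seq))
            rng.shuffle(unused)
            for m in unused:
                pos = int(rng.integers(len(seq) + 1))
                cand = seq[:pos] + [m] + seq[pos:]
                if is_valid(cand, restrictions):
                    seq = cand
                    break
    seq = _repair(seq, restrictions)

    steps = [PrepStepSpec.make(m, **hp_of.get(m, {})) for m in seq]
    if steps and rng.random() < hyperparam_mutation_rate:
        i = int(rng.integers(len(steps)))
        steps[i] = _mutate_hyperparam(steps[i], rng)
    child = Pipeline(tuple(steps))
    assert is_valid(child.method_ids, restrictions)
    return child


def run_mldp(
    training_cohort: LabeledCohort,
    restrictions: RestrictionTable,
    config: SearchConfig,
) -> tuple[Pipeline, SearchTrace]:
    """Evolve a population over the pipeline tree; returns the argmin-fitness
    pipeline (ties broken by shorter length, then method order) and the
    full per-generation trace."""
    tree = PipelineTree(restrictions)
    evaluator = FitnessEvaluator(training_cohort, config)
    trace = SearchTrace()

    population = []
    for i in range(config.population_size):
        pl = sample_pipeline(tree, derive_seed(config.seed, "init", i),
                             include_empty=config.include_empty)
        population.append(evaluator.evaluate(pl))

    best = min(population, key=_fitness_sort_key)
    stall = 0
    for gen in range(config.generations):
        population.sort(key=_fitness_sort_key)
        next_pop = population[: config.elitism_count]
        child_idx = 0
        while len(next_pop) < config.population_size:
            sel_seed = derive_seed(config.seed, "gen", gen, "sel", child_idx)
            pa, pb = select_parents(population, sel_seed)
            child = make_offspring(
                pa.pipeline, pb.pipeline, restrictions,
                seed=derive_seed(config.seed, "gen", gen, "child", child_idx),
                crossover_rate=config.crossover_rate,
                mutation_rate=config.mutation_rate,
                hyperparam_mutation_rate=config.hyperparam_mutation_rate,
            )
            if not config.include_empty and len(child) == 0:
                child = pa.pipeline
            next_pop.append(evaluator.evaluate(child))
            child_idx += 1
        population = next_pop
        gen_best = min(population, key=_fitness_sort_key)
        if _fitness_sort_key(gen_best) < _fitness_sort_key(best):
            best = gen_best
            stall = 0
        else:
            stall += 1
        trace.generations.append({
            "generation": gen,
            "best_fitness": best.fitness,
            "mean_fitness": float(np.mean([r.fitness for r in population])),
            "best_pipeline": str(best.pipeline),
        })
        if stall >= config.plateau_patience:
            break

    trace.best = best
    trace.total_evaluations = evaluator.evaluations
    trace.audit_ids = set(evaluator.audit_ids)
    return best.pipeline, trace


def run_random_search(
    training_cohort: LabeledCohort,
    restrictions: RestrictionTable,
    config: SearchConfig,
    budget: int,
) -> tuple[Pipeline, SearchTrace]:
    """Uniform random sampling baseline at an explicit evaluation budget."""
    tree = PipelineTree(restrictions)
    evaluator = FitnessEvaluator(training_cohort, config)
    trace = SearchTrace()
    best = None
    i = 0
    while evaluator.evaluations < budget:
        pl = sample_pipeline(tree, derive_seed(config.seed, "random", i),
                             include_empty=config.include_empty)
        rec = evaluator.evaluate(pl)
        if best is None or _fitness_sort_key(rec) < _fitness_sort_key(best):
            best = rec
        trace.generations.append({"generation": i, "best_fitness": best.fitness})
        i += 1
    trace.best = best
    trace.total_evaluations = evaluator.evaluations
    trace.audit_ids = set(evaluator.audit_ids)
    return best.pipeline, trace
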