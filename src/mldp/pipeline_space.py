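"""Restriction table, pipeline validity, and the pipeline tree.

A pipeline is an ordered list of preparation steps. The restriction table
bounds pipeline length, per-method repetitions, forbidden co-existing
method pairs and forbidden ordered adjacencies. The pipeline tree contains
a node for every restriction-satisfying pipeline — order matters, so the
same method set in two different orders occupies two distinct nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .prep_ops import METHOD_IDS, PrepStepSpec
from .rng import derive_rng

__all__ = [
    "RestrictionTable",
    "Pipeline",
    "PipelineTree",
    "default_restrictions",
    "is_valid",
    "build_tree",
    "sample_pipeline",
]


@dataclass(frozen=True)
class RestrictionTable:
    method_pool: frozenset
    max_length: int = 7
    max_repetitions: int = 1
    forbidden_pairs: frozenset = frozenset()  # of frozensets {a, b}
    forbidden_adjacencies: frozenset = frozenset()  # of ordered tuples (a, b)

    def __post_init__(self) -> None:
        object.__setattr__(self, "method_pool", frozenset(self.method_pool))
        object.__setattr__(
            self, "forbidden_pairs",
            frozenset(frozenset(p) for p in self.forbidden_pairs))
        object.__setattr__(
            self, "forbidden_adjacencies",
            frozenset(tuple(a) for a in self.forbidden_adjacencies))
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        for pair in self.forbidden_pairs:
            if not pair <= self.method_pool:
                raise ValueError(f"forbidden pair {set(pair)} outside method pool")

    def to_dict(self) -> dict:
        return {
            "method_pool": sorted(self.method_pool),
            "max_length": self.max_length,
            "max_repetitions": self.max_repetitions,
            "forbidden_pairs": sorted(sorted(p) for p in self.forbidden_pairs),
            "forbidden_adjacencies": sorted(list(a) for a in self.forbidden_adjacencies),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RestrictionTable":
        return cls(
            method_pool=frozenset(d["method_pool"]),
            max_length=int(d.get("max_length", 7)),
            max_repetitions=int(d.get("max_repetitions", 1)),
            forbidden_pairs=frozenset(frozenset(p) for p in d.get("forbidden_pairs", [])),
            forbidden_adjacencies=frozenset(
                tuple(a) for a in d.get("forbidden_adjacencies", [])),
        )


def default_restrictions() -> RestrictionTable:
    """Full 8-method pool, length <= 7, no repetitions, SFS and PCA mutually
    exclusive (both reshape the feature space)."""
    return RestrictionTable(
        method_pool=frozenset(METHOD_IDS),
        max_length=7,
        max_repetitions=1,
        forbidden_pairs=frozenset({frozenset({"SFS", "PCA"})}),
    )


@dataclass(frozen=True)
class Pipeline:
    """Ordered, restriction-valid list of preparation steps."""

    steps: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))

    @classmethod
    def from_methods(cls, method_ids, hyperparams: dict | None = None) -> "Pipeline":
        hp = hyperparams or {}
        return cls(tuple(
            PrepStepSpec.make(m, **hp.get(m, {})) for m in method_ids))

    @property
    def method_ids(self) -> tuple:
        return tuple(s.method_id for s in self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def key(self) -> tuple:
        """Hashable identity (methods + hyperparameters), for caching."""
        return tuple((s.method_id, s.hyperparams) for s in self.steps)

    def __str__(self) -> str:
        return " > ".join(str(s) for s in self.steps) if self.steps else "<no-DP>"


def is_valid(method_ids, restrictions: RestrictionTable) -> bool:
    """True iff the ordered method list satisfies every restriction clause.

    The empty pipeline is valid (it is the no-preparation arm).
    """
    seq = [m.method_id if isinstance(m, PrepStepSpec) else m for m in method_ids]
    for m in seq:
        if m not in METHOD_IDS:
            raise ValueError(f"unknown method id {m!r}")
    if any(m not in restrictions.method_pool for m in seq):
        return False
    if len(seq) > restrictions.max_length:
        return False
    for m in set(seq):
        if seq.count(m) > restrictions.max_repetitions:
            return False
    present = set(seq)
    for pair in restrictions.forbidden_pairs:
        if pair <= present:
            return False
    for a, b in zip(seq, seq[1:]):
        if (a, b) in restrictions.forbidden_adjacencies:
            return False
    return True


@dataclass
class PipelineTree:
    """Enumeration of all valid pipelines as root-to-node paths."""

    restrictions: RestrictionTable

    def __post_init__(self) -> None:
        if not self.restrictions.method_pool:
            raise ValueError("method pool is empty")

    def iter_paths(self):
        """Depth-first lazy iteration over every valid pipeline (as a tuple
        of method ids), starting with the empty path."""
        pool = sorted(self.restrictions.method_pool)

        def walk(prefix: list):
            yield tuple(prefix)
            if len(prefix) >= self.restrictions.max_length:
                return
            for m in pool:
                cand = prefix + [m]
                if is_valid(cand, self.restrictions):
                    yield from walk(cand)

        yield from walk([])

    def node_count(self) -> int:
        """1 (root = empty pipeline) + number of valid non-empty pipelines."""
        return sum(1 for _ in self.iter_paths())

    def counts_per_depth(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for path in self.iter_paths():
            counts[len(path)] = counts.get(len(path), 0) + 1
        return counts

    def paths_of_length(self, length: int):
        return [p for p in self.iter_paths() if len(p) == length]


def build_tree(restrictions: RestrictionTable) -> PipelineTree:
    return PipelineTree(restrictions)


def enumerate_valid_bruteforce(restrictions: RestrictionTable) -> set:
    """Independent oracle: filter every <=max_length permutation with
    repetition of the pool through is_valid. Exponential; small pools only."""
    pool = sorted(restrictions.method_pool)
    out = {()}
    # max_repetitions copies of each method can appear
    multiset = pool * restrictions.max_repetitions
    for k in range(1, restrictions.max_length + 1):
        for perm in set(permutations(multiset, k)):
            if is_valid(list(perm), restrictions):
                out.add(perm)
    return out


def sample_pipeline(
    tree: PipelineTree,
    seed: int,
    length_distribution: dict[int, float] | None = None,
    include_empty: bool = False,
    hyperparam_rng: np.random.Generator | None = None,
    max_retries: int = 1000,
) -> Pipeline:
    """Draw a pipeline: first a length (uniform over allowed lengths unless a
    distribution is given), then uniformly among valid pipelines of that
    length by rejection sampling over method sequences. Default
    hyperparameters are attached."""
    rng = derive_rng(seed, "sample_pipeline")
    restrictions = tree.restrictions
    pool = sorted(restrictions.method_pool)
    min_len = 0 if include_empty else 1
    max_len = min(restrictions.max_length,
                  len(pool) * restrictions.max_repetitions)
    if length_distribution is None:
        lengths = list(range(min_len, max_len + 1))
        probs = [1.0 / len(lengths)] * len(lengths)
    else:
        lengths = sorted(length_distribution)
        total = sum(length_distribution.values())
        probs = [length_distribution[L] / total for L in lengths]

    for _ in range(max_retries):
        L = int(rng.choice(lengths, p=probs))
        if L == 0:
            return Pipeline(())
        # uniform over valid length-L sequences: draw uniformly among all
        # no-immediate-repeat-free sequences and reject invalid ones
        for _ in range(200):
            if restrictions.max_repetitions == 1:
                seq = [str(m) for m in rng.permutation(pool)[:L]]
            else:
                seq = [str(m) for m in rng.choice(pool, size=L, replace=True)]
            if is_valid(seq, restrictions):
                return Pipeline(tuple(PrepStepSpec.make(m) for m in seq))
    raise RuntimeError("failed to sample a valid pipeline (retries exhausted)")
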