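"""The eight data-preparation operators.

Each operator follows a uniform contract: it is *fitted and applied* on
training data, returning a prepared cohort plus a :class:`FittedStep`.
Feature-space steps (SFS, PCA) carry a transform that can be replayed on
unseen validation data; sample-space steps (outlier removal, resampling,
purification) may only ever touch training data and refuse to transform.

Distance-based operators (SMOTE, BSMOTE, Tomek links) measure Euclidean
distance on z-scored features (scaling fitted on the cohort at hand) so
large-magnitude features do not dominate neighborhoods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest

from .data_model import CohortError, LabeledCohort
from .rng import derive_rng

__all__ = [
    "METHOD_IDS",
    "CATEGORY_OF",
    "HYPERPARAM_REGISTRY",
    "PrepStepSpec",
    "FittedStep",
    "FittedPipeline",
    "fit_apply_step",
    "fit_pipeline",
    "fit_apply_isolation_forest",
    "fit_sfs_r2",
    "fit_pca",
    "apply_random_oversample",
    "apply_random_undersample",
    "apply_smote",
    "apply_borderline_smote",
    "apply_tomek_links",
]

METHOD_IDS = ("IF", "SFS", "PCA", "RO", "RU", "SMOTE", "BSMOTE", "TL")

# OD outlier detection, FS feature selection, DR dimensionality reduction,
# OS oversampling, US undersampling.
CATEGORY_OF = {
    "IF": "OD",
    "SFS": "FS",
    "PCA": "DR",
    "RO": "OS",
    "SMOTE": "OS",
    "BSMOTE": "OS",
    "RU": "US",
    "TL": "US",
}

FEATURE_SPACE_METHODS = frozenset({"SFS", "PCA"})

# Defaults and search bounds per hyperparameter. Bounds are (low, high,
# is_integer); searchable by the evolutionary optimizer.
HYPERPARAM_REGISTRY: dict[str, dict[str, dict]] = {
    "IF": {
        "n_trees": {"default": 100, "bounds": (50, 200), "int": True},
        "subsample_size": {"default": 256, "bounds": (64, 256), "int": True},
        "score_threshold": {"default": 0.55, "bounds": (0.5, 0.7), "int": False},
    },
    "SFS": {
        "n_keep": {"default": 10, "bounds": (2, 30), "int": True},
        "tol": {"default": 1e-4, "bounds": (1e-6, 1e-2), "int": False},
    },
    "PCA": {
        "variance_retained": {"default": 0.95, "bounds": (0.8, 0.99), "int": False},
    },
    "RO": {
        "target_ratio": {"default": 1.0, "bounds": (0.5, 1.0), "int": False},
    },
    "RU": {
        "target_ratio": {"default": 1.0, "bounds": (0.5, 1.0), "int": False},
    },
    "SMOTE": {
        "k_neighbors": {"default": 5, "bounds": (1, 7), "int": True},
        "target_ratio": {"default": 1.0, "bounds": (0.5, 1.0), "int": False},
    },
    "BSMOTE": {
        "k_neighbors": {"default": 5, "bounds": (1, 7), "int": True},
        "m_danger_neighbors": {"default": 10, "bounds": (5, 15), "int": True},
        "target_ratio": {"default": 1.0, "bounds": (0.5, 1.0), "int": False},
    },
    "TL": {},
}


def default_hyperparams(method_id: str) -> dict:
    return {k: v["default"] for k, v in HYPERPARAM_REGISTRY[method_id].items()}


@dataclass(frozen=True)
class PrepStepSpec:
    """One pipeline step: a method id plus hyperparameters within bounds."""

    method_id: str
    hyperparams: tuple = ()  # sorted (name, value) pairs; hashable

    def __post_init__(self) -> None:
        if self.method_id not in METHOD_IDS:
            raise ValueError(f"unknown method id {self.method_id!r}")
        hp = dict(self.hyperparams) if self.hyperparams else {}
        registry = HYPERPARAM_REGISTRY[self.method_id]
        merged = default_hyperparams(self.method_id)
        for name, value in hp.items():
            if name not in registry:
                raise ValueError(f"{self.method_id} has no hyperparameter {name!r}")
            lo, hi = registry[name]["bounds"]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{self.method_id}.{name}={value} outside bounds [{lo}, {hi}]"
                )
            merged[name] = int(value) if registry[name]["int"] else float(value)
        object.__setattr__(self, "hyperparams", tuple(sorted(merged.items())))

    @property
    def category(self) -> str:
        return CATEGORY_OF[self.method_id]

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)

    @classmethod
    def make(cls, method_id: str, **hyperparams) -> "PrepStepSpec":
        return cls(method_id=method_id, hyperparams=tuple(sorted(hyperparams.items())))

    def __str__(self) -> str:
        inner = ",".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                         for k, v in self.hyperparams)
        return f"{self.method_id}({inner})"


@dataclass
class FittedStep:
    """A step after fitting: scope decides whether it may see unseen data."""

    spec: PrepStepSpec
    scope: str  # "sample_space" | "feature_space"
    state: dict = field(default_factory=dict)

    def transform(self, cohort: LabeledCohort) -> LabeledCohort:
        """Apply the fitted feature-space transform to unseen data."""
        if self.scope != "feature_space":
            raise RuntimeError(
                f"{self.spec.method_id} operates in sample space and cannot "
                "be applied to unseen data"
            )
        if self.spec.method_id == "SFS":
            return cohort.subset_features(self.state["selected"])
        if self.spec.method_id == "PCA":
            Z = (cohort.X - self.state["mean"]) @ self.state["components"].T
            names = [f"PC{i + 1}" for i in range(Z.shape[1])]
            return cohort.with_matrix(Z, names)
        raise RuntimeError(f"no transform for {self.spec.method_id}")


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (X - mu) / sd


def _class_counts(y: np.ndarray) -> tuple[int, int, int, int]:
    """(minority_label, majority_label, n_min, n_maj); ties -> label 1 minority."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 <= n0:
        return 1, 0, n1, n0
    return 0, 1, n0, n1


# ---------------------------------------------------------------------------
# OD: isolation forest


_IF_SCORE_CACHE: dict = {}


def isolation_forest_scores(
    cohort: LabeledCohort, n_trees: int = 100, subsample_size: int = 256, seed: int = 0
) -> np.ndarray:
    """Anomaly scores s(x) = 2^(-E[h(x)]/c(psi)) in (0, 1].

    Scores are memoized on the matrix content hash: within a search the
    same inner-training cohort is scored by many candidate pipelines.
    """
    if cohort.n_samples < 8:
        raise CohortError("isolation forest needs at least 8 samples")
    import hashlib

    key = (
        hashlib.blake2b(cohort.X.tobytes(), digest_size=16).hexdigest(),
        cohort.X.shape, int(n_trees), int(subsample_size), int(seed),
    )
    if key in _IF_SCORE_CACHE:
        return _IF_SCORE_CACHE[key].copy()
    forest = IsolationForest(
        n_estimators=int(n_trees),
        max_samples=min(int(subsample_size), cohort.n_samples),
        random_state=seed,
    )
    forest.fit(cohort.X)
    # sklearn's score_samples is the negated anomaly score of the original
    # formulation, so negate back to the 2^(-E[h]/c) scale.
    scores = -forest.score_samples(cohort.X)
    if len(_IF_SCORE_CACHE) > 4096:
        _IF_SCORE_CACHE.clear()
    _IF_SCORE_CACHE[key] = scores
    return scores.copy()


def fit_apply_isolation_forest(
    cohort: LabeledCohort,
    n_trees: int = 100,
    subsample_size: int = 256,
    score_threshold: float = 0.55,
    seed: int = 0,
) -> tuple[LabeledCohort, FittedStep]:
    """Remove samples whose anomaly score exceeds ``score_threshold``.

    A class is never emptied: if every member of a class would be flagged,
    none of that class is removed and a warning is issued.
    """
    scores = isolation_forest_scores(cohort, n_trees, subsample_size, seed)
    flagged = scores > score_threshold
    for label in (0, 1):
        cls = cohort.y == label
        if cls.any() and flagged[cls].all():
            warnings.warn(
                f"isolation forest would remove every class-{label} sample; "
                "keeping that class intact"
            )
            flagged &= ~cls
    keep = np.flatnonzero(~flagged)
    out = cohort.subset_samples(keep)
    step = FittedStep(
        spec=PrepStepSpec.make(
            "IF",
            n_trees=min(max(n_trees, 50), 200),
            subsample_size=min(max(subsample_size, 64), 256),
            score_threshold=min(max(score_threshold, 0.5), 0.7),
        ),
        scope="sample_space",
        state={"n_removed": int(flagged.sum())},
    )
    return out, step


# ---------------------------------------------------------------------------
# FS: R-squared sequential forward selection


def fit_sfs_r2(
    cohort: LabeledCohort, n_keep: int = 10, tol: float = 1e-4
) -> tuple[LabeledCohort, FittedStep]:
    """Greedy forward selection maximizing OLS R-squared of y on the set.

    Implemented by Gram-Schmidt orthogonalization: at each round the R²
    gain of a candidate equals the squared correlation of its residual
    (after projecting out selected features) with the label residual, so
    each round costs O(n·p). Stops at ``n_keep`` features or when the gain
    drops below ``tol``. Constant/collinear candidates are skipped.
    """
    if not 1 <= n_keep:
        raise ValueError("n_keep must be >= 1")
    n, p = cohort.X.shape
    n_keep = min(int(n_keep), p)

    F = cohort.X - cohort.X.mean(axis=0)  # residual features (intercept out)
    r = cohort.y.astype(float) - cohort.y.mean()  # label residual
    sst = float(r @ r)
    if sst < 1e-12:
        raise CohortError("label has zero variance; SFS undefined")
    if not (F.std(axis=0) > 1e-12).any():
        raise CohortError("all feature columns are constant; SFS undefined")

    selected: list[int] = []
    r2_trace: list[float] = []
    r2 = 0.0
    alive = np.ones(p, dtype=bool)
    for _ in range(n_keep):
        norms2 = np.einsum("ij,ij->j", F, F)
        alive &= norms2 > max(1e-10, 1e-12 * n)
        if not alive.any():
            break
        proj = F.T @ r
        gains = np.where(alive, proj**2 / np.where(norms2 > 0, norms2, 1.0), -1.0)
        best = int(np.argmax(gains))
        gain_r2 = gains[best] / sst
        if gain_r2 < tol:
            break
        q = F[:, best] / math.sqrt(norms2[best])
        r = r - (q @ r) * q
        F = F - np.outer(q, q @ F)
        alive[best] = False
        selected.append(best)
        r2 += gain_r2
        r2_trace.append(r2)

    if not selected:
        # tol killed even the best single feature; keep that one anyway so
        # the step is never a silent no-op feature-space transform.
        norms2 = np.einsum("ij,ij->j", F, F)
        best = int(np.argmax(np.where(norms2 > 1e-10, (F.T @ r) ** 2, -1.0)))
        selected = [best]
        r2_trace = [float((F[:, best] @ r) ** 2 / (norms2[best] * sst))]

    step = FittedStep(
        spec=PrepStepSpec.make("SFS", n_keep=min(max(n_keep, 2), 30),
                               tol=min(max(tol, 1e-6), 1e-2)),
        scope="feature_space",
        state={
            "selected": list(selected),
            "selected_names": [cohort.feature_names[i] for i in selected],
            "r2_trace": r2_trace,
        },
    )
    return step.transform(cohort), step


# ---------------------------------------------------------------------------
# DR: principal component analysis


def fit_pca(
    cohort: LabeledCohort,
    variance_retained: float | None = 0.95,
    n_components: int | None = None,
) -> tuple[LabeledCohort, FittedStep]:
    if cohort.n_samples < 2:
        raise CohortError("PCA needs at least 2 samples")
    if n_components is None:
        if not 0.0 < variance_retained <= 1.0:
            raise ValueError("variance_retained must lie in (0, 1]")
        max_rank = min(cohort.n_samples - 1, cohort.n_features)
        pca = PCA(n_components=max_rank, svd_solver="full")
        pca.fit(cohort.X)
        explained = pca.explained_variance_ratio_
        # smallest k with cumulative explained variance >= target; at
        # variance_retained=1.0 keep the full (numerical) rank
        if variance_retained >= 1.0:
            k = int((pca.explained_variance_ > 1e-10 * pca.explained_variance_[0]).sum())
        else:
            k = int(np.searchsorted(np.cumsum(explained), variance_retained) + 1)
        k = max(1, min(k, max_rank))
    else:
        k = int(n_components)
        pca = PCA(n_components=min(k, min(cohort.n_samples - 1, cohort.n_features)),
                  svd_solver="full")
        pca.fit(cohort.X)
        k = pca.n_components_

    step = FittedStep(
        spec=PrepStepSpec.make("PCA", variance_retained=min(max(
            variance_retained if variance_retained is not None else 0.95, 0.8), 0.99)),
        scope="feature_space",
        state={
            "mean": pca.mean_.copy(),
            "components": pca.components_[:k].copy(),
            "explained_variance": pca.explained_variance_[:k].copy(),
            "input_features": list(cohort.feature_names),
        },
    )
    return step.transform(cohort), step


# ---------------------------------------------------------------------------
# OS / US: resampling


def _oversample_deficit(n_min: int, n_maj: int, target_ratio: float) -> int:
    return max(0, math.ceil(target_ratio * n_maj) - n_min)


def apply_random_oversample(
    cohort: LabeledCohort, target_ratio: float = 1.0, seed: int = 0
) -> tuple[LabeledCohort, FittedStep]:
    """Duplicate uniformly-drawn minority rows until min/maj >= target."""
    cohort.require_both_classes()
    min_lab, _, n_min, n_maj = _class_counts(cohort.y)
    deficit = _oversample_deficit(n_min, n_maj, target_ratio)
    step = FittedStep(PrepStepSpec.make("RO", target_ratio=target_ratio), "sample_space")
    if deficit == 0:
        warnings.warn("oversampling target already met; no-op")
        return cohort, step
    rng = derive_rng(seed, "RO")
    min_idx = np.flatnonzero(cohort.y == min_lab)
    picks = rng.choice(min_idx, size=deficit, replace=True)
    X = np.vstack([cohort.X, cohort.X[picks]])
    y = np.concatenate([cohort.y, cohort.y[picks]])
    ids = list(cohort.sample_ids) + [
        f"{cohort.sample_ids[i]}__ro{j + 1}" for j, i in enumerate(picks)
    ]
    out = LabeledCohort(tuple(ids), cohort.feature_names, X, y,
                        cohort.positive_label_name, cohort.provenance)
    return out, step


def apply_random_undersample(
    cohort: LabeledCohort, target_ratio: float = 1.0, seed: int = 0
) -> tuple[LabeledCohort, FittedStep]:
    """Remove uniformly-drawn majority rows until min/maj >= target."""
    cohort.require_both_classes()
    min_lab, maj_lab, n_min, n_maj = _class_counts(cohort.y)
    n_maj_target = max(n_min, math.floor(n_min / target_ratio))
    step = FittedStep(PrepStepSpec.make("RU", target_ratio=target_ratio), "sample_space")
    if n_maj_target >= n_maj:
        warnings.warn("undersampling target already met; no-op")
        return cohort, step
    rng = derive_rng(seed, "RU")
    maj_idx = np.flatnonzero(cohort.y == maj_lab)
    keep_maj = rng.choice(maj_idx, size=n_maj_target, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(cohort.y == min_lab), keep_maj]))
    return cohort.subset_samples(keep), step


def _synthesize_minority(
    cohort: LabeledCohort,
    seeds_idx: np.ndarray,
    neighbor_pool_idx: np.ndarray,
    k_neighbors: int,
    n_new: int,
    rng: np.random.Generator,
    tag: str,
) -> LabeledCohort:
    """Interpolate n_new synthetic rows between seed points and their k
    nearest neighbors from ``neighbor_pool_idx`` (z-scored Euclidean)."""
    Z = _zscore(cohort.X)
    D = cdist(Z[seeds_idx], Z[neighbor_pool_idx])
    # drop self-distances where a seed is also in the pool
    for si, s in enumerate(seeds_idx):
        self_pos = np.flatnonzero(neighbor_pool_idx == s)
        if self_pos.size:
            D[si, self_pos[0]] = np.inf
    k = min(k_neighbors, max(1, len(neighbor_pool_idx) - 1))
    nn = np.argsort(D, axis=1)[:, :k]

    rows = np.empty((n_new, cohort.n_features))
    labels = np.empty(n_new, dtype=int)
    ids = []
    for j in range(n_new):
        si = rng.integers(len(seeds_idx))
        base = seeds_idx[si]
        nb = neighbor_pool_idx[nn[si, rng.integers(k)]]
        u = rng.random()
        rows[j] = cohort.X[base] + u * (cohort.X[nb] - cohort.X[base])
        labels[j] = cohort.y[base]
        ids.append(f"{cohort.sample_ids[base]}__{tag}{j + 1}")
    X = np.vstack([cohort.X, rows])
    y = np.concatenate([cohort.y, labels])
    all_ids = list(cohort.sample_ids) + ids
    return LabeledCohort(tuple(all_ids), cohort.feature_names, X, y,
                         cohort.positive_label_name, cohort.provenance)


def apply_smote(
    cohort: LabeledCohort,
    k_neighbors: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[LabeledCohort, FittedStep]:
    """Synthetic minority oversampling: x_new = x_i + u (x_nn − x_i)."""
    cohort.require_both_classes()
    min_lab, _, n_min, n_maj = _class_counts(cohort.y)
    if n_min < 2:
        raise CohortError("SMOTE needs at least 2 minority samples")
    k = int(k_neighbors)
    if n_min <= k:
        warnings.warn(f"k_neighbors reduced from {k} to {n_min - 1}")
        k = n_min - 1
    spec = PrepStepSpec.make("SMOTE", k_neighbors=k_neighbors, target_ratio=target_ratio)
    step = FittedStep(spec, "sample_space")
    deficit = _oversample_deficit(n_min, n_maj, target_ratio)
    if deficit == 0:
        warnings.warn("SMOTE target already met; no-op")
        return cohort, step
    rng = derive_rng(seed, "SMOTE")
    min_idx = np.flatnonzero(cohort.y == min_lab)
    out = _synthesize_minority(cohort, min_idx, min_idx, k, deficit, rng, "sm")
    return out, step


def apply_borderline_smote(
    cohort: LabeledCohort,
    k_neighbors: int = 5,
    m_danger_neighbors: int = 10,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[LabeledCohort, FittedStep]:
    """Borderline variant: only danger-zone minority samples seed synthesis.

    Each minority sample is classified by its m nearest neighbors over ALL
    samples: noise (all m majority), danger (at least m/2 majority) or safe.
    """
    cohort.require_both_classes()
    min_lab, maj_lab, n_min, n_maj = _class_counts(cohort.y)
    if n_min < 2:
        raise CohortError("BSMOTE needs at least 2 minority samples")
    k = int(k_neighbors)
    if n_min <= k:
        warnings.warn(f"k_neighbors reduced from {k} to {n_min - 1}")
        k = n_min - 1
    spec = PrepStepSpec.make(
        "BSMOTE",
        k_neighbors=k_neighbors,
        m_danger_neighbors=m_danger_neighbors,
        target_ratio=target_ratio,
    )
    step = FittedStep(spec, "sample_space")

    m = min(int(m_danger_neighbors), cohort.n_samples - 1)
    Z = _zscore(cohort.X)
    min_idx = np.flatnonzero(cohort.y == min_lab)
    D = cdist(Z[min_idx], Z)
    D[np.arange(len(min_idx)), min_idx] = np.inf
    nn = np.argsort(D, axis=1)[:, :m]
    maj_counts = (cohort.y[nn] == maj_lab).sum(axis=1)
    danger = min_idx[(maj_counts >= m / 2.0) & (maj_counts < m)]
    step.state["danger_ids"] = [cohort.sample_ids[i] for i in danger]

    deficit = _oversample_deficit(n_min, n_maj, target_ratio)
    if deficit == 0:
        warnings.warn("BSMOTE target already met; no-op")
        return cohort, step
    if len(danger) == 0:
        warnings.warn("BSMOTE danger set empty; no-op")
        return cohort, step
    rng = derive_rng(seed, "BSMOTE")
    out = _synthesize_minority(cohort, danger, min_idx, k, deficit, rng, "bsm")
    return out, step


def tomek_links(cohort: LabeledCohort) -> list[tuple[int, int]]:
    """All opposite-class mutual-nearest-neighbor pairs (z-scored Euclidean)."""
    cohort.require_both_classes()
    Z = _zscore(cohort.X)
    D = cdist(Z, Z)
    np.fill_diagonal(D, np.inf)
    nn = D.argmin(axis=1)
    links = []
    for a in range(cohort.n_samples):
        b = int(nn[a])
        if a < b and nn[b] == a and cohort.y[a] != cohort.y[b]:
            links.append((a, b))
    return links


def apply_tomek_links(cohort: LabeledCohort) -> tuple[LabeledCohort, FittedStep]:
    """Remove the majority-class member of every Tomek link (deterministic)."""
    min_lab, maj_lab, _, n_maj = _class_counts(cohort.y)
    links = tomek_links(cohort)
    drop = {i for a, b in links for i in (a, b) if cohort.y[i] == maj_lab}
    if len(drop) >= n_maj:
        warnings.warn("Tomek purification would empty the majority class; no-op")
        drop = set()
    keep = [i for i in range(cohort.n_samples) if i not in drop]
    step = FittedStep(PrepStepSpec.make("TL"), "sample_space",
                      {"n_removed": len(drop)})
    return cohort.subset_samples(keep), step


# ---------------------------------------------------------------------------
# dispatch / whole-pipeline fitting

_MIN_FIT_SAMPLES = 8


def fit_apply_step(
    cohort: LabeledCohort, spec: PrepStepSpec, seed: int = 0
) -> tuple[LabeledCohort, FittedStep]:
    hp = spec.params
    if spec.method_id == "IF":
        return fit_apply_isolation_forest(cohort, seed=seed, **hp)
    if spec.method_id == "SFS":
        return fit_sfs_r2(cohort, n_keep=hp["n_keep"], tol=hp["tol"])
    if spec.method_id == "PCA":
        return fit_pca(cohort, variance_retained=hp["variance_retained"])
    if spec.method_id == "RO":
        return apply_random_oversample(cohort, seed=seed, **hp)
    if spec.method_id == "RU":
        return apply_random_undersample(cohort, seed=seed, **hp)
    if spec.method_id == "SMOTE":
        return apply_smote(cohort, seed=seed, **hp)
    if spec.method_id == "BSMOTE":
        return apply_borderline_smote(cohort, seed=seed, **hp)
    if spec.method_id == "TL":
        return apply_tomek_links(cohort)
    raise ValueError(f"unknown method id {spec.method_id!r}")


@dataclass
class FittedPipeline:
    """An ordered pipeline after fitting on training data.

    ``steps`` holds every fitted step in execution order; only the
    feature-space subset is replayed on validation data.
    """

    steps: list[FittedStep]

    @property
    def feature_space_steps(self) -> list[FittedStep]:
        return [s for s in self.steps if s.scope == "feature_space"]

    def transform_validation(self, cohort: LabeledCohort) -> LabeledCohort:
        """Apply only the feature-space transforms, in pipeline order.

        Sample count is invariant by construction.
        """
        n_before = cohort.n_samples
        for step in self.feature_space_steps:
            cohort = step.transform(cohort)
        assert cohort.n_samples == n_before
        return cohort


def fit_pipeline(
    cohort: LabeledCohort, steps, seed: int = 0
) -> tuple[LabeledCohort, FittedPipeline]:
    """Fit-apply an ordered list of :class:`PrepStepSpec` on training data.

    Accepts a ``Pipeline`` (anything with ``.steps``) or a plain list.
    """
    from .rng import derive_seed

    specs = list(getattr(steps, "steps", steps))
    fitted: list[FittedStep] = []
    current = cohort
    seen: dict[str, int] = {}
    for spec in specs:
        occ = seen.get(spec.method_id, 0)
        seen[spec.method_id] = occ + 1
        # seed by method identity (not position) so identical prefixes of
        # different pipelines produce identical intermediate cohorts
        step_seed = derive_seed(seed, spec.method_id, occ)
        current, step = fit_apply_step(current, spec, seed=step_seed)
        fitted.append(step)
    return current, FittedPipeline(fitted)
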