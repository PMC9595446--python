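"""Five fixed-default binary classifier schemes behind one interface.

Schemes: RF (random forest), MG (bespoke multi-Gaussian), SVM (RBF, Platt
probabilities), XGB (gradient boosting; 100 rounds, depth 6, learning rate
0.3), NN (one hidden layer of 32 rectified units). Parameters are pinned in
a registry — "default" is reproducible. Scale-sensitive schemes (SVM, NN,
MG) see z-scored features (scaler fitted on training data); tree ensembles
consume raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .data_model import CohortError, LabeledCohort

__all__ = ["SCHEMES", "ClassifierSpec", "TrainedModel", "train",
           "predict_scores", "MultiGaussian"]

SCHEMES = ("RF", "MG", "SVM", "XGB", "NN")

_SCALED_SCHEMES = frozenset({"SVM", "NN", "MG"})


class MultiGaussian:
    """Per-class diagonal-covariance Gaussian classifier with shrinkage.

    For each class c: mean mu_c, diagonal variance var_c regularized as
    var_c + eps + lam * overall_var (eps = 1e-6 floor, lam = 0.1 shrinkage
    toward the pooled per-feature variance). Scores are posterior
    probabilities P(c=1 | x) from class-conditional log-likelihoods and
    empirical priors.
    """

    EPS = 1e-6
    LAM = 0.1

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MultiGaussian":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        for c in (0, 1):
            if (y == c).sum() < 3:
                raise CohortError("multi-Gaussian needs >= 3 samples per class")
        overall_var = X.var(axis=0)
        self.means_ = {}
        self.vars_ = {}
        self.log_priors_ = {}
        n = len(y)
        for c in (0, 1):
            Xc = X[y == c]
            self.means_[c] = Xc.mean(axis=0)
            self.vars_[c] = Xc.var(axis=0) + self.EPS + self.LAM * overall_var
            self.log_priors_[c] = np.log(len(Xc) / n)
        return self

    def class_log_likelihood(self, X: np.ndarray, c: int) -> np.ndarray:
        mu, var = self.means_[c], self.vars_[c]
        return -0.5 * (np.log(2 * np.pi * var) + (X - mu) ** 2 / var).sum(axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        joint = np.column_stack([
            self.class_log_likelihood(X, c) + self.log_priors_[c] for c in (0, 1)
        ])
        joint -= joint.max(axis=1, keepdims=True)
        p = np.exp(joint)
        p /= p.sum(axis=1, keepdims=True)
        return p


def _build_estimator(scheme: str, seed: int):
    if scheme == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if scheme == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", probability=True,
                   random_state=seed)
    if scheme == "XGB":
        return GradientBoostingClassifier(n_estimators=100, max_depth=6,
                                          learning_rate=0.3, random_state=seed)
    if scheme == "NN":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=200,
                             solver="adam", random_state=seed)
    if scheme == "MG":
        return MultiGaussian()
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    scheme: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    feature_names: tuple
    estimator: object
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None


def train(spec: ClassifierSpec, cohort: LabeledCohort) -> TrainedModel:
    """Fit the scheme at its pinned defaults; deterministic given the seed."""
    cohort.require_both_classes()
    X = cohort.X
    mean = sd = None
    if spec.scheme in _SCALED_SCHEMES:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        X = (X - mean) / sd
    est = _build_estimator(spec.scheme, spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NN convergence chatter at 200 epochs
        est.fit(X, cohort.y)
    return TrainedModel(spec, cohort.feature_names, est, mean, sd)


def predict_scores(model: TrainedModel, data) -> np.ndarray:
    """Positive-class scores in [0, 1]; threshold 0.5 gives class labels.

    ``data`` is a LabeledCohort (feature names must match the fitted ones)
    or a raw matrix with the fitted column count and order.
    """
    if isinstance(data, LabeledCohort):
        if data.feature_names != model.feature_names:
            raise CohortError(
                "feature mismatch: model fitted on "
                f"{len(model.feature_names)} features, got {len(data.feature_names)}"
            )
        X = data.X
    else:
        X = np.asarray(data, float)
        if X.ndim != 2 or X.shape[1] != len(model.feature_names):
            raise CohortError(
                f"feature mismatch: expected {len(model.feature_names)} columns"
            )
    if model.scaler_mean is not None:
        X = (X - model.scaler_mean) / model.scaler_sd
    proba = model.estimator.predict_proba(X)
    return np.clip(proba[:, 1], 0.0, 1.0)
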