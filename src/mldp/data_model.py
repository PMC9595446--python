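"""Core cohort data structures and delimited-text I/O.

A :class:`LabeledCohort` is the currency passed between every preparation
operator, the pipeline search and the evaluation harness: a dense numeric
feature matrix, a binary endpoint vector and stable sample/feature
identifiers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LabeledCohort",
    "ImbalanceRatio",
    "CohortError",
    "SchemaError",
    "ParseError",
    "DegenerateCohortError",
    "read_cohort",
    "write_cohort",
    "imbalance_ratio",
]


class CohortError(ValueError):
    """Base class for cohort construction/ingestion failures."""


class SchemaError(CohortError):
    """A required column is missing or duplicated."""


class ParseError(CohortError):
    """A feature cell failed numeric parsing; message names row and column."""


class DegenerateCohortError(CohortError):
    """The endpoint column carries fewer than two classes."""


@dataclass(frozen=True)
class LabeledCohort:
    """Labeled feature table: one row per sample, one binary endpoint.

    ``y`` is always coded {0, 1} with 1 the positive endpoint. ``X`` is a
    dense float matrix with no NaN/Inf entries.
    """

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    positive_label_name: str = "1"
    provenance: str = ""

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        if X.ndim != 2:
            raise CohortError("X must be a 2-D matrix")
        if X.shape[0] != len(y) or X.shape[0] != len(self.sample_ids):
            raise CohortError(
                f"inconsistent sample counts: X has {X.shape[0]} rows, "
                f"y has {len(y)}, {len(self.sample_ids)} sample ids"
            )
        if X.shape[1] != len(self.feature_names):
            raise CohortError(
                f"X has {X.shape[1]} columns but {len(self.feature_names)} feature names"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortError("sample ids must be unique")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise CohortError("feature names must be unique")
        if not np.all(np.isfinite(X)):
            raise CohortError("X contains NaN/Inf entries")
        if not np.isin(y, (0, 1)).all():
            raise CohortError("y must be coded {0,1}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise DegenerateCohortError(
                f"cohort '{self.provenance or '<unnamed>'}' carries a single class"
            )

    def subset_samples(self, indices) -> "LabeledCohort":
        """Row subset (copy); used by splits and sample-space operators."""
        idx = np.asarray(indices)
        return replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            X=self.X[idx].copy(),
            y=self.y[idx].copy(),
        )

    def subset_features(self, indices) -> "LabeledCohort":
        idx = np.asarray(indices)
        return replace(
            self,
            feature_names=tuple(self.feature_names[i] for i in idx),
            X=self.X[:, idx].copy(),
        )

    def with_matrix(self, X: np.ndarray, feature_names) -> "LabeledCohort":
        """Replace the feature space (same samples), e.g. after projection."""
        return replace(self, X=np.asarray(X, dtype=float), feature_names=tuple(feature_names))


@dataclass(frozen=True)
class ImbalanceRatio:
    """Majority-vs-minority class percentages, reported rounded."""

    majority_pct: int
    minority_pct: int

    def __post_init__(self) -> None:
        if self.majority_pct < self.minority_pct:
            raise ValueError("majority_pct must be >= minority_pct")

    def __str__(self) -> str:  # Table-style "67-vs-33"
        return f"{self.majority_pct}-vs-{self.minority_pct}"


def imbalance_ratio(cohort: LabeledCohort) -> ImbalanceRatio:
    """Class percentages of the cohort, rounded to integers for reporting."""
    if cohort.n_samples == 0:
        raise CohortError("empty cohort has no imbalance ratio")
    n1 = int(cohort.y.sum())
    n0 = cohort.n_samples - n1
    maj, mino = max(n0, n1), min(n0, n1)
    maj_pct = round(100.0 * maj / cohort.n_samples)
    return ImbalanceRatio(majority_pct=maj_pct, minority_pct=100 - maj_pct)


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(65536)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_cohort(
    path: str,
    label_column: str,
    positive_value: str,
    id_column: str | None = None,
    delimiter: str | None = None,
    provenance: str = "",
) -> LabeledCohort:
    """Read a delimited feature table into a :class:`LabeledCohort`.

    Every non-label, non-id column must parse as numeric. Rows with a
    missing feature value are rejected (no silent imputation). Labels are
    binarized immediately: 1 where the label cell equals ``positive_value``.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if label_column not in df.columns:
        raise SchemaError(f"label column '{label_column}' not found in {path}")
    if id_column is not None and id_column not in df.columns:
        raise SchemaError(f"id column '{id_column}' not found in {path}")

    labels = df[label_column].astype(str)
    if id_column is not None:
        sample_ids = [str(v) for v in df[id_column]]
        feat_df = df.drop(columns=[label_column, id_column])
    else:
        sample_ids = [str(i) for i in range(len(df))]
        feat_df = df.drop(columns=[label_column])

    feature_names = list(feat_df.columns)
    parsed = np.empty((len(df), len(feature_names)), dtype=float)
    for j, col in enumerate(feature_names):
        converted = pd.to_numeric(feat_df[col], errors="coerce")
        bad = converted.isna() & feat_df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {feat_df[col].iloc[row]!r} in feature "
                f"column '{col}', row {row}"
            )
        parsed[:, j] = converted.to_numpy(dtype=float)

    keep = np.isfinite(parsed).all(axis=1)
    parsed = parsed[keep]
    sample_ids = [s for s, k in zip(sample_ids, keep) if k]
    labels = labels[keep]

    y = (labels == str(positive_value)).astype(int).to_numpy()
    cohort = LabeledCohort(
        sample_ids=tuple(sample_ids),
        feature_names=tuple(feature_names),
        X=parsed,
        y=y,
        positive_label_name=str(positive_value),
        provenance=provenance or path,
    )
    cohort.require_both_classes()
    return cohort


def write_cohort(
    cohort: LabeledCohort,
    path: str,
    label_column: str = "label",
    id_column: str = "sample_id",
    delimiter: str = ",",
) -> None:
    """Write a cohort so that ``read_cohort`` round-trips it.

    The positive class is written as ``positive_label_name``; the negative
    class as ``not_<positive_label_name>`` unless that would collide.
    """
    pos = cohort.positive_label_name
    neg = f"not_{pos}"
    df = pd.DataFrame(cohort.X, columns=list(cohort.feature_names))
    df.insert(0, id_column, list(cohort.sample_ids))
    df[label_column] = np.where(cohort.y == 1, pos, neg)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
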