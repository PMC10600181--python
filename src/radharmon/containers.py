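"""Core data containers and CSV I/O.

The pipeline's central object is a subjects x features matrix with a
per-subject scanner ("batch") label.  Companion containers hold binary
gene-mutation indicators and per-scanner phantom measurements.  All three
round-trip through plain CSV: ``subject_id`` is always the first column,
and the batch column is named ``batch`` with small-integer labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "MutationMatrix",
    "PhantomMeasurement",
    "read_feature_matrix",
    "read_mutation_matrix",
    "read_phantom",
]


class DataValidationError(ValueError):
    """Malformed or inconsistent input table."""


@dataclass
class FeatureMatrix:
    """Subjects x radiomic-features matrix with per-subject batch labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Real-valued feature matrix, indexed by subject id, one column per
        feature.  All entries must be finite.
    batch : pandas.Series
        Integer batch (scanner) label per subject, aligned with ``values``.
    """

    values: pd.DataFrame
    batch: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate subject ids: {dups}")
        if not self.values.index.equals(self.batch.index):
            raise DataValidationError("batch labels do not align with subject ids")
        if self.batch.isna().any():
            missing = self.batch.index[self.batch.isna()].tolist()
            raise DataValidationError(f"missing batch labels for subjects: {missing}")
        self.batch = self.batch.astype(int)
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = [c for c in self.values.columns
                   if not np.issubdtype(self.values[c].dtype, np.number)]
            raise DataValidationError(f"non-numeric feature columns: {bad}")
        if not np.isfinite(arr).all():
            rows, cols = np.where(~np.isfinite(arr))
            loc = (self.values.index[rows[0]], self.values.columns[cols[0]])
            raise DataValidationError(f"non-finite feature value at {loc}")
        self.values = self.values.astype(float)

    @property
    def subject_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def feature_names(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def batches(self) -> list[int]:
        """Distinct batch labels in sorted order."""
        return sorted(self.batch.unique().tolist())

    def batch_mask(self, label: int) -> np.ndarray:
        return (self.batch == label).to_numpy()

    def with_values(self, new_values: np.ndarray | pd.DataFrame) -> "FeatureMatrix":
        """Copy carrying the same ids/batch labels but new feature values."""
        df = pd.DataFrame(np.asarray(new_values, dtype=float),
                          index=self.values.index, columns=self.values.columns)
        return FeatureMatrix(values=df, batch=self.batch.copy())

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "batch", self.batch)
        out.index.name = "subject_id"
        out.to_csv(path, float_format="%.17g")

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        return (isinstance(other, FeatureMatrix)
                and self.values.equals(other.values)
                and self.batch.equals(other.batch))


@dataclass
class MutationMatrix:
    """Subjects x genes binary mutation indicators (1 = mutated)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate subject ids: {dups}")
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise DataValidationError("mutation matrix entries must be 0 or 1")
        self.values = self.values.astype(int)

    @property
    def subject_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def gene_names(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def frequencies(self) -> pd.Series:
        """Per-gene cohort mutation fraction."""
        return self.values.mean(axis=0)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "subject_id"
        out.to_csv(path)


@dataclass
class PhantomMeasurement:
    """One feature vector measured on a uniform cylinder phantom by one scanner."""

    scanner_id: str
    values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)

    @property
    def feature_names(self) -> list[str]:
        return self.values.index.tolist()

    def to_csv(self, path) -> None:
        out = pd.DataFrame({"scanner_id": self.scanner_id, "value": self.values})
        out.index.name = "feature"
        out.to_csv(path, float_format="%.17g")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a FeatureMatrix CSV (``subject_id``, ``batch``, then features).

    Raises :class:`DataValidationError` naming the offending row/column for
    duplicate ids, missing batch column, or non-numeric cells.
    """
    df = pd.read_csv(path, index_col="subject_id", float_precision="round_trip")
    if "batch" not in df.columns:
        raise DataValidationError(f"{path}: missing required 'batch' column")
    batch = df["batch"]
    feats = df.drop(columns=["batch"])
    for col in feats.columns:
        if not np.issubdtype(feats[col].dtype, np.number):
            bad = feats[col][pd.to_numeric(feats[col], errors="coerce").isna()]
            raise DataValidationError(
                f"{path}: non-numeric value in column '{col}', rows {bad.index.tolist()}")
    return FeatureMatrix(values=feats, batch=batch)


def read_mutation_matrix(path) -> MutationMatrix:
    df = pd.read_csv(path, index_col="subject_id")
    return MutationMatrix(values=df)


def read_phantom(path) -> PhantomMeasurement:
    df = pd.read_csv(path, index_col="feature", float_precision="round_trip")
    if "value" not in df.columns:
        raise DataValidationError(f"{path}: missing required 'value' column")
    scanner = str(df["scanner_id"].iloc[0]) if "scanner_id" in df.columns else "unknown"
    return PhantomMeasurement(scanner_id=scanner, values=df["value"])
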