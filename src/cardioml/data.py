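"""Tabular data containers, CSV I/O, standardization, and stratified splitting.

Every pipeline stage consumes and produces a :class:`Dataset`: a dense float
feature matrix ``X``, a binary label vector ``y`` (1 = disease present), and a
:class:`Schema` describing column names, kinds and the label column.  The
default schema mirrors the common 12-feature cardiovascular-disease (CVD)
record layout: demographics, blood pressure, cholesterol/glucose grades, and
lifestyle flags, with ``cardio`` as the binary target.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Schema",
    "Dataset",
    "Scaler",
    "Split",
    "CVD_SCHEMA",
    "BOOL_CODES",
    "SchemaError",
    "ParseError",
    "load_table",
    "save_table",
    "zscore",
    "stratified_split",
]

COLUMN_KINDS = ("continuous", "binary", "ordinal")

#: Text-to-number codes applied when loading boolean-like columns.
#: "O"/other gender is a documented third code, mapped to 0 (off) by default.
BOOL_CODES = {
    "True": 1.0, "False": 0.0,
    "true": 1.0, "false": 0.0,
    "M": 1.0, "F": 0.0, "O": 0.0,
    "1": 1.0, "0": 0.0,
}


class SchemaError(ValueError):
    """Column layout of a file does not match the declared schema."""


class ParseError(ValueError):
    """A cell could not be coerced to its declared kind."""


@dataclass(frozen=True)
class Schema:
    """Column layout of a record table.

    Parameters
    ----------
    column_names:
        Ordered feature/label column names; must be unique.
    column_kinds:
        One of ``continuous``, ``binary``, ``ordinal`` per column.
    label_name:
        Name of the binary target column (must appear in ``column_names``).
    """

    column_names: tuple[str, ...]
    column_kinds: tuple[str, ...]
    label_name: str

    def __post_init__(self) -> None:
        names = tuple(self.column_names)
        kinds = tuple(self.column_kinds)
        object.__setattr__(self, "column_names", names)
        object.__setattr__(self, "column_kinds", kinds)
        if len(names) != len(set(names)):
            raise SchemaError("column names must be unique")
        if len(kinds) != len(names):
            raise SchemaError(
                f"{len(kinds)} kinds declared for {len(names)} columns"
            )
        for kind in kinds:
            if kind not in COLUMN_KINDS:
                raise SchemaError(f"unknown column kind {kind!r}")
        if self.label_name not in names:
            raise SchemaError(f"label column {self.label_name!r} not in schema")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.column_names if n != self.label_name)

    @property
    def feature_kinds(self) -> tuple[str, ...]:
        return tuple(
            k for n, k in zip(self.column_names, self.column_kinds)
            if n != self.label_name
        )

    @property
    def n_features(self) -> int:
        return len(self.column_names) - 1

    def subset(self, feature_names: Sequence[str]) -> "Schema":
        """Schema restricted to ``feature_names`` (original order) + label."""
        keep = set(feature_names) | {self.label_name}
        names = tuple(n for n in self.column_names if n in keep)
        kinds = tuple(
            k for n, k in zip(self.column_names, self.column_kinds) if n in keep
        )
        return Schema(names, kinds, self.label_name)


#: Default 12-feature CVD schema: 11 named clinical/lifestyle features plus a
#: body-mass-index column, with the presence/absence label ``cardio``.
CVD_SCHEMA = Schema(
    column_names=(
        "age", "gender", "height", "weight", "ap_hi", "ap_lo",
        "cholesterol", "gluc", "smoke", "alco", "active", "bmi", "cardio",
    ),
    column_kinds=(
        "continuous", "binary", "continuous", "continuous", "continuous",
        "continuous", "ordinal", "ordinal", "binary", "binary", "binary",
        "continuous", "binary",
    ),
    label_name="cardio",
)


@dataclass
class Dataset:
    """Feature matrix + binary label vector + schema."""

    X: np.ndarray
    y: np.ndarray
    schema: Schema

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X row count must equal y length")
        if self.X.shape[1] != self.schema.n_features:
            raise ValueError(
                f"X has {self.X.shape[1]} columns, schema declares "
                f"{self.schema.n_features} features"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        labels = set(np.unique(self.y))
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(labels)}")

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {int(c): int(n) for c, n in zip(*np.unique(self.y, return_counts=True))}

    def take(self, indices: np.ndarray) -> "Dataset":
        """Row subset (copy) preserving the schema."""
        idx = np.asarray(indices)
        return Dataset(self.X[idx].copy(), self.y[idx].copy(), self.schema)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.schema.feature_names))
        df[self.schema.label_name] = self.y
        return df[list(self.schema.column_names)]


@dataclass
class Scaler:
    """Per-column location/scale transform (population standard deviation).

    Constant columns (sd = 0) are mapped to all-zeros on transform and restored
    exactly on inverse-transform.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 records to fit a scaler")
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        # constant columns: rounding can leave std ~ 1e-15, which would blow
        # rounding noise up to unit variance; snap those to exactly 0
        std[std <= 1e-12 * (1.0 + np.abs(mean))] = 0.0
        return cls(mean=mean, std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        denom = np.where(self.std > 0, self.std, 1.0)
        return (X - self.mean) / denom

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        denom = np.where(self.std > 0, self.std, 1.0)
        return np.asarray(Z, dtype=float) * denom + self.mean

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("column\tmean\tstd\n")
            for i, (m, s) in enumerate(zip(self.mean, self.std)):
                fh.write(f"{i}\t{float(m)!r}\t{float(s)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Scaler":
        means, stds = [], []
        with open(path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                _, m, s = line.rstrip("\n").split("\t")
                means.append(float(m))
                stds.append(float(s))
        return cls(mean=np.array(means), std=np.array(stds))


@dataclass(frozen=True)
class Split:
    """Disjoint train/test index sets produced by :func:`stratified_split`."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int


def _coerce_cell(value: str, kind: str, row: int, column: str) -> float:
    text = value.strip()
    if kind == "binary" and text in BOOL_CODES:
        return BOOL_CODES[text]
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"cannot parse {value!r} in row {row}, column {column!r}"
        ) from None


def load_table(
    path: str | Path,
    schema: Schema = CVD_SCHEMA,
    missing_policy: str = "drop_row",
) -> Dataset:
    """Load a header-first CSV into a :class:`Dataset`.

    Header order is irrelevant; columns are reordered to the schema.  Cells in
    binary columns accept the :data:`BOOL_CODES` spellings.  Rows with missing
    cells are dropped (``missing_policy="drop_row"``, the default) or rejected
    (``"error"``).
    """
    if missing_policy not in ("drop_row", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path} is empty") from None
        header = [h.strip() for h in header]
        missing_cols = set(schema.column_names) - set(header)
        if missing_cols:
            raise SchemaError(f"file is missing columns {sorted(missing_cols)}")
        unknown = set(header) - set(schema.column_names)
        if unknown:
            raise SchemaError(f"file has unknown columns {sorted(unknown)}")
        col_pos = {name: header.index(name) for name in schema.column_names}
        rows: list[list[float]] = []
        for r, record in enumerate(reader, start=1):
            if not record:
                continue
            cells = []
            has_missing = False
            for name, kind in zip(schema.column_names, schema.column_kinds):
                raw = record[col_pos[name]] if col_pos[name] < len(record) else ""
                if raw.strip() == "" or raw.strip().lower() in ("nan", "na"):
                    has_missing = True
                    break
                cells.append(_coerce_cell(raw, kind, r, name))
            if has_missing:
                if missing_policy == "error":
                    raise ParseError(f"missing cell in row {r}")
                continue
            rows.append(cells)
    if not rows:
        raise SchemaError(f"{path} contains no usable data rows")
    table = np.array(rows, dtype=float)
    label_idx = schema.column_names.index(schema.label_name)
    feat_idx = [i for i in range(len(schema.column_names)) if i != label_idx]
    y = table[:, label_idx]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ParseError(f"label column {schema.label_name!r} is not binary")
    return Dataset(table[:, feat_idx], y.astype(int), schema)


def save_table(ds: Dataset, path: str | Path) -> None:
    """Write a :class:`Dataset` to CSV with the schema's column order."""
    ds.to_frame().to_csv(path, index=False)


def zscore(ds: Dataset) -> tuple[Dataset, Scaler]:
    """Standardize every feature column to mean 0, population sd 1.

    Constant columns become all-zeros.  Returns the transformed dataset and
    the fitted :class:`Scaler`, so the identical transform can be applied to
    held-out data.
    """
    scaler = Scaler.fit(ds.X)
    return Dataset(scaler.transform(ds.X), ds.y, ds.schema), scaler


def stratified_split(
    ds: Dataset, test_fraction: float, seed: int
) -> Split:
    """Class-stratified train/test partition of the record indices.

    Per class, ``round(class_count * test_fraction)`` records go to the test
    set; assignment is a seeded permutation, so the split is reproducible.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    counts = ds.class_counts()
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError(
            f"both classes need >= 2 records for stratification, got {counts}"
        )
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in sorted(counts):
        idx = np.flatnonzero(ds.y == cls)
        idx = rng.permutation(idx)
        n_test = int(round(len(idx) * test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_parts.append(idx[:n_test])
        train_parts.append(idx[n_test:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return Split(train_indices=train, test_indices=test, seed=seed)
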