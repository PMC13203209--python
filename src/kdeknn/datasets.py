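"""Tabular dataset container, CSV I/O and stratified splitting.

The central container is :class:`TabularDataset`: an ``N x d`` float matrix of
continuous clinical features with missing cells stored as NaN, a binary label
vector (1 = the positive / case class, e.g. sepsis) and feature names.  CSV is
the only on-disk format: comma separated, UTF-8, ``.`` decimal point, empty
field = missing value, label column written last.  Floats are exported with 17
significant digits so a write/read round trip is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParseError, SchemaError, StratificationError

__all__ = [
    "TabularDataset",
    "read_csv_dataset",
    "write_csv_dataset",
    "split_train_test",
]

_FLOAT_FMT = "%.17g"


@dataclass
class TabularDataset:
    """A numeric feature matrix with binary labels and optional missing cells.

    Parameters
    ----------
    values : ndarray of shape (N, d)
        Feature matrix; missing entries are NaN.
    labels : ndarray of shape (N,)
        Binary class labels in {0, 1}; 1 is the positive class.
    feature_names : list of str
        One identifier per column.
    label_name : str
        Name of the label column used on export.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    label_name: str = "label"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D matrix")
        n, d = self.values.shape
        if self.labels.shape != (n,):
            raise SchemaError(
                f"labels length {self.labels.shape} does not match N={n}"
            )
        if len(self.feature_names) != d:
            raise SchemaError(
                f"{len(self.feature_names)} feature names for d={d} columns"
            )
        if n and not np.isin(self.labels, (0, 1)).all():
            raise SchemaError("labels must be binary (0/1)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing cells, same shape as ``values``."""
        return np.isnan(self.values)

    def subset(self, index: np.ndarray) -> "TabularDataset":
        """Row subset (boolean mask or integer index), preserving order."""
        return TabularDataset(
            self.values[index], self.labels[index], list(self.feature_names),
            self.label_name,
        )

    def to_frame(self) -> pd.DataFrame:
        """Features plus label column (last), as a DataFrame."""
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[self.label_name] = self.labels
        return df


def read_csv_dataset(
    path,
    label_column: str = "label",
    positive_label=1,
) -> TabularDataset:
    """Read a CSV file into a :class:`TabularDataset`.

    All non-label columns must parse as numeric; empty cells become NaN.  The
    label column must take exactly the positive value and at most one other
    value, and is mapped to {0, 1}.

    Raises
    ------
    SchemaError
        Missing label column, or a third distinct label value.
    ParseError
        A non-numeric feature cell (row and column are named).
    DataError
        No usable data rows.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in raw.columns:
        raise SchemaError(f"label column {label_column!r} not found in {path}")
    if raw.shape[0] == 0:
        raise DataError(f"no data rows in {path}")

    feature_names = [c for c in raw.columns if c != label_column]
    if not feature_names:
        raise SchemaError("dataset has no feature columns")
    values = np.empty((raw.shape[0], len(feature_names)), dtype=float)
    for j, name in enumerate(feature_names):
        col = raw[name].str.strip()
        # to_numeric only locates bad cells; the actual conversion goes
        # through astype(float), which is bit-exact (to_numeric's fast
        # parser can be off by one ulp)
        numeric = pd.to_numeric(col.replace("", np.nan), errors="coerce")
        bad = numeric.isna() & (col != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {col.iloc[row]!r} in column {name!r}, "
                f"row {row}"
            )
        values[:, j] = col.replace("", np.nan).astype(float).to_numpy()

    lab_raw = raw[label_column].str.strip()
    pos = str(positive_label)
    distinct = set(lab_raw.unique())
    others = distinct - {pos}
    if len(others) > 1:
        raise SchemaError(
            f"label column {label_column!r} has more than two values: "
            f"{sorted(distinct)}"
        )
    labels = (lab_raw == pos).astype(int).to_numpy()
    return TabularDataset(values, labels, feature_names, label_column)


def write_csv_dataset(dataset: TabularDataset, path) -> None:
    """Write a dataset as CSV: header row, label column last, NaN -> empty."""
    df = dataset.to_frame()
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")


def split_train_test(
    dataset: TabularDataset,
    test_fraction: float,
    seed: int,
) -> tuple[TabularDataset, TabularDataset]:
    """Stratified train/test split, reproducible per seed.

    Per class, ``floor(n_class * test_fraction)`` rows go to the test set and
    the remainder to train, so class ratios are stable across seeds.  Both
    classes must be able to appear on both sides.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    classes = np.unique(dataset.labels)
    if classes.size < 2:
        raise StratificationError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(dataset.labels == c)
        n_test = int(np.floor(idx.size * test_fraction))
        if n_test < 1 or idx.size - n_test < 1:
            raise StratificationError(
                f"class {c} has {idx.size} rows; cannot appear in both parts "
                f"at test_fraction={test_fraction}"
            )
        perm = rng.permutation(idx)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return dataset.subset(train), dataset.subset(test)
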