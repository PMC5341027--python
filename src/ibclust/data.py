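"""Count-matrix container and delimited-text I/O.

The basic input to the clustering model is a matrix ``w`` with the number of
times each individual (rows) was observed at each location (columns).
Entries are nonnegative integers; every individual must have been observed
at least once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputValidationError

__all__ = ["CountMatrix", "read_counts", "write_counts"]


@dataclass(frozen=True)
class CountMatrix:
    """Individuals x locations visitation counts with labels.

    Parameters
    ----------
    values
        ``(J, L)`` array of nonnegative integers; ``values[j, l]`` is the
        number of times individual ``j`` was seen at location ``l``.
    row_labels
        Unique individual identifiers, length ``J``.
    col_labels
        Unique location labels, length ``L``.
    """

    values: np.ndarray
    row_labels: tuple = field(default=None)
    col_labels: tuple = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise InputValidationError("count matrix must be two-dimensional")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise InputValidationError("count matrix entries must be integers")
            values = values.astype(np.int64)
        else:
            values = values.astype(np.int64)
        if np.any(values < 0):
            j, l = np.argwhere(values < 0)[0]
            raise InputValidationError(
                f"negative count at row {j}, column {l}"
            )
        object.__setattr__(self, "values", values)
        J, L = values.shape
        row_labels = self.row_labels
        col_labels = self.col_labels
        if row_labels is None:
            row_labels = tuple(f"ind{j}" for j in range(J))
        if col_labels is None:
            col_labels = tuple(f"loc{l}" for l in range(L))
        row_labels = tuple(str(r) for r in row_labels)
        col_labels = tuple(str(c) for c in col_labels)
        if len(row_labels) != J or len(col_labels) != L:
            raise InputValidationError("label lengths do not match matrix shape")
        if len(set(row_labels)) != J:
            raise InputValidationError("duplicate individual labels")
        if len(set(col_labels)) != L:
            raise InputValidationError("duplicate location labels")
        object.__setattr__(self, "row_labels", row_labels)
        object.__setattr__(self, "col_labels", col_labels)
        totals = values.sum(axis=1)
        if np.any(totals < 1):
            j = int(np.argmin(totals))
            raise InputValidationError(
                f"individual {row_labels[j]!r} has zero total observations; "
                "never-observed individuals are not representable"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_locations(self) -> int:
        return self.values.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        """Per-individual total observation counts n_j."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    def subset_rows(self, labels) -> "CountMatrix":
        """Return the sub-matrix for the given individuals, in the given order."""
        index = {r: i for i, r in enumerate(self.row_labels)}
        missing = [r for r in labels if r not in index]
        if missing:
            raise InputValidationError(f"unknown individual labels: {missing[:5]}")
        rows = [index[r] for r in labels]
        return CountMatrix(self.values[rows], tuple(labels), self.col_labels)


def read_counts(path, dialect: str | None = None) -> CountMatrix:
    """Read a count matrix from delimited text.

    The first column holds individual IDs, the header row location labels.
    The delimiter is auto-detected (comma or tab) unless ``dialect`` gives
    one explicitly.
    """
    if dialect is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        dialect = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=dialect, index_col=0)
    except Exception as exc:  # ragged rows, empty file, ...
        raise InputValidationError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InputValidationError(f"duplicate individual labels: {dups[:5]}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            j = df.index[bad.isna()][0]
            raise InputValidationError(
                f"non-numeric entry at individual {j!r}, location {col!r}"
            )
    arr = df.to_numpy()
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        j, l = np.argwhere(~np.equal(np.mod(arr, 1), 0))[0]
        raise InputValidationError(
            f"non-integer entry at individual {df.index[j]!r}, location {df.columns[l]!r}"
        )
    if np.any(arr < 0):
        j, l = np.argwhere(arr < 0)[0]
        raise InputValidationError(
            f"negative entry at individual {df.index[j]!r}, location {df.columns[l]!r}"
        )
    return CountMatrix.from_frame(df)


def write_counts(counts: CountMatrix, path) -> None:
    """Write a count matrix as UTF-8 comma-delimited text."""
    counts.to_frame().to_csv(path)
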