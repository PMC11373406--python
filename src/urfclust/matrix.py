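"""Sample-by-feature matrices and their CSV/TSV round trips.

The on-disk convention is a delimited text file with a header row of
feature names and a first column of sample identifiers — the layout
omics feature tables are usually shipped in.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """n samples x p features of finite numbers, with identifiers.

    Parameters
    ----------
    values
        Array of shape ``(n, p)``; coerced to float64.  NaN/Inf are
        rejected — impute before loading.
    sample_ids, feature_names
        Unique string identifiers; generated (``s0001`` / ``f01``) when
        omitted.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at sample index {i}, feature index {j}")
        if not self.sample_ids:
            width = len(str(n - 1))
            self.sample_ids = [f"s{i:0{width}d}" for i in range(n)]
        if not self.feature_names:
            width = len(str(p - 1))
            self.feature_names = [f"f{j:0{width}d}" for j in range(p)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match number of columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)


def _infer_delimiter(path: str | os.PathLike, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_feature_matrix(path: str | os.PathLike, delimiter: str | None = None) -> FeatureMatrix:
    """Read a sample x feature table (header row + ID column).

    Non-numeric cells raise a ``ValueError`` naming the offending sample
    and column.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns found (delimiter {sep!r}?)")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at sample {row!r}, column {col!r}"
            )
    values = df.apply(pd.to_numeric).to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: missing value at sample {df.index[i]!r}, column {df.columns[j]!r}")
    return FeatureMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_feature_matrix(fm: FeatureMatrix, path: str | os.PathLike, delimiter: str | None = None) -> None:
    fm.to_dataframe().to_csv(path, sep=_infer_delimiter(path, delimiter), index_label="sample_id")


def as_values(X) -> np.ndarray:
    """Accept a FeatureMatrix or array-like; return the float64 ndarray."""
    if isinstance(X, FeatureMatrix):
        return X.values
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D sample x feature array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in input matrix")
    return arr


def sample_ids_of(X, n: int) -> list[str]:
    if isinstance(X, FeatureMatrix):
        return list(X.sample_ids)
    width = len(str(max(n - 1, 1)))
    return [f"s{i:0{width}d}" for i in range(n)]
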