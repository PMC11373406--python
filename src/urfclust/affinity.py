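"""Leaf co-occurrence counts and affinity matrices.

Every sample is propagated through every tree; two samples that land
in the same leaf of a tree co-occur once.  Summing the per-tree binary
co-occurrence matrices over the forest gives an integer count matrix
whose diagonal equals the number of trees; dividing by its maximal
entry yields an affinity in [0, 1].  For several omics layers over the
same samples the raw count matrices are summed element-wise before the
final normalisation (late fusion on counts, not on affinities).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fast
from .forest import UForest, UTree
from .matrix import FeatureMatrix, as_values, sample_ids_of


@dataclass
class CountMatrix:
    """Symmetric nonnegative integer co-occurrence counts."""

    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class AffinityMatrix:
    """Symmetric affinities in [0, 1] with unit diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def tree_cooccurrence(tree: UTree, X) -> np.ndarray:
    """Binary n x n matrix: 1 where two samples share a leaf (diagonal 1)."""
    leaves = tree.assign(X)
    return (leaves[:, None] == leaves[None, :]).astype(np.int8)


def _counts_from_leaves(leaves: np.ndarray) -> np.ndarray:
    n = leaves.shape[1]
    counts = np.zeros((n, n), np.int64)
    _fast.cooccurrence_accumulate(leaves, counts)
    return counts + np.triu(counts, 1).T


def forest_counts(forest: UForest, X) -> CountMatrix:
    """Sum of per-tree binary co-occurrence matrices over the forest.

    All samples — including rows a bootstrap resample happened to leave
    out of a given tree — are propagated through every tree, so the
    diagonal equals the number of trees.
    """
    if forest.n_trees == 0:
        raise ValueError("empty forest")
    values = as_values(X)
    return CountMatrix(
        _counts_from_leaves(forest.apply(values)),
        sample_ids_of(X, values.shape[0]),
    )


def normalize_affinity(C: CountMatrix) -> AffinityMatrix:
    """Divide the counts by their maximal entry."""
    m = C.counts.max()
    if m <= 0:
        raise ValueError("count matrix is all zero; cannot normalise")
    return AffinityMatrix(C.counts / m, list(C.sample_ids))


def multiomics_counts(forests, Xs) -> CountMatrix:
    """Element-wise sum of per-layer forest counts over identical samples.

    Each layer contributes ``forest_counts(forest, X)``; the caller
    normalises the fused counts once at the end.
    """
    forests = list(forests)
    Xs = list(Xs)
    if len(forests) != len(Xs):
        raise ValueError("need one forest per omics layer")
    if not forests:
        raise ValueError("no omics layers given")
    ref_ids = None
    total = None
    for layer, (forest, X) in enumerate(zip(forests, Xs)):
        ids = sample_ids_of(X, as_values(X).shape[0])
        if ref_ids is None:
            ref_ids = ids
        elif ids != ref_ids:
            raise ValueError(
                f"omics layer {layer} has sample IDs differing from layer 0 "
                "(same samples in identical order are required)"
            )
        cm = forest_counts(forest, X)
        total = cm.counts if total is None else total + cm.counts
    return CountMatrix(total, ref_ids)


def fit_affinity(X, params=None) -> AffinityMatrix:
    """Convenience: fit a forest on X and return its normalised affinity."""
    from .forest import fit_forest

    forest = fit_forest(X, params)
    return normalize_affinity(forest_counts(forest, X))


# ---------------------------------------------------------------------------
# square-matrix CSV round trips (sample IDs as header and first column)

def write_square_csv(mat: CountMatrix | AffinityMatrix, path: str | os.PathLike) -> None:
    mat.to_dataframe().to_csv(path, index_label="sample_id")


def read_affinity_csv(path: str | os.PathLike) -> AffinityMatrix:
    df = pd.read_csv(path, index_col=0)
    return AffinityMatrix(df.to_numpy(dtype=np.float64), list(df.index.astype(str)))


def read_counts_csv(path: str | os.PathLike) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(df.to_numpy(dtype=np.int64), list(df.index.astype(str)))
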