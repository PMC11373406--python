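"""Cluster-specific feature importance from an unsupervised forest.

Once a cluster solution exists, the already-grown unsupervised splits
can be scored as if they were supervised: for each cluster the labels
are binarised one-vs-all, every internal node's split is scored by the
decrease in Gini impurity of those binary labels weighted by the
fraction of samples reaching the node, and the decreases are
accumulated per split feature and averaged over trees.  Splits are
never re-learned — the trees stay exactly as the unsupervised
criterion grew them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import UForest
from .matrix import as_values


@dataclass
class ImportanceTable:
    """k clusters x p features of nonnegative importance scores.

    ``raw`` holds the mean total weighted impurity decrease per feature;
    ``scores`` is the per-cluster L1 normalisation of ``raw`` (rows sum
    to 1 whenever any split exists), which is what correlation plots
    compare across clusters.
    """

    scores: np.ndarray
    raw: np.ndarray
    clusters: list[int]
    feature_names: list[str]

    def to_dataframe(self, normalized: bool = True) -> pd.DataFrame:
        data = self.scores if normalized else self.raw
        return pd.DataFrame(
            data, index=[f"cluster{c}" for c in self.clusters], columns=self.feature_names
        )


@dataclass
class ImportanceCorrelation:
    """Pairwise Pearson correlation of cluster importance vectors.

    Entries are NaN where a cluster's importance vector has zero
    variance (the correlation is undefined).
    """

    values: np.ndarray
    clusters: list[int]

    def to_dataframe(self) -> pd.DataFrame:
        names = [f"cluster{c}" for c in self.clusters]
        return pd.DataFrame(self.values, index=names, columns=names)


def _gini_binary(pos: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Gini impurity 2q(1-q) of a one-vs-all binarisation, vectorised
    over clusters; zero where the node is empty."""
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(total > 0, pos / total, 0.0)
    return 2.0 * q * (1.0 - q)


def cluster_importance(forest: UForest, X, labels) -> ImportanceTable:
    """One-vs-all Gini importance of every feature for every cluster.

    ``labels`` may be a ClusterSolution or an integer vector covering
    0..k-1 with every cluster nonempty.  All samples of X are routed
    down every tree to label the nodes; the split structure is fixed.
    """
    values = as_values(X)
    lab = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    n = values.shape[0]
    if lab.size != n:
        raise ValueError("labels must cover all samples of X")
    k = int(lab.max()) + 1
    counts_per_cluster = np.bincount(lab, minlength=k)
    if lab.min() < 0 or (counts_per_cluster < 1).any():
        raise ValueError("every cluster in 0..k-1 must contain at least one sample")

    raw = np.zeros((k, forest.p), np.float64)
    for tree in forest.trees:
        # one pass: per-node label counts via in-place partition of an
        # index buffer along the existing splits
        stack = [(0, np.arange(n))]
        while stack:
            node, idx = stack.pop()
            f = int(tree.feature[node])
            if f < 0 or idx.size == 0:
                continue
            go_left = values[idx, f] <= tree.threshold[node]
            left_idx = idx[go_left]
            right_idx = idx[~go_left]
            nt, nl, nr = idx.size, left_idx.size, right_idx.size
            pos_t = np.bincount(lab[idx], minlength=k).astype(np.float64)
            pos_l = np.bincount(lab[left_idx], minlength=k).astype(np.float64)
            pos_r = pos_t - pos_l
            decrease = (
                _gini_binary(pos_t, nt)
                - (nl / nt) * _gini_binary(pos_l, nl)
                - (nr / nt) * _gini_binary(pos_r, nr)
            )
            raw[:, f] += (nt / n) * decrease
            stack.append((int(tree.left[node]), left_idx))
            stack.append((int(tree.right[node]), right_idx))
    raw /= forest.n_trees
    raw = np.maximum(raw, 0.0)

    totals = raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(totals > 0, raw / totals, 0.0)
    names = forest.feature_names or [f"f{j}" for j in range(forest.p)]
    return ImportanceTable(scores, raw, list(range(k)), list(names))


def importance_correlation(table: ImportanceTable) -> ImportanceCorrelation:
    """Pairwise Pearson correlation across the p-dimensional importance
    vectors of the clusters; pairs involving a zero-variance vector are
    reported as NaN."""
    k = table.scores.shape[0]
    if k < 2:
        raise ValueError("need at least two clusters to correlate")
    out = np.full((k, k), np.nan)
    sd = table.scores.std(axis=1)
    for i in range(k):
        for j in range(k):
            if i == j:
                out[i, j] = 1.0
            elif sd[i] > 0 and sd[j] > 0:
                out[i, j] = float(np.corrcoef(table.scores[i], table.scores[j])[0, 1])
    return ImportanceCorrelation(out, list(table.clusters))
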