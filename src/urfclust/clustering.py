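"""Ward clustering on affinity-derived distances and choice of k.

The affinity is turned into a dissimilarity by ``D = 1 - A`` and fed
to agglomerative Ward linkage (Lance–Williams update on the precomputed
matrix, scipy's ``ward``).  Two ways of picking the number of clusters
are provided:

* the mean Silhouette width over a range of k (ties to the smallest k);
* a tree-count-stability diagnostic: the clustering at a given k is
  treated as a multiclass response, the forest is used as an
  out-of-bag leaf-majority classifier for those labels, and the
  agreement (ARI) with the reference labels is tracked while the
  number of trees is reduced.  A k whose curve stays flat is supported
  by the data; the heuristic cut-off is opt-in because the curves are
  primarily meant for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .affinity import AffinityMatrix, forest_counts, normalize_affinity
from .forest import ForestParams, UForest, fit_forest


@dataclass
class ClusterSolution:
    """Flat cluster labels in [0, k) plus the merge history."""

    labels: np.ndarray
    k: int
    linkage: np.ndarray
    sample_ids: list[str] | None = None


@dataclass
class StabilityCurve:
    """ARI between reduced-forest predictions and the full solution at one k."""

    k: int
    tree_counts: list[int]
    ari_values: list[float] = field(default_factory=list)


def affinity_to_distance(A: AffinityMatrix | np.ndarray) -> np.ndarray:
    """D = 1 - A with an exactly zero diagonal."""
    values = A.values if isinstance(A, AffinityMatrix) else np.asarray(A, dtype=np.float64)
    D = 1.0 - values
    np.fill_diagonal(D, 0.0)
    return D


def _relabel_first_appearance(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 0..k-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(raw.size, np.int64)
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping)
        out[i] = mapping[v]
    return out


def ward_cluster(D: np.ndarray, k: int, sample_ids: list[str] | None = None) -> ClusterSolution:
    """Agglomerative Ward linkage on a precomputed distance matrix, cut at k."""
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    Z = linkage(squareform(D, checks=False), method="ward")
    # cut by merge count (not height) so tied merges still yield exactly k
    labels = _relabel_first_appearance(cut_tree(Z, n_clusters=k).ravel())
    return ClusterSolution(labels, k, Z, sample_ids)


def silhouette_select_k(D: np.ndarray, k_range) -> int:
    """k maximising the mean Silhouette width on D; ties -> smallest k."""
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("empty k_range")
    n = np.asarray(D).shape[0]
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    best_k, best_s = None, -np.inf
    for k in ks:
        labels = ward_cluster(D, k).labels
        s = silhouette_score(D, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    return best_k


# ---------------------------------------------------------------------------
# tree-count stability

def _leaf_majority_predict(
    forest: UForest, leaves: np.ndarray, ref: np.ndarray, n_trees: int
) -> np.ndarray:
    """Predict reference labels with the first ``n_trees`` trees.

    Each leaf is labelled by the majority reference label of the
    training samples it holds (ties -> lowest label); a sample is then
    labelled by majority vote over trees.  For bootstrapped trees the
    leaf labels come from in-bag samples and only out-of-bag trees vote
    for a sample — the usual forest generalisation estimate.  Samples
    never out-of-bag fall back to in-bag votes.
    """
    n = ref.size
    k = int(ref.max()) + 1
    votes = np.zeros((n, k), np.int64)
    inbag_votes = np.zeros((n, k), np.int64)
    for t in range(n_trees):
        tree = forest.trees[t]
        lv = leaves[t]
        if forest.params.bootstrap and tree.in_bag is not None:
            ib = np.zeros(n, bool)
            ib[tree.in_bag] = True
        else:
            ib = np.ones(n, bool)
        leaf_label: dict[int, int] = {}
        for leaf in np.unique(lv[ib]):
            counts = np.bincount(ref[ib & (lv == leaf)], minlength=k)
            leaf_label[int(leaf)] = int(counts.argmax())
        for i in range(n):
            lab = leaf_label.get(int(lv[i]))
            if lab is None:
                continue
            if ib[i]:
                inbag_votes[i, lab] += 1
            else:
                votes[i, lab] += 1
    no_oob = votes.sum(axis=1) == 0
    votes[no_oob] = inbag_votes[no_oob]
    return votes.argmax(axis=1)


def stability_curves(
    X,
    params: ForestParams,
    k_range,
    tree_counts,
    seed: int | None = None,
) -> list[StabilityCurve]:
    """Stability of Ward solutions under reduction of the tree count.

    Fits one forest (seeded by ``seed`` when given, else ``params.seed``),
    derives the reference Ward labels for each k, and for each reduced
    tree count records the ARI between the reduced-forest leaf-majority
    predictions and the reference labels.
    """
    from sklearn.metrics import adjusted_rand_score

    tree_counts = sorted({int(t) for t in tree_counts}, reverse=True)
    if tree_counts[-1] < 1:
        raise ValueError("tree counts must be positive")
    if tree_counts[0] > params.n_trees:
        raise ValueError("tree counts cannot exceed the forest size")
    ks = sorted(int(k) for k in k_range)
    if ks and ks[0] < 2:
        raise ValueError("k_range must start at 2: ARI is undefined for a single cluster")
    if seed is not None:
        from dataclasses import replace

        params = replace(params, seed=seed)
    forest = fit_forest(X, params)
    leaves = forest.apply(X)
    D = affinity_to_distance(normalize_affinity(forest_counts(forest, X)))
    curves = []
    for k in ks:
        ref = ward_cluster(D, k).labels
        curve = StabilityCurve(k, tree_counts)
        for m in tree_counts:
            pred = _leaf_majority_predict(forest, leaves, ref, m)
            curve.ari_values.append(float(adjusted_rand_score(ref, pred)))
        curves.append(curve)
    return curves


def select_k_stability(curves: list[StabilityCurve], drop_threshold: float = 0.05) -> int:
    """Heuristic: largest k whose ARI drop from the full forest to the
    smallest tree count stays below ``drop_threshold``."""
    stable = [c.k for c in curves if c.ari_values[0] - c.ari_values[-1] < drop_threshold]
    if not stable:
        return min(c.k for c in curves)
    return max(stable)
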