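import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from urfclust import (
    ForestParams,
    adjusted_rand_index,
    affinity_to_distance,
    fit_affinity,
    select_k_stability,
    silhouette_select_k,
    stability_curves,
    ward_cluster,
)
from urfclust.affinity import AffinityMatrix

from oracles import silhouette_oracle, ward_merges_oracle


def test_affinity_to_distance_basics():
    A = np.eye(4)
    D = affinity_to_distance(AffinityMatrix(A, list("abcd")))
    assert np.allclose(np.diag(D), 0.0)
    assert np.all(D[~np.eye(4, dtype=bool)] == 1.0)
    assert np.allclose(affinity_to_distance(np.ones((3, 3))), 0.0)
    # monotone: larger affinity -> smaller distance
    A2 = np.array([[1.0, 0.9], [0.9, 1.0]])
    A3 = np.array([[1.0, 0.2], [0.2, 1.0]])
    assert affinity_to_distance(A2)[0, 1] < affinity_to_distance(A3)[0, 1]


def test_ward_recovers_zero_distance_blocks():
    D = np.ones((6, 6))
    D[:3, :3] = 0.0
    D[3:, 3:] = 0.0
    np.fill_diagonal(D, 0.0)
    sol = ward_cluster(D, 2)
    assert adjusted_rand_index(sol.labels, [0, 0, 0, 1, 1, 1]) == 1.0


def test_ward_k_equals_n_gives_singletons():
    rng = np.random.default_rng(1)
    D = squareform(pdist(rng.normal(size=(5, 2))))
    sol = ward_cluster(D, 5)
    assert sorted(sol.labels) == list(range(5))


def test_ward_k_out_of_range():
    D = np.zeros((4, 4))
    with pytest.raises(ValueError):
        ward_cluster(D, 1)
    with pytest.raises(ValueError):
        ward_cluster(D, 5)


def test_ward_merge_order_matches_lance_williams():
    """scipy's ward on a precomputed matrix must replay the textbook
    Lance–Williams recursion on a 6-point toy."""
    pts = np.array([0.0, 0.13, 0.31, 5.0, 5.47, 9.2])[:, None]
    D = squareform(pdist(pts))
    expected = ward_merges_oracle(D)
    sol = ward_cluster(D, 2)
    Z = sol.linkage
    n = 6
    members = {i: frozenset([i]) for i in range(n)}
    got = []
    for row, (i, j) in enumerate(zip(Z[:, 0].astype(int), Z[:, 1].astype(int))):
        merged = members[i] | members[j]
        members[n + row] = merged
        got.append(merged)
    assert got == expected


def test_ward_invariant_to_sample_permutation():
    rng = np.random.default_rng(5)
    pts = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(4, 0.3, (12, 2))])
    D = squareform(pdist(pts))
    perm = rng.permutation(22)
    lab = ward_cluster(D, 2).labels
    lab_perm = ward_cluster(D[np.ix_(perm, perm)], 2).labels
    assert adjusted_rand_index(lab[perm], lab_perm) == 1.0


@pytest.mark.parametrize("case", range(10))
def test_silhouette_matches_bruteforce(case):
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(case)
    n = int(rng.integers(6, 21))
    D = squareform(pdist(rng.normal(size=(n, 2))))
    labels = rng.integers(0, 3, n)
    if len(np.unique(labels)) < 2:
        labels[0] = (labels[0] + 1) % 3
    assert silhouette_score(D, labels, metric="precomputed") == pytest.approx(
        silhouette_oracle(D, labels), abs=1e-12
    )


def test_silhouette_selects_true_k_on_blob_scale_affinity(three_blob_data):
    """With leaves as coarse as the clusters (min_leaf_size large enough
    that a 30-point blob cannot split) the affinity is block-like and the
    Silhouette optimum sits at the true k.  At finer leaf granularity the
    leaf-level affinity grades distances locally and the Silhouette width
    keeps growing with k — selection is then only meaningful at the
    affinity's own scale."""
    X, _ = three_blob_data
    A = fit_affinity(
        X, ForestParams(n_trees=60, mtry=2, min_leaf_size=25, bootstrap=False, seed=21)
    )
    D = affinity_to_distance(A)
    assert silhouette_select_k(D, range(2, 7)) == 3


def test_silhouette_two_block_toy():
    D = np.ones((8, 8))
    D[:4, :4] = 0.0
    D[4:, 4:] = 0.0
    np.fill_diagonal(D, 0.0)
    assert silhouette_select_k(D, range(2, 7)) == 2


def test_silhouette_empty_range():
    with pytest.raises(ValueError):
        silhouette_select_k(np.zeros((5, 5)), [])


class TestStability:
    def test_full_forest_reproduces_reference(self, three_blob_data):
        X, _ = three_blob_data
        params = ForestParams(n_trees=40, seed=17)
        curves = stability_curves(X, params, k_range=[3], tree_counts=[40, 10], seed=17)
        assert curves[0].k == 3
        assert curves[0].ari_values[0] >= 0.9

    def test_k_range_must_start_at_two(self, three_blob_data):
        X, _ = three_blob_data
        with pytest.raises(ValueError, match="k_range"):
            stability_curves(X, ForestParams(n_trees=5), [1, 2], [5])

    def test_tree_counts_validated(self, three_blob_data):
        X, _ = three_blob_data
        with pytest.raises(ValueError):
            stability_curves(X, ForestParams(n_trees=5), [2], [10])

    def test_heuristic_prefers_largest_stable_k(self):
        from urfclust import StabilityCurve

        curves = [
            StabilityCurve(2, [40, 10], [1.0, 0.99]),
            StabilityCurve(3, [40, 10], [1.0, 0.98]),
            StabilityCurve(4, [40, 10], [0.95, 0.70]),
        ]
        assert select_k_stability(curves) == 3
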