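import numpy as np
import pytest

from urfclust import (
    FeatureMatrix,
    ForestParams,
    concatenate_models,
    federated_affinity,
    federated_counts,
    fit_forest,
    forest_counts,
    load_federated_model,
    normalize_affinity,
    save_federated_model,
    simulate_federation,
)
from urfclust.federated import federated_model_from_dict, federated_model_to_dict


@pytest.fixture
def client_forests(three_blob_data):
    X, _ = three_blob_data
    rng = np.random.default_rng(0)
    parts = np.array_split(rng.permutation(X.n_samples), 3)
    forests, matrices = [], []
    for i, part in enumerate(parts):
        fm = FeatureMatrix(X.values[part], feature_names=X.feature_names)
        forests.append(fit_forest(fm, ForestParams(n_trees=10, seed=i)))
        matrices.append(fm)
    return forests, matrices


def test_single_client_global_equals_local(client_forests):
    forests, matrices = client_forests
    model = concatenate_models(forests[:1])
    local = normalize_affinity(forest_counts(forests[0], matrices[0]))
    glob = federated_affinity(model, matrices[0])
    assert np.allclose(local.values, glob.values)


def test_concatenation_preserves_order_and_provenance(client_forests):
    forests, _ = client_forests
    model = concatenate_models(forests, client_ids=["a", "b", "c"])
    assert model.n_trees == 30
    assert model.client_tree_counts == {"a": 10, "b": 10, "c": 10}
    assert model.trees[0] == forests[0].trees[0]
    assert model.trees[29] == forests[2].trees[9]


def test_schema_mismatch_names_client(client_forests):
    forests, matrices = client_forests
    odd = fit_forest(matrices[0].values[:, :1], ForestParams(n_trees=3, seed=9))
    with pytest.raises(ValueError, match="client2"):
        concatenate_models([forests[0], forests[1], odd], ["client0", "client1", "client2"])


def test_global_counts_are_sum_of_per_client_counts(client_forests):
    """Propagating local data through the concatenated model equals the
    sum of counts from propagating it through each client's forest."""
    forests, matrices = client_forests
    model = concatenate_models(forests)
    X_local = matrices[1]
    total = sum(forest_counts(f, X_local).counts for f in forests)
    assert np.array_equal(federated_counts(model, X_local).counts, total)


def test_replicated_forests_change_nothing(client_forests):
    """K clients with identical forests: normalisation cancels replication."""
    forests, matrices = client_forests
    model = concatenate_models([forests[0]] * 3)
    single = normalize_affinity(forest_counts(forests[0], matrices[0]))
    assert np.allclose(federated_affinity(model, matrices[0]).values, single.values)


def test_client_order_is_irrelevant(client_forests):
    forests, matrices = client_forests
    a = federated_affinity(concatenate_models(forests), matrices[0])
    b = federated_affinity(concatenate_models(forests[::-1]), matrices[0])
    assert np.allclose(a.values, b.values)


def test_federated_affinity_invariants(client_forests):
    forests, matrices = client_forests
    model = concatenate_models(forests)
    aff = federated_affinity(model, matrices[2])
    assert np.allclose(np.diag(aff.values), 1.0)
    assert np.array_equal(aff.values, aff.values.T)
    assert aff.values.max() == 1.0


def test_wire_format_roundtrip(client_forests, tmp_path):
    forests, matrices = client_forests
    model = concatenate_models(forests, ["hospital_a", "hospital_b", "hospital_c"])
    path = tmp_path / "global.json"
    save_federated_model(model, path)
    restored = load_federated_model(path)
    assert restored.client_ids == model.client_ids
    assert all(a == b for a, b in zip(model.trees, restored.trees))
    assert np.allclose(
        federated_affinity(model, matrices[0]).values,
        federated_affinity(restored, matrices[0]).values,
    )
    again = federated_model_from_dict(federated_model_to_dict(restored))
    assert all(a == b for a, b in zip(restored.trees, again.trees))


def test_wire_format_carries_no_sample_data(client_forests):
    """Privacy contract: the serialised model holds split rules and leaf
    ids only — no training rows, no in-bag bookkeeping."""
    forests, _ = client_forests
    d = federated_model_to_dict(concatenate_models(forests))

    def walk(node):
        if "leaf_id" in node:
            assert set(node) <= {"leaf_id", "n_train"}
        else:
            assert set(node) == {"feature", "threshold", "left", "right"}
            walk(node["left"])
            walk(node["right"])

    for entry in d["trees"]:
        walk(entry["tree"])


class TestSimulateFederation:
    def test_single_client_local_equals_global(self, three_blob_data):
        X, _ = three_blob_data
        res = simulate_federation(X, 1, ForestParams(n_trees=10, seed=1), seed=1, k=3)
        cr = res.clients[0]
        assert np.allclose(cr.local_affinity.values, cr.global_affinity.values)
        assert np.array_equal(cr.local_labels, cr.global_labels)

    def test_seeded_partition_reproducible(self, three_blob_data):
        X, _ = three_blob_data
        r1 = simulate_federation(X, 3, ForestParams(n_trees=5, seed=2), seed=2, k=3)
        r2 = simulate_federation(X, 3, ForestParams(n_trees=5, seed=2), seed=2, k=3)
        for a, b in zip(r1.clients, r2.clients):
            assert np.array_equal(a.indices, b.indices)
            assert np.array_equal(a.global_labels, b.global_labels)

    def test_partition_covers_all_samples(self, three_blob_data):
        X, _ = three_blob_data
        res = simulate_federation(X, 3, ForestParams(n_trees=5, seed=3), seed=3, k=2)
        all_idx = np.concatenate([c.indices for c in res.clients])
        assert sorted(all_idx) == list(range(X.n_samples))

    def test_too_small_clients_rejected(self):
        X = np.random.default_rng(1).normal(size=(12, 2))
        with pytest.raises(ValueError, match="too few"):
            simulate_federation(X, 4, ForestParams(min_leaf_size=5), seed=0, k=2)
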