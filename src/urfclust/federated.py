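"""Federated forests: share trees, never data.

Each client grows a forest on its own samples; the serialised trees
(split rules and leaf ids only) are pooled and concatenated into a
global model.  A client then propagates its *own* samples through every
tree of the global model to obtain a federated affinity — the result is
always n_local x n_local, so no sample pair spanning two clients is
ever formed and no raw value leaves a client.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np

from .affinity import AffinityMatrix, CountMatrix, _counts_from_leaves, normalize_affinity
from .clustering import affinity_to_distance, silhouette_select_k, ward_cluster
from .forest import SCHEMA_VERSION, ForestParams, UForest, UTree, derive_seed, fit_forest
from .matrix import FeatureMatrix, as_values, sample_ids_of


@dataclass
class FederatedModel:
    """Order-preserving concatenation of client forests.

    ``client_ids[i]`` records which client contributed ``trees[i]``.
    """

    trees: list[UTree]
    client_ids: list[str]
    p: int
    feature_names: list[str] | None = None
    params: ForestParams | None = None

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.client_ids):
            raise ValueError("one client id per tree required")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def clients(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.client_ids:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def client_tree_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.client_ids:
            out[c] = out.get(c, 0) + 1
        return out

    def apply(self, X) -> np.ndarray:
        values = as_values(X)
        leaves = np.empty((self.n_trees, values.shape[0]), np.int64)
        for i, tree in enumerate(self.trees):
            leaves[i] = tree.assign(values)
        return leaves


def concatenate_models(local_models, client_ids=None) -> FederatedModel:
    """Concatenate client forests into the global model.

    The trees are taken in client order, unmodified.  All clients must
    agree on the feature schema; a mismatch raises an error naming the
    offending clients.
    """
    local_models = list(local_models)
    if not local_models:
        raise ValueError("need at least one client model")
    if client_ids is None:
        client_ids = [f"client{i}" for i in range(len(local_models))]
    client_ids = [str(c) for c in client_ids]
    if len(client_ids) != len(local_models):
        raise ValueError("one client id per model required")
    ref = local_models[0]
    for cid, model in zip(client_ids[1:], local_models[1:]):
        if model.p != ref.p or (
            model.feature_names is not None
            and ref.feature_names is not None
            and model.feature_names != ref.feature_names
        ):
            raise ValueError(
                f"feature schema of client {cid!r} differs from client {client_ids[0]!r}"
            )
    trees: list[UTree] = []
    tags: list[str] = []
    for cid, model in zip(client_ids, local_models):
        trees.extend(model.trees)
        tags.extend([cid] * model.n_trees)
    return FederatedModel(trees, tags, ref.p, ref.feature_names, ref.params)


def federated_counts(model: FederatedModel, X_local) -> CountMatrix:
    """Co-occurrence counts of the local samples over *all* clients' trees."""
    if model.n_trees == 0:
        raise ValueError("empty federated model")
    values = as_values(X_local)
    return CountMatrix(
        _counts_from_leaves(model.apply(values)),
        sample_ids_of(X_local, values.shape[0]),
    )


def federated_affinity(model: FederatedModel, X_local) -> AffinityMatrix:
    """Normalised affinity of a client's own samples under the global model."""
    return normalize_affinity(federated_counts(model, X_local))


# ---------------------------------------------------------------------------
# serialisation (the shareable wire format: trees only, no data)

def federated_model_to_dict(model: FederatedModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "p": model.p,
        "feature_names": model.feature_names,
        "params": model.params.to_dict() if model.params is not None else None,
        "trees": [
            {"client_id": cid, "tree": tree.to_dict()}
            for cid, tree in zip(model.client_ids, model.trees)
        ],
    }


def federated_model_from_dict(d: dict) -> FederatedModel:
    trees = [UTree.from_dict(entry["tree"]) for entry in d["trees"]]
    cids = [str(entry["client_id"]) for entry in d["trees"]]
    params = ForestParams(**d["params"]) if d.get("params") else None
    if params is not None and params.n_trees != len(trees):
        params = replace(params, n_trees=max(len(trees), 1))
    return FederatedModel(trees, cids, int(d["p"]), d.get("feature_names"), params)


def save_federated_model(model: FederatedModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(federated_model_to_dict(model), fh)


def load_federated_model(path: str | os.PathLike) -> FederatedModel:
    with open(path) as fh:
        return federated_model_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# simulation of a federation on one pooled matrix

@dataclass
class ClientResult:
    client_id: str
    indices: np.ndarray
    k_local: int
    k_global: int
    local_affinity: AffinityMatrix
    local_labels: np.ndarray
    global_affinity: AffinityMatrix
    global_labels: np.ndarray


@dataclass
class FederationResult:
    clients: list[ClientResult]
    model: FederatedModel


def simulate_federation(
    X,
    n_clients: int,
    params: ForestParams | None = None,
    seed: int = 0,
    k: int | str = "auto",
    k_range=range(2, 8),
) -> FederationResult:
    """Partition the rows of X uniformly at random across ``n_clients``,
    fit a forest per client, concatenate, and report per client both the
    local-model and global-model affinity and Ward labels.

    ``k`` may be an integer (used for every clustering) or ``"auto"``,
    in which case each clustering re-selects k by Silhouette over
    ``k_range``.
    """
    if params is None:
        params = ForestParams()
    values = as_values(X)
    ids = sample_ids_of(X, values.shape[0])
    n = values.shape[0]
    if n_clients < 1:
        raise ValueError("need at least one client")
    if n < n_clients * 2 * params.min_leaf_size:
        raise ValueError(
            f"{n} samples are too few for {n_clients} clients to grow any tree "
            f"(need at least {2 * params.min_leaf_size} per client)"
        )
    rng = np.random.default_rng(derive_seed(seed, 0))
    perm = rng.permutation(n)
    parts = [np.sort(perm[c::n_clients]) for c in range(n_clients)]

    local_forests = []
    for c, part in enumerate(parts):
        cp = replace(params, seed=derive_seed(seed, 1, c))
        local_forests.append(fit_forest(values[part], cp))
    model = concatenate_models(local_forests)

    def _cluster(aff: AffinityMatrix) -> tuple[int, np.ndarray]:
        D = affinity_to_distance(aff)
        kk = silhouette_select_k(D, k_range) if k == "auto" else int(k)
        return kk, ward_cluster(D, kk).labels

    clients = []
    for c, (part, forest) in enumerate(zip(parts, local_forests)):
        X_local = values[part]
        local_ids = [ids[i] for i in part]
        from .affinity import forest_counts

        loc = normalize_affinity(forest_counts(forest, X_local))
        loc.sample_ids = local_ids
        glo = federated_affinity(model, X_local)
        glo.sample_ids = local_ids
        k_loc, lab_loc = _cluster(loc)
        k_glo, lab_glo = _cluster(glo)
        clients.append(
            ClientResult(f"client{c}", part, k_loc, k_glo, loc, lab_loc, glo, lab_glo)
        )
    return FederationResult(clients, model)
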