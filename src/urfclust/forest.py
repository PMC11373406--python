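"""Unsupervised random forests.

Trees are grown without a response: at each node ``mtry`` candidate
features are drawn uniformly at random and the axis-aligned split
minimising the within/between spread ratio (see :mod:`urfclust.splitting`)
is applied, subject to every child holding at least ``min_leaf_size``
training samples.  By default each tree is grown on a bootstrap
resample of the rows.

A forest is an ordered list of trees plus the hyperparameters used to
grow it.  Trees serialise to a nested JSON schema — internal nodes
``{"feature", "threshold", "left", "right"}``, leaves
``{"leaf_id", "n_train"}`` — which doubles as the wire format shared
between federated clients.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import _fast
from .matrix import FeatureMatrix, as_values

SCHEMA_VERSION = 1


def derive_seed(seed: int, *key: int) -> int:
    """Counter-based substream derivation: stable in the number of
    streams actually consumed, so changing e.g. the tree count does not
    reshuffle unrelated randomness."""
    return int(np.random.SeedSequence(seed, spawn_key=tuple(key)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    Defaults are the small-data 2-D settings (500 trees, minimum leaf
    size 5, one candidate feature per node); :meth:`benchmark` gives the
    tabular settings (100 trees, mtry 2).  ``mtry`` is clipped to the
    number of features at fit time.
    """

    n_trees: int = 500
    mtry: int = 1
    min_leaf_size: int = 5
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.mtry < 1:
            raise ValueError("mtry must be at least 1")
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be positive")

    @classmethod
    def benchmark(cls, seed: int = 0, **kw) -> "ForestParams":
        """Settings used for tabular benchmark matrices."""
        kw.setdefault("n_trees", 100)
        kw.setdefault("mtry", 2)
        return cls(seed=seed, **kw)

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "min_leaf_size": self.min_leaf_size,
            "bootstrap": self.bootstrap,
            "seed": self.seed,
        }


@dataclass
class UTree:
    """One grown tree in flat-array form.

    ``feature[i] == -1`` marks node ``i`` as a leaf; leaves carry a
    ``leaf_id`` numbered 0..n_leaves-1 left to right.  ``in_bag`` holds
    the training-row indices (the bootstrap multiset when bootstrapping);
    it stays local and is never serialised.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_id: np.ndarray
    n_train: np.ndarray
    in_bag: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())

    def max_feature_index(self) -> int:
        internal = self.feature[self.feature >= 0]
        return int(internal.max()) if internal.size else -1

    def assign(self, X) -> np.ndarray:
        """Route each row of X to a leaf ('<= threshold' goes left)."""
        values = as_values(X)
        if self.max_feature_index() >= values.shape[1]:
            raise ValueError(
                f"tree references feature index {self.max_feature_index()} "
                f"but the matrix has only {values.shape[1]} columns"
            )
        return _fast.assign_kernel(
            self.feature, self.threshold, self.left, self.right, self.leaf_id, values
        )

    def __eq__(self, other) -> bool:
        # structural equality: node numbering is an implementation detail
        # (serialisation renumbers in preorder), the split tree is not
        if not isinstance(other, UTree):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def to_dict(self, node: int = 0) -> dict:
        if self.feature[node] < 0:
            return {"leaf_id": int(self.leaf_id[node]), "n_train": int(self.n_train[node])}
        return {
            "feature": int(self.feature[node]),
            "threshold": float(self.threshold[node]),
            "left": self.to_dict(int(self.left[node])),
            "right": self.to_dict(int(self.right[node])),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UTree":
        feature: list[int] = []
        threshold: list[float] = []
        left: list[int] = []
        right: list[int] = []
        leaf_id: list[int] = []
        n_train: list[int] = []

        def build(node: dict) -> int:
            i = len(feature)
            feature.append(-1)
            threshold.append(float("nan"))
            left.append(-1)
            right.append(-1)
            leaf_id.append(-1)
            n_train.append(0)
            if "leaf_id" in node:
                leaf_id[i] = int(node["leaf_id"])
                n_train[i] = int(node.get("n_train", 0))
            else:
                feature[i] = int(node["feature"])
                threshold[i] = float(node["threshold"])
                left[i] = build(node["left"])
                right[i] = build(node["right"])
            return i

        build(d)
        return cls(
            np.asarray(feature, np.int64),
            np.asarray(threshold, np.float64),
            np.asarray(left, np.int64),
            np.asarray(right, np.int64),
            np.asarray(leaf_id, np.int64),
            np.asarray(n_train, np.int64),
        )


@dataclass
class UForest:
    """An ordered list of trees plus fit metadata."""

    trees: list[UTree]
    params: ForestParams
    p: int
    feature_names: list[str] | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def apply(self, X) -> np.ndarray:
        """Leaf assignment for every tree: array of shape (n_trees, n)."""
        values = as_values(X)
        out = np.empty((self.n_trees, values.shape[0]), np.int64)
        for i, tree in enumerate(self.trees):
            out[i] = tree.assign(values)
        return out


def grow_tree(X, params: ForestParams, tree_seed: int | None = None) -> UTree:
    """Grow a single unsupervised tree.

    ``tree_seed`` defaults to the substream 0 of ``params.seed``; the
    result is a pure function of ``(X, params, tree_seed)``.
    """
    values = as_values(X)
    if values.shape[0] < 1:
        raise ValueError("cannot grow a tree on an empty matrix")
    if tree_seed is None:
        tree_seed = derive_seed(params.seed, 0)
    mtry = min(params.mtry, values.shape[1])
    arrays = _fast.grow_kernel(
        values, tree_seed, mtry, params.min_leaf_size, params.bootstrap
    )
    return UTree(*arrays[:6], in_bag=arrays[6])


def fit_forest(X, params: ForestParams | None = None) -> UForest:
    """Grow ``params.n_trees`` trees, each from its own seed substream."""
    if params is None:
        params = ForestParams()
    values = as_values(X)
    trees = [
        grow_tree(values, params, derive_seed(params.seed, i))
        for i in range(params.n_trees)
    ]
    names = X.feature_names if isinstance(X, FeatureMatrix) else None
    return UForest(trees, params, values.shape[1], names)


def assign_leaves(tree: UTree, X) -> np.ndarray:
    """Leaf id for every row of X under ``tree``."""
    return tree.assign(X)


# ---------------------------------------------------------------------------
# serialisation

def forest_to_dict(forest: UForest) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "params": forest.params.to_dict(),
        "p": forest.p,
        "feature_names": forest.feature_names,
        "trees": [t.to_dict() for t in forest.trees],
    }


def forest_from_dict(d: dict) -> UForest:
    params = ForestParams(**d["params"])
    trees = [UTree.from_dict(t) for t in d["trees"]]
    if len(trees) != params.n_trees:
        params = replace(params, n_trees=len(trees))
    return UForest(trees, params, int(d["p"]), d.get("feature_names"))


def save_forest(forest: UForest, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(forest_to_dict(forest), fh)


def load_forest(path: str | os.PathLike) -> UForest:
    with open(path) as fh:
        return forest_from_dict(json.load(fh))
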