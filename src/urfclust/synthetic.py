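"""Synthetic 2-D benchmark scenarios and the clustering comparison.

Four scenario families probe where a Euclidean affinity works and where
it breaks: three equal isotropic Gaussian clusters at varying spread;
the same clusters with a percentage of far-out outliers; clusters of
strongly differing spread; and two concentric rings (a non-convex
structure no Euclidean prototype distance can capture).  Each generator
is a pure function of its parameters and seed.

``run_scenario_experiment`` replicates the comparison protocol: per
replicate the forest affinity (500 trees, minimum leaf 5, one candidate
feature per node), the raw Euclidean distance and the Euclidean
distance on per-feature standardised data are each Ward-cut at the
true number of clusters and scored against the ground truth with the
Adjusted Rand Index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .affinity import forest_counts, normalize_affinity
from .clustering import affinity_to_distance, ward_cluster
from .forest import ForestParams, derive_seed, fit_forest
from .matrix import FeatureMatrix

_CLUSTER_CENTERS = [(1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
_OUTLIER_CENTERS = [(3.0, 0.0), (0.0, 3.0), (3.0, 3.0)]
_SIZE_CENTERS = [(0.0, 0.0), (1.0, 1.0), (-2.0, 2.0)]


@dataclass
class LabeledDataset:
    """A 2-feature matrix plus ground-truth cluster labels."""

    X: FeatureMatrix
    labels: np.ndarray
    scenario: str
    parameter: float


def _dataset(points: np.ndarray, labels: np.ndarray, scenario: str, parameter: float) -> LabeledDataset:
    fm = FeatureMatrix(points, feature_names=["x", "y"])
    return LabeledDataset(fm, np.asarray(labels, np.int64), scenario, parameter)


def make_equal_globular(sd: float, seed: int = 0, n_per_cluster: int = 100) -> LabeledDataset:
    """Three Gaussian clusters of ``n_per_cluster`` points at centers
    (1,0), (0,1), (1,1) with common isotropic standard deviation ``sd``."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(c, sd, (n_per_cluster, 2)) for c in _CLUSTER_CENTERS])
    labels = np.repeat(np.arange(3), n_per_cluster)
    return _dataset(pts, labels, "equal_globular", sd)


def make_outlier_scenario(outlier_pct: float, seed: int = 0, n_per_cluster: int = 100) -> LabeledDataset:
    """Equal clusters (sd 0.25) plus ``outlier_pct`` percent outliers.

    Each cluster receives outliers drawn around its paired far-out
    center — (3,0), (0,3), (3,3) — with standard deviation 1; the
    outliers keep the label of their cluster, so the ground truth stays
    three classes.
    """
    if outlier_pct < 0:
        raise ValueError("outlier percentage cannot be negative")
    rng = np.random.default_rng(seed)
    n_out = int(round(outlier_pct / 100.0 * n_per_cluster))
    blocks, labels = [], []
    for c, (center, ocenter) in enumerate(zip(_CLUSTER_CENTERS, _OUTLIER_CENTERS)):
        blocks.append(rng.normal(center, 0.25, (n_per_cluster, 2)))
        labels.append(np.full(n_per_cluster, c))
        if n_out:
            blocks.append(rng.normal(ocenter, 1.0, (n_out, 2)))
            labels.append(np.full(n_out, c))
    return _dataset(np.vstack(blocks), np.concatenate(labels), "outliers", outlier_pct)


def make_varying_sizes(m: float, seed: int = 0, n_per_cluster: int = 100) -> LabeledDataset:
    """Three clusters at (0,0), (1,1), (-2,2) with standard deviations
    0.1, 0.1 + 0.1 m and 0.1 + 0.2 m — spatial sizes diverge as m grows."""
    if m < 0:
        raise ValueError("m cannot be negative")
    sds = [0.1, 0.1 + 0.1 * m, 0.1 + 0.2 * m]
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [rng.normal(c, s, (n_per_cluster, 2)) for c, s in zip(_SIZE_CENTERS, sds)]
    )
    labels = np.repeat(np.arange(3), n_per_cluster)
    return _dataset(pts, labels, "varying_sizes", m)


def make_rings(distance: float, seed: int = 0, n_per_ring: int = 100) -> LabeledDataset:
    """Two concentric rings centred at the origin.

    Ring 1 has radii uniform in [1, 2]; ring 2, also of width 1, starts
    ``distance`` beyond ring 1's outer radius (radii uniform in
    [2 + distance, 3 + distance]).  Angles are uniform.
    """
    if distance <= 0:
        raise ValueError("ring distance must be positive")
    rng = np.random.default_rng(seed)
    r = np.concatenate(
        [
            rng.uniform(1.0, 2.0, n_per_ring),
            rng.uniform(2.0 + distance, 3.0 + distance, n_per_ring),
        ]
    )
    theta = rng.uniform(0.0, 2.0 * np.pi, 2 * n_per_ring)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    labels = np.repeat(np.arange(2), n_per_ring)
    return _dataset(pts, labels, "rings", distance)


def make_half_moons(noise: float = 0.05, seed: int = 0, n_per_moon: int = 100) -> LabeledDataset:
    """Two interleaved half-moons — a second non-convex shape used for
    side experiments; not part of the main scenario grids."""
    from sklearn.datasets import make_moons

    pts, labels = make_moons(n_samples=2 * n_per_moon, noise=noise, random_state=seed)
    return _dataset(pts, labels, "half_moons", noise)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement of two partitions (standard contingency
    form with the expected-index correction)."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError("labelings must have equal length")
    if a.size < 2:
        raise ValueError("need at least two samples")
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# the scenario comparison

_GENERATORS = {
    "equal_globular": make_equal_globular,
    "outliers": make_outlier_scenario,
    "varying_sizes": make_varying_sizes,
    "rings": make_rings,
    "half_moons": make_half_moons,
}

DEFAULT_GRIDS = {
    "equal_globular": [0.1, 0.2, 0.3, 0.4, 0.5],
    "outliers": [2.0, 4.0, 6.0, 8.0, 10.0],
    "varying_sizes": [1.0, 2.0, 3.0, 4.0, 5.0],
    "rings": [1.0, 1.5, 2.0, 2.5, 3.0],
    "half_moons": [0.05],
}

TRUE_K = {
    "equal_globular": 3,
    "outliers": 3,
    "varying_sizes": 3,
    "rings": 2,
    "half_moons": 2,
}


@dataclass
class ScenarioConfig:
    scenario: str
    parameters: list[float] | None = None
    n_replicates: int = 30
    seed: int = 0
    forest: ForestParams = field(default_factory=ForestParams)

    def __post_init__(self) -> None:
        if self.scenario not in _GENERATORS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {sorted(_GENERATORS)}"
            )
        if self.parameters is None:
            self.parameters = list(DEFAULT_GRIDS[self.scenario])
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")


def generate_scenario(scenario: str, parameter: float, seed: int = 0) -> LabeledDataset:
    return _GENERATORS[scenario](parameter, seed)


def _euclidean_labels(points: np.ndarray, k: int, standardize: bool) -> np.ndarray:
    if standardize:
        points = (points - points.mean(axis=0)) / points.std(axis=0)
    D = squareform(pdist(points))
    return ward_cluster(D, k).labels


def run_scenario_experiment(config: ScenarioConfig) -> pd.DataFrame:
    """Replicated ARI comparison of uRF vs Euclidean Ward clustering.

    Returns a tidy frame with one row per (parameter, method,
    replicate): columns scenario, parameter, method, replicate, ari.
    Methods: ``uRF`` (forest affinity), ``HC`` (raw Euclidean),
    ``HCscaled`` (Euclidean on standardised features).
    """
    k = TRUE_K[config.scenario]
    rows = []
    for pi, parameter in enumerate(config.parameters):
        for rep in range(config.n_replicates):
            data_seed = derive_seed(config.seed, pi, rep, 0)
            forest_seed = derive_seed(config.seed, pi, rep, 1)
            ds = generate_scenario(config.scenario, parameter, data_seed)
            pts = ds.X.values

            forest = fit_forest(ds.X, replace(config.forest, seed=forest_seed))
            D = affinity_to_distance(normalize_affinity(forest_counts(forest, ds.X)))
            results = {
                "uRF": ward_cluster(D, k).labels,
                "HC": _euclidean_labels(pts, k, standardize=False),
                "HCscaled": _euclidean_labels(pts, k, standardize=True),
            }
            for method, labels in results.items():
                rows.append(
                    {
                        "scenario": config.scenario,
                        "parameter": parameter,
                        "method": method,
                        "replicate": rep,
                        "ari": adjusted_rand_index(ds.labels, labels),
                    }
                )
    return pd.DataFrame(rows)


def median_ari(results: pd.DataFrame) -> pd.DataFrame:
    """Median ARI per (parameter, method), wide format."""
    return results.pivot_table(
        index="parameter", columns="method", values="ari", aggfunc="median"
    )
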