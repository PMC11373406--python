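"""The unsupervised split criterion.

A candidate split of a tree node is scored by the ratio of the mean
squared pairwise difference of the candidate feature *within* the two
children (averaged over the children) to the mean squared difference
*between* the children — a fixation-index-style contrast of within- vs
between-group spread.  A score of 0 means the children are internally
homogeneous on that feature; the best split *minimises* the score.

This module is the readable numpy reference; the tree grower in
``_fast`` re-implements the same arithmetic with prefix sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SplitRule:
    """An axis-aligned split: values ``<= threshold`` go to the left child."""

    feature_index: int
    threshold: float


def _mean_sq_within(x: np.ndarray) -> float:
    """Mean of (x_i - x_j)^2 over ordered pairs i != j; 0 for a singleton."""
    n = x.size
    if n < 2:
        return 0.0
    s1 = float(x.sum())
    s2 = float((x * x).sum())
    return 2.0 * (n * s2 - s1 * s1) / (n * (n - 1))


def _mean_sq_between(left: np.ndarray, right: np.ndarray) -> float:
    """Mean of (x_i - x_j)^2 over pairs with i in left, j in right."""
    nl, nr = left.size, right.size
    cross = nr * float((left * left).sum()) + nl * float((right * right).sum()) \
        - 2.0 * float(left.sum()) * float(right.sum())
    return cross / (nl * nr)


def split_score(x_node: np.ndarray, left_mask: np.ndarray) -> float:
    """Score a split of the node values `x_node` defined by `left_mask`.

    Returns within-children spread divided by between-children spread;
    lower is better.  If every value is identical across the two
    children the between-term is zero and the split is invalid: the
    score is ``inf`` so it is never selected.

    Raises
    ------
    ValueError
        If either child is empty or the values are not finite.
    """
    x = np.asarray(x_node, dtype=np.float64).ravel()
    mask = np.asarray(left_mask, dtype=bool).ravel()
    if x.shape != mask.shape:
        raise ValueError("x_node and left_mask must have the same length")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in x_node")
    left = x[mask]
    right = x[~mask]
    if left.size == 0 or right.size == 0:
        raise ValueError("both children must be nonempty")
    between = _mean_sq_between(left, right)
    if between <= 0.0:
        return math.inf
    return 0.5 * (_mean_sq_within(left) + _mean_sq_within(right)) / between


def best_split(
    X_node: np.ndarray,
    candidate_features,
    min_leaf_size: int,
) -> tuple[SplitRule, float] | None:
    """Exhaustive threshold search over the candidate features.

    Thresholds are midpoints between consecutive distinct sorted values.
    Returns the (rule, score) minimising the split score among splits
    leaving at least ``min_leaf_size`` samples per child, with ties
    broken by lowest feature index then lowest threshold, or ``None``
    when no valid split exists.
    """
    X = np.asarray(X_node, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X_node must be 2-D")
    n = X.shape[0]
    if n < 2 * min_leaf_size:
        return None
    best: tuple[SplitRule, float] | None = None
    for f in sorted(int(f) for f in candidate_features):
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        for i in range(1, n):
            if xs[i] == xs[i - 1]:
                continue
            if i < min_leaf_size or n - i < min_leaf_size:
                continue
            thr = 0.5 * (xs[i - 1] + xs[i])
            if thr >= xs[i]:  # midpoint rounded up between adjacent floats
                thr = float(xs[i - 1])
            score = split_score(x, x <= thr)
            if math.isinf(score):
                continue
            if best is None or score < best[1]:
                best = (SplitRule(f, float(thr)), score)
    return best
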