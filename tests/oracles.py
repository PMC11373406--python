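"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import itertools
import math

import numpy as np


def split_score_oracle(x, left_mask) -> float:
    """Double loop over all ordered pairs: within/between spread ratio."""
    x = np.asarray(x, dtype=float)
    left = x[np.asarray(left_mask, bool)]
    right = x[~np.asarray(left_mask, bool)]

    def within(v):
        n = len(v)
        if n < 2:
            return 0.0
        total = sum((v[i] - v[j]) ** 2 for i in range(n) for j in range(n) if i != j)
        return total / (n * (n - 1))

    between = sum((a - b) ** 2 for a in left for b in right) / (len(left) * len(right))
    if between == 0.0:
        return math.inf
    return 0.5 * (within(left) + within(right)) / between


def best_split_oracle(X, features, min_leaf):
    """Exhaustive midpoint scan scored with the brute-force criterion."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best = None
    for f in sorted(features):
        xs = np.sort(np.unique(X[:, f]))
        for lo, hi in zip(xs[:-1], xs[1:]):
            thr = (lo + hi) / 2
            mask = X[:, f] <= thr
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            s = split_score_oracle(X[:, f], mask)
            if math.isinf(s):
                continue
            if best is None or s < best[2]:
                best = (f, thr, s)
    return best


def ari_oracle(a, b) -> float:
    """Pair-counting Adjusted Rand Index."""
    a = list(a)
    b = list(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = ((ss + sd) + (ss + ds)) / 2
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)


def ward_merges_oracle(D):
    """Textbook agglomerative Ward via the Lance–Williams update.

    Returns the merge history as a list of frozensets of original leaf
    indices, mirroring how a linkage matrix can be read.  Assumes all
    inter-cluster distances stay distinct (no tie handling).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), _ = min(
            ((tuple(sorted(key)), v) for key, v in dist.items()),
            key=lambda kv: kv[1],
        )
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        ni, nj = sizes[i], sizes[j]
        dij = dist.pop(frozenset((i, j)))
        for k in list(clusters):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            new = math.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            dist[frozenset((next_id, k))] = new
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[next_id] = merged
        sizes[next_id] = len(merged)
        next_id += 1
    return merges


def silhouette_oracle(D, labels) -> float:
    """Per-sample a/b silhouette on a precomputed distance matrix."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    vals = []
    for i in range(len(labels)):
        own = (labels == labels[i]) & (np.arange(len(labels)) != i)
        if own.sum() == 0:
            vals.append(0.0)
            continue
        a = D[i, own].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))
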