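"""Numba kernels for tree growing, leaf routing and co-occurrence counting.

The tree grower works on a flat array representation (one row per node)
and partitions an index buffer in place, sklearn-style.  All randomness
is drawn from numba's ``np.random`` state, seeded once per tree, so a
tree is a pure function of ``(X, seed, mtry, min_leaf, bootstrap)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def grow_kernel(X, seed, mtry, min_leaf, bootstrap):
    """Grow one unsupervised tree; returns flat node arrays.

    Split criterion: mean within-child squared pairwise difference of the
    candidate feature (averaged over the two children) divided by the mean
    across-children squared difference; the split minimising this ratio is
    chosen.  Ties break to the lowest feature index, then lowest threshold.
    """
    np.random.seed(seed)
    n, p = X.shape
    idx = np.empty(n, np.int64)
    if bootstrap:
        for i in range(n):
            idx[i] = np.random.randint(0, n)
    else:
        for i in range(n):
            idx[i] = i

    max_leaves = max(1, n // max(min_leaf, 1))
    max_nodes = 2 * max_leaves
    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.full(max_nodes, np.nan, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    leaf_id = np.full(max_nodes, -1, np.int64)
    n_train = np.zeros(max_nodes, np.int64)

    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    cand = np.empty(p, np.int64)
    vals = np.empty(n, np.float64)

    n_nodes = 1
    n_leaves = 0
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    top = 1
    while top > 0:
        top -= 1
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        m = hi - lo
        n_train[node] = m

        best_score = np.inf
        best_f = -1
        best_thr = 0.0
        if m >= 2 * min_leaf:
            for i in range(p):
                cand[i] = i
            kf = mtry if mtry < p else p
            # partial Fisher-Yates: uniform sample of kf features
            for i in range(kf):
                j = i + np.random.randint(0, p - i)
                tmp = cand[i]
                cand[i] = cand[j]
                cand[j] = tmp
            cands = np.sort(cand[:kf])
            for ci in range(kf):
                f = cands[ci]
                v = vals[:m]
                for i in range(m):
                    v[i] = X[idx[lo + i], f]
                v = np.sort(v)
                tot1 = 0.0
                tot2 = 0.0
                for i in range(m):
                    tot1 += v[i]
                    tot2 += v[i] * v[i]
                s1 = 0.0
                s2 = 0.0
                for i in range(1, m):
                    s1 += v[i - 1]
                    s2 += v[i - 1] * v[i - 1]
                    if v[i] == v[i - 1]:
                        continue
                    nl = i
                    nr = m - i
                    if nl < min_leaf or nr < min_leaf:
                        continue
                    r1 = tot1 - s1
                    r2 = tot2 - s2
                    # sum over ordered pairs (a,b), a!=b, of (x_a-x_b)^2
                    # equals 2*(N*sum(x^2) - sum(x)^2)
                    dl = 0.0 if nl == 1 else 2.0 * (nl * s2 - s1 * s1) / (nl * (nl - 1.0))
                    dr = 0.0 if nr == 1 else 2.0 * (nr * r2 - r1 * r1) / (nr * (nr - 1.0))
                    cross = nr * s2 + nl * r2 - 2.0 * s1 * r1
                    dnab = cross / (nl * nr)
                    if dnab <= 0.0:
                        continue
                    score = 0.5 * (dl + dr) / dnab
                    if score < best_score:
                        thr = 0.5 * (v[i - 1] + v[i])
                        if thr >= v[i]:
                            # midpoint rounded up to the upper value; fall
                            # back so that "<= thr" keeps the left block
                            thr = v[i - 1]
                        best_score = score
                        best_f = f
                        best_thr = thr

        if best_f < 0:
            leaf_id[node] = n_leaves
            n_leaves += 1
            continue

        i = lo
        j = hi - 1
        while i <= j:
            if X[idx[i], best_f] <= best_thr:
                i += 1
            else:
                tmp = idx[i]
                idx[i] = idx[j]
                idx[j] = tmp
                j -= 1
        mid = i
        feature[node] = best_f
        threshold[node] = best_thr
        lc = n_nodes
        rc = n_nodes + 1
        n_nodes += 2
        left[node] = lc
        right[node] = rc
        # push right first so the left subtree is grown first and leaf
        # ids run left-to-right
        stack_node[top] = rc
        stack_lo[top] = mid
        stack_hi[top] = hi
        top += 1
        stack_node[top] = lc
        stack_lo[top] = lo
        stack_hi[top] = mid
        top += 1

    return (
        feature[:n_nodes],
        threshold[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        leaf_id[:n_nodes],
        n_train[:n_nodes],
        idx,
    )


@njit(cache=True)
def assign_kernel(feature, threshold, left, right, leaf_id, X):
    """Route every row of X to a leaf; '<= threshold' goes left."""
    n = X.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = leaf_id[node]
    return out


@njit(cache=True)
def cooccurrence_accumulate(leaves, counts):
    """Add, for each tree row in `leaves` (T x n), 1 to counts[i, j] when
    samples i and j share a leaf.  Fills the upper triangle incl. diagonal;
    the caller symmetrises."""
    T, n = leaves.shape
    for t in range(T):
        for i in range(n):
            li = leaves[t, i]
            for j in range(i, n):
                if leaves[t, j] == li:
                    counts[i, j] += 1
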