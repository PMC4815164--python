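"""Numba kernels for tree growth, prediction, noise-up traversal and
maximal-subtree depth bookkeeping.

Trees are stored as flat parallel arrays indexed by node id; node ids are
assigned in creation order, so every parent id is smaller than its
children's ids (the depth kernels rely on this topological ordering).
Genotype thresholds are 0.5 and 1.5 on the 0/1/2 dosage scale.  All
randomness inside a kernel comes from numba's global NumPy legacy RNG,
seeded at kernel entry, which makes every tree reproducible from its seed
alone.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LEAF = -1


@njit(cache=True)
def _weighted_gini_gain(c0p, c1p, c0l, c1l, c0r, c1r):
    """Count-weighted impurity decrease n_p*G_p - n_l*G_l - n_r*G_r.

    Algebraically equal to sum-of-squares form; clamped at 0 so zero-gain
    splits compare exactly equal.
    """
    nl = c0l + c1l
    nr = c0r + c1r
    npar = c0p + c1p
    dec = (
        (c0l * c0l + c1l * c1l) / nl
        + (c0r * c0r + c1r * c1r) / nr
        - (c0p * c0p + c1p * c1p) / npar
    )
    if dec < 0.0:
        dec = 0.0
    return dec


@njit(cache=True)
def grow_tree_kernel(X, y, in_bag, mtry, seed):
    """Grow one classification tree to purity on the in-bag sample.

    Candidate variables at each node are the first ``mtry`` entries of a
    fresh full shuffle of all variables; if none of them admits a split at
    an impure node, the remaining shuffled variables are scanned in order
    and the best split of the first splittable one is used, so leaves are
    impure only when their covariate rows are identical.  Ties between
    candidate splits go to the earlier candidate in the shuffled order.

    Returns flat arrays: split_var (-1 at leaves), threshold, left, right,
    parent, depth, class counts (controls, cases), gini decrease, leaf class.
    """
    np.random.seed(seed)
    m = in_bag.shape[0]
    p = X.shape[1]
    max_nodes = 2 * m + 1

    split_var = np.full(max_nodes, LEAF, np.int64)
    threshold = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    parent = np.full(max_nodes, -1, np.int64)
    depth = np.zeros(max_nodes, np.int64)
    count0 = np.zeros(max_nodes, np.int64)
    count1 = np.zeros(max_nodes, np.int64)
    gdec = np.zeros(max_nodes, np.float64)
    leaf_class = np.full(max_nodes, -1, np.int64)

    idx = in_bag.copy()
    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    top = 0
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = m
    n_nodes = 1
    order = np.empty(p, np.int64)

    while top >= 0:
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        top -= 1

        c1 = 0
        for i in range(lo, hi):
            c1 += y[idx[i]]
        c0 = (hi - lo) - c1
        count0[node] = c0
        count1[node] = c1

        if c0 == 0 or c1 == 0:
            leaf_class[node] = 0 if c1 == 0 else 1
            continue

        # fresh full shuffle; first mtry entries are the candidate draw
        for j in range(p):
            order[j] = j
        for k in range(p - 1):
            j = k + np.random.randint(p - k)
            t = order[k]
            order[k] = order[j]
            order[j] = t

        best_var = -1
        best_thr = 0.0
        best_dec = -1.0
        ci = 0
        while ci < p:
            if ci >= mtry and best_var >= 0:
                break  # fallback vars only matter while no split exists
            var = order[ci]
            l0c0 = 0
            l0c1 = 0
            l1c0 = 0
            l1c1 = 0
            for i in range(lo, hi):
                g = X[idx[i], var]
                yy = y[idx[i]]
                if g == 0:
                    l0c0 += 1 - yy
                    l0c1 += yy
                if g <= 1:
                    l1c0 += 1 - yy
                    l1c1 += yy
            # ties in the decrease go to the earlier candidate in the
            # shuffled order (and to threshold 0.5 within a candidate):
            # deterministic given the tree seed, and unbiased across
            # variable indices — an index-preferring tie rule would inflate
            # low-index importances, exact ties being common in small nodes
            # threshold 0.5: left = genotype 0
            nl = l0c0 + l0c1
            if 0 < nl < c0 + c1:
                dec = _weighted_gini_gain(c0, c1, l0c0, l0c1, c0 - l0c0, c1 - l0c1)
                if dec > best_dec:
                    best_var = var
                    best_thr = 0.5
                    best_dec = dec
            # threshold 1.5: left = genotype 0 or 1
            nl = l1c0 + l1c1
            if 0 < nl < c0 + c1:
                dec = _weighted_gini_gain(c0, c1, l1c0, l1c1, c0 - l1c0, c1 - l1c1)
                if dec > best_dec:
                    best_var = var
                    best_thr = 1.5
                    best_dec = dec
            ci += 1

        if best_var < 0:
            # impure but unsplittable: identical covariate rows
            if c1 > c0:
                leaf_class[node] = 1
            elif c0 > c1:
                leaf_class[node] = 0
            else:
                leaf_class[node] = np.random.randint(2)
            continue

        # partition idx[lo:hi] on the chosen split
        cut = 0 if best_thr == 0.5 else 1
        i = lo
        j = hi - 1
        while i <= j:
            if X[idx[i], best_var] <= cut:
                i += 1
            else:
                t = idx[i]
                idx[i] = idx[j]
                idx[j] = t
                j -= 1
        mid = i

        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        split_var[node] = best_var
        threshold[node] = best_thr
        gdec[node] = best_dec
        left[node] = lid
        right[node] = rid
        parent[lid] = node
        parent[rid] = node
        depth[lid] = depth[node] + 1
        depth[rid] = depth[node] + 1
        # push right first so the left child is processed (and numbered) next
        top += 1
        stack_node[top] = rid
        stack_lo[top] = mid
        stack_hi[top] = hi
        top += 1
        stack_node[top] = lid
        stack_lo[top] = lo
        stack_hi[top] = mid

    return (
        split_var[:n_nodes].copy(),
        threshold[:n_nodes].copy(),
        left[:n_nodes].copy(),
        right[:n_nodes].copy(),
        parent[:n_nodes].copy(),
        depth[:n_nodes].copy(),
        count0[:n_nodes].copy(),
        count1[:n_nodes].copy(),
        gdec[:n_nodes].copy(),
        leaf_class[:n_nodes].copy(),
    )


@njit(cache=True)
def predict_rows_kernel(
    split_var, threshold, left, right, leaf_class, X, rows, ov_cols, ov_vals
):
    """Predict class labels for X[rows] by tree traversal.

    ``ov_cols``/``ov_vals`` optionally override up to a few columns:
    ov_vals[q, r] replaces X[rows[r], ov_cols[q]] (used for permutation
    importance).  Pass empty arrays for plain prediction.
    """
    nr = rows.shape[0]
    nov = ov_cols.shape[0]
    out = np.empty(nr, np.int64)
    for r in range(nr):
        row = rows[r]
        node = 0
        while split_var[node] >= 0:
            v = split_var[node]
            g = np.int64(-1)
            for q in range(nov):
                if ov_cols[q] == v:
                    g = ov_vals[q, r]
            if g < 0:
                g = np.int64(X[row, v])
            if g <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[r] = leaf_class[node]
    return out


@njit(cache=True)
def noise_up_predict_kernel(
    split_var, threshold, left, right, leaf_class, X, rows, triggers, seed
):
    """Traverse normally until a node splitting on a trigger variable is
    reached (the root of a maximal subtree of that variable); from that node
    on, every split resolves by a fair coin flip."""
    np.random.seed(seed)
    nr = rows.shape[0]
    nt = triggers.shape[0]
    out = np.empty(nr, np.int64)
    for r in range(nr):
        row = rows[r]
        node = 0
        randomized = False
        while split_var[node] >= 0:
            v = split_var[node]
            if not randomized:
                for q in range(nt):
                    if triggers[q] == v:
                        randomized = True
                        break
            if randomized:
                if np.random.randint(2) == 0:
                    node = left[node]
                else:
                    node = right[node]
            else:
                if X[row, v] <= threshold[node]:
                    node = left[node]
                else:
                    node = right[node]
        out[r] = leaf_class[node]
    return out


@njit(cache=True)
def subtree_depth_kernel(split_var, parent, depth, track):
    """Minimal depths and second-order minimal depths for tracked variables.

    Returns
    -------
    min_depth : (t,) shallowest split depth per tracked variable, -1 absent.
    so_depth : (t, t) minimum over (i-ancestor, j-descendant) node pairs of
        the depth of the shallowest x_j split inside any maximal x_i-subtree,
        measured in edges from that subtree's root; -1 when no x_j split lies
        inside any maximal x_i-subtree.  Row index = i, column = j.

    Relies on parent ids preceding child ids (creation order).
    """
    t = track.shape[0]
    n = split_var.shape[0]
    min_depth = np.full(t, -1, np.int64)
    so_depth = np.full((t, t), -1, np.int64)
    # topmost[a, node]: depth of the highest ancestor of `node` splitting on
    # track[a]; -1 if none.  Computed top-down in id order.
    topmost = np.full((t, n), -1, np.int64)
    for node in range(n):
        par = parent[node]
        if par >= 0:
            for a in range(t):
                if topmost[a, par] >= 0:
                    topmost[a, node] = topmost[a, par]
                elif split_var[par] == track[a]:
                    topmost[a, node] = depth[par]
        sv = split_var[node]
        if sv < 0:
            continue
        for a in range(t):
            if sv == track[a]:
                if min_depth[a] < 0 or depth[node] < min_depth[a]:
                    min_depth[a] = depth[node]
                for b in range(t):
                    if b == a:
                        continue
                    if topmost[b, node] >= 0:
                        rel = depth[node] - topmost[b, node]
                        if so_depth[b, a] < 0 or rel < so_depth[b, a]:
                            so_depth[b, a] = rel
    return min_depth, so_depth
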