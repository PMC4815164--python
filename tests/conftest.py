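"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (exhaustive
enumeration, recursive greedy search, direct counting) so that the fast
array/kernel implementations are checked against logic that shares none of
their machinery.
"""

from __future__ import annotations

import numpy as np
import pytest

from epiforest.forest import Tree


# ---------------------------------------------------------------------------
# datasets


@pytest.fixture
def xor_dataset():
    """Noiseless two-variable checkerboard: class = parity of the two
    binary-like genotypes (0 or 2).  No marginal effect exists, so the first
    split is necessarily zero-gain."""
    rng = np.random.default_rng(42)
    cells = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=np.int8)
    X = np.repeat(cells, 50, axis=0)  # exactly balanced: no marginal signal
    rng.shuffle(X)
    y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(np.int8)
    return X, y


def small_dataset(seed: int, n: int = 8, p: int = 3):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    y = rng.integers(0, 2, size=n).astype(np.int8)
    return X, y


# ---------------------------------------------------------------------------
# brute-force greedy CART oracle (mtry = all variables, no bootstrap)


def _kernel_gain(c0, c1, a, b):
    """Same algebraic form as the growth kernel so exact float ties agree."""
    nl = a + b
    nr = (c0 - a) + (c1 - b)
    npar = c0 + c1
    dec = (
        (a * a + b * b) / nl
        + ((c0 - a) ** 2 + (c1 - b) ** 2) / nr
        - (c0 * c0 + c1 * c1) / npar
    )
    return max(dec, 0.0)


def exhaustive_argmax_splits(X, y):
    """Every (variable, threshold, decrease) achieving the maximal Gini
    decrease over all candidate splits of this node; [] if unsplittable."""
    X = np.asarray(X)
    y = np.asarray(y)
    c0, c1 = int((y == 0).sum()), int((y == 1).sum())
    found = []
    for var in range(X.shape[1]):
        for thr in (0.5, 1.5):
            mask = X[:, var] <= thr
            a = int(((y == 0) & mask).sum())
            b = int(((y == 1) & mask).sum())
            if (a + b) in (0, c0 + c1):
                continue
            found.append((var, thr, _kernel_gain(c0, c1, a, b)))
    if not found:
        return []
    top = max(d for _, _, d in found)
    return [s for s in found if s[2] == top]


def assert_greedy_cart(tree: Tree, X, y):
    """Brute-force greedy consistency: every internal node's split must be a
    global maximizer of the Gini decrease over all (variable, threshold)
    pairs on the rows reaching that node; counts, purity stopping and leaf
    majorities (up to ties) are checked too.  Valid for trees grown with all
    variables as candidates and no bootstrap."""
    X = np.asarray(X)
    y = np.asarray(y)

    def walk(node, rows):
        ys = y[rows]
        c0, c1 = int((ys == 0).sum()), int((ys == 1).sum())
        assert tuple(node.class_counts) == (c0, c1)
        argmax = exhaustive_argmax_splits(X[rows], ys)
        if node.split_variable is None:
            # leaf: must be pure or unsplittable, with a majority class
            assert c0 == 0 or c1 == 0 or not argmax
            if c0 != c1:
                assert node.leaf_class == int(c1 > c0)
            return
        assert c0 > 0 and c1 > 0 and argmax
        assert any(
            v == node.split_variable
            and t == node.split_threshold
            and node.gini_decrease == pytest.approx(d)
            for v, t, d in argmax
        ), (node.split_variable, node.split_threshold, argmax)
        mask = X[rows, node.split_variable] <= node.split_threshold
        walk(node.left, rows[mask])
        walk(node.right, rows[~mask])

    walk(tree.root, np.arange(X.shape[0]))


# ---------------------------------------------------------------------------
# random nested fixture trees + exhaustive depth oracles


def random_tree_dict(rng: np.random.Generator, n_vars: int = 6, max_depth: int = 7):
    """Random split structure (not grown from data) for depth oracles."""

    def node(depth):
        if depth >= max_depth or rng.random() < 0.35:
            return {
                "split_variable": None,
                "class_counts": (1, 0),
                "leaf_class": 0,
            }
        return {
            "split_variable": int(rng.integers(n_vars)),
            "split_threshold": float(rng.choice([0.5, 1.5])),
            "class_counts": (1, 1),
            "left": node(depth + 1),
            "right": node(depth + 1),
        }

    root = node(0)
    while root["split_variable"] is None:  # ensure a non-trivial tree
        root = node(0)
    return root


def oracle_min_depth(node: dict, var: int, depth: int = 0):
    """Shallowest split on ``var`` by full traversal; None when absent."""
    if node["split_variable"] is None:
        return None
    best = depth if node["split_variable"] == var else None
    for child in (node["left"], node["right"]):
        d = oracle_min_depth(child, var, depth + 1)
        if d is not None and (best is None or d < best):
            best = d
    return best


def oracle_second_order_depth(node: dict, var_i: int, var_j: int):
    """Exhaustive nested scan: minimum, over all maximal x_i-subtrees, of the
    shallowest x_j split measured from that subtree's root; None if absent."""

    def maximal_subtree_roots(nd, inside_i):
        if nd["split_variable"] is None:
            return []
        roots = []
        if nd["split_variable"] == var_i and not inside_i:
            roots.append(nd)
            inside_i = True
        for child in (nd["left"], nd["right"]):
            roots.extend(maximal_subtree_roots(child, inside_i))
        return roots

    best = None
    for sub in maximal_subtree_roots(node, False):
        d = oracle_min_depth(sub, var_j)
        if d is not None and (best is None or d < best):
            best = d
    return best


def tree_height_dict(node: dict) -> int:
    if node["split_variable"] is None:
        return 0
    return 1 + max(tree_height_dict(node["left"]), tree_height_dict(node["right"]))
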