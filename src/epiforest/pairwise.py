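"""Pairwise importance measures for interaction detection.

Three measures rank unordered variable pairs:

* **PPI** (pairwise permutation importance): the OOB-accuracy drop when both
  columns are permuted simultaneously (default: the same row permutation for
  both, preserving the pair's joint distribution), averaged over trees.
  Higher = more important.
* **JMST** (joint importance by maximal subtrees): the tree-height-normalized
  minimal depth of second-order maximal subtrees, averaged over trees with a
  penalty of 1.0 where the nested structure is absent, then symmetrized over
  the two orders.  Lower = more important.
* **JVIMP** (joint variable importance via noise-up): single importance
  V_i = baseline OOB accuracy minus the accuracy when traversal turns into
  fair coin flips below any maximal x_i-subtree; the pair score is
  (V_i + V_j) - V_ij, ranked by absolute value by default.

Pairs containing noise SNPs are excluded upstream when building the
evaluation pair set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import (
    noise_up_predict_kernel,
    predict_rows_kernel,
    subtree_depth_kernel,
)
from .forest import (
    _EMPTY_COLS,
    _EMPTY_VALS,
    Forest,
    Tree,
    _check_genotypes,
    oob_accuracy,
)

__all__ = [
    "PairImportanceMatrix",
    "MaximalSubtreeRecord",
    "effect_pairs",
    "pairwise_permutation_importance",
    "minimal_depth",
    "second_order_minimal_depth",
    "jmst",
    "noise_up_accuracy",
    "jvimp",
]

PENALTY_DEPTH = 1.0  # normalized depth charged when the structure is absent


@dataclass
class PairImportanceMatrix:
    pairs: list[tuple[int, int]]  # unordered, each appears once, no self-pairs
    scores: np.ndarray
    measure: str  # "ppi" | "jmst" | "jvimp"
    direction: str  # "higher" | "lower" | "abs"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError("self-pairs are not allowed")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)


@dataclass
class MaximalSubtreeRecord:
    variable: int
    tree: int
    minimal_depth: int  # edges from the reference root; height if absent
    normalized_depth: float  # minimal_depth / tree height; 1.0 if absent
    present: bool


def effect_pairs(roles: np.ndarray) -> list[tuple[int, int]]:
    """All unordered pairs among non-noise SNPs (noise pairs are excluded
    from pairwise rankings)."""
    keep = np.flatnonzero(np.asarray(roles, dtype=object) != "noise")
    return [(int(a), int(b)) for i, a in enumerate(keep) for b in keep[i + 1 :]]


def _validate_pairs(pairs, variable_count: int) -> list[tuple[int, int]]:
    out = []
    for a, b in pairs:
        if not (0 <= a < variable_count and 0 <= b < variable_count):
            raise ValueError(f"pair ({a}, {b}) out of range")
        if a == b:
            raise ValueError("self-pairs are not allowed")
        out.append((int(a), int(b)))
    return out


# ---------------------------------------------------------------------------
# pairwise permutation importance


def pairwise_permutation_importance(
    forest: Forest,
    X: np.ndarray,
    y: np.ndarray,
    pairs,
    rng: np.random.Generator | int | None = 0,
    joint_permutation: bool = True,
    permutation_hook=None,
) -> PairImportanceMatrix:
    """OOB-accuracy drop when both pair members are permuted simultaneously.

    ``joint_permutation=True`` applies the same row permutation to both
    columns; ``False`` draws independent permutations.  ``permutation_hook``
    (size -> index array) replaces the random permutation in tests.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pairs = _validate_pairs(pairs, forest.variable_count)
    X = _check_genotypes(X)
    y = np.asarray(y, dtype=np.int64)
    scores = np.zeros(len(pairs))
    n_used = 0
    cols = np.empty(2, dtype=np.int64)
    for tree in forest.trees:
        if tree.oob.size == 0:
            warnings.warn("skipping a tree with an empty OOB set")
            continue
        n_used += 1
        rows = tree.oob
        y_oob = y[rows]
        pred = predict_rows_kernel(
            tree.split_var, tree.threshold, tree.left, tree.right,
            tree.leaf_class, X, rows, _EMPTY_COLS, _EMPTY_VALS,
        )
        base = np.mean(pred == y_oob)
        present = set(tree.split_var[tree.split_var >= 0].tolist())
        draw = permutation_hook or (lambda size: rng.permutation(size))
        for k, (a, b) in enumerate(pairs):
            if a not in present and b not in present:
                continue  # predictions cannot change; drop is exactly 0
            perm_a = draw(rows.size)
            perm_b = perm_a if joint_permutation else draw(rows.size)
            cols[0], cols[1] = a, b
            vals = np.stack([
                X[rows, a][perm_a].astype(np.int64),
                X[rows, b][perm_b].astype(np.int64),
            ])
            pred = predict_rows_kernel(
                tree.split_var, tree.threshold, tree.left, tree.right,
                tree.leaf_class, X, rows, cols, vals,
            )
            scores[k] += base - np.mean(pred == y_oob)
    if n_used == 0:
        raise ValueError("no tree has a non-empty OOB set")
    return PairImportanceMatrix(
        pairs=pairs, scores=scores / n_used, measure="ppi", direction="higher"
    )


# ---------------------------------------------------------------------------
# maximal subtrees


def minimal_depth(tree: Tree, variable: int, tree_id: int = 0) -> MaximalSubtreeRecord:
    """Depth of the shallowest split on ``variable`` (the root of its
    highest maximal subtree); penalty values when the variable is unused."""
    md, _ = subtree_depth_kernel(
        tree.split_var, tree.parent, tree.depth,
        np.asarray([variable], dtype=np.int64),
    )
    height = tree.height
    if md[0] < 0 or height == 0:
        return MaximalSubtreeRecord(
            variable=variable, tree=tree_id, minimal_depth=height,
            normalized_depth=PENALTY_DEPTH, present=False,
        )
    return MaximalSubtreeRecord(
        variable=variable, tree=tree_id, minimal_depth=int(md[0]),
        normalized_depth=float(md[0]) / height, present=True,
    )


def second_order_minimal_depth(
    tree: Tree, variable_i: int, variable_j: int, tree_id: int = 0
) -> MaximalSubtreeRecord:
    """Minimal depth of maximal (x_j, x_i)-subtrees: the shallowest x_j
    split inside any maximal x_i-subtree, in edges from that subtree's root.
    """
    if variable_i == variable_j:
        raise ValueError("second-order minimal depth needs two distinct variables")
    _, so = subtree_depth_kernel(
        tree.split_var, tree.parent, tree.depth,
        np.asarray([variable_i, variable_j], dtype=np.int64),
    )
    rel = int(so[0, 1])  # j-split within a maximal i-subtree
    height = tree.height
    if rel < 0 or height == 0:
        return MaximalSubtreeRecord(
            variable=variable_j, tree=tree_id, minimal_depth=height,
            normalized_depth=PENALTY_DEPTH, present=False,
        )
    return MaximalSubtreeRecord(
        variable=variable_j, tree=tree_id, minimal_depth=rel,
        normalized_depth=min(rel / height, 1.0), present=True,
    )


def jmst(forest: Forest, pairs) -> PairImportanceMatrix:
    """Symmetrized mean normalized second-order minimal depth (lower =
    more important); absent structure contributes the penalty 1.0."""
    pairs = _validate_pairs(pairs, forest.variable_count)
    track = sorted({v for p in pairs for v in p})
    track_arr = np.asarray(track, dtype=np.int64)
    pos = {v: i for i, v in enumerate(track)}
    total = np.zeros((len(track), len(track)))
    for tree in forest.trees:
        _, so = subtree_depth_kernel(
            tree.split_var, tree.parent, tree.depth, track_arr
        )
        height = tree.height
        if height == 0:
            total += PENALTY_DEPTH
            continue
        norm = np.where(so >= 0, np.minimum(so / height, 1.0), PENALTY_DEPTH)
        total += norm
    mean_ordered = total / forest.n_trees
    scores = np.array([
        0.5 * (mean_ordered[pos[a], pos[b]] + mean_ordered[pos[b], pos[a]])
        for a, b in pairs
    ])
    return PairImportanceMatrix(
        pairs=pairs, scores=scores, measure="jmst", direction="lower"
    )


# ---------------------------------------------------------------------------
# noise-up / JVIMP


def noise_up_accuracy(
    forest: Forest,
    X: np.ndarray,
    y: np.ndarray,
    variables,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Per-tree OOB accuracy with random descent below any maximal subtree
    of the listed variables (fair coin flips at every subsequent split)."""
    variables = np.asarray(sorted(set(int(v) for v in variables)), dtype=np.int64)
    if variables.size == 0:
        raise ValueError("variables must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = _check_genotypes(X)
    y = np.asarray(y, dtype=np.int64)
    accs = []
    for tree in forest.trees:
        if tree.oob.size == 0:
            accs.append(np.nan)
            continue
        seed = int(rng.integers(2**31))
        pred = noise_up_predict_kernel(
            tree.split_var, tree.threshold, tree.left, tree.right,
            tree.leaf_class, X, tree.oob, variables, seed,
        )
        accs.append(float(np.mean(pred == y[tree.oob])))
    return np.asarray(accs)


def jvimp(
    forest: Forest,
    X: np.ndarray,
    y: np.ndarray,
    pairs,
    rng: np.random.Generator | int | None = 0,
    signed: bool = False,
) -> PairImportanceMatrix:
    """Interaction score (V_i + V_j) - V_ij from noise-up importances.

    V_S = mean over trees of (OOB accuracy - noise-up accuracy for S).
    By default pairs are ranked by |score| (largest deviation from additivity
    first); ``signed=True`` ranks by the signed value instead.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pairs = _validate_pairs(pairs, forest.variable_count)
    X = np.asarray(X)
    y = np.asarray(y)
    base = np.array([
        oob_accuracy(t, X, y) if t.oob.size else np.nan for t in forest.trees
    ])
    valid = ~np.isnan(base)
    if not valid.any():
        raise ValueError("no tree has a non-empty OOB set")
    # common random numbers: every noise-up query reuses the same per-tree
    # coin-flip streams, so a pair query degenerates exactly to the single
    # query when one member is absent from a tree
    noise_seed = int(rng.integers(2**31))

    def importance(variables) -> float:
        accs = noise_up_accuracy(
            forest, X, y, variables, np.random.default_rng(noise_seed)
        )
        return float(np.nanmean(base[valid] - accs[valid]))

    singles = {v: importance([v]) for v in sorted({v for p in pairs for v in p})}
    scores = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        v_ab = importance([a, b])
        scores[k] = (singles[a] + singles[b]) - v_ab
    return PairImportanceMatrix(
        pairs=pairs,
        scores=scores,
        measure="jvimp",
        direction="higher" if signed else "abs",
    )
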