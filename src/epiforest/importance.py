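"""Single-variable importance: Gini importance and permutation importance.

Gini importance of variable i is the per-tree sum of count-weighted impurity
decreases at nodes splitting on i, averaged over all trees.  Permutation
importance is the per-tree drop in OOB accuracy when the variable's OOB
values are permuted (one fresh permutation per tree and variable), averaged
over trees with a non-empty OOB set; scores are unscaled raw averages
(positive = important) and may be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import predict_rows_kernel
from .forest import Forest, _check_genotypes, _EMPTY_COLS, _EMPTY_VALS

__all__ = ["ImportanceVector", "gini_importance", "permutation_importance"]


@dataclass
class ImportanceVector:
    scores: np.ndarray  # per-variable score
    measure: str  # "gini" | "permutation"
    direction: str = "higher"  # higher score = more important

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def gini_importance(forest: Forest) -> ImportanceVector:
    """Average over trees of the summed Gini decrease per split variable."""
    totals = np.zeros(forest.variable_count)
    for tree in forest.trees:
        internal = tree.split_var >= 0
        np.add.at(totals, tree.split_var[internal], tree.gini_dec[internal])
    return ImportanceVector(scores=totals / forest.n_trees, measure="gini")


def permutation_importance(
    forest: Forest,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | int | None = 0,
) -> ImportanceVector:
    """OOB-accuracy drop under per-variable permutation, averaged over trees.

    Variables absent from a tree are exactly zero for that tree and are not
    recomputed.  Trees with an empty OOB set are skipped with a warning.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = _check_genotypes(X)
    y = np.asarray(y, dtype=np.int64)
    scores = np.zeros(forest.variable_count)
    n_used = 0
    col = np.empty(1, dtype=np.int64)
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
        present = np.unique(tree.split_var[tree.split_var >= 0])
        for var in present:
            perm = rng.permutation(rows.size)
            col[0] = var
            vals = X[rows, var][perm].astype(np.int64)[None, :]
            pred = predict_rows_kernel(
                tree.split_var, tree.threshold, tree.left, tree.right,
                tree.leaf_class, X, rows, col, vals,
            )
            scores[var] += base - np.mean(pred == y_oob)
    if n_used == 0:
        raise ValueError("no tree has a non-empty OOB set")
    return ImportanceVector(scores=scores / n_used, measure="permutation")
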