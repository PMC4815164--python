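"""Classification random forest with full structural access.

Bagged CART with Gini splitting, per-node candidate sampling (mtry), trees
grown to purity, and explicit out-of-bag bookkeeping.  Unlike off-the-shelf
forests, every tree exposes its complete split structure (variables,
thresholds, class counts, impurity decreases, parent/depth links), which the
importance modules need for Gini sums, OOB permutation accuracy, maximal
subtrees and noise-up traversal.

Genotypes are treated as ordered numeric dosages, so the only candidate
thresholds are 0.5 and 1.5.  Zero-gain splits are permitted at impure nodes;
without them, pure-interaction (XOR-like) structure could never be split at
the top of a tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import (
    LEAF,
    grow_tree_kernel,
    noise_up_predict_kernel,
    predict_rows_kernel,
)

__all__ = [
    "TreeNode",
    "Tree",
    "Forest",
    "gini_decrease",
    "best_split",
    "grow_tree",
    "grow_forest",
    "predict",
    "oob_accuracy",
    "forest_to_json",
    "forest_from_json",
]

_EMPTY_COLS = np.empty(0, dtype=np.int64)
_EMPTY_VALS = np.empty((0, 0), dtype=np.int64)


@dataclass
class TreeNode:
    """Recursive view of one node; built on demand from the flat arrays."""

    split_variable: int | None
    split_threshold: float | None
    gini_decrease: float
    class_counts: tuple[int, int]
    depth: int
    leaf_class: int | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None


@dataclass
class Tree:
    """Flat-array tree representation (node ids in creation order)."""

    split_var: np.ndarray  # -1 at leaves
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    parent: np.ndarray
    depth: np.ndarray
    class_counts: np.ndarray  # (n_nodes, 2) = (controls, cases)
    gini_dec: np.ndarray
    leaf_class: np.ndarray  # -1 at internal nodes
    in_bag: np.ndarray  # bootstrap row indices (with multiplicity)
    oob: np.ndarray  # sorted out-of-bag row indices

    @property
    def n_nodes(self) -> int:
        return self.split_var.shape[0]

    @property
    def height(self) -> int:
        return int(self.depth.max())

    @property
    def root(self) -> TreeNode:
        return self._build_node(0)

    def _build_node(self, i: int) -> TreeNode:
        if self.split_var[i] == LEAF:
            return TreeNode(
                split_variable=None,
                split_threshold=None,
                gini_decrease=0.0,
                class_counts=(int(self.class_counts[i, 0]), int(self.class_counts[i, 1])),
                depth=int(self.depth[i]),
                leaf_class=int(self.leaf_class[i]),
            )
        return TreeNode(
            split_variable=int(self.split_var[i]),
            split_threshold=float(self.threshold[i]),
            gini_decrease=float(self.gini_dec[i]),
            class_counts=(int(self.class_counts[i, 0]), int(self.class_counts[i, 1])),
            depth=int(self.depth[i]),
            left=self._build_node(int(self.left[i])),
            right=self._build_node(int(self.right[i])),
        )

    def predict(self, X: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
        X = _check_genotypes(X)
        rows = np.arange(X.shape[0]) if rows is None else np.asarray(rows)
        return predict_rows_kernel(
            self.split_var, self.threshold, self.left, self.right,
            self.leaf_class, X, rows.astype(np.int64), _EMPTY_COLS, _EMPTY_VALS,
        )

    @classmethod
    def from_nested(
        cls,
        node: dict,
        in_bag: np.ndarray | None = None,
        oob: np.ndarray | None = None,
    ) -> "Tree":
        """Build a Tree from a nested node dict (fixtures, JSON round-trip).

        Node keys: ``split_variable`` (None for a leaf), ``split_threshold``,
        ``class_counts``, optional ``gini_decrease``, ``leaf_class``,
        ``left``/``right`` child dicts.
        """
        records: list[dict] = []

        def visit(nd: dict, parent: int, depth: int) -> int:
            i = len(records)
            records.append({
                "sv": LEAF if nd.get("split_variable") is None else int(nd["split_variable"]),
                "thr": float(nd.get("split_threshold") or 0.0),
                "parent": parent,
                "depth": depth,
                "c": tuple(nd.get("class_counts", (0, 0))),
                "g": float(nd.get("gini_decrease", 0.0)),
                "lc": nd.get("leaf_class", -1),
                "left": -1,
                "right": -1,
            })
            if nd.get("split_variable") is not None:
                records[i]["left"] = visit(nd["left"], i, depth + 1)
                records[i]["right"] = visit(nd["right"], i, depth + 1)
            return i

        visit(node, -1, 0)
        n = len(records)
        tree = cls(
            split_var=np.array([r["sv"] for r in records], dtype=np.int64),
            threshold=np.array([r["thr"] for r in records]),
            left=np.array([r["left"] for r in records], dtype=np.int64),
            right=np.array([r["right"] for r in records], dtype=np.int64),
            parent=np.array([r["parent"] for r in records], dtype=np.int64),
            depth=np.array([r["depth"] for r in records], dtype=np.int64),
            class_counts=np.array([r["c"] for r in records], dtype=np.int64),
            gini_dec=np.array([r["g"] for r in records]),
            leaf_class=np.array([-1 if r["lc"] is None else r["lc"] for r in records], dtype=np.int64),
            in_bag=np.empty(0, dtype=np.int64) if in_bag is None else np.asarray(in_bag, dtype=np.int64),
            oob=np.empty(0, dtype=np.int64) if oob is None else np.asarray(oob, dtype=np.int64),
        )
        return tree

    def to_nested(self) -> dict:
        def build(i: int) -> dict:
            leaf = self.split_var[i] == LEAF
            d: dict = {
                "split_variable": None if leaf else int(self.split_var[i]),
                "split_threshold": None if leaf else float(self.threshold[i]),
                "class_counts": [int(self.class_counts[i, 0]), int(self.class_counts[i, 1])],
                "gini_decrease": float(self.gini_dec[i]),
            }
            if leaf:
                d["leaf_class"] = int(self.leaf_class[i])
            else:
                d["left"] = build(int(self.left[i]))
                d["right"] = build(int(self.right[i]))
            return d

        return build(0)


@dataclass
class Forest:
    trees: list[Tree]
    mtry: int
    variable_count: int
    seed: int | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# splitting primitives (reference implementations; the growth kernel inlines
# the same logic)


def gini_decrease(parent_counts, left_counts, right_counts) -> float:
    """Count-weighted Gini impurity decrease n_p*G(p) - n_l*G(l) - n_r*G(r)."""
    p = np.asarray(parent_counts, dtype=float)
    l = np.asarray(left_counts, dtype=float)
    r = np.asarray(right_counts, dtype=float)
    if np.any(p < 0) or np.any(l < 0) or np.any(r < 0):
        raise ValueError("class counts must be non-negative")
    if not np.array_equal(l + r, p):
        raise ValueError("left and right counts must sum to the parent's")
    if l.sum() == 0 or r.sum() == 0:
        raise ValueError("both children must be non-empty")

    def g(c: np.ndarray) -> float:
        n = c.sum()
        return 1.0 - float((c / n) @ (c / n))

    dec = p.sum() * g(p) - l.sum() * g(l) - r.sum() * g(r)
    return max(dec, 0.0)


def best_split(
    X_node: np.ndarray, y_node: np.ndarray, candidates
) -> tuple[int, float, float] | None:
    """Best (variable, threshold, decrease) among the candidates, or None.

    Thresholds 0.5 and 1.5 are evaluated per candidate; zero-decrease splits
    are valid as long as both children are non-empty.  Ties break toward the
    smallest (variable index, threshold).
    """
    X_node = np.asarray(X_node)
    y_node = np.asarray(y_node)
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        raise ValueError("candidate set must be non-empty")
    parent = np.array([(y_node == 0).sum(), (y_node == 1).sum()])
    best: tuple[int, float, float] | None = None
    for var in np.sort(candidates):
        g = X_node[:, var]
        for thr in (0.5, 1.5):
            mask = g <= thr
            if mask.all() or not mask.any():
                continue
            lc = np.array([(y_node[mask] == 0).sum(), (y_node[mask] == 1).sum()])
            dec = gini_decrease(parent, lc, parent - lc)
            if best is None or dec > best[2]:
                best = (int(var), thr, dec)
    return best


# ---------------------------------------------------------------------------
# growth


def _check_genotypes(X: np.ndarray) -> np.ndarray:
    X = np.ascontiguousarray(X, dtype=np.int8)
    if not np.isin(X, (0, 1, 2)).all():
        raise ValueError("genotype values must be in {0, 1, 2}")
    return X


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int,
    rng: np.random.Generator | int,
    bootstrap: bool = True,
) -> Tree:
    """Grow one tree: bootstrap n rows with replacement (unless disabled),
    then recursively split with fresh mtry candidate draws per node until
    every leaf is pure or its covariate rows are identical."""
    X = _check_genotypes(X)
    y = np.ascontiguousarray(y, dtype=np.int8)
    if X.shape[0] == 0:
        raise ValueError("dataset must be non-empty")
    if not 1 <= mtry <= X.shape[1]:
        raise ValueError("mtry must lie in [1, n_variables]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = X.shape[0]
    if bootstrap:
        in_bag = rng.integers(0, n, size=n).astype(np.int64)
        oob = np.setdiff1d(np.arange(n, dtype=np.int64), in_bag)
    else:
        in_bag = np.arange(n, dtype=np.int64)
        oob = np.empty(0, dtype=np.int64)
    (sv, thr, left, right, parent, depth, c0, c1, gdec, leaf_class) = grow_tree_kernel(
        X, y, in_bag, mtry, _kernel_seed(rng)
    )
    return Tree(
        split_var=sv,
        threshold=thr,
        left=left,
        right=right,
        parent=parent,
        depth=depth,
        class_counts=np.stack([c0, c1], axis=1),
        gini_dec=gdec,
        leaf_class=leaf_class,
        in_bag=in_bag,
        oob=oob,
    )


def grow_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    mtry: int,
    rng: np.random.Generator | int | None = 0,
    bootstrap: bool = True,
) -> Forest:
    """Grow ``n_trees`` independent trees with independent bootstraps and
    candidate draws; per-tree OOB index sets are recorded."""
    X = _check_genotypes(X)
    if mtry > X.shape[1]:
        raise ValueError(f"mtry={mtry} exceeds variable count {X.shape[1]}")
    seed = rng if not isinstance(rng, np.random.Generator) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    trees = [grow_tree(X, y, mtry, rng, bootstrap=bootstrap) for _ in range(n_trees)]
    return Forest(trees=trees, mtry=mtry, variable_count=X.shape[1], seed=seed)


# ---------------------------------------------------------------------------
# prediction and OOB accuracy


def predict(
    forest_or_tree: Forest | Tree,
    X: np.ndarray,
    rng: np.random.Generator | int | None = 0,
    return_votes: bool = False,
):
    """Majority-vote class prediction (single tree: its leaf class).

    Forest vote ties are broken by a seeded coin flip.
    """
    X = _check_genotypes(X)
    if isinstance(forest_or_tree, Tree):
        return forest_or_tree.predict(X)
    votes = np.zeros((X.shape[0], 2), dtype=np.int64)
    for tree in forest_or_tree.trees:
        pred = tree.predict(X)
        votes[np.arange(X.shape[0]), pred] += 1
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = np.where(votes[:, 1] > votes[:, 0], 1, 0)
    ties = votes[:, 1] == votes[:, 0]
    if ties.any():
        out[ties] = rng.integers(0, 2, size=int(ties.sum()))
    return (out, votes) if return_votes else out


def oob_accuracy(
    tree: Tree,
    X: np.ndarray,
    y: np.ndarray,
    genotype_override: dict[int, np.ndarray] | None = None,
) -> float:
    """Fraction of this tree's OOB rows classified correctly.

    ``genotype_override`` maps a column index to replacement values aligned
    with the OOB rows (used for permutation importance).  Raises on an empty
    OOB set: such a tree contributes nothing to averages.
    """
    if tree.oob.size == 0:
        raise ValueError("tree has an empty OOB set")
    X = _check_genotypes(X)
    y = np.asarray(y)
    rows = tree.oob
    if genotype_override:
        cols = np.array(sorted(genotype_override), dtype=np.int64)
        vals = np.stack(
            [np.asarray(genotype_override[int(c)], dtype=np.int64) for c in cols]
        )
        if vals.shape[1] != rows.shape[0]:
            raise ValueError("override values must align with the OOB rows")
    else:
        cols, vals = _EMPTY_COLS, _EMPTY_VALS
    pred = predict_rows_kernel(
        tree.split_var, tree.threshold, tree.left, tree.right, tree.leaf_class,
        X, rows, cols, vals,
    )
    return float(np.mean(pred == y[rows]))


def noise_up_tree_predict(
    tree: Tree, X: np.ndarray, rows: np.ndarray, triggers: np.ndarray, seed: int
) -> np.ndarray:
    """Predictions with random descent below the listed variables' maximal
    subtrees (thin wrapper over the kernel; used by the pairwise module)."""
    X = _check_genotypes(X)
    return noise_up_predict_kernel(
        tree.split_var, tree.threshold, tree.left, tree.right, tree.leaf_class,
        X, np.asarray(rows, dtype=np.int64),
        np.asarray(triggers, dtype=np.int64), seed,
    )


# ---------------------------------------------------------------------------
# serialization


def forest_to_json(forest: Forest, path: str | Path | None = None) -> str:
    doc = {
        "mtry": forest.mtry,
        "variable_count": forest.variable_count,
        "seed": forest.seed,
        "trees": [
            {
                "root": t.to_nested(),
                "in_bag": t.in_bag.tolist(),
                "oob": t.oob.tolist(),
            }
            for t in forest.trees
        ],
    }
    text = json.dumps(doc)
    if path is not None:
        Path(path).write_text(text)
    return text


def forest_from_json(source: str | Path) -> Forest:
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        text = Path(source).read_text()
    else:
        text = source
    doc = json.loads(text)
    trees = [
        Tree.from_nested(
            t["root"],
            in_bag=np.asarray(t["in_bag"], dtype=np.int64),
            oob=np.asarray(t["oob"], dtype=np.int64),
        )
        for t in doc["trees"]
    ]
    return Forest(
        trees=trees,
        mtry=doc["mtry"],
        variable_count=doc["variable_count"],
        seed=doc.get("seed"),
    )
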