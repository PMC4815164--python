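"""Forest core: splitting, growth to purity, OOB bookkeeping, serialization."""

import math

import numpy as np
import pytest

import epiforest as ef
from epiforest.forest import Tree, best_split, gini_decrease

from conftest import assert_greedy_cart, small_dataset


class TestGiniDecrease:
    def test_hand_values(self):
        assert gini_decrease((5, 5), (5, 0), (0, 5)) == pytest.approx(5.0)
        assert gini_decrease((4, 0), (2, 0), (2, 0)) == pytest.approx(0.0)
        assert gini_decrease((2, 2), (1, 1), (1, 1)) == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            gini_decrease((4, 2), (4, 2), (0, 0))  # empty child
        with pytest.raises(ValueError):
            gini_decrease((4, 2), (3, 0), (0, 2))  # counts do not add up

    def test_nonnegative_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.integers(1, 20, 2)
            a = rng.integers(0, p[0] + 1)
            b = rng.integers(0, p[1] + 1)
            left = np.array([a, b])
            if left.sum() == 0 or (p - left).sum() == 0:
                continue
            assert gini_decrease(p, left, p - left) >= 0


class TestBestSplit:
    def test_separable(self):
        X = np.array([[0], [0], [2], [2]], dtype=np.int8)
        y = np.array([0, 0, 1, 1], dtype=np.int8)
        var, thr, dec = best_split(X, y, [0])
        assert (var, thr) == (0, 0.5) and dec == pytest.approx(2.0)

    def test_constant_candidates_return_none(self):
        X = np.ones((4, 2), dtype=np.int8)
        y = np.array([0, 1, 0, 1], dtype=np.int8)
        assert best_split(X, y, [0, 1]) is None

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            best_split(np.zeros((2, 1), dtype=np.int8), np.array([0, 1]), [])

    def test_matches_exhaustive_search(self):
        """Tie policy and maximization agree with a brute-force enumeration
        of every (variable, threshold) pair on tiny nodes."""
        for seed in range(50):
            X, y = small_dataset(seed, n=3, p=3)
            if len(set(y.tolist())) < 2:
                continue
            got = best_split(X, y, range(3))
            best = None
            for var in range(3):
                for thr in (0.5, 1.5):
                    mask = X[:, var] <= thr
                    if mask.all() or not mask.any():
                        continue
                    parent = np.array([(y == 0).sum(), (y == 1).sum()])
                    lc = np.array([(y[mask] == 0).sum(), (y[mask] == 1).sum()])
                    dec = gini_decrease(parent, lc, parent - lc)
                    if best is None or dec > best[2]:
                        best = (var, thr, dec)
            assert got == best


class TestGrowTree:
    def test_pure_input_is_leaf(self):
        X = np.zeros((6, 3), dtype=np.int8)
        y = np.zeros(6, dtype=np.int8)
        t = ef.grow_tree(X, y, mtry=3, rng=0)
        assert t.n_nodes == 1 and t.root.is_leaf and t.root.leaf_class == 0

    def test_mtry_one_forced_candidate(self):
        X, y = small_dataset(3, n=40, p=5)
        t = ef.grow_tree(X, y, mtry=1, rng=0)
        assert (t.split_var[t.split_var >= 0] < 5).all()

    def test_determinism(self):
        X, y = small_dataset(4, n=60, p=8)
        t1 = ef.grow_tree(X, y, mtry=3, rng=7)
        t2 = ef.grow_tree(X, y, mtry=3, rng=7)
        for f in ("split_var", "threshold", "left", "right", "in_bag", "leaf_class"):
            assert np.array_equal(getattr(t1, f), getattr(t2, f))

    def test_grown_to_purity_unless_duplicate_rows(self):
        for seed in range(10):
            X, y = small_dataset(seed + 100, n=80, p=6)
            t = ef.grow_tree(X, y, mtry=2, rng=seed)
            order = np.argsort(t.depth, kind="stable")
            # walk leaves: impure leaves must have identical in-bag rows
            impure = np.flatnonzero(
                (t.split_var < 0) & (t.class_counts.min(axis=1) > 0)
            )
            for leaf in impure:
                rows = _leaf_rows(t, X, leaf)
                assert len({tuple(r) for r in rows}) == 1

    def test_structural_audit(self):
        """Child class counts sum to the parent's, depths increment, and the
        stored Gini decrease is reproducible from the stored counts."""
        X, y = small_dataset(5, n=120, p=10)
        t = ef.grow_tree(X, y, mtry=4, rng=1)
        for i in range(t.n_nodes):
            if t.split_var[i] < 0:
                continue
            l, r = t.left[i], t.right[i]
            assert (t.class_counts[i] == t.class_counts[l] + t.class_counts[r]).all()
            assert t.depth[l] == t.depth[i] + 1 and t.depth[r] == t.depth[i] + 1
            rec = gini_decrease(t.class_counts[i], t.class_counts[l], t.class_counts[r])
            assert rec == pytest.approx(t.gini_dec[i], rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_brute_force_greedy_cart(self, seed):
        """With all variables as candidates and no bootstrap, every split is
        a global maximizer found by exhaustive greedy search (tie choices
        among equal maximizers follow the seeded candidate order)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        p = int(rng.integers(1, 4))
        X, y = small_dataset(seed * 13 + 1, n=n, p=p)
        t = ef.grow_tree(X, y, mtry=p, rng=seed, bootstrap=False)
        assert_greedy_cart(t, X, y)


def _leaf_rows(t, X, leaf):
    """Collect the in-bag covariate rows routed to a leaf."""
    rows = []
    for i in t.in_bag:
        node = 0
        while t.split_var[node] >= 0:
            node = (
                t.left[node]
                if X[i, t.split_var[node]] <= t.threshold[node]
                else t.right[node]
            )
        if node == leaf:
            rows.append(X[i])
    return rows


class TestXorFixture:
    def test_single_tree_perfect_training_fit(self, xor_dataset):
        """A checkerboard with no marginal signal needs a zero-gain first
        split; the two subsequent splits then separate the classes."""
        X, y = xor_dataset
        t = ef.grow_tree(X, y, mtry=2, rng=0, bootstrap=False)
        assert np.array_equal(t.predict(X), y)
        assert t.gini_dec[0] == pytest.approx(0.0, abs=1e-9)

    def test_forest_oob_accuracy(self, xor_dataset):
        X, y = xor_dataset
        f = ef.grow_forest(X, y, n_trees=100, mtry=2, rng=1)
        accs = [ef.oob_accuracy(t, X, y) for t in f.trees if t.oob.size]
        assert float(np.mean(accs)) >= 0.9


class TestGrowForest:
    def test_single_tree_and_errors(self):
        X, y = small_dataset(6, n=30, p=4)
        f = ef.grow_forest(X, y, n_trees=1, mtry=2, rng=0)
        assert f.n_trees == 1
        with pytest.raises(ValueError):
            ef.grow_forest(X, y, n_trees=2, mtry=5, rng=0)

    def test_determinism(self):
        X, y = small_dataset(7, n=50, p=6)
        f1 = ef.grow_forest(X, y, n_trees=5, mtry=2, rng=3)
        f2 = ef.grow_forest(X, y, n_trees=5, mtry=2, rng=3)
        for t1, t2 in zip(f1.trees, f2.trees):
            assert np.array_equal(t1.split_var, t2.split_var)
            assert np.array_equal(t1.in_bag, t2.in_bag)

    def test_oob_fraction_matches_bootstrap_exclusion(self):
        """Per-tree OOB fraction is (1 - 1/n)^n on average."""
        n = 1000
        rng = np.random.default_rng(8)
        X = rng.integers(0, 3, size=(n, 5)).astype(np.int8)
        y = rng.integers(0, 2, size=n).astype(np.int8)
        f = ef.grow_forest(X, y, n_trees=500, mtry=2, rng=2)
        frac = np.array([t.oob.size / n for t in f.trees])
        q = (1 - 1 / n) ** n
        se = math.sqrt(q * (1 - q) / n) / math.sqrt(500)
        assert abs(frac.mean() - q) < 3 * se


class TestPredict:
    def test_value_range_checked(self):
        X, y = small_dataset(9, n=20, p=3)
        f = ef.grow_forest(X, y, n_trees=3, mtry=2, rng=0)
        with pytest.raises(ValueError):
            ef.predict(f, np.full((2, 3), 3, dtype=np.int8))

    def test_in_bag_training_accuracy_is_one(self):
        """Grown to purity: in-bag rows are classified perfectly whenever no
        duplicated covariate rows carry conflicting labels."""
        rng = np.random.default_rng(10)
        X = rng.integers(0, 3, size=(100, 12)).astype(np.int8)
        y = rng.integers(0, 2, size=100).astype(np.int8)
        # 12 ternary SNPs on 100 rows: duplicated rows are unlikely
        assert len({tuple(r) for r in X}) == 100
        t = ef.grow_tree(X, y, mtry=12, rng=0)
        assert np.array_equal(t.predict(X, rows=t.in_bag), y[t.in_bag])

    def test_single_leaf_tree_constant(self):
        t = Tree.from_nested(
            {"split_variable": None, "class_counts": (3, 0), "leaf_class": 0}
        )
        assert (t.predict(np.zeros((4, 2), dtype=np.int8)) == 0).all()

    def test_forest_majority_vote(self):
        X, y = small_dataset(11, n=60, p=5)
        f = ef.grow_forest(X, y, n_trees=15, mtry=2, rng=4)
        pred, votes = ef.predict(f, X, return_votes=True)
        assert votes.sum(axis=1).max() == 15
        strict = votes[:, 1] != votes[:, 0]
        assert np.array_equal(pred[strict], (votes[strict, 1] > votes[strict, 0]))


def _hand_tree():
    """3-node tree: split on variable 0 at 0.5; left leaf class 0, right 1."""
    return Tree.from_nested(
        {
            "split_variable": 0,
            "split_threshold": 0.5,
            "class_counts": (3, 3),
            "gini_decrease": 3.0,
            "left": {"split_variable": None, "class_counts": (3, 0), "leaf_class": 0},
            "right": {"split_variable": None, "class_counts": (0, 3), "leaf_class": 1},
        },
        in_bag=np.arange(5, 10),
        oob=np.arange(5),
    )


class TestOobAccuracy:
    def setup_method(self):
        self.X = np.array(
            [[0, 1], [2, 0], [0, 2], [1, 1], [2, 2]] + [[0, 0]] * 5, dtype=np.int8
        )
        self.y = np.array([0, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=np.int8)
        self.tree = _hand_tree()

    def test_hand_count(self):
        # OOB rows 0..4: genotypes at var0 = (0,2,0,1,2) -> pred (0,1,0,1,1)
        # truth (0,1,1,1,1): 4/5 correct
        assert ef.oob_accuracy(self.tree, self.X, self.y) == pytest.approx(0.8)

    def test_identity_override_unchanged(self):
        base = ef.oob_accuracy(self.tree, self.X, self.y)
        same = ef.oob_accuracy(
            self.tree, self.X, self.y, genotype_override={0: self.X[:5, 0]}
        )
        assert same == base

    def test_designated_override_hand_value(self):
        # force var0 values (2,2,2,2,0): pred (1,1,1,1,0) vs truth (0,1,1,1,1)
        acc = ef.oob_accuracy(
            self.tree, self.X, self.y,
            genotype_override={0: np.array([2, 2, 2, 2, 0])},
        )
        assert acc == pytest.approx(0.6)

    def test_absent_variable_exactly_unchanged(self):
        base = ef.oob_accuracy(self.tree, self.X, self.y)
        permuted = ef.oob_accuracy(
            self.tree, self.X, self.y,
            genotype_override={1: self.X[:5, 1][::-1]},
        )
        assert permuted == base

    def test_empty_oob_flagged(self):
        t = _hand_tree()
        t.oob = np.empty(0, dtype=np.int64)
        with pytest.raises(ValueError):
            ef.oob_accuracy(t, self.X, self.y)


class TestSerialization:
    def test_json_round_trip(self):
        X, y = small_dataset(12, n=40, p=6)
        f = ef.grow_forest(X, y, n_trees=4, mtry=3, rng=5)
        text = ef.forest_to_json(f)
        back = ef.forest_from_json(text)
        assert back.n_trees == 4 and back.variable_count == 6
        assert np.array_equal(ef.predict(back, X, rng=0), ef.predict(f, X, rng=0))
        gi1 = ef.gini_importance(f).scores
        gi2 = ef.gini_importance(back).scores
        assert np.allclose(gi1, gi2)

    def test_file_round_trip(self, tmp_path):
        X, y = small_dataset(13, n=30, p=4)
        f = ef.grow_forest(X, y, n_trees=2, mtry=2, rng=6)
        path = tmp_path / "forest.json"
        ef.forest_to_json(f, path)
        back = ef.forest_from_json(path)
        assert np.array_equal(back.trees[0].oob, f.trees[0].oob)
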