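"""Split search, growth, routing, importance and serialization."""

import numpy as np
import pandas as pd
import pytest

from rpdtree import (
    ContractError,
    Hyperparams,
    best_split_subset,
    best_split_threshold,
    export_tree,
    grow_tree,
    import_tree,
    predict,
    predict_frame,
    route,
    variable_importance,
)
from tests.conftest import brute_force_best_delta, node_membership, random_mixed_dataset


class TestBestSplitThreshold:
    def test_clean_step(self):
        res = best_split_threshold([1, 2, 3, 4], [0, 0, 10, 10])
        assert res is not None
        thr, delta = res
        assert thr == pytest.approx(2.5)
        assert delta == pytest.approx(100.0)

    def test_constant_y_no_split(self):
        assert best_split_threshold([1, 2, 3, 4], [5, 5, 5, 5]) is None

    def test_minleafsize_restricts_to_middle_cut(self):
        # y strictly increasing; only the 2|2 cut is admissible
        res = best_split_threshold([1, 2, 3, 4], [1, 2, 3, 4], minleafsize=2)
        thr, _ = res
        assert thr == pytest.approx(2.5)

    def test_identical_values_no_split(self):
        assert best_split_threshold([3, 3, 3], [1, 2, 3]) is None

    def test_missing_excluded(self):
        res = best_split_threshold([1, 2, np.nan, 3, 4], [0, 0, 99, 10, 10])
        thr, delta = res
        assert thr == pytest.approx(2.5)
        assert delta == pytest.approx(100.0)

    def test_matches_brute_force_on_random_columns(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.normal(size=n)
            res = best_split_threshold(x, y, minleafsize=2)
            best, _ = brute_force_best_delta(pd.DataFrame({"x": x}), y, minleafsize=2)
            if res is None:
                assert best is None
            else:
                assert res[1] == pytest.approx(best, rel=1e-9)


class TestBestSplitSubset:
    def test_mean_ordering_groups(self):
        cats = ["A", "B", "C", "A", "B", "C"]
        y = [0, 0, 10, 0, 0, 10]
        left, delta = best_split_subset(cats, y)
        assert left == ("A", "B")
        ref, _ = brute_force_best_delta(pd.DataFrame({"g": cats}), np.array(y, float))
        assert delta == pytest.approx(ref, rel=1e-12)

    def test_exchangeable_categories_no_split(self):
        assert best_split_subset(["A", "B", "A", "B"], [1.0, 1.0, 1.0, 1.0]) is None

    def test_two_categories_forced(self):
        left, _ = best_split_subset(["A", "B", "A", "B"], [0, 5, 0, 5])
        assert left == ("A",)

    def test_single_category_none(self):
        assert best_split_subset(["A", "A", "A"], [1, 2, 3]) is None

    def test_agrees_with_exhaustive_subsets(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = int(rng.integers(8, 40))
            k = int(rng.integers(2, 7))
            cats = rng.choice([f"c{i}" for i in range(k)], size=n)
            y = rng.normal(size=n) + 2.0 * np.isin(cats, ["c0", "c2"])
            res = best_split_subset(cats, y, minleafsize=1)
            ref, _ = brute_force_best_delta(pd.DataFrame({"g": cats}), y)
            if res is None:
                assert ref is None
            else:
                assert res[1] == pytest.approx(ref, rel=1e-9)


class TestGrowTree:
    def test_constant_y_single_leaf(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        tree = grow_tree(X, [4.0, 4.0, 4.0])
        assert tree.root.is_leaf
        assert variable_importance(tree).empty

    def test_maxdepth_one_is_stump(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = (X["x"] > 0).astype(float) + rng.normal(scale=0.1, size=50)
        tree = grow_tree(X, y, Hyperparams(maxdepth=1))
        assert len(tree.leaves()) == 2
        assert tree.depth == 1

    def test_planted_interaction_structure(self):
        rng = np.random.default_rng(1)
        n = 1000
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = 2.0 * (X["x1"] > 0) + 1.0 * (X["x2"] > 0) + rng.normal(scale=0.2, size=n)
        tree = grow_tree(X, y, Hyperparams(maxdepth=3, minleafsize=20))
        assert tree.root.rule.variable == "x1"  # larger effect wins the root
        assert {"x1", "x2"} <= set(tree.split_variables())

    def test_node_bookkeeping(self):
        df, y = random_mixed_dataset(np.random.default_rng(3), n=60)
        tree = grow_tree(df, y, Hyperparams(maxdepth=4, minleafsize=3))
        for nd in tree.root.walk():
            if not nd.is_leaf:
                assert nd.n == nd.left.n + nd.right.n
                assert nd.sse + 1e-9 >= nd.left.sse + nd.right.sse

    def test_determinism(self):
        df, y = random_mixed_dataset(np.random.default_rng(8), n=80)
        t1 = grow_tree(df, y, Hyperparams(maxdepth=4, minleafsize=2))
        t2 = grow_tree(df.copy(), y.copy(), Hyperparams(maxdepth=4, minleafsize=2))
        assert export_tree(t1) == export_tree(t2)

    def test_monotone_transform_preserves_partition(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        y = np.sin(X["x"].to_numpy()) + rng.normal(scale=0.2, size=100)
        t1 = grow_tree(X, y, Hyperparams(maxdepth=3, minleafsize=5))
        t2 = grow_tree(np.exp(X), y, Hyperparams(maxdepth=3, minleafsize=5))
        m1 = node_membership(t1, X)
        m2 = node_membership(t2, np.exp(X))
        leaves1 = sorted(tuple(m1[nd.id]) for nd in t1.leaves())
        leaves2 = sorted(tuple(m2[nd.id]) for nd in t2.leaves())
        assert leaves1 == leaves2

    def test_empty_or_missing_y_rejected(self):
        with pytest.raises(ContractError):
            grow_tree(pd.DataFrame({"x": []}), [])
        with pytest.raises(ContractError):
            grow_tree(pd.DataFrame({"x": [1.0, 2.0]}), [1.0, np.nan])

    def test_matches_sklearn_on_complete_numeric_data(self):
        # independent cross-check: same criterion, same stopping rules
        sklearn = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(17)
        for seed in range(3):
            r = np.random.default_rng(seed)
            n = 200
            X = pd.DataFrame({f"x{j}": r.normal(size=n) for j in range(4)})
            y = X["x0"].to_numpy() + 0.5 * (X["x1"] > 0.3) + r.normal(scale=0.3, size=n)
            ours = grow_tree(X, y, Hyperparams(maxdepth=3, minleafsize=5, minvariance=0.0))
            ref = sklearn.DecisionTreeRegressor(
                max_depth=3, min_samples_leaf=5, random_state=0
            ).fit(X, y)
            ase_ours = float(((predict_frame(ours, X) - y) ** 2).mean())
            ase_ref = float(((ref.predict(X) - y) ** 2).mean())
            assert ase_ours == pytest.approx(ase_ref, rel=1e-9)


class TestOracleEquivalence:
    def test_every_node_split_matches_exhaustive_search(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            df, y = random_mixed_dataset(rng, n=int(rng.integers(15, 50)))
            hp = Hyperparams(maxdepth=3, minleafsize=2)
            tree = grow_tree(df, y, hp)
            members = node_membership(tree, df)
            for nd in tree.root.walk():
                if nd.is_leaf:
                    continue
                idx = members[nd.id]
                best, winners = brute_force_best_delta(
                    df.iloc[idx], y[idx], minleafsize=hp.minleafsize
                )
                assert best is not None
                assert nd.rule.sse_reduction == pytest.approx(best, rel=1e-8)
                if len(winners) == 1:
                    assert nd.rule.variable in winners


class TestRouting:
    @staticmethod
    def _tree_with_surrogate():
        # x2 copies x1's split side for most rows -> strong surrogate
        rng = np.random.default_rng(6)
        n = 200
        x1 = rng.normal(size=n)
        x2 = np.where(x1 < 0, -1.0, 1.0)
        flip = rng.random(n) < 0.05
        x2[flip] *= -1
        x1[rng.random(n) < 0.15] = np.nan  # make the node compute surrogates
        X = pd.DataFrame({"x1": x1, "x2": x2})
        y = np.where(np.nan_to_num(x1, nan=x2) < 0, 0.0, 4.0) + rng.normal(scale=0.2, size=n)
        return grow_tree(X, y, Hyperparams(maxdepth=1))

    def test_primary_observed_decides(self):
        tree = self._tree_with_surrogate()
        rule = tree.root.rule
        assert rule.variable == "x1"
        assert route({"x1": rule.threshold - 1, "x2": 99.0}, tree.root) == "left"

    def test_surrogate_decides_when_primary_missing(self):
        tree = self._tree_with_surrogate()
        assert tree.root.rule.surrogates, "expected a surrogate on x2"
        sr = tree.root.rule.surrogates[0]
        assert sr.variable == "x2"
        assert sr.agreement > 0.9
        assert route({"x1": np.nan, "x2": -1.0}, tree.root) == "left"
        assert route({"x1": np.nan, "x2": 1.0}, tree.root) == "right"

    def test_majority_branch_fallback(self):
        tree = self._tree_with_surrogate()
        side = route({"x1": np.nan, "x2": None}, tree.root)
        assert side == tree.root.rule.majority_branch

    def test_prediction_set_is_leaf_means(self):
        df, y = random_mixed_dataset(np.random.default_rng(9), n=80)
        tree = grow_tree(df, y, Hyperparams(maxdepth=3, minleafsize=4))
        preds = set(np.round(predict_frame(tree, df), 12))
        leaf_means = {round(nd.mean, 12) for nd in tree.leaves()}
        assert preds <= leaf_means

    def test_single_leaf_predicts_global_mean(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        tree = grow_tree(X, [3.0, 5.0], Hyperparams(minvariance=100.0))
        assert predict(tree, {"x": 999.0}) == pytest.approx(4.0)


class TestImportance:
    def test_single_split_is_100(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = (X["x"] > 0).astype(float)
        tree = grow_tree(X, y, Hyperparams(maxdepth=1))
        imp = variable_importance(tree)
        assert list(imp["variable"]) == ["x"]
        assert imp["importance"].iloc[0] == pytest.approx(100.0)
        assert imp["count"].iloc[0] == 1

    def test_shares_sum_to_100_counts_match(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            df, y = random_mixed_dataset(rng, n=60)
            tree = grow_tree(df, y, Hyperparams(maxdepth=4, minleafsize=2))
            imp = variable_importance(tree)
            if imp.empty:
                continue
            assert imp["importance"].sum() == pytest.approx(100.0, abs=1e-9)
            recount = {}
            for nd in tree.root.walk():
                if not nd.is_leaf:
                    recount[nd.rule.variable] = recount.get(nd.rule.variable, 0) + 1
            assert dict(zip(imp["variable"], imp["count"])) == recount


class TestSerialization:
    def test_json_round_trip_byte_identical(self):
        df, y = random_mixed_dataset(np.random.default_rng(11), n=70)
        tree = grow_tree(df, y, Hyperparams(maxdepth=3, minleafsize=3))
        blob = export_tree(tree, "json")
        assert export_tree(import_tree(blob), "json") == blob

    def test_stump_has_three_nodes_every_format(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        tree = grow_tree(X, [0.0, 0.0, 1.0, 1.0], Hyperparams(maxdepth=1))
        import json

        assert len(json.loads(export_tree(tree, "json"))["nodes"]) == 3
        assert export_tree(tree, "dot").count("[label=") >= 3
        assert len(export_tree(tree, "text").strip().splitlines()) == 3

    def test_dot_is_structurally_valid(self):
        df, y = random_mixed_dataset(np.random.default_rng(13), n=50)
        tree = grow_tree(df, y, Hyperparams(maxdepth=3))
        dot = export_tree(tree, "dot")
        assert dot.startswith("digraph")
        import re

        skeleton = re.sub(r'"[^"]*"', '""', dot)  # braces inside labels are content
        assert skeleton.count("{") == skeleton.count("}") == 1
        n_internal = sum(1 for nd in tree.root.walk() if not nd.is_leaf)
        assert dot.count("->") == 2 * n_internal

    def test_unknown_format_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        tree = grow_tree(X, [0.0, 1.0])
        with pytest.raises(ContractError):
            export_tree(tree, "yaml")
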