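import numpy as np
import pandas as pd
import pytest

import octadme as od
from octadme.tree import (MissingPredictorError, TreeNode, UnspecifiedLeafError)


def _one_split_table(seed=0, n=100):
    rng = np.random.default_rng(seed)
    x = rng.uniform(200, 600, n)
    y = np.where(x >= 373, 65.0, 78.0)
    return pd.DataFrame({"cmt_baseline": x, "bcva_final": y})


class TestFit:
    def test_recovers_single_split_rule_exactly(self):
        table = _one_split_table()
        tree = od.fit_regression_tree(table, predictors=("cmt_baseline",),
                                      max_depth=2, min_leaf_n=2)
        root = tree.root
        assert root.split_var == "cmt_baseline"
        below = table.cmt_baseline[table.cmt_baseline < 373].max()
        above = table.cmt_baseline[table.cmt_baseline >= 373].min()
        assert root.threshold == pytest.approx((below + above) / 2)
        assert od.r_squared(tree, table) == 1.0
        assert sorted(l.value for l in root.leaves()) == [65.0, 78.0]

    def test_constant_outcome_single_leaf_with_warning(self):
        table = pd.DataFrame({"cmt_baseline": [1.0, 2, 3, 4, 5, 6],
                              "bcva_final": [70.0] * 6})
        with pytest.warns(UserWarning, match="constant outcome"):
            tree = od.fit_regression_tree(table, predictors=("cmt_baseline",),
                                          min_leaf_n=2)
        assert tree.root.is_leaf
        assert tree.root.value == 70.0

    def test_too_few_rows_raises(self):
        table = _one_split_table(n=5)
        with pytest.raises(ValueError, match="too few rows"):
            od.fit_regression_tree(table, predictors=("cmt_baseline",),
                                   min_leaf_n=5)

    def test_zero_noise_cohort_routes_like_published_structure(self):
        params = od.CohortSimParams(n_eyes=2000, outcome_noise_sd=0.0, rng_seed=4)
        table = od.generate_cohort(params)
        tree, r2 = od.select_best_tree(table)
        assert r2 == pytest.approx(1.0)
        preds = tree.predict_table(table)
        expected = np.array([params.leaf_values[b] for b in table.true_branch])
        assert np.array_equal(preds, expected)

    def test_weighted_mean_invariant_holds_on_every_node(self):
        params = od.CohortSimParams(n_eyes=400, outcome_noise_sd=5.0, rng_seed=8)
        tree, _ = od.select_best_tree(od.generate_cohort(params))

        def check(node):
            if node.is_leaf:
                return
            lo, hi = node.low, node.high
            assert node.n == lo.n + hi.n
            weighted = (lo.value * lo.n + hi.value * hi.n) / node.n
            assert node.value == pytest.approx(weighted, abs=1e-9)
            check(lo)
            check(hi)

        check(tree.root)

    def test_matches_sklearn_greedy_cart(self):
        sklearn = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(5)
        n = 300
        table = pd.DataFrame({
            "a": rng.normal(size=n), "b": rng.normal(size=n),
            "c": rng.normal(size=n),
        })
        table["bcva_final"] = 2 * table.a + np.sin(3 * table.b) + rng.normal(0, 0.5, n)
        mine = od.fit_regression_tree(table, predictors=("a", "b", "c"),
                                      max_depth=3, min_leaf_n=5)
        ref = sklearn.DecisionTreeRegressor(max_depth=3, min_samples_leaf=5,
                                            random_state=0)
        ref.fit(table[["a", "b", "c"]], table.bcva_final)
        assert np.allclose(mine.predict_table(table),
                           ref.predict(table[["a", "b", "c"]]))


class TestRSquared:
    def test_perfect_fit_is_one(self):
        table = _one_split_table(seed=1)
        tree = od.fit_regression_tree(table, predictors=("cmt_baseline",),
                                      max_depth=1, min_leaf_n=2)
        assert od.r_squared(tree, table) == 1.0

    def test_single_leaf_is_zero(self):
        table = pd.DataFrame({"bcva_final": [60.0, 70, 80, 90]})
        tree = od.RegressionTree(root=TreeNode(value=75.0, n=4))
        assert od.r_squared(tree, table) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # y = [60,70,80,90], yhat = [65,65,85,85]: 1 - 100/500 = 0.8
        table = pd.DataFrame({"x": [0.0, 0, 1, 1],
                              "bcva_final": [60.0, 70, 80, 90]})
        root = TreeNode(split_var="x", threshold=0.5, value=75.0, n=4,
                        low=TreeNode(value=65.0, n=2),
                        high=TreeNode(value=85.0, n=2))
        tree = od.RegressionTree(root=root, predictors=("x",))
        assert od.r_squared(tree, table) == pytest.approx(0.8)

    def test_constant_outcome_undefined(self):
        table = pd.DataFrame({"bcva_final": [70.0, 70.0]})
        tree = od.RegressionTree(root=TreeNode(value=70.0, n=2))
        with pytest.raises(ValueError, match="zero variance"):
            od.r_squared(tree, table)


class TestSelectBestTree:
    def test_noiseless_two_split_data_selects_minimal_tree(self):
        params = od.CohortSimParams(n_eyes=600, outcome_noise_sd=0.0,
                                    vma_prevalence=0.0, rng_seed=6)
        table = od.generate_cohort(params)
        tree, r2 = od.select_best_tree(table)
        assert r2 == pytest.approx(1.0)
        assert tree.root.n_leaves() == 3  # CMT split then LAC split

    def test_single_point_grid_equals_plain_fit(self):
        table = od.generate_cohort(
            od.CohortSimParams(n_eyes=300, outcome_noise_sd=4.0, rng_seed=9))
        cfg = od.TreeFitConfig(max_depth_grid=(3,), min_leaf_n_grid=(5,))
        selected, _ = od.select_best_tree(table, cfg)
        plain = od.fit_regression_tree(table, max_depth=3, min_leaf_n=5)
        assert np.array_equal(selected.predict_table(table),
                              plain.predict_table(table))

    def test_training_r2_non_decreasing_in_depth_grid(self):
        table = od.generate_cohort(
            od.CohortSimParams(n_eyes=400, outcome_noise_sd=6.0, rng_seed=10))
        r2s = []
        for max_depth in (1, 2, 3, 4):
            cfg = od.TreeFitConfig(max_depth_grid=tuple(range(1, max_depth + 1)),
                                   min_leaf_n_grid=(5,))
            _, r2 = od.select_best_tree(table, cfg)
            r2s.append(r2)
        assert all(a <= b + 1e-12 for a, b in zip(r2s, r2s[1:]))


class TestPublishedTree:
    def test_printed_leaf_values(self):
        tree = od.published_tree()
        assert od.predict(tree, {"vma": 0, "cmt_baseline": 400, "lac_dcp": 0.50}) == 65
        assert od.predict(tree, {"vma": 0, "cmt_baseline": 400, "lac_dcp": 0.30}) == 73

    def test_boundaries_route_high(self):
        tree = od.published_tree()
        assert od.predict(tree, {"vma": 0, "cmt_baseline": 373.0,
                                 "lac_dcp": 0.41}) == 65

    def test_thick_cmt_node_is_weighted_leaf_mean(self):
        node = od.published_tree().root.low.high
        assert node.value == 71.0 and node.n == 36
        assert (node.low.value * node.low.n + node.high.value * node.high.n) / node.n \
            == pytest.approx((26 * 73 + 10 * 65) / 36)

    def test_unprinted_leaf_raises_without_override(self):
        tree = od.published_tree()
        with pytest.raises(UnspecifiedLeafError):
            od.predict(tree, {"vma": 0, "cmt_baseline": 372.9, "lac_dcp": 0.3})
        with pytest.raises(UnspecifiedLeafError):
            od.predict(tree, {"vma": 1, "cmt_baseline": 400, "lac_dcp": 0.3})

    def test_leaf_overrides(self):
        tree = od.published_tree({"vma_present": 60.0, "cmt_low": 78.0})
        assert od.predict(tree, {"vma": 1, "cmt_baseline": 400, "lac_dcp": 0.3}) == 60
        assert od.predict(tree, {"vma": 0, "cmt_baseline": 300, "lac_dcp": 0.3}) == 78

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError):
            od.published_tree({"bogus": 1.0})


class TestPredict:
    def test_single_leaf_always_returns_value(self):
        tree = od.RegressionTree(root=TreeNode(value=70.0, n=1))
        assert od.predict(tree, {}) == 70.0

    def test_missing_variable_named_in_error(self):
        tree = od.published_tree()
        with pytest.raises(MissingPredictorError, match="lac_dcp"):
            od.predict(tree, {"vma": 0, "cmt_baseline": 400})

    def test_pure_function(self):
        tree = od.published_tree()
        rec = {"vma": 0, "cmt_baseline": 450, "lac_dcp": 0.6}
        assert od.predict(tree, rec) == od.predict(tree, rec)

    def test_serialization_round_trip_preserves_predictions(self, tmp_path):
        params = od.CohortSimParams(n_eyes=100, outcome_noise_sd=4.0, rng_seed=12)
        table = od.generate_cohort(params)
        tree, _ = od.select_best_tree(table)
        path = tmp_path / "tree.json"
        od.save_tree(tree, path)
        back = od.load_tree(path)
        assert np.array_equal(tree.predict_table(table), back.predict_table(table))
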