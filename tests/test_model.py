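"""The regression tree, the stratified split, CV tuning and importances."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from conftest import make_table
from reference_impls import oracle_cart, oracle_signature, oracle_training_mse
from wat2barthel import model as md


class TestStratifiedSplit:
    def test_largest_remainder_arithmetic(self):
        table = make_table({"none": 52, "cane_or_walker": 23, "wheelchair": 15})
        train, valid = md.stratified_split(table, md.SplitSpec(seed=0))
        assert len(train) == 63 and len(valid) == 27
        by_group = train.groupby("aid_group").size()
        assert by_group["none"] == 36
        assert by_group["cane_or_walker"] == 16
        assert by_group["wheelchair"] == 11

    def test_partition_properties(self):
        table = make_table({"none": 31, "cane_or_walker": 14, "wheelchair": 9}, seed=4)
        train, valid = md.stratified_split(table, md.SplitSpec(seed=5))
        ids = pd.concat([train, valid])["patient_id"]
        assert sorted(ids) == sorted(table["patient_id"])
        assert set(train["patient_id"]).isdisjoint(valid["patient_id"])

    def test_same_seed_identical_partitions(self):
        table = make_table({"none": 20, "wheelchair": 10})
        a = md.stratified_split(table, md.SplitSpec(seed=3))
        b = md.stratified_split(table, md.SplitSpec(seed=3))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_tiny_group_goes_to_train_with_warning(self):
        table = make_table({"none": 10, "wheelchair": 1})
        with pytest.warns(UserWarning, match="wheelchair"):
            train, valid = md.stratified_split(table, md.SplitSpec(seed=0))
        assert (train["aid_group"] == "wheelchair").sum() == 1
        assert (valid["aid_group"] == "wheelchair").sum() == 0

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            md.SplitSpec(train_fraction=1.0)


class TestFitTree:
    def test_constant_targets_single_leaf(self):
        X = np.arange(6.0).reshape(-1, 1)
        y = np.full(6, 42.0)
        m = md.fit_tree((X, y))
        assert m.root.is_leaf
        assert m.predict([[99.0]]) == pytest.approx([42.0])

    def test_step_function_split_at_midpoint(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        y = np.array([0.0, 0, 0, 100, 100, 100])
        m = md.fit_tree((X, y))
        assert m.root.threshold == pytest.approx(6.5)
        assert m.n_leaves == 2
        assert m.predict([[2.0]]) == pytest.approx([0.0])
        assert m.predict([[11.0]]) == pytest.approx([100.0])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            md.fit_tree((np.empty((0, 2)), np.empty(0)))

    def test_refuses_test_tagged_rows(self):
        table = make_table({"none": 6})
        table["role"] = "test"
        with pytest.raises(ValueError, match="role"):
            md.fit_tree(table)
        with pytest.raises(ValueError, match="role"):
            md.cross_validate(table, k=2)

    def test_min_samples_split_one_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            md.Hyperparams(min_samples_split=1).effective()

    def test_predictions_bounded_by_training_targets(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 4))
        y = rng.uniform(0, 100, 60)
        m = md.fit_tree((X, y))
        preds = m.predict(rng.normal(scale=10, size=(1000, 4)))
        assert preds.min() >= y.min() - 1e-9
        assert preds.max() <= y.max() + 1e-9

    def test_leaf_sample_counts_sum_to_n(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(37, 3))
        y = rng.normal(size=37)
        m = md.fit_tree((X, y), md.Hyperparams(min_samples_leaf=2))

        def leaves(node):
            return [node] if node.is_leaf else leaves(node.left) + leaves(node.right)

        lv = leaves(m.root)
        assert sum(n.n_samples for n in lv) == 37
        assert all(n.n_samples >= 2 for n in lv)

    def test_loss_non_increasing_in_depth(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        losses = [
            md.fit_tree((X, y), md.Hyperparams(max_depth=d)).training_mse()
            for d in range(1, 7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_huge_impurity_threshold_gives_single_leaf(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 2))
        y = rng.uniform(0, 100, 30)
        root_var = y.var()
        m = md.fit_tree((X, y), md.Hyperparams(min_impurity_decrease=root_var + 1))
        assert m.root.is_leaf

    def test_matches_exhaustive_oracle_small_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(2, 13))
            p = int(rng.integers(1, 4))
            X = np.round(rng.normal(size=(n, p)), 3)
            y = np.round(rng.uniform(0, 100, n), 2)
            hp = md.Hyperparams(
                min_impurity_decrease=float(rng.choice([0.0, 0.05, 1.0, 5.0])),
                min_samples_leaf=int(rng.integers(1, 4)),
                min_samples_split=int(rng.integers(2, 5)),
            )
            mine = md.fit_tree((X, y), hp)
            oracle = oracle_cart(
                X, y, hp.min_impurity_decrease, hp.min_samples_leaf, hp.min_samples_split
            )
            assert mine.structure_signature() == oracle_signature(oracle)
            assert mine.training_mse() == pytest.approx(oracle_training_mse(oracle, n))

    def test_matches_sklearn_on_random_tables(self):
        """Independent library cross-check (tie-free continuous features)."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            p = int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            msl = int(rng.integers(1, 4))
            mss = int(rng.integers(2, 6))
            mine = md.fit_tree((X, y), md.Hyperparams(min_samples_leaf=msl, min_samples_split=mss))
            sk = DecisionTreeRegressor(
                min_samples_leaf=msl, min_samples_split=mss, random_state=0
            ).fit(X, y)
            assert np.allclose(mine.predict(X), sk.predict(X), atol=1e-8)

    def test_missing_feature_rejected_at_predict(self):
        table = make_table({"none": 10})
        m = md.fit_tree(table)
        with pytest.raises(KeyError):
            m.predict_one({"morning_max": 1.0})
        with pytest.raises(KeyError):
            m.predict(table.drop(columns=["evening_max"]))

    def test_json_round_trip(self):
        table = make_table({"none": 15, "wheelchair": 5}, seed=2)
        m = md.fit_tree(table, md.Hyperparams(min_samples_leaf=2))
        back = md.RegressionTreeModel.from_json(m.to_json())
        assert back.structure_signature() == m.structure_signature()
        assert np.allclose(back.predict(table), m.predict(table))


class TestPruneEquivalence:
    def test_prune_equals_refit(self):
        """A higher impurity gate is exactly a pruning of the full fit."""
        rng = np.random.default_rng(14)
        X = rng.normal(size=(45, 3))
        y = rng.uniform(0, 100, 45)
        full = md.fit_tree((X, y))
        for mid in [0.0, 0.5, 2.0, 10.0, 50.0]:
            direct = md.fit_tree((X, y), md.Hyperparams(min_impurity_decrease=mid))
            pruned = md.prune_tree(full, mid)
            assert direct.structure_signature() == pruned.structure_signature()


class TestCrossValidate:
    def test_single_point_grid_returned(self, small_feature_table):
        grid = {
            "min_impurity_decrease": [0.3],
            "min_samples_leaf": [2],
            "min_samples_split": [4],
        }
        best, scores = md.cross_validate(small_feature_table, grid=grid, k=3)
        assert best.min_impurity_decrease == 0.3
        assert best.min_samples_leaf == 2
        assert best.min_samples_split == 4
        assert len(scores) == 1

    def test_too_many_folds_rejected(self, small_feature_table):
        with pytest.raises(ValueError):
            md.cross_validate(small_feature_table, k=len(small_feature_table) + 1)

    def test_grid_size_and_determinism(self):
        table = make_table({"none": 20, "cane_or_walker": 10}, seed=6)
        grid = {
            "min_impurity_decrease": [0.0, 0.5],
            "min_samples_leaf": [1, 2],
            "min_samples_split": [2, 3],
        }
        b1, s1 = md.cross_validate(table, grid=grid, k=3, seed=11)
        b2, s2 = md.cross_validate(table, grid=grid, k=3, seed=11)
        assert b1 == b2
        pd.testing.assert_frame_equal(s1, s2)
        assert len(s1) == 8

    def test_pruned_scoring_matches_direct_refits(self):
        """The pruning shortcut scores every candidate exactly as a naive
        refit-per-candidate loop would."""
        table = make_table({"none": 18, "wheelchair": 8}, seed=7)
        grid = {
            "min_impurity_decrease": [0.0, 1.0, 20.0],
            "min_samples_leaf": [1, 3],
            "min_samples_split": [2, 5],
        }
        k, seed = 3, 21
        _, scores = md.cross_validate(table, grid=grid, k=k, seed=seed)
        from wat2barthel.features import feature_matrix

        X, y, _ = feature_matrix(table)
        rng = np.random.default_rng(seed)
        folds = np.array_split(rng.permutation(len(y)), k)
        for _, row in scores.iterrows():
            hp = md.Hyperparams(
                min_impurity_decrease=row["min_impurity_decrease"],
                min_samples_leaf=int(row["min_samples_leaf"]),
                min_samples_split=int(row["min_samples_split"]),
            )
            total = 0.0
            for fold in folds:
                mask = np.ones(len(y), dtype=bool)
                mask[fold] = False
                m = md.fit_tree((X[mask], y[mask]), hp)
                total += -np.mean((y[fold] - m.predict(X[fold])) ** 2) / k
            assert row["mean_score"] == pytest.approx(total)

    def test_noiseless_step_function_recovered(self):
        rng = np.random.default_rng(15)
        table = make_table({"none": 40, "cane_or_walker": 20}, seed=8)
        x = table["evening_max"].to_numpy()
        table["barthel_index"] = np.where(x < 70, 10.0, np.where(x < 140, 45.0, 85.0))
        grid = {
            "min_impurity_decrease": [0.0, 0.5, 1.0],
            "min_samples_leaf": list(range(1, 6)),
            "min_samples_split": [2, 4, 6],
        }
        best, _ = md.cross_validate(table, grid=grid, k=5, seed=3)
        m = md.fit_tree(table, best)
        assert m.first_split_feature() == "evening_max"
        assert np.allclose(m.predict(table), table["barthel_index"])


class TestPermutationImportance:
    def test_unused_feature_has_near_zero_importance(self):
        rng = np.random.default_rng(16)
        table = make_table({"none": 60}, seed=9)
        table["barthel_index"] = np.where(table["evening_max"] > 100, 80.0, 20.0)
        m = md.fit_tree(table, md.Hyperparams(max_depth=1))
        assert m.first_split_feature() == "evening_max"
        imp = md.permutation_importance(m, table, n_repeats=50, seed=1)
        means = imp.groupby("feature")["mean_importance"].first()
        assert abs(means["morning_max"]) < 0.01
        assert abs(means["overnight_max"]) < 0.01

    def test_perfect_single_feature_tree_importance_near_one(self):
        table = make_table({"none": 50}, seed=10)
        table["barthel_index"] = np.where(table["evening_max"] > 100, 80.0, 20.0)
        m = md.fit_tree(table)
        imp = md.permutation_importance(m, table, n_repeats=30, seed=2)
        means = imp.groupby("feature")["mean_importance"].first()
        assert means["evening_max"] > 0.8

    def test_same_seed_identical_samples(self, small_feature_table):
        m = md.fit_tree(small_feature_table)
        a = md.permutation_importance(m, small_feature_table, n_repeats=5, seed=7)
        b = md.permutation_importance(m, small_feature_table, n_repeats=5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_sorted_by_descending_mean(self, small_feature_table):
        m = md.fit_tree(small_feature_table)
        imp = md.permutation_importance(m, small_feature_table, n_repeats=5, seed=7)
        means = imp["mean_importance"].to_numpy()
        assert (np.diff(means) <= 1e-12).all()
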