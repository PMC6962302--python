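"""Trait derivation, splitting, SMOTE, model training and importance."""

import numpy as np
import pandas as pd
import pytest

from placmine.model import (
    TRAITS,
    FittedTraitModel,
    TraitSpec,
    derive_traits,
    evaluate_model,
    permutation_importance,
    run_trait_models,
    select_features,
    smote_augment,
    stratified_split,
    train_trait_model,
    zscore_from_reference,
    _make_estimator,
)
from placmine.network import (
    build_importance_network,
    supplementary_table,
    write_sif,
)


class TestDeriveTraits:
    def make(self, ga):
        return pd.DataFrame(
            {
                "group": ["case"] * len(ga),
                "gestational_age": ga,
                "birth_weight_z": np.zeros(len(ga)),
                "head_circumference_z": np.zeros(len(ga)),
            },
            index=[f"s{i}" for i in range(len(ga))],
        )

    def test_premature_birth_boundaries(self):
        ph = derive_traits(self.make([39.0, 37.0, 42.0]))
        # term birth 0; the pre-term boundary at +2; post-term at -3
        assert ph["premature_birth"].tolist() == [0.0, 2.0, -3.0]

    def test_z_from_reference_interpolation(self):
        ref = pd.DataFrame(
            {
                "sex": ["M", "M", "F", "F"],
                "gestational_age": [30.0, 40.0, 30.0, 40.0],
                "mean": [1000.0, 3000.0, 900.0, 2900.0],
                "sd": [100.0, 300.0, 100.0, 300.0],
            }
        )
        z = zscore_from_reference([2000.0, 2900.0], [35.0, 40.0], ["M", "F"], ref)
        assert z[0] == pytest.approx(0.0)  # exactly the interpolated mean
        assert z[1] == pytest.approx(0.0)

    def test_out_of_range_ga_names_sample(self):
        ref = pd.DataFrame(
            {"sex": ["M", "M"], "gestational_age": [30.0, 40.0],
             "mean": [1.0, 2.0], "sd": [1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="reference range"):
            zscore_from_reference([1.0], [25.0], ["M"], ref)

    def test_missing_z_without_reference_errors(self):
        ph = self.make([38.0]).drop(columns=["birth_weight_z"])
        with pytest.raises(ValueError):
            derive_traits(ph)


class TestSelectFeatures:
    def test_selection_is_the_flagged_rows(self, default_screens):
        meth, expr = default_screens
        sel = select_features(meth, expr)
        flagged = set(meth.index[meth["significant"]]) | set(
            expr.index[expr["significant"]]
        )
        assert set(sel) == flagged
        assert sel == select_features(meth, expr)  # deterministic order

    def test_empty_selection_errors(self):
        empty = pd.DataFrame({"significant": [False, False]}, index=["a", "b"])
        with pytest.raises(ValueError, match="threshold"):
            select_features(empty)


class TestStratifiedSplit:
    def test_cohort_allocation_by_rounding_rule(self):
        ids = [f"c{i}" for i in range(8)] + [f"i{i}" for i in range(28)]
        groups = ["control"] * 8 + ["case"] * 28
        train, test = stratified_split(ids, groups, seed=0)
        # floor(8 * 2/3 + .5) = 5 controls, floor(28 * 2/3 + .5) = 19 cases
        assert sum(s.startswith("c") for s in train) == 5
        assert sum(s.startswith("i") for s in train) == 19
        assert sorted(train + test) == sorted(ids)
        assert not set(train) & set(test)

    def test_same_seed_reproduces_split(self):
        ids = list("abcdefghij")
        groups = ["x"] * 5 + ["y"] * 5
        assert stratified_split(ids, groups, seed=3) == stratified_split(
            ids, groups, seed=3
        )

    def test_degenerate_ratios_and_groups(self):
        ids = list("abcd")
        with pytest.raises(ValueError):
            stratified_split(ids, ["x", "x", "x", "y"], seed=0)  # group of 1
        with pytest.raises(ValueError):
            stratified_split(ids, ["x", "x", "y", "y"], ratio=1.0, seed=0)


class TestSmote:
    def test_two_point_minority_stays_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[5.0, 5.0]] * 6)
        y = np.array(["m"] * 2 + ["M"] * 6)
        Xa, ya, _ = smote_augment(X, y, k=1, seed=0)
        new = Xa[len(X):]
        assert len(new) == 4
        assert np.allclose(new[:, 0], new[:, 1])  # on the diagonal
        assert ((new >= 0) & (new <= 1)).all()

    def test_balancing_arithmetic(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 3))
        y = np.array(["a"] * 5 + ["b"] * 15)
        Xa, ya, _ = smote_augment(X, y, k=3, seed=0)
        assert (ya == "a").sum() == 15 and (ya == "b").sum() == 15
        assert len(Xa) == 30

    def test_synthetic_points_are_minority_convex_combinations(self):
        rng = np.random.default_rng(13)
        Xmin = rng.normal(0, 1, (6, 4))
        Xmaj = rng.normal(8, 1, (18, 4))
        X = np.vstack([Xmin, Xmaj])
        y = np.array(["m"] * 6 + ["M"] * 18)
        Xa, ya, _ = smote_augment(X, y, k=3, seed=1)
        new = Xa[len(X):]
        # nearest original neighbour of every synthetic point is minority
        for p in new:
            d = np.linalg.norm(X - p, axis=1)
            assert y[np.argmin(d)] == "m"

    def test_regression_targets_interpolated_within_stratum(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        strata = np.array(["m"] * 4 + ["M"] * 8)
        Xa, ya, sa = smote_augment(X, y, strata=strata, k=2, seed=2)
        assert len(ya) == 16
        new_y = ya[12:]
        # interpolated targets stay within the minority target range
        ymin = y[:4]
        assert new_y.min() >= ymin.min() - 1e-12
        assert new_y.max() <= ymin.max() + 1e-12

    def test_single_minority_sample_errors(self):
        X = np.zeros((4, 2))
        y = np.array(["m", "M", "M", "M"])
        with pytest.raises(ValueError):
            smote_augment(X, y, seed=0)


CLS = TraitSpec("group", "classification", "accuracy")
REG = TraitSpec("birth_weight_z", "regression", "pearson_r")


class TestTraining:
    def test_separable_data_reaches_perfect_cv(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal(-3, 0.3, (12, 4)), rng.normal(3, 0.3, (12, 4))])
        y = np.array(["a"] * 12 + ["b"] * 12)
        best, table = train_trait_model(X, y, CLS, cv_folds=3, seed=0)
        assert table["cv_score"].max() == pytest.approx(1.0)

    def test_same_seed_same_hyperparameters(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(24, 5))
        y = rng.normal(size=24)
        b1, _ = train_trait_model(X, y, REG, cv_folds=3, seed=5)
        b2, _ = train_trait_model(X, y, REG, cv_folds=3, seed=5)
        assert b1 == b2

    def test_pure_noise_accuracy_near_majority_rate(self):
        rng = np.random.default_rng(17)
        n_test, majority = 40, 0.5
        X = rng.normal(size=(60, 10))
        y = np.array(["a", "b"] * 30)
        best, _ = train_trait_model(X, y, CLS, cv_folds=3, seed=0)
        est = _make_estimator(CLS, best, 0, calibrated=True, cv=3)
        est.fit(X, y)
        model = FittedTraitModel(CLS, est, best, None, np.zeros(10), np.ones(10))
        Xt = rng.normal(size=(n_test, 10))
        yt = np.array(["a", "b"] * (n_test // 2))
        res = evaluate_model(model, Xt, yt)
        # binomial 99.9% envelope around the chance rate
        se = np.sqrt(majority * (1 - majority) / n_test)
        assert abs(res.metric - majority) < 3.5 * se

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            train_trait_model(np.zeros((4, 2)), np.zeros(4), REG, grid=[])


class TestEvaluate:
    def test_perfect_regression(self):
        est = _make_estimator(REG, {"kernel": "linear", "C": 10.0, "epsilon": 0.01}, 0)
        rng = np.random.default_rng(18)
        X = rng.normal(size=(30, 1))
        y = 2 * X[:, 0]
        est.fit(X, y)
        model = FittedTraitModel(REG, est, {}, None, np.zeros(1), np.ones(1))
        res = evaluate_model(model, X, y)
        assert res.metric > 0.999
        assert res.p_value < 1e-10

    def test_constant_predictions_flagged(self):
        est = _make_estimator(REG, {"kernel": "rbf", "C": 0.001, "epsilon": 10.0}, 0)
        rng = np.random.default_rng(19)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        est.fit(X, y)
        model = FittedTraitModel(REG, est, {}, None, np.zeros(2), np.ones(2))
        res = evaluate_model(model, X, y)
        assert not res.defined

    def test_empty_test_set_errors(self):
        model = FittedTraitModel(REG, None, {}, None, np.zeros(1), np.ones(1))
        with pytest.raises(ValueError):
            evaluate_model(model, np.zeros((0, 1)), np.array([]))


class TestPermutationImportance:
    def _fit_single_signal(self, seed=20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 5))
        y = 3 * X[:, 2] + rng.normal(0, 0.1, 60)
        est = _make_estimator(REG, {"kernel": "linear", "C": 10.0, "epsilon": 0.1}, 0)
        est.fit(X[:40], y[:40])
        model = FittedTraitModel(
            REG, est, {}, None, np.zeros(5), np.ones(5),
            features=[f"f{j}" for j in range(5)],
        )
        return model, X[40:], y[40:]

    def test_sole_informative_feature_gets_100_percent(self):
        model, Xt, yt = self._fit_single_signal()
        imp = permutation_importance(model, Xt, yt, n_repeats=10, seed=0)
        assert imp["percent"].idxmax() == "f2"
        assert imp.loc["f2", "percent"] == pytest.approx(100.0)
        # independent features sit near zero
        assert (imp.drop("f2")["percent"] < 20).all()

    def test_stable_under_test_row_shuffling(self):
        model, Xt, yt = self._fit_single_signal()
        imp1 = permutation_importance(model, Xt, yt, n_repeats=50, seed=1)
        order = np.random.default_rng(0).permutation(len(yt))
        imp2 = permutation_importance(model, Xt[order], yt[order], n_repeats=50, seed=1)
        assert imp1["percent"].idxmax() == imp2["percent"].idxmax()
        assert np.corrcoef(imp1["raw"], imp2["raw"])[0, 1] > 0.95

    def test_single_test_sample_errors(self):
        model, Xt, yt = self._fit_single_signal()
        with pytest.raises(ValueError):
            permutation_importance(model, Xt[:1], yt[:1])


class TestNetwork:
    def test_only_trait_nodes_when_no_feature_passes(self):
        imp = pd.DataFrame(
            np.full((3, 4), 5.0),
            index=["f1", "f2", "f3"],
            columns=[t.name for t in TRAITS],
        )
        g = build_importance_network(imp)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 0

    def test_single_labeled_feature(self):
        imp = pd.DataFrame(
            [[85.0, 0.0, 0.0, 0.0]],
            index=["cg1"],
            columns=[t.name for t in TRAITS],
        )
        g = build_importance_network(imp)
        assert g.nodes["cg1"]["labeled"]
        assert g.number_of_edges() == 1

    def test_edge_count_matches_brute_recount(self):
        rng = np.random.default_rng(21)
        imp = pd.DataFrame(
            rng.uniform(0, 100, size=(30, 4)),
            index=[f"f{j}" for j in range(30)],
            columns=[t.name for t in TRAITS],
        )
        g = build_importance_network(imp)
        expected = int((imp.to_numpy() >= 10.0).sum())
        assert g.number_of_edges() == expected
        labeled = {n for n, d in g.nodes(data=True)
                   if d["kind"] == "feature" and d["labeled"]}
        assert labeled == set(imp.index[(imp >= 80).any(axis=1)])

    def test_supplementary_table_threshold(self):
        imp = pd.DataFrame(
            [[55.0, 49.9, 0.0, 0.0], [10.0, 20.0, 30.0, 40.0]],
            index=["a", "b"],
            columns=[t.name for t in TRAITS],
        )
        supp = supplementary_table(imp)
        assert len(supp) == 1
        assert supp.iloc[0]["feature"] == "a"

    def test_sif_export_hand_counted(self, tmp_path):
        imp = pd.DataFrame(
            [[85.0, 12.0, 0.0, 0.0], [9.9, 0.0, 0.0, 0.0]],
            index=["fA", "fB"],
            columns=[t.name for t in TRAITS],
        )
        g = build_importance_network(imp)
        path = tmp_path / "net.sif"
        write_sif(g, path)
        lines = [l for l in path.read_text().splitlines() if "\t" in l]
        assert len(lines) == 2
        assert all(l.split("\t")[0] == "fA" for l in lines)


class TestEndToEnd:
    def test_full_model_stage_on_default_study(self, default_study, feature_matrix):
        results = run_trait_models(
            feature_matrix, default_study.phenotypes, seed=0, n_repeats=3
        )
        assert set(results) == {t.name for t in TRAITS}
        grp = results["group"]
        assert grp.metric == 1.0
        case = grp.y_test == "case"
        assert grp.probabilities[case].min() > grp.probabilities[~case].max()
        for t in ("premature_birth", "birth_weight_z", "head_circumference_z"):
            assert results[t].defined
            assert results[t].metric > 0
            imp = results[t].importance
            assert imp["percent"].max() == pytest.approx(100.0)
            assert (imp["percent"] >= 0).all()

    def test_test_samples_never_in_training(self, default_study):
        ph = default_study.phenotypes
        train, test = stratified_split(
            list(ph.index), ph["group"], seed=4
        )
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(ph.index)
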