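"""Interaction features, stratified split, selection, boosting, SHAP, Youden."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from histotme.response import (
    OPS,
    engineer_interactions,
    cv_tune,
    feature_name,
    parse_feature_name,
    rf_select_features,
    shap_attributions,
    stratified_split,
    train_gbt,
    youden_threshold,
)


@pytest.fixture(scope="module")
def profile30(registry):
    r = np.random.default_rng(1)
    return pd.DataFrame(r.normal(size=(8, 30)), columns=list(registry.names),
                        index=[f"S{i}" for i in range(8)])


class TestStratifiedSplit:
    def test_230_patient_cohort_counts(self):
        y = pd.Series([1] * 119 + [0] * 111, index=[f"p{i}" for i in range(230)])
        train, test = stratified_split(y, 0.7, seed=0)
        assert len(train) == 161 and len(test) == 69
        assert (y.loc[train] == 1).sum() == 84 and (y.loc[train] == 0).sum() == 77
        assert (y.loc[test] == 1).sum() == 35 and (y.loc[test] == 0).sum() == 34

    def test_balanced_10_patient_split(self):
        y = pd.Series([1] * 5 + [0] * 5, index=[f"p{i}" for i in range(10)])
        train, test = stratified_split(y, 0.7, seed=1)
        assert len(train) == 7
        counts = sorted([(y.loc[train] == 1).sum(), (y.loc[train] == 0).sum()])
        assert counts == [3, 4]

    def test_full_train_fraction(self):
        y = pd.Series([1, 1, 0, 0])
        train, test = stratified_split(y, 1.0, seed=0)
        assert len(train) == 4 and test == []

    def test_disjoint_and_exhaustive(self):
        y = pd.Series(np.random.default_rng(2).integers(0, 2, 37))
        train, test = stratified_split(y, 0.7, seed=3)
        assert set(train) | set(test) == set(y.index)
        assert set(train) & set(test) == set()

    def test_tiny_class_rejected(self):
        y = pd.Series([1, 0, 0, 0])
        with pytest.raises(ValueError):
            stratified_split(y, 0.7, seed=0)


class TestEngineerInteractions:
    def test_feature_count_is_1740(self, profile30):
        X = engineer_interactions(profile30)
        assert X.shape == (8, 1740)
        assert 1740 == 30 * 29 // 2 * 4

    def test_zero_profile(self, profile30):
        zero = profile30.iloc[[0]] * 0.0
        X = engineer_interactions(zero)
        vals = X.iloc[0]
        for name in X.columns:
            _, _, op = parse_feature_name(name)
            assert vals[name] == pytest.approx(1.0 if op in "*/" else 0.0)

    def test_matches_double_loop_oracle(self, profile30):
        X = engineer_interactions(profile30)
        names = list(profile30.columns)
        row = profile30.iloc[3]
        expected = {}
        for i in range(30):
            for j in range(i + 1, 30):
                a, b = names[i], names[j]
                expected[f"{a}+{b}"] = row[a] + row[b]
                expected[f"{a}-{b}"] = row[a] - row[b]
                expected[f"exp({a})*exp({b})"] = np.exp(row[a]) * np.exp(row[b])
                expected[f"exp({a})/exp({b})"] = np.exp(row[a]) / np.exp(row[b])
        assert len(expected) == 1740
        for name, v in expected.items():
            assert X.iloc[3][name] == pytest.approx(v)

    def test_name_grammar_roundtrip(self, profile30):
        X = engineer_interactions(profile30)
        names = list(profile30.columns)
        order = {n: i for i, n in enumerate(names)}
        for fname in X.columns:
            a, b, op = parse_feature_name(fname)
            assert feature_name(a, b, op) == fname
            assert order[a] < order[b]
            assert op in OPS

    def test_exp_features_are_monotone_transforms(self, profile30):
        X = engineer_interactions(profile30)
        names = list(profile30.columns)
        a, b = names[0], names[1]
        np.testing.assert_allclose(
            X[f"exp({a})*exp({b})"], np.exp(X[f"{a}+{b}"]), rtol=1e-12
        )
        np.testing.assert_allclose(
            X[f"exp({a})/exp({b})"], np.exp(X[f"{a}-{b}"]), rtol=1e-12
        )

    def test_overflow_guard(self, profile30):
        big = profile30.copy()
        big.iloc[0, 0] = 60.0
        with pytest.raises(ValueError, match="magnitude"):
            engineer_interactions(big)


class TestRFSelect:
    def test_planted_feature_ranked_first(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 20)), columns=[f"f{i}" for i in range(20)])
        y = (X["f7"] > 0).astype(int)
        top = rf_select_features(X, y, k=3, n_trees=200, seed=0)
        assert top[0] == "f7"

    def test_k_equals_all_returns_rank_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        y = (X["a"] > 0).astype(int)
        out = rf_select_features(X, y, k=6, n_trees=50, seed=0)
        assert sorted(out) == list("abcdef")
        assert out[0] == "a"

    def test_sample_order_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 10)), columns=[f"f{i}" for i in range(10)],
                         index=[f"s{i}" for i in range(60)])
        y = pd.Series((X["f2"] + 0.5 * X["f5"] > 0).astype(int), index=X.index)
        sel1 = rf_select_features(X, y, k=4, n_trees=100, seed=1)
        perm = rng.permutation(60)
        sel2 = rf_select_features(X.iloc[perm], y.iloc[perm], k=4, n_trees=100, seed=1)
        assert sel1 == sel2

    def test_invalid_k(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        y = pd.Series([0, 1] * 5)
        with pytest.raises(ValueError):
            rf_select_features(X, y, k=0)
        with pytest.raises(ValueError):
            rf_select_features(X, y, k=4)


class TestCvTune:
    def test_single_k_grid_returns_it(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 30)), columns=[f"f{i}" for i in range(30)])
        y = (X["f0"] > 0).astype(int)
        best_k, best_rounds, rec = cv_tune(X, y, k_grid=(7,), seed=0, rf_trees=50)
        assert best_k == 7
        assert best_rounds >= 1
        assert list(rec.index) == [7]

    def test_pure_noise_cv_auroc_near_half(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 40)), columns=[f"f{i}" for i in range(40)])
        y = pd.Series(rng.integers(0, 2, 120), index=X.index)
        _, _, rec = cv_tune(X, y, k_grid=(5,), seed=0, rf_trees=50)
        assert 0.35 <= rec.loc[5, "cv_auroc"] <= 0.65

    def test_planted_signal_tunes_small_k_with_high_auroc(self, rng):
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 30)), columns=[f"f{i}" for i in range(30)])
        logit = 3.0 * X["f4"]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
        best_k, _, rec = cv_tune(X, y, k_grid=(5, 10, 30), seed=0, rf_trees=100)
        assert best_k <= 10
        assert rec["cv_auroc"].max() >= 0.9


class TestTrainGbt:
    def test_separable_training_auroc_one(self):
        X = pd.DataFrame({"f": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)]
        clf = train_gbt(X, y, rounds=10, seed=0)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, clf.predict_proba(X.to_numpy())[:, 1]) == 1.0

    def test_single_round_bounded_leaf_count(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 5)))
        y = (X.iloc[:, 0] + 0.3 * rng.normal(size=200) > 0).astype(int)
        clf = train_gbt(X, y, rounds=1, seed=0)
        probs = clf.predict_proba(X.to_numpy())[:, 1]
        assert len(np.unique(probs)) <= 2 ** 6  # one tree of default depth 6

    def test_deterministic_under_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 8)))
        y = (X.iloc[:, 1] > 0).astype(int)
        p1 = train_gbt(X, y, rounds=20, seed=3).predict_proba(X.to_numpy())
        p2 = train_gbt(X, y, rounds=20, seed=3).predict_proba(X.to_numpy())
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            train_gbt(X, np.zeros(10), rounds=5)


def _exact_shap_two_feature_stumps(booster, x, X_bg):
    """Exact Shapley values for an ensemble of depth-1 trees over 2 features.

    For stump trees each split on a single feature, the game is additive:
    the Shapley value of feature j is the sum over trees splitting on j of
    (leaf(x_j) - cover-weighted mean leaf). Enumerate coalitions explicitly.
    """
    df = booster.trees_to_dataframe()
    base = 0.0
    phi = np.zeros(2)
    for tid in df.Tree.unique():
        t = df[df.Tree == tid]
        root = t[t.Node == 0].iloc[0]
        if root.Feature == "Leaf":
            base += root.Gain
            continue
        j = int(root.Feature[1:]) if root.Feature.startswith("f") else int(root.Feature)
        yes = t[t.ID == root.Yes].iloc[0]
        no = t[t.ID == root.No].iloc[0]
        mean_leaf = (yes.Gain * yes.Cover + no.Gain * no.Cover) / (yes.Cover + no.Cover)
        leaf_x = yes.Gain if x[j] < root.Split else no.Gain
        phi[j] += leaf_x - mean_leaf
        base += mean_leaf
    return phi, base


class TestShap:
    def _stump_ensemble(self, X, y, rounds=2):
        dtrain = xgb.DMatrix(X, label=y, feature_names=["f0", "f1"])
        params = {"max_depth": 1, "eta": 0.5, "base_score": 0.5, "objective": "binary:logistic"}
        return xgb.train(params, dtrain, num_boost_round=rounds)

    def test_additivity_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=[f"f{i}" for i in range(4)])
        y = (X["f0"] + X["f2"] > 0).astype(int)
        clf = train_gbt(X, y, rounds=15, seed=0)
        phi, base = shap_attributions(clf, X)
        margin = clf.get_booster().predict(xgb.DMatrix(X.to_numpy()), output_margin=True)
        np.testing.assert_allclose(base + phi.sum(axis=1), margin, atol=1e-4)

    def test_stump_sign_matches_split_side(self, rng):
        X = pd.DataFrame({"f0": np.r_[-np.ones(30), np.ones(30)], "f1": rng.normal(size=60)})
        y = np.r_[np.zeros(30), np.ones(30)]
        clf = train_gbt(X, y, rounds=1, seed=0)
        phi, _ = shap_attributions(clf, X)
        assert (phi["f0"].iloc[:30] < 0).all() and (phi["f0"].iloc[30:] > 0).all()

    def test_matches_bruteforce_shapley_on_stumps(self, rng):
        X = rng.normal(size=(80, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] < 0)).astype(int)
        booster = self._stump_ensemble(X, y, rounds=2)
        contribs = booster.predict(xgb.DMatrix(X, feature_names=["f0", "f1"]), pred_contribs=True)
        for i in range(5):
            phi_exact, base_exact = _exact_shap_two_feature_stumps(booster, X[i], X)
            np.testing.assert_allclose(contribs[i, :2], phi_exact, atol=1e-5)
            np.testing.assert_allclose(contribs[i, 2], base_exact, atol=1e-5)

    def test_feature_mismatch_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = (X["a"] > 0).astype(int)
        clf = train_gbt(X, y, rounds=5, seed=0)
        with pytest.raises(ValueError):
            shap_attributions(clf, X[["a", "b"]])


class TestYouden:
    def test_perfect_separation_lowest_threshold(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        thr, sens, spec = youden_threshold(probs, labels)
        assert thr == pytest.approx(0.8)  # lowest candidate achieving J = 1
        assert sens == 1.0 and spec == 1.0

    def test_matches_bruteforce_scan(self, rng):
        labels = rng.integers(0, 2, 60)
        probs = labels + rng.normal(0, 0.4, 60)  # noisy scores
        probs = 1 / (1 + np.exp(-probs))
        flip = rng.uniform(size=60) < 0.1
        labels = np.where(flip, 1 - labels, labels)
        thr, sens, spec = youden_threshold(probs, labels)
        best_j, best_thr = -np.inf, None
        for t in np.sort(np.unique(probs)):
            pred = probs >= t
            j = pred[labels == 1].mean() + (~pred)[labels == 0].mean() - 1
            if j > best_j + 1e-12:
                best_j, best_thr = j, t
        assert thr == pytest.approx(best_thr)
        assert sens + spec - 1 == pytest.approx(best_j)

    def test_anticorrelated_scores_give_zero_j(self):
        probs = np.array([0.9, 0.9, 0.1, 0.1])
        labels = np.array([0, 0, 1, 1])
        thr, sens, spec = youden_threshold(probs, labels)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_constant_probs_warns(self, caplog):
        with caplog.at_level("WARNING"):
            thr, sens, spec = youden_threshold(np.full(6, 0.4), np.array([0, 1, 0, 1, 0, 1]))
        assert thr == pytest.approx(0.4)
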