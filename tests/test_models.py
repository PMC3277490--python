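"""PLS/forest estimators, repeated resampling and cross-set transfer."""

import numpy as np
import pandas as pd
import pytest

from ameskit.evaluation import auc
from ameskit.models import (
    ForestOOBClassifier,
    ForestSpec,
    PlsClassifier,
    cross_set_evaluate,
    fit_forest_oob,
    repeated_resampling,
)


def _xy(rng, n=60, p=4):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    y = (X["x0"] + 0.5 * rng.normal(size=n) > 0).astype(float)
    if y.nunique() < 2:
        y.iloc[0] = 1 - y.iloc[0]
    return X, y.to_numpy()


class TestPls:
    def test_one_predictor_one_component_equals_ols_slope(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = (X["x"] + rng.normal(size=40) > 0).astype(float).to_numpy()
        m = PlsClassifier(1).fit(X, y)
        slope = np.cov(X["x"], y, ddof=1)[0, 1] / np.var(X["x"], ddof=1)
        assert m.coefficients_[0] == pytest.approx(slope, rel=1e-9)

    def test_full_components_reproduce_ols_fitted_values(self, rng):
        X, y = _xy(rng)
        m = PlsClassifier(4).fit(X, y)
        design = np.c_[np.ones(len(X)), X.to_numpy()]
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(m.score_samples(X), design @ beta, atol=1e-6)

    def test_score_vectors_mutually_orthogonal(self, rng):
        X, y = _xy(rng, p=6)
        m = PlsClassifier(3).fit(X, y)
        gram = m.x_scores_.T @ m.x_scores_
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6

    def test_component_aligned_with_informative_orthonormal_predictor(self):
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(30, 2)))
        X = pd.DataFrame(q, columns=["x1", "x2"])
        y = X["x1"].to_numpy().copy()
        y = (y > np.median(y)).astype(float)
        m = PlsClassifier(1).fit(X, y)
        w = np.abs(m.pls_.x_weights_[:, 0])
        assert w[0] > w[1]

    def test_constant_response_errors(self, rng):
        X, _ = _xy(rng)
        with pytest.raises(ValueError, match="single-class"):
            PlsClassifier(1).fit(X, np.ones(len(X)))

    def test_components_beyond_rank_error(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = 2 * X["a"]  # rank 1
        y = (X["a"] > 0).astype(float).to_numpy()
        with pytest.raises(ValueError, match="rank"):
            PlsClassifier(2).fit(X, y)

    def test_mean_centered_row_predicts_mean_response(self, rng):
        X, y = _xy(rng)
        Xc = X - X.mean()
        m = PlsClassifier(2).fit(Xc, y)
        zero_row = pd.DataFrame([np.zeros(X.shape[1])], columns=X.columns)
        assert m.score_samples(zero_row)[0] == pytest.approx(y.mean(), abs=1e-9)

    def test_row_permutation_permutes_scores(self, rng):
        X, y = _xy(rng)
        m = PlsClassifier(2).fit(X, y)
        perm = rng.permutation(len(X))
        np.testing.assert_allclose(m.score_samples(X.iloc[perm]), m.score_samples(X)[perm])

    def test_column_mismatch_errors(self, rng):
        X, y = _xy(rng)
        m = PlsClassifier(1).fit(X, y)
        with pytest.raises(ValueError, match="columns"):
            m.score_samples(X.rename(columns={"x0": "other"}))


class TestForest:
    def test_planted_rule_recovered_with_top_importance(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 15)), columns=[f"v{i}" for i in range(15)])
        y = (X["v0"] > 0).astype(float).to_numpy()
        m = fit_forest_oob(X, y, ForestSpec(n_trees=200), seed=3)
        assert auc(m.oob_scores_, y) > 0.9
        assert m.importances_.idxmax() == "v0"

    def test_oob_scores_are_probabilities(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)))
        y = (X[0] > 0).astype(float).to_numpy()
        m = fit_forest_oob(X, y, ForestSpec(n_trees=100), seed=1)
        assert ((m.oob_scores_ >= 0) & (m.oob_scores_ <= 1)).all()

    def test_duplicated_predictor_splits_importance(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 6)), columns=[f"v{i}" for i in range(6)])
        y = (X["v0"] > 0).astype(float).to_numpy()
        base = fit_forest_oob(X, y, ForestSpec(n_trees=200), seed=5)
        X2 = X.copy()
        X2["v0_dup"] = X2["v0"]
        dup = fit_forest_oob(X2, y, ForestSpec(n_trees=200), seed=5)
        # importance mass moves onto the duplicate while discrimination holds
        assert dup.importances_["v0_dup"] > 0
        assert dup.importances_["v0"] < base.importances_["v0"]
        assert abs(auc(dup.oob_scores_, y) - auc(base.oob_scores_, y)) < 0.05

    def test_same_seed_reproduces_oob_scores(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 4)))
        y = (X[0] > 0).astype(float).to_numpy()
        a = fit_forest_oob(X, y, ForestSpec(n_trees=50), seed=9)
        b = fit_forest_oob(X, y, ForestSpec(n_trees=50), seed=9)
        np.testing.assert_array_equal(a.oob_scores_, b.oob_scores_)

    def test_oob_auc_invariant_to_monotone_predictor_transform(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"v{i}" for i in range(5)])
        y = (X["v0"] > 0).astype(float).to_numpy()
        a = auc(fit_forest_oob(X, y, ForestSpec(100), seed=2).oob_scores_, y)
        X2 = X.copy()
        X2["v0"] = np.exp(X2["v0"])  # strictly monotone
        b = auc(fit_forest_oob(X2, y, ForestSpec(100), seed=2).oob_scores_, y)
        assert abs(a - b) < 0.05

    def test_single_class_errors(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError, match="single-class"):
            ForestOOBClassifier(seed=1).fit(X, np.zeros(20))


class TestRepeatedResampling:
    def test_train_only_run_has_no_test_metrics(self, rng):
        X, y = _xy(rng)
        res = repeated_resampling(X, y, lambda s: PlsClassifier(1),
                                  n_reps=1, train_fraction=1.0, seed=0)
        assert len(res.train_aucs) == 1 and len(res.test_aucs) == 0
        assert "test_auc_mean" not in res.summary()

    def test_separable_data_high_test_auc(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"v{i}" for i in range(5)])
        y = (X["v0"] > 0).astype(float).to_numpy()
        res = repeated_resampling(X, y, lambda s: PlsClassifier(1), n_reps=10, seed=1)
        s = res.summary()
        assert s["test_auc_mean"] > 0.9 and s["test_auc_sd"] < 0.1

    def test_label_shuffle_degrades_test_not_train_structure(self, rng):
        # shuffling test labels is emulated by shuffling y before the
        # split: test AUC collapses to ~0.5 while in-sample train AUC
        # stays high (no leakage from test rows into the fit)
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"v{i}" for i in range(5)])
        y = (X["v0"] > 0).astype(float).to_numpy()
        res = repeated_resampling(X, y, lambda s: PlsClassifier(1), n_reps=5, seed=2)
        y_perm = rng.permutation(y)
        res_perm = repeated_resampling(X, y_perm, lambda s: PlsClassifier(3), n_reps=5, seed=2)
        assert res.summary()["test_auc_mean"] > 0.9
        assert abs(res_perm.summary()["test_auc_mean"] - 0.5) < 0.15
        assert res_perm.summary()["train_auc_mean"] > res_perm.summary()["test_auc_mean"]

    def test_summary_equals_recomputation_from_per_rep_aucs(self, rng):
        X, y = _xy(rng, n=100)
        res = repeated_resampling(X, y, lambda s: PlsClassifier(1), n_reps=8, seed=3)
        s = res.summary()
        assert s["test_auc_mean"] == np.mean(res.test_aucs)
        assert s["test_auc_sd"] == np.std(res.test_aucs, ddof=1)

    def test_deterministic_given_seed(self, rng):
        X, y = _xy(rng, n=100)
        a = repeated_resampling(X, y, lambda s: PlsClassifier(1), n_reps=4, seed=7)
        b = repeated_resampling(X, y, lambda s: PlsClassifier(1), n_reps=4, seed=7)
        np.testing.assert_array_equal(a.test_aucs, b.test_aucs)


class TestCrossSet:
    def test_same_set_transfer_equals_training_auc(self, rng):
        X, y = _xy(rng, n=100)
        res = cross_set_evaluate(X, y, X, y, lambda s: PlsClassifier(1))
        assert res.test_auc == pytest.approx(res.train_auc)

    def test_one_class_test_set_errors(self, rng):
        X, y = _xy(rng)
        X2, _ = _xy(rng)
        with pytest.raises(ValueError, match="single-class"):
            cross_set_evaluate(X, y, X2, np.zeros(len(X2)), lambda s: PlsClassifier(1))

    def test_descriptor_mismatch_errors(self, rng):
        X, y = _xy(rng)
        X2 = X.rename(columns={"x0": "z"})
        with pytest.raises(ValueError, match="registries"):
            cross_set_evaluate(X, y, X2, y, lambda s: PlsClassifier(1))

    def test_score_summaries_are_five_number(self, rng):
        X, y = _xy(rng)
        res = cross_set_evaluate(X, y, X, y, lambda s: PlsClassifier(1))
        assert set(res.train_score_summary) == {"min", "q1", "median", "q3", "max"}
        assert res.train_score_summary["min"] <= res.train_score_summary["median"]
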