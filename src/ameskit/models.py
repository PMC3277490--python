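"""PLS and random-forest classification with repeated-resampling and
cross-set evaluation protocols.

Both learners are thin estimator classes: PLS regression on a 0/1
response whose continuous prediction is the classification score, and a
random forest scored by its combined out-of-bag (OOB) class
probabilities.  The resampling protocol refits the variance screen and
scaler on each training split so test rows never influence the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier

from .descriptors import DescriptorPreprocessor
from .evaluation import RocCurve, auc, roc_curve, vertical_average


def _validate_xy(X, y):
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("response is single-class")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be coded 0 (negative) / 1 (positive)")
    return X, y


class PlsClassifier(BaseEstimator):
    """PLS regression on the 0/1 Ames response used as a classifier.

    The fitted regression prediction is a continuous score; any cutoff
    turns it into a classification (see
    :func:`ameskit.evaluation.sensitivity_cutoff`).  Successive score
    vectors are mutually orthogonal; with as many components as the rank
    of X the fitted values coincide with ordinary least squares.
    """

    def __init__(self, n_components: int = 1):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
        if self.n_components > rank:
            raise ValueError(f"n_components={self.n_components} exceeds rank(X)={rank}")
        self.pls_ = PLSRegression(n_components=self.n_components, scale=False)
        self.pls_.fit(X.to_numpy(dtype=float), y)
        self.columns_ = list(X.columns)
        self.x_scores_ = self.pls_.x_scores_
        self.coefficients_ = self.pls_.coef_.ravel()
        self.intercept_ = float(self.pls_.intercept_.ravel()[0])
        return self

    def score_samples(self, X) -> np.ndarray:
        """Continuous regression scores (higher = more likely Ames+)."""
        X = pd.DataFrame(X)
        if list(X.columns) != self.columns_:
            raise ValueError("descriptor columns do not match the fitted model")
        return self.pls_.predict(X.to_numpy(dtype=float)).ravel()

    predict = score_samples


@dataclass
class ForestSpec:
    """Forest protocol: 500 unpruned trees, sqrt(p) candidate predictors
    per split, bootstrap (with replacement, ~63.2% unique rows) per tree."""

    n_trees: int = 500
    max_features: str = "sqrt"


class ForestOOBClassifier(BaseEstimator):
    """Random forest scored by combined out-of-bag class probabilities.

    ``oob_scores_`` holds, for each training row, the positive-class
    fraction over only the trees whose bootstrap excluded that row.
    ``importances_`` is the Gini (mean decrease in impurity) importance.
    """

    def __init__(self, spec: ForestSpec | None = None, seed: int = 0):
        self.spec = spec
        self.seed = seed

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        spec = self.spec or ForestSpec()
        self.forest_ = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=spec.max_features,
            bootstrap=True,
            oob_score=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(X.to_numpy(dtype=float), y.astype(int))
        self.columns_ = list(X.columns)
        self.oob_scores_ = self.forest_.oob_decision_function_[:, 1]
        self.importances_ = pd.Series(self.forest_.feature_importances_, index=self.columns_)
        return self

    def score_samples(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        if list(X.columns) != self.columns_:
            raise ValueError("descriptor columns do not match the fitted model")
        return self.forest_.predict_proba(X.to_numpy(dtype=float))[:, 1]

    predict = score_samples


def fit_forest_oob(X, y, spec: ForestSpec | None = None, seed: int = 0) -> ForestOOBClassifier:
    return ForestOOBClassifier(spec=spec, seed=seed).fit(X, y)


@dataclass
class ResamplingResult:
    """Per-replicate train/test ROC and AUC under repeated 70/30 random
    splits, plus vertically averaged curves with SDs."""

    n_reps: int
    train_fraction: float
    seed: int
    train_aucs: np.ndarray
    test_aucs: np.ndarray
    train_curves: list = field(repr=False, default_factory=list)
    test_curves: list = field(repr=False, default_factory=list)

    def summary(self) -> dict:
        out = {
            "train_auc_mean": float(np.mean(self.train_aucs)),
            "train_auc_sd": float(np.std(self.train_aucs, ddof=1)) if self.n_reps > 1 else 0.0,
        }
        if len(self.test_aucs):
            out["test_auc_mean"] = float(np.mean(self.test_aucs))
            out["test_auc_sd"] = float(np.std(self.test_aucs, ddof=1)) if self.n_reps > 1 else 0.0
        return out

    def averaged(self, role: str = "test"):
        curves = self.test_curves if role == "test" else self.train_curves
        return vertical_average(curves)

    def per_rep_table(self) -> pd.DataFrame:
        data = {"rep": np.arange(self.n_reps), "train_auc": self.train_aucs}
        if len(self.test_aucs):
            data["test_auc"] = self.test_aucs
        return pd.DataFrame(data)


def repeated_resampling(
    X,
    y,
    model_factory,
    n_reps: int = 100,
    train_fraction: float = 0.7,
    seed: int = 0,
    preprocessor_kwargs: dict | None = None,
) -> ResamplingResult:
    """Random 70/30 resampling repeated ``n_reps`` times.

    ``model_factory(seed)`` must return an unfitted estimator with
    ``fit``/``score_samples``.  Preprocessing (zero-variance removal,
    center/scale) is refit on each training split; an estimator exposing
    ``oob_scores_`` contributes its OOB scores as the training ROC.
    """
    X, y = _validate_xy(X, y)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    n = len(X)
    n_train = int(round(train_fraction * n))
    train_aucs, test_aucs, train_curves, test_curves = [], [], [], []
    for rep_seed in rep_seeds:
        rep_rng = np.random.default_rng(int(rep_seed))
        perm = rep_rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        y_train, y_test = y[train_idx], y[test_idx]
        if len(np.unique(y_train)) < 2:
            raise ValueError("training split is single-class; use a larger set")
        prep = DescriptorPreprocessor(**(preprocessor_kwargs or {}))
        X_train = prep.fit(X.iloc[train_idx]).transform(X.iloc[train_idx])
        model = model_factory(int(rep_seed)).fit(X_train, y_train)
        train_scores = getattr(model, "oob_scores_", None)
        if train_scores is None:
            train_scores = model.score_samples(X_train)
        c = roc_curve(train_scores, y_train)
        train_curves.append(c)
        train_aucs.append(auc(c))
        if len(test_idx) and len(np.unique(y_test)) == 2:
            X_test = prep.transform(X.iloc[test_idx])
            c = roc_curve(model.score_samples(X_test), y_test)
            test_curves.append(c)
            test_aucs.append(auc(c))
    return ResamplingResult(
        n_reps=n_reps,
        train_fraction=train_fraction,
        seed=seed,
        train_aucs=np.asarray(train_aucs),
        test_aucs=np.asarray(test_aucs),
        train_curves=train_curves,
        test_curves=test_curves,
    )


def _five_number(scores: np.ndarray) -> dict:
    q = np.percentile(scores, [0, 25, 50, 75, 100])
    return dict(zip(("min", "q1", "median", "q3", "max"), map(float, q)))


@dataclass
class CrossSetResult:
    train_auc: float
    test_auc: float
    train_curve: RocCurve = field(repr=False, default=None)
    test_curve: RocCurve = field(repr=False, default=None)
    train_score_summary: dict = field(default_factory=dict)
    test_score_summary: dict = field(default_factory=dict)


def cross_set_evaluate(
    X_train, y_train, X_test, y_test, model_factory, seed: int = 0,
    preprocessor_kwargs: dict | None = None,
) -> CrossSetResult:
    """Fit on 100% of one set, evaluate on the other; returns both AUCs
    and five-number summaries of the unscaled scores per set."""
    X_train, y_train = _validate_xy(X_train, y_train)
    X_test, y_test = _validate_xy(X_test, y_test)
    if list(X_train.columns) != list(X_test.columns):
        raise ValueError("descriptor registries of the two sets differ")
    prep = DescriptorPreprocessor(**(preprocessor_kwargs or {}))
    Xt = prep.fit(X_train).transform(X_train)
    model = model_factory(seed).fit(Xt, y_train)
    train_scores = model.score_samples(Xt)
    test_scores = model.score_samples(prep.transform(X_test))
    train_curve = roc_curve(train_scores, y_train)
    test_curve = roc_curve(test_scores, y_test)
    return CrossSetResult(
        train_auc=auc(train_curve),
        test_auc=auc(test_curve),
        train_curve=train_curve,
        test_curve=test_curve,
        train_score_summary=_five_number(train_scores),
        test_score_summary=_five_number(test_scores),
    )
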