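"""The six-classifier suite as a scikit-learn estimator.

``OperonPairSuite`` fits logistic regression (L2), an RBF-kernel SVM, a
random forest, gradient-boosted trees, a small multilayer perceptron and
Gaussian naive Bayes on the 12 pair features. Features are min-max scaled
for every algorithm except the two tree ensembles, which are scale
invariant. Per-algorithm positive calls (probability >= 0.5) feed the vote
tally in :mod:`operon_voter.voting`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .io import ALGORITHM_KEYS, FEATURE_COLUMNS
from .hyperopt import SEARCH_SPACES, optimize_hyperparameters

#: Algorithms that receive min-max scaled features.
SCALED_ALGORITHMS = frozenset({"LR", "SVM", "MLP", "GNB"})

DEFAULT_SEED = 1009731

#: Documented defaults used when hyperparameter optimization is off.
DEFAULT_HYPERPARAMETERS: Dict[str, dict] = {
    "LR": {"penalty": "l2", "C": 1.0},
    "SVM": {"C": 1.0, "gamma": "scale", "kernel": "rbf"},
    "RF": {"min_samples_split": 2, "max_depth": None, "n_estimators": 200},
    "XGB": {"gamma": 0.0, "learning_rate": 0.1, "n_estimators": 200},
    "GNB": {"var_smoothing": 1e-9},
    "MLP": {"alpha": 1e-4, "max_iter": 500, "n_hidden_layers": 1, "n_neurons": 32},
}


class PlattSVC(BaseEstimator, ClassifierMixin):
    """SVC with probabilities from a Platt-calibrated decision function.

    With enough samples the calibration is the standard cross-fitted sigmoid
    (CalibratedClassifierCV); on very small training sets, where cross
    fitting is impossible, a logistic sigmoid is fit directly to the
    training decision values.
    """

    def __init__(self, svc: SVC):
        self.svc = svc

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        min_class = int(np.min(np.bincount(y.astype(int))))
        if min_class >= 5:
            self.model_ = CalibratedClassifierCV(
                self.svc, method="sigmoid", cv=5, ensemble=False
            ).fit(X, y)
            self.svc_ = None
        else:
            self.svc_ = SVC(**self.svc.get_params()).fit(X, y)
            scores = self.svc_.decision_function(X).reshape(-1, 1)
            self.sigmoid_ = LogisticRegression(C=1e6).fit(scores, y)
            self.model_ = None
        return self

    def predict_proba(self, X):
        if self.model_ is not None:
            return self.model_.predict_proba(X)
        scores = self.svc_.decision_function(X).reshape(-1, 1)
        return self.sigmoid_.predict_proba(scores)

    def predict(self, X):
        pos = int(np.nonzero(self.classes_ == self.classes_.max())[0][0])
        return np.where(
            self.predict_proba(X)[:, pos] >= 0.5,
            self.classes_.max(),
            self.classes_.min(),
        )


def build_classifier(key: str, params: dict, seed: int):
    """Instantiate one of the six algorithms from a hyperparameter dict."""
    if key == "LR":
        # lasso (l1) vs ridge (l2) expressed through l1_ratio
        l1_ratio = 1.0 if params.get("penalty", "l2") == "l1" else 0.0
        return LogisticRegression(
            l1_ratio=l1_ratio,
            C=params.get("C", 1.0),
            solver="liblinear",
            random_state=seed,
            max_iter=1000,
        )
    if key == "SVM":
        # probabilities via a Platt-calibrated decision function
        svc = SVC(
            kernel=params.get("kernel", "rbf"),
            C=params.get("C", 1.0),
            gamma=params.get("gamma", "scale"),
            random_state=seed,
        )
        return PlattSVC(svc)
    if key == "RF":
        return RandomForestClassifier(
            min_samples_split=params.get("min_samples_split", 2),
            max_depth=params.get("max_depth"),
            n_estimators=params.get("n_estimators", 200),
            random_state=seed,
            n_jobs=1,
        )
    if key == "XGB":
        return XGBClassifier(
            gamma=params.get("gamma", 0.0),
            learning_rate=params.get("learning_rate", 0.1),
            n_estimators=params.get("n_estimators", 200),
            min_child_weight=0,  # allow splits on very small node populations
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    if key == "GNB":
        return GaussianNB(var_smoothing=params.get("var_smoothing", 1e-9))
    if key == "MLP":
        layers = tuple(
            [params.get("n_neurons", 32)] * params.get("n_hidden_layers", 1)
        )
        return MLPClassifier(
            hidden_layer_sizes=layers,
            alpha=params.get("alpha", 1e-4),
            max_iter=params.get("max_iter", 500),
            solver="adam",
            activation="relu",
            random_state=seed,
        )
    raise KeyError(f"unknown algorithm key {key!r}")


def _as_feature_matrix(X, feature_names: Optional[List[str]] = None) -> np.ndarray:
    """Validate and extract the 12-feature matrix in canonical column order."""
    expected = list(feature_names or FEATURE_COLUMNS)
    if isinstance(X, pd.DataFrame):
        missing = [c for c in expected if c not in X.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        mat = X[expected].to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != len(expected):
            raise ValueError(
                f"expected a 2-D array with {len(expected)} feature columns"
            )
    if np.isnan(mat).any():
        bad = sorted(set(np.nonzero(np.isnan(mat))[0].tolist()))
        raise ValueError(f"NaN features in rows {bad[:20]}")
    return mat


class OperonPairSuite(BaseEstimator, ClassifierMixin):
    """Six-classifier suite for operon-pair calling.

    Parameters
    ----------
    optimize : bool
        Run Bayesian hyperparameter optimization per algorithm before the
        final fit. Off by default; documented defaults are used instead.
    optimizer : {"gp", "random"}
        Surrogate-based optimization or random search over the same spaces.
    n_opt_iterations, cv_folds : int
        Optimization budget and stratified CV folds for the objective.
    vote_threshold : int
        Number of positive algorithm calls required for ``predict`` to
        return 1 (1..6).
    random_state : int
        Seed for all stochastic components.

    Attributes
    ----------
    scaler_ : fitted MinMaxScaler (applied to all algorithms except RF/XGB)
    models_ : dict of the six fitted classifiers keyed LR/SVM/RF/XGB/MLP/GNB
    hyperparameters_ : per-algorithm hyperparameters used for the final fit
    feature_names_ : canonical feature column order, validated on predict
    """

    def __init__(
        self,
        optimize: bool = False,
        optimizer: str = "gp",
        n_opt_iterations: int = 10,
        cv_folds: int = 10,
        vote_threshold: int = 3,
        random_state: int = DEFAULT_SEED,
    ):
        self.optimize = optimize
        self.optimizer = optimizer
        self.n_opt_iterations = n_opt_iterations
        self.cv_folds = cv_folds
        self.vote_threshold = vote_threshold
        self.random_state = random_state

    def fit(self, X, y):
        mat = _as_feature_matrix(X)
        y = np.asarray(y, dtype=int)
        if mat.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        self.classes_ = np.unique(y)
        self.feature_names_ = list(FEATURE_COLUMNS)
        self.n_features_in_ = mat.shape[1]
        self.scaler_ = MinMaxScaler().fit(mat)
        scaled = self.scaler_.transform(mat)
        self.hyperparameters_ = {}
        self.models_ = {}
        for key in ALGORITHM_KEYS:
            Xk = scaled if key in SCALED_ALGORITHMS else mat
            if self.optimize:
                params = optimize_hyperparameters(
                    key,
                    Xk,
                    y,
                    space=SEARCH_SPACES[key],
                    n_iterations=self.n_opt_iterations,
                    cv_folds=self.cv_folds,
                    seed=self.random_state,
                    method=self.optimizer,
                )
            else:
                params = dict(DEFAULT_HYPERPARAMETERS[key])
            clf = build_classifier(key, params, self.random_state)
            clf.fit(Xk, y)
            self.hyperparameters_[key] = params
            self.models_[key] = clf
        return self

    def _matrices(self, X):
        check_is_fitted(self, "models_")
        mat = _as_feature_matrix(X, self.feature_names_)
        return mat, self.scaler_.transform(mat)

    def predict_proba_suite(self, X) -> pd.DataFrame:
        """Positive-class probability per algorithm (columns keyed LR..GNB)."""
        mat, scaled = self._matrices(X)
        out = {}
        for key in ALGORITHM_KEYS:
            Xk = scaled if key in SCALED_ALGORITHMS else mat
            clf = self.models_[key]
            pos = int(np.nonzero(clf.classes_ == 1)[0][0])
            out[key] = clf.predict_proba(Xk)[:, pos]
        return pd.DataFrame(out, columns=list(ALGORITHM_KEYS))

    def predict_calls(self, X) -> pd.DataFrame:
        """Binary call per algorithm: 1 iff probability >= 0.5."""
        probs = self.predict_proba_suite(X)
        return (probs >= 0.5).astype(int)

    def vote_counts(self, X) -> np.ndarray:
        return self.predict_calls(X).to_numpy().sum(axis=1)

    def predict(self, X) -> np.ndarray:
        """Ensemble call at ``vote_threshold`` positive algorithms."""
        return (self.vote_counts(X) >= self.vote_threshold).astype(int)

    def predict_proba(self, X) -> np.ndarray:
        """Mean positive-class probability across the six algorithms."""
        p = self.predict_proba_suite(X).to_numpy().mean(axis=1)
        return np.column_stack([1 - p, p])


def train_suite(
    features: pd.DataFrame,
    labels: Optional[Iterable[int]] = None,
    optimize: bool = False,
    seed: int = DEFAULT_SEED,
    **kwargs,
) -> OperonPairSuite:
    """Fit a suite from a feature table (labels default to its label column)."""
    if labels is None:
        if "label" not in features.columns:
            raise ValueError("no labels given and feature table has no label column")
        labels = features["label"].to_numpy()
    suite = OperonPairSuite(optimize=optimize, random_state=seed, **kwargs)
    return suite.fit(features, np.asarray(list(labels), dtype=int))


def predict_suite(suite: OperonPairSuite, features: pd.DataFrame) -> pd.DataFrame:
    """Per-pair predictions: one row per feature row with per-algorithm
    calls and probabilities (prediction table format)."""
    if len(features) == 0:
        cols = ["pair_id", "sample_id"]
        cols += [f"call_{k}" for k in ALGORITHM_KEYS]
        cols += [f"prob_{k}" for k in ALGORITHM_KEYS]
        return pd.DataFrame(columns=cols)
    probs = suite.predict_proba_suite(features)
    calls = (probs >= 0.5).astype(int)
    out = pd.DataFrame(
        {
            "pair_id": features["pair_id"].to_numpy(),
            "sample_id": features["sample_id"].to_numpy(),
        }
    )
    for key in ALGORITHM_KEYS:
        out[f"call_{key}"] = calls[key].to_numpy()
    for key in ALGORITHM_KEYS:
        out[f"prob_{key}"] = probs[key].to_numpy()
    return out


_META_FILE = "suite.json"


def save_suite(suite: OperonPairSuite, path) -> None:
    """Persist a fitted suite as a directory: JSON metadata + joblib blobs."""
    check_is_fitted(suite, "models_")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": 1,
        "feature_names": suite.feature_names_,
        "hyperparameters": {
            k: {kk: vv for kk, vv in v.items()} for k, v in suite.hyperparameters_.items()
        },
        "random_state": suite.random_state,
        "vote_threshold": suite.vote_threshold,
        "optimize": suite.optimize,
    }
    (path / _META_FILE).write_text(json.dumps(meta, indent=2, default=str) + "\n")
    joblib.dump(suite.scaler_, path / "scaler.joblib")
    for key, clf in suite.models_.items():
        joblib.dump(clf, path / f"model_{key}.joblib")


def load_suite(path) -> OperonPairSuite:
    path = Path(path)
    meta = json.loads((path / _META_FILE).read_text())
    suite = OperonPairSuite(
        optimize=meta["optimize"],
        vote_threshold=meta["vote_threshold"],
        random_state=meta["random_state"],
    )
    suite.feature_names_ = meta["feature_names"]
    suite.n_features_in_ = len(suite.feature_names_)
    suite.hyperparameters_ = meta["hyperparameters"]
    suite.classes_ = np.array([0, 1])
    suite.scaler_ = joblib.load(path / "scaler.joblib")
    suite.models_ = {
        key: joblib.load(path / f"model_{key}.joblib") for key in ALGORITHM_KEYS
    }
    return suite


# Thin functional wrappers over the scaler, mirroring fit/transform.
def fit_scaler(features) -> MinMaxScaler:
    return MinMaxScaler().fit(_as_feature_matrix(features))


def apply_scaler(scaler: MinMaxScaler, features) -> np.ndarray:
    return scaler.transform(_as_feature_matrix(features))
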