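"""Registry of the 12 base-learner families behind one contract.

Each learner is tuned by randomized search (default 20 draws) with an
internal stratified 3-fold cross-validation on the rows it is given,
scored by G-mean at the 0.5 probability threshold, then refit on all
rows.  Every fitted learner emits class-1 (resistant) probabilities;
SVMs use Platt sigmoid calibration fitted on internal folds
(``SVC(probability=True)``) so the probability contract is uniform.

The roster covers linear (LR), distance-based (KNN, SVM), tree-based
(DT, RF, ExtraTrees, BalancedRF) and boosting (AdaBoost,
GradientBoosting, XGBoost, LGBM, CatBoost) paradigms.  CatBoost is
registered but only available when the optional ``catboost`` package is
installed; the grid shrinks (with a logged warning) otherwise.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import loguniform, randint
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort_io import log_stage

try:  # optional learner backend
    from catboost import CatBoostClassifier
    HAS_CATBOOST = True
except ImportError:  # pragma: no cover - environment dependent
    CatBoostClassifier = None
    HAS_CATBOOST = False

import lightgbm as lgb
import xgboost as xgb


@contextmanager
def _quiet_fit():
    """Silence chatty backend warnings (feature-name checks, deprecation
    notices) during the thousands of fits a grid evaluation performs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", FutureWarning)
        yield


class BalancedRandomForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest over balanced bootstrap samples.

    Each tree is trained on a bootstrap of the minority class plus an
    equally sized random draw (with replacement) from the majority class,
    so every tree sees a 1:1 class mix.
    """

    def __init__(self, n_estimators: int = 100, max_depth: int | None = None,
                 max_features: str | float = "sqrt", random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        counts = np.bincount(y_enc)
        minority = int(np.argmin(counts))
        n_min = int(counts[minority])
        idx_by_class = [np.flatnonzero(y_enc == c) for c in range(len(counts))]
        self.estimators_ = []
        for t in range(self.n_estimators):
            rows = np.concatenate([
                rng.choice(idx, size=n_min, replace=True)
                for idx in idx_by_class
            ])
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(X[rows], y_enc[rows])
            self.estimators_.append(tree)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros((len(X), len(self.classes_)))
        for tree in self.estimators_:
            proba = tree.predict_proba(X)
            out[:, tree.classes_] += proba
        return out / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class LearnerSpec:
    """One learner family: estimator factory plus a search space."""

    learner_id: str
    factory: Any
    search_space: dict[str, Any]
    available: bool = True


def _registry() -> dict[str, LearnerSpec]:
    depth = randint(2, 11)
    n_est = randint(50, 301)
    lr_rate = loguniform(1e-3, 10 ** 0.5)
    specs = {
        "AdaBoost": LearnerSpec(
            "AdaBoost",
            lambda seed: AdaBoostClassifier(random_state=seed),
            {"n_estimators": n_est, "learning_rate": lr_rate}),
        "BalancedRF": LearnerSpec(
            "BalancedRF",
            lambda seed: BalancedRandomForestClassifier(random_state=seed),
            {"n_estimators": n_est, "max_depth": depth}),
        "CatBoost": LearnerSpec(
            "CatBoost",
            (lambda seed: CatBoostClassifier(
                random_seed=seed, verbose=0, allow_writing_files=False))
            if HAS_CATBOOST else None,
            {"iterations": n_est, "depth": randint(2, 9),
             "learning_rate": loguniform(1e-3, 0.3)},
            available=HAS_CATBOOST),
        "DT": LearnerSpec(
            "DT",
            lambda seed: DecisionTreeClassifier(random_state=seed),
            {"max_depth": depth, "min_samples_leaf": randint(1, 11)}),
        "ExtraTrees": LearnerSpec(
            "ExtraTrees",
            lambda seed: ExtraTreesClassifier(random_state=seed, n_jobs=1),
            {"n_estimators": n_est, "max_depth": depth}),
        "GradientBoosting": LearnerSpec(
            "GradientBoosting",
            lambda seed: GradientBoostingClassifier(random_state=seed),
            {"n_estimators": n_est, "max_depth": randint(2, 6),
             "learning_rate": lr_rate}),
        "KNN": LearnerSpec(
            "KNN",
            lambda seed: KNeighborsClassifier(),
            {"n_neighbors": randint(3, 16),
             "weights": ["uniform", "distance"]}),
        "LGBM": LearnerSpec(
            "LGBM",
            lambda seed: lgb.LGBMClassifier(random_state=seed, n_jobs=1,
                                            verbose=-1),
            {"n_estimators": n_est, "max_depth": depth,
             "learning_rate": loguniform(1e-3, 0.3),
             "min_child_samples": randint(2, 21)}),
        "LR": LearnerSpec(
            "LR",
            lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
            {"C": loguniform(1e-3, 1e2)}),
        "RF": LearnerSpec(
            "RF",
            lambda seed: RandomForestClassifier(random_state=seed, n_jobs=1),
            {"n_estimators": n_est, "max_depth": depth}),
        "SVM": LearnerSpec(
            "SVM",
            lambda seed: SVC(probability=True, random_state=seed),
            {"C": loguniform(1e-2, 1e2), "gamma": loguniform(1e-3, 1e1)}),
        "XGBoost": LearnerSpec(
            "XGBoost",
            lambda seed: xgb.XGBClassifier(random_state=seed, n_jobs=1,
                                           eval_metric="logloss",
                                           verbosity=0),
            {"n_estimators": n_est, "max_depth": randint(2, 9),
             "learning_rate": loguniform(1e-3, 0.3)}),
    }
    return specs


LEARNERS: dict[str, LearnerSpec] = _registry()
LEARNER_IDS: list[str] = sorted(LEARNERS)


def available_learners() -> list[str]:
    return [lid for lid in LEARNER_IDS if LEARNERS[lid].available]


def _gmean_at_half(y_true: np.ndarray, proba: np.ndarray) -> float:
    pred = (proba > 0.5).astype(int)
    pos = y_true == 1
    neg = ~pos
    sens = float(np.mean(pred[pos] == 1)) if pos.any() else 0.0
    spec = float(np.mean(pred[neg] == 0)) if neg.any() else 0.0
    return float(np.sqrt(sens * spec))


@dataclass
class FittedLearner:
    """A tuned, refit learner bound to its training feature indices."""

    learner_id: str
    params: dict[str, Any]
    estimator: Any
    feature_indices: np.ndarray
    inner_gmean: float = 0.0
    feature_names: list[str] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability for rows of the FULL feature matrix."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] == len(self.feature_indices):
            Xs = X
        else:
            Xs = X[:, self.feature_indices]
        with _quiet_fit():
            proba = self.estimator.predict_proba(Xs)
        col = int(np.flatnonzero(np.asarray(self.estimator.classes_) == 1)[0])
        return np.clip(proba[:, col], 0.0, 1.0)


def tune_and_fit(learner_id: str, X: np.ndarray, y: np.ndarray,
                 feature_indices: np.ndarray | None = None,
                 n_iter: int = 20, inner_folds: int = 3,
                 seed: int = 0,
                 feature_names: list[str] | None = None) -> FittedLearner:
    """Randomized-search tuning with stratified inner CV, then refit.

    Candidate draws are scored by mean inner-fold G-mean of the 0.5-
    thresholded probabilities; the best (ties to the earlier draw) is
    refit on all provided rows.  Only the rows passed in are ever touched,
    which keeps the outer validation fold unseen.
    """
    spec = LEARNERS.get(learner_id)
    if spec is None:
        raise KeyError(f"unknown learner {learner_id!r}")
    if not spec.available:
        raise RuntimeError(f"learner {learner_id!r} backend not installed")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set")
    if feature_indices is None:
        feature_indices = np.arange(X.shape[1])
    Xs = X[:, feature_indices]

    candidates = list(ParameterSampler(spec.search_space, n_iter=n_iter,
                                       random_state=seed))
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(Xs, y))

    best_params, best_score = None, -np.inf
    with _quiet_fit():
        for params in candidates:
            scores = []
            for tr, te in splits:
                est = clone(spec.factory(seed))
                est.set_params(**params)
                est.fit(Xs[tr], y[tr])
                col = int(np.flatnonzero(np.asarray(est.classes_) == 1)[0])
                proba = est.predict_proba(Xs[te])[:, col]
                scores.append(_gmean_at_half(y[te], proba))
            mean_score = float(np.mean(scores))
            if mean_score > best_score:
                best_params, best_score = params, mean_score

        final = clone(spec.factory(seed))
        final.set_params(**best_params)
        final.fit(Xs, y)
    log_stage("tune_and_fit", learner=learner_id, inner_gmean=round(best_score, 4))
    return FittedLearner(
        learner_id=learner_id, params=dict(best_params), estimator=final,
        feature_indices=np.asarray(feature_indices, dtype=int),
        inner_gmean=best_score,
        feature_names=list(feature_names) if feature_names else [])


def predict_proba(model: FittedLearner, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)
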