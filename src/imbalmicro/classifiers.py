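"""Seven classifier backends behind a uniform fit / predict / score contract.

The backends are ordinary scikit-learn estimators plus XGBoost; everything
around them (folds, augmentation, metrics, hyperparameter selection) is
implemented in :mod:`imbalmicro.evaluate`. Scores are always oriented so
that larger means "more smoker-like" (the positive class, label 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.stats import loguniform
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

__all__ = ["ClassifierSpec", "FittedBackend", "default_specs", "CLASSIFIER_NAMES"]

CLASSIFIER_NAMES = ("LR", "KNN", "SVML", "SVMR", "DT", "RF", "XGBoost")

POSITIVE_LABEL = 0  # smoker; the minority class the study focuses on


@dataclass
class FittedBackend:
    """A fitted estimator with smoker-oriented scoring."""

    estimator: Any
    positive_label: int = POSITIVE_LABEL

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))

    def score_positive(self, X: np.ndarray) -> np.ndarray:
        """Continuous score per sample; larger = more likely positive (smoker)."""
        est = self.estimator
        classes = list(est.classes_)
        pos = classes.index(self.positive_label)
        if hasattr(est, "predict_proba"):
            return np.asarray(est.predict_proba(X))[:, pos]
        score = np.asarray(est.decision_function(X))
        # decision_function is oriented toward classes_[1]
        return score if pos == 1 else -score


@dataclass(frozen=True)
class ClassifierSpec:
    """A named backend plus its randomized-search space.

    ``search_space`` maps hyperparameter names to either a list of candidate
    values or a scipy frozen distribution (anything with ``.rvs``).
    """

    name: str
    builder: Callable[..., Any]
    search_space: dict[str, Any] = field(default_factory=dict)
    n_search_iterations: int = 30

    def __post_init__(self) -> None:
        if not self.search_space:
            raise ValueError(f"search space for {self.name} must be non-empty")

    def sample_params(self, rng: np.random.Generator) -> dict[str, Any]:
        params: dict[str, Any] = {}
        for key, spec in self.search_space.items():
            if hasattr(spec, "rvs"):
                params[key] = spec.rvs(random_state=int(rng.integers(2**31 - 1)))
            else:
                params[key] = spec[rng.integers(len(spec))]
        return params

    def fit(
        self, X: np.ndarray, y: np.ndarray, params: dict[str, Any], seed: int
    ) -> FittedBackend:
        est = self.builder(random_state=seed, **params)
        est.fit(X, y)
        return FittedBackend(est)


def _build_lr(random_state: int, **p: Any) -> LogisticRegression:
    return LogisticRegression(solver="liblinear", max_iter=2000, random_state=random_state, **p)


def _build_knn(random_state: int, **p: Any) -> KNeighborsClassifier:
    return KNeighborsClassifier(**p)  # deterministic; no seed


def _build_svml(random_state: int, **p: Any) -> LinearSVC:
    return LinearSVC(max_iter=5000, random_state=random_state, **p)


def _build_svmr(random_state: int, **p: Any) -> SVC:
    return SVC(kernel="rbf", random_state=random_state, **p)


def _build_dt(random_state: int, **p: Any) -> DecisionTreeClassifier:
    return DecisionTreeClassifier(random_state=random_state, **p)


def _build_rf(random_state: int, **p: Any) -> RandomForestClassifier:
    return RandomForestClassifier(n_jobs=1, random_state=random_state, **p)


def _build_xgb(random_state: int, **p: Any) -> XGBClassifier:
    return XGBClassifier(
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
        random_state=random_state,
        **p,
    )


def default_specs(
    names: tuple[str, ...] | list[str] = CLASSIFIER_NAMES,
    n_search_iterations: int = 30,
) -> list[ClassifierSpec]:
    """The seven evaluated backends with editable default search spaces."""
    all_specs = {
        "LR": ClassifierSpec(
            "LR", _build_lr, {"C": loguniform(1e-4, 1e4)}, n_search_iterations
        ),
        "KNN": ClassifierSpec(
            "KNN",
            _build_knn,
            {
                "n_neighbors": [1, 3, 5, 7, 11, 15, 21, 31],
                "weights": ["uniform", "distance"],
            },
            n_search_iterations,
        ),
        "SVML": ClassifierSpec(
            "SVML", _build_svml, {"C": loguniform(1e-4, 1e4)}, n_search_iterations
        ),
        "SVMR": ClassifierSpec(
            "SVMR",
            _build_svmr,
            {"C": loguniform(1e-2, 1e4), "gamma": loguniform(1e-4, 1e1)},
            n_search_iterations,
        ),
        "DT": ClassifierSpec(
            "DT",
            _build_dt,
            {
                "max_depth": [2, 3, 5, 8, 12, None],
                "min_samples_leaf": [1, 2, 5, 10, 20],
            },
            n_search_iterations,
        ),
        "RF": ClassifierSpec(
            "RF",
            _build_rf,
            {
                "n_estimators": [100, 200],
                "max_depth": [3, 6, 12, None],
                "max_features": ["sqrt", 0.3, 0.6],
            },
            n_search_iterations,
        ),
        "XGBoost": ClassifierSpec(
            "XGBoost",
            _build_xgb,
            {
                "n_estimators": [50, 100, 200],
                "max_depth": [2, 3, 5, 8],
                "learning_rate": loguniform(1e-2, 0.5),
                "subsample": [0.6, 0.8, 1.0],
            },
            n_search_iterations,
        ),
    }
    unknown = [n for n in names if n not in all_specs]
    if unknown:
        raise ValueError(f"unknown classifier name(s): {unknown}")
    return [all_specs[n] for n in names]
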