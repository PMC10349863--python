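"""Signature-based disease-stage classification.

A thin, reproducible wrapper around sklearn learners: stratified 70/30
discovery/validation split, hyperparameters chosen by repeated 5-fold
cross-validation on the discovery set, AUC on the held-out set (binary, or
macro one-vs-rest for three stages) and model-agnostic permutation
importances computed on the held-out set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedStratifiedKFold,
    train_test_split,
)

LEARNERS = ("boosted_trees", "random_forest", "multinomial_logit")


def _make_learner(name: str, seed: int):
    if name == "boosted_trees":
        est = GradientBoostingClassifier(random_state=seed)
        grid = {"n_estimators": [100, 200], "max_depth": [2, 3]}
    elif name == "random_forest":
        est = RandomForestClassifier(random_state=seed)
        grid = {"n_estimators": [200, 500], "max_features": ["sqrt", None]}
    elif name == "multinomial_logit":
        est = LogisticRegression(max_iter=5000, random_state=seed)
        grid = {"C": [0.1, 1.0, 10.0]}
    else:
        raise ValueError(f"unknown learner {name!r}; choose from {LEARNERS}")
    return est, grid


@dataclass
class StageModelReport:
    """Held-out performance and ranked permutation importances."""

    auc: dict[str, float]  # comparison label -> AUC
    importances: pd.Series  # mean decrease in score, descending
    confusion: pd.DataFrame
    cv_config: dict = field(default_factory=dict)
    best_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "importances": self.importances.round(6).to_dict(),
            "confusion": self.confusion.to_dict(),
            "cv_config": self.cv_config,
            "best_params": {k: str(v) for k, v in self.best_params.items()},
        }


class StageClassifier(BaseEstimator, ClassifierMixin):
    """Disease-stage classifier over signature/clonality features.

    Parameters mirror the study design: ``split`` 0.70/0.30 discovery/
    validation, ``cv_folds`` 5 and ``cv_iters`` repeats of the CV used for
    hyperparameter selection. ``fit`` performs the whole protocol and
    stores a :class:`StageModelReport` in ``report_``.
    """

    def __init__(
        self,
        learner: str = "boosted_trees",
        split: float = 0.70,
        cv_folds: int = 5,
        cv_iters: int = 100,
        seed: int = 0,
        n_permutations: int = 20,
    ):
        self.learner = learner
        self.split = split
        self.cv_folds = cv_folds
        self.cv_iters = cv_iters
        self.seed = seed
        self.n_permutations = n_permutations

    def fit(self, X: pd.DataFrame, y) -> "StageClassifier":
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y), index=X.index)
        classes = sorted(y.unique())
        if len(classes) < 2:
            raise ValueError("stage classification needs at least 2 classes")
        min_per_class = y.value_counts().min()
        if min_per_class < max(self.cv_folds, 4):
            raise ValueError(
                f"smallest class has {min_per_class} samples; reduce cv_folds or "
                "provide >= 20 samples per class"
            )
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=self.split, stratify=y, random_state=self.seed
        )
        est, grid = _make_learner(self.learner, self.seed)
        cv = RepeatedStratifiedKFold(
            n_splits=self.cv_folds, n_repeats=self.cv_iters, random_state=self.seed
        )
        search = GridSearchCV(est, grid, cv=cv, scoring="roc_auc_ovr", n_jobs=1)
        search.fit(X_tr.to_numpy(), y_tr.to_numpy())
        self.model_ = search.best_estimator_
        self.classes_ = np.array(classes)

        proba = self.model_.predict_proba(X_te.to_numpy())
        auc: dict[str, float] = {}
        if len(classes) == 2:
            auc[f"{classes[0]}_vs_{classes[1]}"] = float(
                roc_auc_score((y_te == classes[1]).astype(int), proba[:, 1])
            )
        else:
            auc["macro_ovr"] = float(
                roc_auc_score(y_te, proba, multi_class="ovr", average="macro")
            )
            for i, cls in enumerate(self.model_.classes_):
                auc[f"{cls}_vs_rest"] = float(
                    roc_auc_score((y_te == cls).astype(int), proba[:, i])
                )
        perm = permutation_importance(
            self.model_,
            X_te.to_numpy(),
            y_te.to_numpy(),
            n_repeats=self.n_permutations,
            random_state=self.seed,
            scoring="roc_auc_ovr" if len(classes) > 2 else "roc_auc",
        )
        importances = pd.Series(
            perm.importances_mean, index=X.columns, name="permutation_importance"
        ).sort_values(ascending=False)
        pred = self.model_.predict(X_te.to_numpy())
        confusion = pd.crosstab(
            pd.Series(y_te.to_numpy(), name="true"), pd.Series(pred, name="predicted")
        ).reindex(index=classes, columns=classes, fill_value=0)
        self.report_ = StageModelReport(
            auc=auc,
            importances=importances,
            confusion=confusion,
            cv_config={
                "split": self.split,
                "cv_folds": self.cv_folds,
                "cv_iters": self.cv_iters,
                "learner": self.learner,
                "seed": self.seed,
            },
            best_params=search.best_params_,
        )
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(np.asarray(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(np.asarray(X))


def train_stage_model(
    features: pd.DataFrame,
    labels,
    learner: str = "boosted_trees",
    split: float = 0.70,
    cv_folds: int = 5,
    cv_iters: int = 100,
    seed: int = 0,
) -> StageModelReport:
    """Run the full train/validate protocol and return its report."""
    clf = StageClassifier(
        learner=learner, split=split, cv_folds=cv_folds, cv_iters=cv_iters, seed=seed
    ).fit(features, labels)
    return clf.report_
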