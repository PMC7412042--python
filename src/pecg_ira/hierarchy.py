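"""Angiography-mimicking hierarchical localization of the culprit artery.

Four binary classifiers arranged like a catheter working down the
coronary tree:

  L1  healthy control (HC) vs myocardial infarction (MI)
  L2  location-indiscernible (E) vs localizable left/right (LR)
  L3  left coronary branches (LAD, LCX) vs right coronary artery (RCA)
  L4  left anterior descending (LAD) vs left circumflex (LCX)

Each level can use any of five interchangeable base models (CART, SVM,
KNN, NN, BET) and is trained on the subset of samples its question
applies to, with Borderline-SMOTE balancing applied inside the training
data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .selection import BorderlineSMOTE

CLASS_LABELS = ("HC", "E", "LAD", "LCX", "RCA")
LEVEL_NAMES = ("L1", "L2", "L3", "L4")

#: per level: (positive class, negative class, labels the question applies to)
LEVEL_DEFS = {
    "L1": ("HC", "MI", ("HC", "E", "LAD", "LCX", "RCA")),
    "L2": ("E", "LR", ("E", "LAD", "LCX", "RCA")),
    "L3": ("LCA", "RCA", ("LAD", "LCX", "RCA")),
    "L4": ("LAD", "LCX", ("LAD", "LCX")),
}


def _level_target(level: str, labels: np.ndarray) -> np.ndarray:
    if level == "L1":
        return np.where(labels == "HC", "HC", "MI")
    if level == "L2":
        return np.where(labels == "E", "E", "LR")
    if level == "L3":
        return np.where(labels == "RCA", "RCA", "LCA")
    return labels.astype(str)  # L4: LAD vs LCX directly


def base_model_registry(name: str, seed: int = 0, **params):
    """Factory for the five supported base classifiers.

    Distance-based models (SVM, KNN, NN) are wrapped with a standard
    scaler because the octant features span several orders of magnitude.
    """
    makers = {
        "CART": lambda: DecisionTreeClassifier(
            random_state=seed, **({"max_depth": None} | params)
        ),
        "SVM": lambda: make_pipeline(
            StandardScaler(), SVC(random_state=seed, **({"C": 10.0} | params))
        ),
        "KNN": lambda: make_pipeline(
            StandardScaler(), KNeighborsClassifier(**({"n_neighbors": 5} | params))
        ),
        "NN": lambda: make_pipeline(
            StandardScaler(),
            MLPClassifier(
                random_state=seed,
                **({"hidden_layer_sizes": (32,), "max_iter": 2000} | params),
            ),
        ),
        "BET": lambda: BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            random_state=seed,
            **({"n_estimators": 50} | params),
        ),
    }
    try:
        return makers[name]()
    except KeyError:
        raise ValueError(
            f"unknown base model {name!r}; supported: {sorted(makers)}"
        ) from None


class UntrainableLevelError(ValueError):
    def __init__(self, level: str, message: str):
        self.level = level
        super().__init__(f"{level}: {message}")


class HierarchicalIRAClassifier(ClassifierMixin, BaseEstimator):
    """Four-level hierarchical classifier over {HC, E, LAD, LCX, RCA}.

    Parameters
    ----------
    level_models : tuple of 4 base-model names, one per level. The
        default (CART, SVM, SVM, SVM) uses a decision tree for MI
        detection and support vector machines for localization.
    balance : apply Borderline-SMOTE to each level's training subset.
    level_features : optional mapping level -> list of feature columns,
        overriding the full matrix per level.
    """

    def __init__(
        self,
        level_models: tuple = ("CART", "SVM", "SVM", "SVM"),
        balance: bool = True,
        k_neighbors: int = 5,
        level_features: dict | None = None,
        model_params: dict | None = None,
        random_state: int = 0,
        allow_missing_levels: bool = False,
    ):
        self.level_models = level_models
        self.balance = balance
        self.k_neighbors = k_neighbors
        self.level_features = level_features
        self.model_params = model_params
        self.random_state = random_state
        self.allow_missing_levels = allow_missing_levels

    # -- helpers -----------------------------------------------------------

    def _columns(self, X: pd.DataFrame, level: str):
        if self.level_features and level in self.level_features:
            return list(self.level_features[level])
        return list(X.columns)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        return X.reset_index(drop=True) if isinstance(X, pd.DataFrame) else pd.DataFrame(X)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y) -> "HierarchicalIRAClassifier":
        X = self._as_frame(X)
        y = np.asarray(y, dtype=object).astype(str)
        unknown = set(y) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")

        self.classifiers_ = {}
        self.level_columns_ = {}
        for level, model_name in zip(LEVEL_NAMES, self.level_models):
            _, _, applicable = LEVEL_DEFS[level]
            mask = np.isin(y, applicable)
            target = _level_target(level, y[mask])
            present = np.unique(target)
            if len(present) < 2:
                if self.allow_missing_levels:
                    continue
                raise UntrainableLevelError(
                    level, f"only one class ({present.tolist()}) present"
                )
            cols = self._columns(X, level)
            xs = X.loc[mask, cols]
            if self.balance:
                k = min(self.k_neighbors, int(pd.Series(target).value_counts().min()) - 1)
                if k >= 1:
                    balanced = BorderlineSMOTE(
                        k_neighbors=k, random_state=self.random_state
                    ).fit_resample(xs, target)
                    xs, target = balanced.features, balanced.labels
            params = (self.model_params or {}).get(level, {})
            clf = base_model_registry(model_name, seed=self.random_state, **params)
            clf.fit(xs.to_numpy(float), target)
            self.classifiers_[level] = clf
            self.level_columns_[level] = cols
        self.classes_ = np.array(CLASS_LABELS)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.array(X.columns, dtype=object)
        return self

    def _decide(self, level: str, row: pd.DataFrame) -> str:
        if level not in self.classifiers_:
            raise UntrainableLevelError(
                level, "level was not trained (class absent in training data)"
            )
        cols = self.level_columns_[level]
        return str(self.classifiers_[level].predict(row[cols].to_numpy(float))[0])

    def predict_with_paths(self, X):
        """Predict labels and return the audited per-level decision path."""
        if not hasattr(self, "classifiers_"):
            raise ValueError("classifier is not fitted")
        X = self._as_frame(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        labels, paths = [], []
        for i in range(len(X)):
            row = X.iloc[[i]]
            path = {}
            path["L1"] = self._decide("L1", row)
            if path["L1"] == "HC":
                labels.append("HC")
            else:
                path["L2"] = self._decide("L2", row)
                if path["L2"] == "E":
                    labels.append("E")
                else:
                    path["L3"] = self._decide("L3", row)
                    if path["L3"] == "RCA":
                        labels.append("RCA")
                    else:
                        path["L4"] = self._decide("L4", row)
                        labels.append(path["L4"])
            paths.append(path)
        return np.array(labels), paths

    def predict(self, X) -> np.ndarray:
        labels, _ = self.predict_with_paths(X)
        return labels


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-level accuracies (percent) over folds x repeats."""

    accuracies: dict[str, np.ndarray]       # level -> per-fold percents
    confusion: dict[str, np.ndarray]        # level -> summed 2x2 matrix
    folds: int
    repeats: int
    seed: int

    def mean(self, level: str) -> float:
        a = self.accuracies[level]
        return float(np.nanmean(a)) if len(a) else float("nan")

    def sd(self, level: str) -> float:
        a = self.accuracies[level]
        return float(np.nanstd(a)) if len(a) else float("nan")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(LEVEL_NAMES),
                "accuracy_mean": [self.mean(l) for l in LEVEL_NAMES],
                "accuracy_sd": [self.sd(l) for l in LEVEL_NAMES],
            }
        )

    def to_dict(self) -> dict:
        return {
            level: {"mean": self.mean(level), "sd": self.sd(level)}
            for level in LEVEL_NAMES
        }


def cross_validate(
    features,
    labels,
    model: HierarchicalIRAClassifier | None = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated stratified k-fold evaluation of every hierarchy level.

    Each level's accuracy is measured on the ground-truth-relevant test
    subset using that level's binary decision, so a level is never
    penalized for an upstream mistake; balancing happens inside training
    folds only.
    """
    X = HierarchicalIRAClassifier._as_frame(features)
    y = np.asarray(labels, dtype=object).astype(str)
    model = model or HierarchicalIRAClassifier()
    min_class = int(pd.Series(y).value_counts().min())
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} samples; reducing folds "
            f"from {folds} to {max(2, min_class)}",
            stacklevel=2,
        )
        folds = max(2, min_class)

    acc = {level: [] for level in LEVEL_NAMES}
    conf = {level: np.zeros((2, 2), dtype=int) for level in LEVEL_NAMES}
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in splitter.split(X, y):
            fold_model = clone(model)
            fold_model.set_params(
                random_state=model.random_state + rep, allow_missing_levels=True
            )
            fold_model.fit(X.iloc[train_idx], y[train_idx])
            for level in LEVEL_NAMES:
                pos, _, applicable = LEVEL_DEFS[level]
                mask = np.isin(y[test_idx], applicable)
                if not mask.any() or level not in fold_model.classifiers_:
                    acc[level].append(np.nan)
                    continue
                idx = test_idx[mask]
                truth = _level_target(level, y[idx])
                cols = fold_model.level_columns_[level]
                pred = fold_model.classifiers_[level].predict(
                    X.iloc[idx][cols].to_numpy(float)
                )
                acc[level].append(100.0 * float(np.mean(pred == truth)))
                neg = LEVEL_DEFS[level][1]
                for t, p in zip(truth, pred):
                    conf[level][int(t != pos), int(p != pos)] += 1
    return EvaluationReport(
        accuracies={k: np.array(v) for k, v in acc.items()},
        confusion=conf,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )
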