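"""Feature weighting, selection and class balancing.

Features are z-standardized, the correlation-matrix eigendecomposition
retains the principal components explaining a configurable fraction of
variance (default 80%), and each feature k receives the contribution
weight ``w_k = sum_i beta_i * c_ki^2`` over the retained components
(beta_i the eigenvalue, c_ki the loading). Features are then chosen as
the smallest prefix of the weight-sorted list holding a target fraction
of total weight. A random-forest Gini-importance ranking provides the
secondary cutoff, and Borderline-SMOTE (Han's Borderline-1) equalizes
class counts before classifier training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors


# --------------------------------------------------------------------------
# PCA contribution weights
# --------------------------------------------------------------------------

@dataclass
class PCAWeights:
    weights: pd.Series          # w_k per feature, original column order
    eigenvalues: np.ndarray     # all, descending
    loadings: np.ndarray        # (n_features, n_retained)
    n_components: int
    variance_fraction: float    # fraction actually retained


def pca_weights(features, variance_fraction: float = 0.80) -> PCAWeights:
    """Per-feature contribution to the retained principal components.

    Works on the correlation matrix (features are z-standardized first;
    constant columns get weight 0).
    """
    x = pd.DataFrame(features)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance fraction must be in (0, 1]")
    values = x.to_numpy(float)
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    keep = std > 0
    z = np.zeros_like(values)
    z[:, keep] = (values[:, keep] - mean[keep]) / std[keep]
    corr = (z.T @ z) / len(z)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    total = vals.sum()
    if total == 0:
        n = 1
    else:
        n = int(np.searchsorted(np.cumsum(vals) / total, variance_fraction - 1e-12) + 1)
    retained = vals[:n]
    loadings = vecs[:, :n]
    w = (loadings**2) @ retained
    w[~keep] = 0.0
    return PCAWeights(
        weights=pd.Series(w, index=x.columns),
        eigenvalues=vals,
        loadings=loadings,
        n_components=n,
        variance_fraction=float(retained.sum() / total) if total else 0.0,
    )


def select_by_weight(weights: PCAWeights, mass_fraction: float = 0.80) -> list:
    """Smallest prefix of weight-sorted features holding ``mass_fraction``
    of the total weight; ties broken by feature name for determinism."""
    if not 0 < mass_fraction <= 1:
        raise ValueError("mass fraction must be in (0, 1]")
    s = weights.weights
    ordered = sorted(s.index, key=lambda k: (-s[k], str(k)))
    total = float(s.sum())
    if total == 0:
        return list(ordered[:1])
    acc = 0.0
    chosen = []
    for name in ordered:
        chosen.append(name)
        acc += float(s[name])
        if acc >= mass_fraction * total - 1e-12:
            break
    return chosen


# --------------------------------------------------------------------------
# Gini importance
# --------------------------------------------------------------------------

@dataclass
class GiniRanking:
    ranked: list                # feature names, importance descending
    importances: pd.Series      # aligned with ranked order
    cutoff_index: int           # size of the retained head


def gini_rank(features, labels, n_trees: int = 200, seed: int = 0) -> GiniRanking:
    """Rank features by mean Gini-impurity decrease in a seeded forest.

    The cutoff falls after the largest consecutive drop in sorted
    importance (the elbow of the importance plot).
    """
    x = pd.DataFrame(features)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to rank by impurity")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(x.to_numpy(float), y)
    imp = pd.Series(forest.feature_importances_, index=x.columns)
    ordered = imp.sort_values(ascending=False, kind="stable")
    drops = ordered.to_numpy()[:-1] - ordered.to_numpy()[1:]
    cutoff = int(np.argmax(drops) + 1) if len(drops) else 1
    return GiniRanking(
        ranked=list(ordered.index),
        importances=ordered,
        cutoff_index=cutoff,
    )


# --------------------------------------------------------------------------
# Borderline-SMOTE (Borderline-1)
# --------------------------------------------------------------------------

@dataclass
class BalancedSet:
    features: pd.DataFrame
    labels: np.ndarray
    synthetic: np.ndarray   # bool flag per row
    k_neighbors: int


class BorderlineSMOTE:
    """Borderline-1 synthetic minority oversampling.

    Minority samples in "danger" (at least half but not all of their k
    nearest neighbors belong to other classes) are interpolated with
    their own-class nearest neighbors: ``x + u * (x' - x)``, u ~ U(0, 1).
    If no sample is in danger the whole minority class seeds the
    interpolation. Original rows are preserved verbatim and all class
    counts are raised to the majority count.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"k_neighbors": self.k_neighbors, "random_state": self.random_state}

    def set_params(self, **params) -> "BorderlineSMOTE":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_resample(self, X, y) -> BalancedSet:
        if self.k_neighbors < 1:
            raise ValueError("k must be >= 1")
        x = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y)
        values = x.to_numpy(float)
        counts = pd.Series(y).value_counts()
        target = int(counts.max())
        rng = np.random.default_rng(self.random_state)

        new_rows, new_labels = [], []
        for cls in sorted(counts.index, key=str):
            need = target - int(counts[cls])
            if need == 0:
                continue
            cls_idx = np.flatnonzero(y == cls)
            if len(cls_idx) < 2:
                raise ValueError(
                    f"minority class {cls!r} has fewer than 2 samples; "
                    "no segment to interpolate on"
                )
            k = min(self.k_neighbors, len(y) - 1)
            nn_all = NearestNeighbors(n_neighbors=k + 1).fit(values)
            _, neigh = nn_all.kneighbors(values[cls_idx])
            neigh = neigh[:, 1:]  # drop self
            other = (y[neigh] != cls).sum(axis=1)
            danger = (other >= k / 2.0) & (other < k)
            seeds = cls_idx[danger] if danger.any() else cls_idx

            k_min = min(self.k_neighbors, len(cls_idx) - 1)
            nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(values[cls_idx])
            _, min_neigh = nn_min.kneighbors(values[seeds])
            for _ in range(need):
                si = rng.integers(len(seeds))
                base = values[seeds[si]]
                # nearest own-class neighbors of the seed, excluding itself
                options = [
                    cls_idx[j] for j in min_neigh[si] if cls_idx[j] != seeds[si]
                ]
                partner = values[options[rng.integers(len(options))]]
                u = rng.uniform(0.0, 1.0)
                new_rows.append(base + u * (partner - base))
                new_labels.append(cls)

        if new_rows:
            extra = pd.DataFrame(new_rows, columns=x.columns)
            features = pd.concat([x, extra], ignore_index=True)
            labels = np.concatenate([y, np.array(new_labels, dtype=y.dtype)])
            synthetic = np.concatenate(
                [np.zeros(len(x), bool), np.ones(len(new_rows), bool)]
            )
        else:
            features, labels = x, y.copy()
            synthetic = np.zeros(len(x), bool)
        return BalancedSet(features, labels, synthetic, self.k_neighbors)


def borderline_smote(X, y, k: int = 5, seed: int = 0) -> BalancedSet:
    """Functional wrapper over :class:`BorderlineSMOTE`."""
    return BorderlineSMOTE(k_neighbors=k, random_state=seed).fit_resample(X, y)


class PCAContributionSelector:
    """sklearn-style selector: PCA-contribution weights + weight-mass cutoff.

    ``fit`` computes the weights on the training matrix; ``transform``
    keeps the selected columns.
    """

    def __init__(self, variance_fraction: float = 0.80, mass_fraction: float = 0.80):
        self.variance_fraction = variance_fraction
        self.mass_fraction = mass_fraction

    def get_params(self, deep: bool = True) -> dict:
        return {
            "variance_fraction": self.variance_fraction,
            "mass_fraction": self.mass_fraction,
        }

    def set_params(self, **params) -> "PCAContributionSelector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "PCAContributionSelector":
        self.weights_ = pca_weights(X, self.variance_fraction)
        self.selected_features_ = select_by_weight(self.weights_, self.mass_fraction)
        return self

    def transform(self, X) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
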