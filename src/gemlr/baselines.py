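"""Cluster-then-predict and plain elastic-net logistic baselines.

Cluster-then-predict (CP) first partitions the data by k-means on the
gate features — ignoring the outcome — then fits an independent
elastic-net logistic regression per cluster using only that cluster's
points.  Unlike GeM-LR there is no soft weighting and no borrowing of
information across clusters, which is exactly the contrast the mixture
model is designed to beat.  With C=1 both CP and GeM-LR collapse to the
same plain elastic-net logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .em_fit import _fit_logistic, _weighted_class1_frequency
from .exceptions import InfeasibleClusterError, SchemaError
from .model_core import (
    ClusterPredictor,
    FeatureRoles,
    FeatureTable,
    FrequencyHead,
    Standardizer,
    head_prob,
    validate_outcome,
)

__all__ = ["CPModel", "kmeans", "fit_cp", "fit_lr", "predict_cp"]


@dataclass
class CPModel:
    """k-means centroids plus one independent classifier per cluster."""

    centroids: np.ndarray
    heads: list[ClusterPredictor]
    roles: FeatureRoles
    standardizer: Standardizer | None
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if len(self.heads) != self.centroids.shape[0]:
            raise SchemaError("one head per centroid required")

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


def kmeans(X_G: np.ndarray, C: int, seed: int = 0, n_init: int = 5):
    """Lloyd's algorithm with k-means++ seeding, best of ``n_init`` restarts.

    Returns ``(labels, centroids)``; deterministic given ``seed``.
    """
    X_G = np.atleast_2d(np.asarray(X_G, dtype=float))
    if X_G.shape[0] < C:
        raise InfeasibleClusterError(
            C, max_feasible=X_G.shape[0],
            message=f"cannot form C={C} clusters from n={X_G.shape[0]} points")
    km = KMeans(n_clusters=C, init="k-means++", n_init=n_init,
                random_state=int(seed))
    labels = km.fit_predict(X_G)
    return labels, km.cluster_centers_


def fit_cp(table: FeatureTable, y, roles: FeatureRoles, C: int,
           lambda1: float = 0.0, lambda2: float = 0.8, seed: int = 0,
           n_init: int = 5, min_cluster_ess: float | None = None,
           head_tol: float = 1e-8, head_max_iter: int = 5000) -> CPModel:
    """Unsupervised k-means on gate features, then per-cluster classifiers.

    Each cluster's elastic-net logistic regression sees only that
    cluster's points; clusters below ``min_cluster_ess`` members (default
    |classifier features| + 1) or containing a single class get a clipped
    frequency head.  The standardizer is learned here and applied at
    prediction time, including to the k-means space.
    """
    y = validate_outcome(y, table.n)
    std = Standardizer.fit(table)
    Z = std.transform(table)
    X_G = Z.values[:, roles.gate_features]
    X_L = Z.values[:, roles.classifier_features]
    labels, centroids = kmeans(X_G, C, seed=seed, n_init=n_init)
    if min_cluster_ess is None:
        min_cluster_ess = X_L.shape[1] + 1
    heads: list[ClusterPredictor] = []
    for c in range(C):
        mask = labels == c
        n_c = int(mask.sum())
        if n_c == 0:
            heads.append(FrequencyHead(0.5))
            continue
        single_class = len(np.unique(y[mask])) < 2
        if n_c < min_cluster_ess or single_class:
            heads.append(FrequencyHead(
                _weighted_class1_frequency(y[mask], np.ones(n_c))))
            continue
        heads.append(_fit_logistic(X_L[mask], y[mask], np.ones(n_c),
                                   lambda1, lambda2, head_tol, head_max_iter))
    return CPModel(centroids=centroids, heads=heads, roles=roles,
                   standardizer=std,
                   config={"C": C, "lambda1": lambda1, "lambda2": lambda2,
                           "seed": seed})


def fit_lr(table: FeatureTable, y, roles: FeatureRoles, lambda1: float = 0.0,
           lambda2: float = 0.8, **kw) -> CPModel:
    """Plain elastic-net logistic regression (CP with a single cluster)."""
    return fit_cp(table, y, roles, C=1, lambda1=lambda1, lambda2=lambda2, **kw)


def predict_cp(x, model: CPModel, pre_standardized: bool = False):
    """Hard nearest-centroid assignment, then that cluster's head probability.

    Distances are Euclidean in standardized gate-feature space; ties go
    to the lowest centroid index.
    """
    if isinstance(x, FeatureTable):
        if model.standardizer is not None and not pre_standardized:
            x = model.standardizer.transform(x)
        V = x.values
        squeeze = False
    else:
        V = np.asarray(x, dtype=float)
        squeeze = V.ndim == 1
        V = np.atleast_2d(V)
        if model.standardizer is not None and not pre_standardized:
            V = (V - model.standardizer.mean_) / model.standardizer.scale_
    X_G = V[:, model.roles.gate_features]
    X_L = V[:, model.roles.classifier_features]
    d2 = ((X_G[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    c = np.argmin(d2, axis=1)  # argmin returns the first minimum
    out = np.array([head_prob(X_L[i], model.heads[c[i]]) for i in range(len(c))])
    return float(out[0]) if squeeze else out
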