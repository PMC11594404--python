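"""EM estimation of GeM-LR.

The latent cluster label is treated as missing data.  Fitting alternates:

* E-step: responsibilities r_ic ∝ pi_c N(x_i^G | mu_c, Sigma_c) P(y_i | x_i^L, c),
  i.e. cluster membership is informed by the outcome as well as the features;
* M-step (gate): responsibility-weighted Gaussian-mixture updates, with
  optional shrinkage towards a diagonal covariance and tied structures;
* M-step (heads): one elastic-net logistic regression per cluster fitted on
  *all* points with observation weights r_ic — small clusters borrow
  strength from the rest of the data instead of being fit in isolation.

The gate is initialized by conventional unsupervised GMM fitting (k-means
seeded, best of ``n_init`` restarts) without looking at the outcome.
Because the penalty and the Gaussian terms are separable in the complete-data
objective, each M-step maximizes its block exactly and the penalized
observed-data log likelihood is non-decreasing (up to the covariance
shrinkage/floor adjustments, which may cost a bounded amount per step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture

from .exceptions import InfeasibleClusterError, NumericalError, SchemaError
from .model_core import (
    FREQ_CLIP,
    ClusterPredictor,
    FeatureRoles,
    FeatureTable,
    FrequencyHead,
    GaussianComponent,
    GeMLRModel,
    LogisticHead,
    MixtureGate,
    Standardizer,
    complete_log_likelihood_matrix,
    elastic_net_penalty,
    gate_posterior,
    validate_outcome,
)

__all__ = [
    "FitConfig",
    "init_gate",
    "e_step",
    "m_step_gate",
    "m_step_heads",
    "regularize_covariance",
    "fit",
    "kkt_violation",
    "COVARIANCE_STRUCTURES",
]

COVARIANCE_STRUCTURES = ("full", "diagonal", "tied", "tied_diagonal")

#: relative eigenvalue floor: fraction of the mean gate-feature variance
VAR_FLOOR_FRACTION = 1e-6


@dataclass
class FitConfig:
    """Tuning knobs for one GeM-LR fit.

    ``lambda1`` scales the elastic-net penalty, ``lambda2`` blends lasso
    (1) against ridge (0); 0.8 is the package default mixing weight.
    ``shrinkage`` pulls each covariance towards its diagonal (0 = none;
    0.9 is a sensible preset for very small samples).  ``min_cluster_ess``
    is the effective-size threshold below which a cluster's classifier
    falls back to an empirical class frequency; ``None`` means
    ``len(classifier features) + 1``.
    """

    C: int = 2
    lambda1: float = 0.0
    lambda2: float = 0.8
    covariance_structure: str = "full"
    shrinkage: float = 0.0
    tol: float = 1e-6
    max_iter: int = 500
    n_init: int = 5
    seed: int = 0
    min_cluster_ess: float | None = None
    sample_weights: np.ndarray | None = None
    head_tol: float = 1e-8
    head_max_iter: int = 5000

    def __post_init__(self):
        if self.C < 1:
            raise SchemaError("C must be >= 1")
        if self.lambda1 < 0:
            raise SchemaError("lambda1 must be >= 0")
        if not 0.0 <= self.lambda2 <= 1.0:
            raise SchemaError("lambda2 must lie in [0, 1]")
        if self.covariance_structure not in COVARIANCE_STRUCTURES:
            raise SchemaError(
                f"covariance_structure must be one of {COVARIANCE_STRUCTURES}")
        if not 0.0 <= self.shrinkage < 1.0:
            raise SchemaError("shrinkage must lie in [0, 1)")
        if self.sample_weights is not None:
            self.sample_weights = np.asarray(self.sample_weights, dtype=float)
            if np.any(self.sample_weights <= 0):
                raise SchemaError("sample weights must be positive")


# ---------------------------------------------------------------------------
# covariance regularization
# ---------------------------------------------------------------------------

def regularize_covariance(S: np.ndarray, structure: str = "full",
                          shrinkage: float = 0.0,
                          var_floor: float = 0.0) -> np.ndarray:
    """Shrink a raw covariance towards its diagonal and apply structure.

    Sigma = (1 - alpha) * S + alpha * diag(S); ``diagonal`` structures then
    zero the off-diagonal entries; finally eigenvalues are clamped at
    ``var_floor`` to guard against EM degeneracy.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if not np.allclose(S, S.T, atol=1e-8):
        raise SchemaError("covariance input must be symmetric")
    S = 0.5 * (S + S.T)
    out = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    if structure in ("diagonal", "tied_diagonal"):
        out = np.diag(np.clip(np.diag(out), var_floor, None))
        return out
    if var_floor > 0:
        vals, vecs = np.linalg.eigh(out)
        if vals.min() < var_floor:
            vals = np.clip(vals, var_floor, None)
            out = (vecs * vals) @ vecs.T
            out = 0.5 * (out + out.T)
    return out


def _gate_var_floor(X_G: np.ndarray) -> float:
    v = np.var(X_G, axis=0).mean()
    return VAR_FLOOR_FRACTION * (v if v > 0 else 1.0)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_gate(X_G: np.ndarray, C: int, seed: int = 0, n_init: int = 5,
              covariance_structure: str = "full",
              shrinkage: float = 0.0) -> MixtureGate:
    """Unsupervised GMM initialization on the gate features alone.

    Runs k-means-seeded EM (via scikit-learn) with ``n_init`` restarts and
    keeps the highest-likelihood fit; the outcome plays no role here.
    Deterministic given ``seed``.
    """
    X_G = np.atleast_2d(np.asarray(X_G, dtype=float))
    n, d = X_G.shape
    if n < C:
        raise InfeasibleClusterError(
            C, max_feasible=n, message=f"cannot initialize C={C} clusters from n={n} points")
    floor = _gate_var_floor(X_G)
    gm = GaussianMixture(n_components=C, covariance_type="full",
                         init_params="kmeans", n_init=n_init,
                         random_state=int(seed), reg_covar=max(floor, 1e-10),
                         max_iter=200)
    gm.fit(X_G)
    covs = [gm.covariances_[c] for c in range(C)]
    return _build_gate(gm.weights_, gm.means_, covs, covariance_structure,
                       shrinkage, floor)


def _build_gate(priors, means, covs, structure, shrinkage, floor) -> MixtureGate:
    priors = np.asarray(priors, dtype=float)
    C = len(priors)
    if structure in ("tied", "tied_diagonal"):
        pooled = np.zeros_like(np.atleast_2d(covs[0]))
        for c in range(C):
            pooled += priors[c] * np.atleast_2d(covs[c])
        covs = [pooled] * C
    comps = [GaussianComponent(
        np.atleast_1d(means[c]),
        regularize_covariance(covs[c], structure, shrinkage, floor))
        for c in range(C)]
    return MixtureGate(priors, comps)


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def e_step(X_G: np.ndarray, X_L: np.ndarray, y: np.ndarray,
           gate: MixtureGate, heads: Sequence[ClusterPredictor]) -> np.ndarray:
    """Supervised responsibilities r_ic ∝ pi_c N_c(x_i^G) P(y_i | x_i^L, c)."""
    y = validate_outcome(y, np.atleast_2d(X_G).shape[0])
    ll = complete_log_likelihood_matrix(X_G, X_L, y, gate, heads)
    norm = logsumexp(ll, axis=1)
    if np.any(np.isneginf(norm)):
        raise NumericalError("a data point received zero mass in every cluster")
    return np.exp(ll - norm[:, None])


# ---------------------------------------------------------------------------
# M-steps
# ---------------------------------------------------------------------------

def m_step_gate(X_G: np.ndarray, R: np.ndarray, cfg: FitConfig,
                sample_weights: np.ndarray | None = None) -> MixtureGate:
    """Responsibility-weighted Gaussian mixture update.

    pi_c is the normalized responsibility mass, mu_c the weighted mean and
    Sigma_c the weighted scatter about mu_c (denominator = responsibility
    mass); tied structures pool a single covariance across clusters, then
    :func:`regularize_covariance` is applied.
    """
    X_G = np.atleast_2d(np.asarray(X_G, dtype=float))
    R = np.asarray(R, dtype=float)
    W = R if sample_weights is None else R * sample_weights[:, None]
    mass = W.sum(axis=0)
    if np.any(mass <= 0):
        raise InfeasibleClusterError(R.shape[1],
                                     message="a cluster has zero responsibility mass")
    priors = mass / mass.sum()
    floor = _gate_var_floor(X_G)
    means, covs = [], []
    for c in range(R.shape[1]):
        w = W[:, c]
        mu = (w[:, None] * X_G).sum(axis=0) / mass[c]
        dev = X_G - mu
        S = (w[:, None] * dev).T @ dev / mass[c]
        means.append(mu)
        covs.append(S)
    return _build_gate(priors, means, covs, cfg.covariance_structure,
                       cfg.shrinkage, floor)


def _weighted_class1_frequency(y, w) -> float:
    return float(np.clip((w * y).sum() / w.sum(), FREQ_CLIP, 1.0 - FREQ_CLIP))


def _fit_logistic(X, y, w, lambda1, lambda2, tol, max_iter) -> LogisticHead:
    """Weighted elastic-net logistic regression via scikit-learn.

    The target objective is  sum_i w_i * logloss_i
    + lambda1 * sum_j ((1-lambda2)/2 * b_j^2 + lambda2 * |b_j|),
    intercept unpenalized, which maps onto scikit-learn's ``C = 1/lambda1``
    and ``l1_ratio = lambda2`` parameterization.
    """
    if lambda1 > 0:
        # the objective is convex; a fixed shuffle seed keeps refits
        # bit-identical without affecting the optimum
        clf = LogisticRegression(solver="saga", l1_ratio=lambda2,
                                 C=1.0 / lambda1, tol=tol, max_iter=max_iter,
                                 random_state=0)
    else:
        clf = LogisticRegression(solver="lbfgs", C=np.inf,
                                 tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        clf.fit(X, y, sample_weight=w)
    if clf.n_iter_[0] >= max_iter:
        warnings.warn(
            f"logistic solver stopped at the iteration cap ({max_iter}); "
            "coefficients may be short of the optimum (often a sign of "
            "quasi-separation under a weak penalty)", stacklevel=2)
    coef = clf.coef_.ravel().copy()
    b0 = _polish_intercept(X, y, w, coef, float(clf.intercept_[0]))
    return LogisticHead(coef, b0)


def _polish_intercept(X, y, w, coef, b0, n_steps=50, gtol=1e-12):
    """Newton refinement of the unpenalized intercept at fixed coefficients.

    saga's stopping rule watches the coefficients only, so under strong
    penalties it can halt with the intercept short of its optimum; this
    1-D convex polish closes that gap without touching the selection.
    """
    offset = X @ coef
    for _ in range(n_steps):
        p = expit(offset + b0)
        g = np.sum(w * (p - y))
        if abs(g) < gtol * max(1.0, np.sum(w)):
            break
        h = np.sum(w * p * (1.0 - p))
        if h <= 0:
            break
        b0 -= g / h
    return b0


def m_step_heads(X_L: np.ndarray, y: np.ndarray, R: np.ndarray,
                 cfg: FitConfig,
                 sample_weights: np.ndarray | None = None
                 ) -> list[ClusterPredictor]:
    """Per-cluster penalized logistic fits with responsibility weights.

    Every data point contributes to every cluster's regression, weighted
    by its responsibility (times any sampling weight).  Clusters whose
    effective size falls below ``min_cluster_ess``, or that see only one
    outcome class with nonzero weight, fall back to a clipped frequency
    head.
    """
    X_L = np.atleast_2d(np.asarray(X_L, dtype=float))
    y = validate_outcome(y, X_L.shape[0])
    R = np.asarray(R, dtype=float)
    W = R if sample_weights is None else R * sample_weights[:, None]
    min_ess = cfg.min_cluster_ess
    if min_ess is None:
        min_ess = X_L.shape[1] + 1
    heads: list[ClusterPredictor] = []
    for c in range(R.shape[1]):
        w = W[:, c]
        ess = R[:, c].sum()
        p1 = _weighted_class1_frequency(y, w) if w.sum() > 0 else 0.5
        both_classes = (w[y == 1].sum() > 0) and (w[y == 0].sum() > 0)
        if ess < min_ess or not both_classes:
            heads.append(FrequencyHead(p1))
            continue
        heads.append(_fit_logistic(X_L, y, w, cfg.lambda1, cfg.lambda2,
                                   cfg.head_tol, cfg.head_max_iter))
    return heads


def kkt_violation(X_L, y, w, head: LogisticHead, lambda1: float,
                  lambda2: float, zeros_only: bool = False) -> float:
    """Max KKT residual of the weighted elastic-net logistic objective.

    For active coefficients the gradient of the smooth part must cancel
    the subgradient lambda1*(lambda2*sign(b) + (1-lambda2)*b); for zeroed
    coefficients its magnitude must not exceed lambda1*lambda2.  Returns
    the largest violation (0 means first-order optimality holds).  With
    ``zeros_only`` only the zeroed-coefficient bound is assessed.
    """
    X_L = np.atleast_2d(np.asarray(X_L, dtype=float))
    y = np.asarray(y, dtype=float)
    p = expit(head.decision(X_L))
    grad = X_L.T @ (w * (p - y))
    b = head.coefficients
    viol = np.abs(np.where(
        b == 0.0,
        np.clip(np.abs(grad) - lambda1 * lambda2, 0.0, None),
        0.0 if zeros_only else
        grad + lambda1 * ((1.0 - lambda2) * b + lambda2 * np.sign(b))))
    out = viol.max() if viol.size else 0.0
    if not zeros_only:
        out = max(out, abs(np.sum(w * (p - y))))  # unpenalized intercept
    return float(out)


# ---------------------------------------------------------------------------
# the full EM loop
# ---------------------------------------------------------------------------

def _objective(X_G, X_L, y, gate, heads, lambda1, lambda2) -> float:
    ll = float(np.sum(logsumexp(
        complete_log_likelihood_matrix(X_G, X_L, y, gate, heads), axis=1)))
    return ll - elastic_net_penalty(heads, lambda1, lambda2)


def fit(table: FeatureTable, y, roles: FeatureRoles, cfg: FitConfig,
        standardize: bool = True, _find_feasible: bool = True) -> GeMLRModel:
    """Fit GeM-LR by EM on a feature table with a binary outcome.

    The standardizer is learned on ``table`` and applied before any model
    computation.  Iterates E/M steps from the unsupervised initialization
    until the relative change of the penalized observed-data log
    likelihood drops below ``cfg.tol`` or ``cfg.max_iter`` is reached.
    If a cluster's effective size collapses below 2 the requested ``C``
    is infeasible and an :class:`InfeasibleClusterError` is raised
    carrying the largest feasible cluster count.
    """
    y = validate_outcome(y, table.n)
    if table.n < cfg.C:
        raise InfeasibleClusterError(cfg.C, max_feasible=table.n)
    sw = cfg.sample_weights
    if sw is not None and sw.shape != (table.n,):
        raise SchemaError("sample_weights length must match the data")

    std = Standardizer.fit(table) if standardize else None
    Z = std.transform(table) if standardize else table
    X_G = Z.values[:, roles.gate_features]
    X_L = Z.values[:, roles.classifier_features]

    try:
        model = _fit_standardized(X_G, X_L, y, roles, cfg, std, sw)
    except InfeasibleClusterError as err:
        if not _find_feasible or cfg.C <= 1:
            raise
        max_c = _max_feasible_C(table, y, roles, cfg)
        raise InfeasibleClusterError(cfg.C, max_feasible=max_c) from err
    return model


def _fit_standardized(X_G, X_L, y, roles, cfg, std, sw) -> GeMLRModel:
    gate = init_gate(X_G, cfg.C, seed=cfg.seed, n_init=cfg.n_init,
                     covariance_structure=cfg.covariance_structure,
                     shrinkage=cfg.shrinkage)
    # seed the heads from the unsupervised partition before the first E-step
    R = gate_posterior(X_G, gate)
    heads = m_step_heads(X_L, y, R, cfg, sw)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        R = e_step(X_G, X_L, y, gate, heads)
        ess = R.sum(axis=0)
        if np.any(ess < 2.0):
            raise InfeasibleClusterError(cfg.C)
        gate = m_step_gate(X_G, R, cfg, sw)
        heads = m_step_heads(X_L, y, R, cfg, sw)
        obj = _objective(X_G, X_L, y, gate, heads, cfg.lambda1, cfg.lambda2)
        trace.append(obj)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(obj - prev) / (abs(prev) + 1e-12) < cfg.tol:
                converged = True
                break
    R = e_step(X_G, X_L, y, gate, heads)
    diagnostics = {
        "objective_trace": trace,
        "n_iter": n_iter,
        "converged": converged,
        "effective_sizes": R.sum(axis=0).tolist(),
    }
    config = {
        "C": cfg.C, "lambda1": cfg.lambda1, "lambda2": cfg.lambda2,
        "covariance_structure": cfg.covariance_structure,
        "shrinkage": cfg.shrinkage, "tol": cfg.tol,
        "max_iter": cfg.max_iter, "n_init": cfg.n_init, "seed": cfg.seed,
    }
    gate.gate_features = list(roles.gate_features)
    return GeMLRModel(gate=gate, heads=heads, roles=roles, standardizer=std,
                      diagnostics=diagnostics, config=config)


def _max_feasible_C(table, y, roles, cfg) -> int:
    """Largest cluster count (< cfg.C) that fits without an empty cluster."""
    for c_try in range(cfg.C - 1, 0, -1):
        try:
            fit(table, y, roles, replace(cfg, C=c_try), _find_feasible=False)
            return c_try
        except InfeasibleClusterError:
            continue
    return 1
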