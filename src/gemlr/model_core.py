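"""Core data types and probability computations for GeM-LR.

GeM-LR is a latent-variable model for binary outcomes: a categorical
cluster label ``Z`` with priors ``pi_c`` gates the data, the feature
vector follows a cluster-specific Gaussian ``N(mu_c, Sigma_c)`` over a
designated subset of *gate* features, and the outcome follows a
cluster-specific logistic regression over a (possibly different) subset
of *classifier* features.  Prediction mixes the per-cluster logistic
probabilities with the Gaussian posterior cluster weights:

    P(Y=1 | x) = sum_c P(Z=c | x_G) * sigmoid(beta_c' x_L + beta_c0)

All mixture arithmetic is done in the log domain with log-sum-exp so
that moderate dimensionality does not underflow at small sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logsumexp

from .exceptions import NumericalError, SchemaError

__all__ = [
    "FeatureTable",
    "FeatureRoles",
    "GaussianComponent",
    "MixtureGate",
    "LogisticHead",
    "FrequencyHead",
    "ClusterPredictor",
    "Standardizer",
    "GeMLRModel",
    "validate_outcome",
    "gmm_density",
    "gmm_log_density",
    "gate_posterior",
    "gate_log_posterior",
    "head_prob",
    "head_log_prob",
    "predict_soft",
    "predict_hard",
    "elastic_net_penalty",
    "penalized_loglik",
]

#: probability clip for frequency fallback heads
FREQ_CLIP = 1e-3

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """An n x p numeric feature matrix with row and column identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("feature table values must be 2-dimensional")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise SchemaError("feature table must have at least one row and column")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.sample_ids) != n:
            raise SchemaError(
                f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != p:
            raise SchemaError(
                f"{len(self.feature_names)} feature names for {p} columns")
        if len(set(self.feature_names)) != p:
            raise SchemaError("feature names must be unique")
        if np.isnan(self.values).any():
            bad = [self.sample_ids[i]
                   for i in np.unique(np.nonzero(np.isnan(self.values))[0])]
            raise SchemaError(f"missing values in rows: {bad}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(self.values[idx],
                            [self.sample_ids[i] for i in idx],
                            list(self.feature_names))

    def column_indices(self, names: Sequence[str]) -> list[int]:
        lookup = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in lookup]
        if missing:
            raise SchemaError(f"unknown feature names: {missing}")
        return [lookup[f] for f in names]


def validate_outcome(y, n: int | None = None) -> np.ndarray:
    """Coerce a binary 0/1 outcome vector, checking length and codes."""
    y = np.asarray(y)
    if n is not None and y.shape != (n,):
        raise SchemaError(f"outcome length {y.shape} does not match n={n}")
    vals = np.unique(y)
    if not np.all(np.isin(vals, [0, 1])):
        raise SchemaError(f"outcome codes must be 0/1, got {vals}")
    return y.astype(int)


@dataclass
class FeatureRoles:
    """Which columns feed the gating mixture vs. the cluster classifiers.

    Both are index sets into the same feature table; they may overlap or
    be disjoint (e.g., study-indicator covariates that only enter the
    classifiers).
    """

    gate_features: list[int]
    classifier_features: list[int]

    def __post_init__(self):
        self.gate_features = [int(j) for j in self.gate_features]
        self.classifier_features = [int(j) for j in self.classifier_features]
        if not self.gate_features:
            raise SchemaError("gate feature set must be nonempty")
        if not self.classifier_features:
            raise SchemaError("classifier feature set must be nonempty")

    @classmethod
    def from_names(cls, table: FeatureTable, gate: Sequence[str],
                   classifier: Sequence[str]) -> "FeatureRoles":
        return cls(table.column_indices(gate), table.column_indices(classifier))


@dataclass
class GaussianComponent:
    """One Gaussian gate component N(mean, covariance)."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        d = self.mean.shape[0]
        if self.covariance.shape != (d, d):
            raise SchemaError("covariance shape does not match mean dimension")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise SchemaError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Log density at each row of X, via Cholesky factorization."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise SchemaError(
                f"input dimension {X.shape[1]} != component dimension {self.dim}")
        try:
            factor = cho_factor(self.covariance, lower=True)
        except np.linalg.LinAlgError as e:
            raise NumericalError(f"singular gate covariance: {e}") from e
        dev = X - self.mean
        solved = cho_solve(factor, dev.T).T
        maha = np.einsum("ij,ij->i", dev, solved)
        logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
        return -0.5 * (self.dim * np.log(2.0 * np.pi) + logdet + maha)


@dataclass
class MixtureGate:
    """Gaussian mixture over the gate features: priors + components."""

    priors: np.ndarray
    components: list[GaussianComponent]
    gate_features: list[int] | None = None

    def __post_init__(self):
        self.priors = np.asarray(self.priors, dtype=float)
        if self.priors.ndim != 1 or len(self.components) != self.priors.shape[0]:
            raise SchemaError("one prior per component required")
        if np.any(self.priors < -1e-12) or abs(self.priors.sum() - 1.0) > 1e-8:
            raise SchemaError("priors must be a probability vector")
        self.priors = np.clip(self.priors, 0.0, None)
        self.priors = self.priors / self.priors.sum()
        dims = {c.dim for c in self.components}
        if len(dims) > 1:
            raise SchemaError("all components must share a dimension")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return self.components[0].dim

    def component_log_pdfs(self, X: np.ndarray) -> np.ndarray:
        """n x C matrix of per-component log densities."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([c.log_pdf(X) for c in self.components])

    def weighted_log_pdfs(self, X: np.ndarray) -> np.ndarray:
        """n x C matrix of log(pi_c) + log N_c(x); -inf where pi_c = 0."""
        with np.errstate(divide="ignore"):
            log_pi = np.log(self.priors)
        return log_pi[None, :] + self.component_log_pdfs(X)


@dataclass
class LogisticHead:
    """Per-cluster logistic regression: P(Y=1|x) = sigmoid(coef'x + intercept)."""

    coefficients: np.ndarray
    intercept: float

    def __post_init__(self):
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        self.intercept = float(self.intercept)

    def decision(self, X_L: np.ndarray) -> np.ndarray:
        X_L = np.atleast_2d(np.asarray(X_L, dtype=float))
        if X_L.shape[1] != self.coefficients.shape[0]:
            raise SchemaError(
                f"classifier input has {X_L.shape[1]} features, head expects "
                f"{self.coefficients.shape[0]}")
        return X_L @ self.coefficients + self.intercept


@dataclass
class FrequencyHead:
    """Degenerate classifier for tiny clusters: constant class-1 frequency."""

    prob1: float

    def __post_init__(self):
        self.prob1 = float(np.clip(self.prob1, FREQ_CLIP, 1.0 - FREQ_CLIP))


ClusterPredictor = Union[LogisticHead, FrequencyHead]


@dataclass
class Standardizer:
    """Column-wise centering/scaling learned on training data.

    Constant columns get scale 1 so they are centered but not divided by
    zero.  Scaling uses the sample standard deviation (ddof=1).
    """

    mean_: np.ndarray
    scale_: np.ndarray
    feature_names: list[str]

    @classmethod
    def fit(cls, table: FeatureTable) -> "Standardizer":
        mean = table.values.mean(axis=0)
        if table.n > 1:
            sd = table.values.std(axis=0, ddof=1)
        else:
            sd = np.zeros(table.p)
        scale = np.where(sd > 0, sd, 1.0)
        return cls(mean_=mean, scale_=scale, feature_names=list(table.feature_names))

    def _check(self, table: FeatureTable):
        if list(table.feature_names) != list(self.feature_names):
            raise SchemaError("feature names do not match the standardizer")

    def transform(self, table: FeatureTable) -> FeatureTable:
        self._check(table)
        return FeatureTable((table.values - self.mean_) / self.scale_,
                            table.sample_ids, table.feature_names)

    def inverse_transform(self, table: FeatureTable) -> FeatureTable:
        self._check(table)
        return FeatureTable(table.values * self.scale_ + self.mean_,
                            table.sample_ids, table.feature_names)


@dataclass
class GeMLRModel:
    """A fitted GeM-LR model: gate + per-cluster heads + preprocessing."""

    gate: MixtureGate
    heads: list[ClusterPredictor]
    roles: FeatureRoles
    standardizer: Standardizer | None
    diagnostics: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.heads) != self.gate.n_components:
            raise SchemaError("number of heads must equal number of gate components")

    @property
    def n_clusters(self) -> int:
        return self.gate.n_components

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        heads = []
        for h in self.heads:
            if isinstance(h, LogisticHead):
                heads.append({"type": "logistic",
                              "coefficients": h.coefficients.tolist(),
                              "intercept": h.intercept})
            else:
                heads.append({"type": "frequency", "prob1": h.prob1})
        std = None
        if self.standardizer is not None:
            std = {"mean": self.standardizer.mean_.tolist(),
                   "scale": self.standardizer.scale_.tolist(),
                   "feature_names": list(self.standardizer.feature_names)}
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "roles": {"gate_features": self.roles.gate_features,
                      "classifier_features": self.roles.classifier_features},
            "priors": self.gate.priors.tolist(),
            "means": [c.mean.tolist() for c in self.gate.components],
            "covariances": [c.covariance.tolist() for c in self.gate.components],
            "heads": heads,
            "standardizer": std,
            "diagnostics": _jsonify(self.diagnostics),
            "config": _jsonify(self.config),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeMLRModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise SchemaError(
                f"unsupported model format version {d.get('format_version')!r}")
        comps = [GaussianComponent(np.asarray(m), np.asarray(S))
                 for m, S in zip(d["means"], d["covariances"])]
        roles = FeatureRoles(d["roles"]["gate_features"],
                             d["roles"]["classifier_features"])
        gate = MixtureGate(np.asarray(d["priors"]), comps,
                           gate_features=roles.gate_features)
        heads: list[ClusterPredictor] = []
        for h in d["heads"]:
            if h["type"] == "logistic":
                heads.append(LogisticHead(np.asarray(h["coefficients"]),
                                          h["intercept"]))
            elif h["type"] == "frequency":
                heads.append(FrequencyHead(h["prob1"]))
            else:
                raise SchemaError(f"unknown head type {h['type']!r}")
        std = None
        if d.get("standardizer") is not None:
            s = d["standardizer"]
            std = Standardizer(np.asarray(s["mean"]), np.asarray(s["scale"]),
                               list(s["feature_names"]))
        return cls(gate=gate, heads=heads, roles=roles, standardizer=std,
                   diagnostics=d.get("diagnostics", {}),
                   config=d.get("config", {}))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# density / posterior / prediction operations
# ---------------------------------------------------------------------------

def gmm_log_density(x_G: np.ndarray, gate: MixtureGate) -> np.ndarray:
    """Log of the mixture density sum_c pi_c N(x | mu_c, Sigma_c)."""
    x_G, squeeze = _rows(x_G)
    out = logsumexp(gate.weighted_log_pdfs(x_G), axis=1)
    return out[0] if squeeze else out


def gmm_density(x_G: np.ndarray, gate: MixtureGate) -> np.ndarray:
    return np.exp(gmm_log_density(x_G, gate))


def gate_log_posterior(x_G: np.ndarray, gate: MixtureGate) -> np.ndarray:
    """Log posterior log P(Z=c | x_G), computed via log-sum-exp."""
    x_G, squeeze = _rows(x_G)
    wl = gate.weighted_log_pdfs(x_G)
    norm = logsumexp(wl, axis=1)
    if np.any(np.isneginf(norm)):
        raise NumericalError("all gate components have zero density at some input")
    out = wl - norm[:, None]
    return out[0] if squeeze else out


def gate_posterior(x_G: np.ndarray, gate: MixtureGate) -> np.ndarray:
    return np.exp(gate_log_posterior(x_G, gate))


def head_prob(x_L: np.ndarray, head: ClusterPredictor) -> np.ndarray:
    """P(Y=1 | x_L) under a single cluster head."""
    x_L, squeeze = _rows(x_L)
    if isinstance(head, FrequencyHead):
        out = np.full(x_L.shape[0], head.prob1)
    else:
        out = expit(head.decision(x_L))
    return out[0] if squeeze else out


def head_log_prob(x_L: np.ndarray, head: ClusterPredictor, y: int) -> np.ndarray:
    """Log P(Y=y | x_L) for y in {0,1}, numerically stable for logits."""
    x_L, squeeze = _rows(x_L)
    if isinstance(head, FrequencyHead):
        p = head.prob1 if y == 1 else 1.0 - head.prob1
        out = np.full(x_L.shape[0], np.log(p))
    else:
        eta = head.decision(x_L)
        # log sigmoid(eta) = -log1p(exp(-eta)); flip sign of eta for y=0
        sgn = 1.0 if y == 1 else -1.0
        out = -np.logaddexp(0.0, -sgn * eta)
    return out[0] if squeeze else out


def _head_prob_matrix(X_L: np.ndarray, heads: Sequence[ClusterPredictor]) -> np.ndarray:
    return np.column_stack([head_prob(X_L, h) for h in heads])


def _prepare_input(x, model: GeMLRModel, pre_standardized: bool):
    """Standardize raw input and split into gate / classifier views."""
    squeeze = False
    if isinstance(x, FeatureTable):
        if model.standardizer is not None and not pre_standardized:
            x = model.standardizer.transform(x)
        V = x.values
    else:
        V = np.asarray(x, dtype=float)
        if V.ndim == 1:
            V, squeeze = V[None, :], True
        if model.standardizer is not None and not pre_standardized:
            V = (V - model.standardizer.mean_) / model.standardizer.scale_
    return (V[:, model.roles.gate_features],
            V[:, model.roles.classifier_features], squeeze)


def predict_soft(x, model: GeMLRModel, pre_standardized: bool = False) -> np.ndarray:
    """Mixture prediction: gate-posterior-weighted sum of head probabilities.

    ``x`` is a FeatureTable or array over the full feature set (raw scale
    unless ``pre_standardized``); the model's standardizer is applied first.
    """
    X_G, X_L, squeeze = _prepare_input(x, model, pre_standardized)
    w = np.atleast_2d(gate_posterior(X_G, model.gate))
    probs = _head_prob_matrix(X_L, model.heads)
    out = np.einsum("nc,nc->n", w, probs)
    return float(out[0]) if squeeze else out


def predict_hard(x, model: GeMLRModel, pre_standardized: bool = False):
    """Hard-partition prediction: argmax-posterior cluster, its head's probability.

    Ties in the gate posterior break toward the lowest cluster index.
    Returns ``(cluster_indices, probabilities)`` (0-based clusters).
    """
    X_G, X_L, squeeze = _prepare_input(x, model, pre_standardized)
    w = np.atleast_2d(gate_posterior(X_G, model.gate))
    cstar = np.argmax(w, axis=1)  # argmax returns the first maximum
    probs = _head_prob_matrix(X_L, model.heads)
    out = probs[np.arange(len(cstar)), cstar]
    if squeeze:
        return int(cstar[0]), float(out[0])
    return cstar, out


def elastic_net_penalty(heads: Sequence[ClusterPredictor], lambda1: float,
                        lambda2: float) -> float:
    """R(beta) = sum_c lambda1 * sum_j ((1-lambda2)/2 * b^2 + lambda2 * |b|).

    Intercepts and frequency heads are unpenalized.
    """
    total = 0.0
    for h in heads:
        if isinstance(h, LogisticHead):
            b = h.coefficients
            total += lambda1 * np.sum((1.0 - lambda2) / 2.0 * b ** 2
                                      + lambda2 * np.abs(b))
    return float(total)


def complete_log_likelihood_matrix(X_G, X_L, y, gate: MixtureGate,
                                   heads: Sequence[ClusterPredictor]) -> np.ndarray:
    """n x C matrix log[pi_c N_c(x_G) P(y | x_L, c)] for observed outcomes."""
    y = np.asarray(y)
    wl = gate.weighted_log_pdfs(X_G)
    for c, h in enumerate(heads):
        lp1 = head_log_prob(X_L, h, 1)
        lp0 = head_log_prob(X_L, h, 0)
        wl[:, c] += np.where(y == 1, lp1, lp0)
    return wl


def penalized_loglik(table, y, model: GeMLRModel, lambda1: float,
                     lambda2: float, pre_standardized: bool = True) -> float:
    """Penalized observed-data log likelihood, the EM objective.

    sum_i log sum_c pi_c N(x_i^G) P(y_i | x_i^L, c)  -  R(beta).
    Data must already be on the scale the model was fitted on (the EM
    loop fits on standardized data); pass ``pre_standardized=False`` for
    raw-scale input with a standardizing model.
    """
    X_G, X_L, _ = _prepare_input(table, model, pre_standardized)
    y = validate_outcome(y, X_G.shape[0])
    ll = float(np.sum(logsumexp(
        complete_log_likelihood_matrix(X_G, X_L, y, model.gate, model.heads),
        axis=1)))
    return ll - elastic_net_penalty(model.heads, lambda1, lambda2)


def _rows(x):
    """Coerce to 2-D, remembering whether the input was a single vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        return x[None, None], True
    if x.ndim == 1:
        return x[None, :], True
    return x, False
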