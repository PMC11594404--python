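"""Cluster annotation via closed-form Gaussian overlap measures.

A fitted gate assigns each cluster a Gaussian N(mu_c, Sigma_c) with prior
pi_c.  To describe what makes cluster ``c`` distinct, we score feature
subsets ``h`` by how well the marginal mixture on ``h`` separates the
cluster from the rest:

* ``tau_plus``  — expected share of mixture mass claimed by cluster c for
  points drawn from cluster c (a true-positive rate, as a ratio of
  expectations);
* ``tau_minus`` — the same share for points drawn from the other
  components (a false-positive rate);
* ``discriminative_accuracy`` — A_c(h) = pi_c tau+ + (1-pi_c)(1-tau-),
  the prior-weighted sum of true-positive and true-negative rates, on
  the absolute probability scale.

All three reduce to Gaussian product integrals
``O(s,t) = ∫ N(x|mu_s,Sigma_s) N(x|mu_t,Sigma_t) dx = N(mu_s | mu_t,
Sigma_s + Sigma_t)``, so they are exact and cheap: with x ~ N_c,
E[pi_s N_s(x)] = pi_s O(c,s), hence

    tau_plus(c,h)  = pi_c O(c,c) / sum_s pi_s O(c,s)
    tau_minus(c,h) = pi_c sum_{s!=c} pi_s O(c,s)
                     / sum_{s!=c} pi_s sum_t pi_t O(s,t)

(the 1/(1-pi_c) normalizations of the complement mixture cancel).
Forward selection grows ``h`` greedily by the largest gain in A_c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import NumericalError, SchemaError
from .model_core import GaussianComponent, MixtureGate

__all__ = [
    "FeatureSubset",
    "AnnotationResult",
    "marginal_gate",
    "gaussian_overlap",
    "overlap_matrix",
    "tau_plus",
    "tau_minus",
    "discriminative_accuracy",
    "forward_select",
    "annotate_all",
]

FeatureSubset = Sequence[int]


@dataclass
class AnnotationResult:
    """Forward-selection outcome for one cluster."""

    cluster: int
    selected: list[int]
    trace: list[tuple[int, float]]
    A_full: float
    stop_reason: str

    @property
    def A_final(self) -> float:
        return self.trace[-1][1]


def marginal_gate(gate: MixtureGate, h: FeatureSubset) -> MixtureGate:
    """The implied mixture on a subset of gate coordinates.

    Marginalizing a Gaussian mixture only restricts each component's mean
    and covariance to the kept coordinates; priors are unchanged.  ``h``
    indexes coordinates of the gate's own feature space (0-based).
    """
    h = list(h)
    if len(h) == 0:
        raise SchemaError("feature subset must be nonempty")
    d = gate.dim
    if any(j < 0 or j >= d for j in h):
        raise SchemaError(f"subset {h} outside gate dimension {d}")
    comps = [GaussianComponent(c.mean[h], c.covariance[np.ix_(h, h)])
             for c in gate.components]
    return MixtureGate(gate.priors.copy(), comps)


def gaussian_overlap(comp_s: GaussianComponent,
                     comp_t: GaussianComponent) -> float:
    """∫ N(x|mu_s,Sigma_s) N(x|mu_t,Sigma_t) dx = N(mu_s | mu_t, Sigma_s+Sigma_t).

    The product integral of two Gaussian densities; symmetric in its
    arguments.
    """
    if comp_s.dim != comp_t.dim:
        raise SchemaError("components must share a dimension")
    conv = GaussianComponent(comp_t.mean, comp_s.covariance + comp_t.covariance)
    try:
        return float(np.exp(conv.log_pdf(comp_s.mean[None, :])[0]))
    except NumericalError as e:
        raise NumericalError(f"singular covariance sum in overlap: {e}") from e


def overlap_matrix(gate: MixtureGate) -> np.ndarray:
    """Symmetric C x C matrix of pairwise component overlaps O(s, t)."""
    C = gate.n_components
    O = np.empty((C, C))
    for s in range(C):
        for t in range(s, C):
            O[s, t] = O[t, s] = gaussian_overlap(gate.components[s],
                                                 gate.components[t])
    return O


def _check_cluster(gate: MixtureGate, c: int):
    if not 0 <= c < gate.n_components:
        raise SchemaError(f"cluster {c} out of range for C={gate.n_components}")


def tau_plus(gate: MixtureGate, c: int, h: FeatureSubset | None = None) -> float:
    """True-positive discrimination of cluster c on feature subset h."""
    _check_cluster(gate, c)
    g = gate if h is None else marginal_gate(gate, h)
    O = overlap_matrix(g)
    pi = g.priors
    denom = float(pi @ O[c])
    if denom <= 0:
        raise NumericalError("vanishing mixture mass in tau_plus")
    return float(pi[c] * O[c, c] / denom)


def tau_minus(gate: MixtureGate, c: int, h: FeatureSubset | None = None) -> float:
    """False-positive discrimination of cluster c on feature subset h.

    Defined against the prior-weighted mixture of the other components;
    requires at least two components.
    """
    _check_cluster(gate, c)
    if gate.n_components < 2:
        raise SchemaError("tau_minus requires at least two components")
    g = gate if h is None else marginal_gate(gate, h)
    O = overlap_matrix(g)
    pi = g.priors
    others = [s for s in range(g.n_components) if s != c]
    num = pi[c] * sum(pi[s] * O[c, s] for s in others)
    denom = sum(pi[s] * float(pi @ O[s]) for s in others)
    if denom <= 0:
        raise NumericalError("vanishing complement-mixture mass in tau_minus")
    return float(num / denom)


def discriminative_accuracy(gate: MixtureGate, c: int,
                            h: FeatureSubset | None = None) -> float:
    """A_c(h) = pi_c tau+ + (1 - pi_c)(1 - tau-); equals 1 for C = 1."""
    _check_cluster(gate, c)
    if gate.n_components == 1:
        return 1.0
    pi_c = float(gate.priors[c])
    tp = tau_plus(gate, c, h)
    fp = tau_minus(gate, c, h)
    return float(pi_c * tp + (1.0 - pi_c) * (1.0 - fp))


def forward_select(gate: MixtureGate, c: int, delta_stop: float = 0.1,
                   gap_stop: float = 0.01,
                   A_target: float | None = None) -> AnnotationResult:
    """Greedy forward selection of discriminative gate features.

    Starting from the empty set, repeatedly adds the feature that
    maximizes A_c(h ∪ {j}) (ties towards the lowest index).  At least one
    feature is always selected.  Selection stops when the best available
    gain falls below ``delta_stop`` while |A_c(h) - A_c(all)| < ``gap_stop``,
    when ``A_target`` (if given) is reached, or when every feature is in.
    """
    _check_cluster(gate, c)
    d = gate.dim
    A_full = discriminative_accuracy(gate, c)
    h: list[int] = []
    trace: list[tuple[int, float]] = []
    A_current = -np.inf
    stop_reason = "all_features"
    while len(h) < d:
        remaining = [j for j in range(d) if j not in h]
        scores = [discriminative_accuracy(gate, c, h + [j]) for j in remaining]
        best = int(np.argmax(scores))  # first max: lowest-index tie break
        j_best, A_best = remaining[best], scores[best]
        if h:  # the first feature is added unconditionally
            if A_target is not None and A_current >= A_target:
                stop_reason = "target_reached"
                break
            if (A_best - A_current) < delta_stop and \
                    abs(A_current - A_full) < gap_stop:
                stop_reason = "converged"
                break
        h.append(j_best)
        trace.append((j_best, A_best))
        A_current = A_best
    return AnnotationResult(cluster=c, selected=list(h), trace=trace,
                            A_full=A_full, stop_reason=stop_reason)


def annotate_all(gate: MixtureGate, delta_stop: float = 0.1,
                 gap_stop: float = 0.01) -> list[AnnotationResult]:
    """Forward-select discriminative features for every cluster."""
    return [forward_select(gate, c, delta_stop, gap_stop)
            for c in range(gate.n_components)]
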