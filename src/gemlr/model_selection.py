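"""Cross-validated evaluation and tuning for GeM-LR and its baselines.

The protocol is built for small samples: K-fold CV (default K=5,
stratified) with per-fold AUCs averaged — not pooled — per repeat, and
non-nested tuning: the penalty weight ``lambda1`` and the cluster count
``C`` are chosen by CV on the entire dataset, and the chosen model's
performance is then assessed by an independent CV run.  Two-phase
sampling designs are handled by inverse-probability oversampling of the
training rows and an inverse-probability-weighted AUC on the held-out
rows.

Standardization is always refit on the training rows of each fold; the
held-out rows only ever see the training statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import baselines as _baselines
from . import em_fit
from .exceptions import InfeasibleClusterError, SchemaError
from .model_core import FeatureRoles, FeatureTable, predict_soft, validate_outcome
from .util import derive_seed

__all__ = [
    "CVPlan",
    "CVResult",
    "make_folds",
    "auc",
    "ip_oversample",
    "cv_evaluate",
    "select_lambda1",
    "select_C",
    "top_variance_features",
    "default_lambda1_grid",
    "paired_cv_test",
    "METHODS",
]

METHODS = ("gemlr", "lr", "cp")


@dataclass
class CVPlan:
    """Fold assignments for (repeated) K-fold cross-validation."""

    K: int
    repeats: int
    stratified: bool
    seed: int
    assignments: list[np.ndarray]  # one n-vector of fold ids per repeat

    @property
    def n(self) -> int:
        return len(self.assignments[0])


@dataclass
class CVResult:
    """Per-fold AUCs with their repeat-wise and overall summaries."""

    fold_aucs: list[list[float]]          # [repeat][fold]
    repeat_means: list[float]
    cv_auc: float
    se: float
    ci: tuple[float, float]
    config: dict = field(default_factory=dict)


def make_folds(y, K: int = 5, stratified: bool = True, seed: int = 0,
               repeats: int = 1) -> CVPlan:
    """Random (optionally stratified) fold assignments, one set per repeat.

    Stratification balances class counts across folds to within one; it
    falls back to plain folds with a warning if only one class is present.
    Deterministic given ``seed``.
    """
    y = np.asarray(y)
    n = len(y)
    if n < K:
        raise SchemaError(f"cannot make {K} folds from {n} samples")
    if stratified and len(np.unique(y)) < 2:
        warnings.warn("only one outcome class present; falling back to "
                      "unstratified folds", stacklevel=2)
        stratified = False
    assignments = []
    for rep in range(repeats):
        rng = np.random.default_rng(derive_seed(seed, 101, rep))
        fold_of = np.empty(n, dtype=int)
        if stratified:
            # deal each class's shuffled members round-robin over folds,
            # rotating the starting fold so fold sizes stay within one
            offset = 0
            for cls in np.unique(y):
                idx = np.flatnonzero(y == cls)
                rng.shuffle(idx)
                fold_of[idx] = (np.arange(len(idx)) + offset) % K
                offset = (offset + len(idx)) % K
        else:
            idx = rng.permutation(n)
            fold_of[idx] = np.arange(n) % K
        assignments.append(fold_of)
    return CVPlan(K=K, repeats=repeats, stratified=stratified, seed=seed,
                  assignments=assignments)


def auc(scores, labels, weights=None) -> float:
    """Mann-Whitney AUC, optionally with per-sample importance weights.

    sum over (positive i, negative j) of w_i w_j [1(s_i > s_j) + 1/2 1(s_i = s_j)]
    normalized by sum w_i w_j.  Ties count one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = validate_outcome(labels, len(scores))
    if weights is None:
        weights = np.ones(len(scores))
    else:
        weights = np.asarray(weights, dtype=float)
    pos, neg = labels == 1, labels == 0
    if not pos.any() or not neg.any():
        raise SchemaError("AUC undefined: only one class present")
    sp, sn = scores[pos], scores[neg]
    wp, wn = weights[pos], weights[neg]
    gt = (sp[:, None] > sn[None, :]).astype(float)
    eq = (sp[:, None] == sn[None, :]).astype(float)
    W = wp[:, None] * wn[None, :]
    return float((W * (gt + 0.5 * eq)).sum() / W.sum())


def _auc_influence(scores, labels, fold_auc) -> np.ndarray:
    """Per-observation influence values for the AUC of one fold.

    phi_i = 1(y=1)/p1 * (F0(s_i) - AUC) + 1(y=0)/p0 * (S1(s_i) - AUC),
    where F0 is the negatives' CDF (ties half) and S1 the positives'
    survival function; the fold variance of AUC is mean(phi^2)/n.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = labels == 1, labels == 0
    p1, p0 = pos.mean(), neg.mean()
    sp, sn = scores[pos], scores[neg]
    phi = np.empty(len(scores))
    # F0(s) among negatives for each positive's score
    lt = (sn[None, :] < scores[pos][:, None]).mean(axis=1)
    eqp = (sn[None, :] == scores[pos][:, None]).mean(axis=1)
    phi[pos] = ((lt + 0.5 * eqp) - fold_auc) / p1
    gt = (sp[None, :] > scores[neg][:, None]).mean(axis=1)
    eqn = (sp[None, :] == scores[neg][:, None]).mean(axis=1)
    phi[neg] = ((gt + 0.5 * eqn) - fold_auc) / p0
    return phi


def ip_oversample(table: FeatureTable, y, sampling_probs, seed: int = 0,
                  extra=None):
    """Replicate each row ~1/p_i times to undo two-phase sampling bias.

    The replication count is round(1/p_i) with the fractional part
    resolved by a seeded Bernoulli draw (stochastic rounding), so the
    expected count is exactly 1/p_i.  All-ones probabilities return the
    data unchanged.  ``extra`` is an optional per-sample array replicated
    alongside.
    """
    probs = np.asarray(sampling_probs, dtype=float)
    if np.any(probs <= 0) or np.any(probs > 1):
        raise SchemaError("sampling probabilities must lie in (0, 1]")
    y = validate_outcome(y, table.n)
    inv = 1.0 / probs
    base = np.floor(inv).astype(int)
    frac = inv - base
    rng = np.random.default_rng(derive_seed(seed, 211))
    counts = base + (rng.random(table.n) < frac)
    idx = np.repeat(np.arange(table.n), counts)
    # keep ids unique across replicates
    seen: dict[str, int] = {}
    uniq_ids = []
    for i in idx:
        s = table.sample_ids[i]
        k = seen.get(s, 0)
        seen[s] = k + 1
        uniq_ids.append(s if k == 0 else f"{s}#{k}")
    out = FeatureTable(table.values[idx], uniq_ids, list(table.feature_names))
    if extra is not None:
        return out, y[idx], np.asarray(extra)[idx]
    return out, y[idx]


def _fit_one(train: FeatureTable, y_train, roles: FeatureRoles,
             cfg: em_fit.FitConfig, method: str, seed: int):
    """Fit one method on a training slice; returns a raw-input scorer."""
    cfg = replace(cfg, seed=seed)
    if method == "gemlr":
        model = em_fit.fit(train, y_train, roles, cfg)
        return lambda t: predict_soft(t, model)
    if method == "lr":
        model = em_fit.fit(train, y_train, roles, replace(cfg, C=1))
        return lambda t: predict_soft(t, model)
    if method == "cp":
        model = _baselines.fit_cp(train, y_train, roles, C=cfg.C,
                                  lambda1=cfg.lambda1, lambda2=cfg.lambda2,
                                  seed=seed, n_init=cfg.n_init,
                                  min_cluster_ess=cfg.min_cluster_ess)
        return lambda t: _baselines.predict_cp(t, model)
    raise SchemaError(f"unknown method {method!r}; choose from {METHODS}")


def cv_evaluate(table: FeatureTable, y, roles: FeatureRoles,
                cfg: em_fit.FitConfig, plan: CVPlan, method: str = "gemlr",
                sampling_probs=None) -> CVResult:
    """Repeated K-fold CV AUC for one configuration.

    Per fold: a standardizer and model are fit on the training rows only
    (oversampled by inverse sampling probability when ``sampling_probs``
    is given), and the AUC — inverse-probability weighted in that case —
    is computed on the held-out rows.  Fold AUCs are averaged within each
    repeat and repeat means averaged for the overall CV AUC.  The 95% CI
    uses the cross-validated influence-function variance estimator for
    averaged fold AUCs.
    """
    y = validate_outcome(y, table.n)
    if sampling_probs is not None:
        sampling_probs = np.asarray(sampling_probs, dtype=float)
    fold_aucs: list[list[float]] = []
    var_terms: list[float] = []
    n_folds_used = 0
    for rep, fold_of in enumerate(plan.assignments):
        rep_aucs = []
        for k in range(plan.K):
            test = fold_of == k
            train = ~test
            if len(np.unique(y[test])) < 2:
                warnings.warn(f"fold {k} of repeat {rep} holds a single "
                              "class; skipping its AUC", stacklevel=2)
                continue
            tr_tab = table.subset_rows(np.flatnonzero(train))
            y_tr = y[train]
            if sampling_probs is not None:
                tr_tab, y_tr = ip_oversample(
                    tr_tab, y_tr, sampling_probs[train],
                    seed=derive_seed(plan.seed, 307, rep, k))
            scorer = _fit_one(tr_tab, y_tr, roles, cfg, method,
                              seed=derive_seed(plan.seed, 401, rep, k))
            te_tab = table.subset_rows(np.flatnonzero(test))
            scores = np.asarray(scorer(te_tab))
            w = None if sampling_probs is None else 1.0 / sampling_probs[test]
            a = auc(scores, y[test], w)
            rep_aucs.append(a)
            phi = _auc_influence(scores, y[test], a)
            var_terms.append(float(np.mean(phi ** 2)) / len(scores))
            n_folds_used += 1
        fold_aucs.append(rep_aucs)
    repeat_means = [float(np.mean(a)) for a in fold_aucs if a]
    if not repeat_means:
        raise SchemaError("no evaluable folds")
    cv_auc = float(np.mean(repeat_means))
    se = float(np.sqrt(np.sum(var_terms)) / n_folds_used)
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, cv_auc - z * se), min(1.0, cv_auc + z * se))
    return CVResult(fold_aucs=fold_aucs, repeat_means=repeat_means,
                    cv_auc=cv_auc, se=se, ci=ci,
                    config={"C": cfg.C, "lambda1": cfg.lambda1,
                            "lambda2": cfg.lambda2, "method": method})


def default_lambda1_grid(table: FeatureTable, y, roles: FeatureRoles,
                         lambda2: float = 0.8, n_points: int = 20,
                         decades: float = 4.0) -> np.ndarray:
    """Log-spaced lambda1 grid from the all-zero threshold downwards.

    lambda_max is the smallest lambda1 for which the single-cluster
    elastic-net logistic solution is fully sparse: at beta=0 with the
    intercept at the weighted base-rate logit, the KKT bound gives
    lambda_max = max_j |x_j'(y - ybar)| / lambda2 on standardized data.
    """
    from .model_core import Standardizer
    y = validate_outcome(y, table.n)
    Z = Standardizer.fit(table).transform(table)
    X = Z.values[:, roles.classifier_features]
    resid = y - y.mean()
    lam_max = float(np.max(np.abs(X.T @ resid)))
    lam_max /= max(lambda2, 1e-3)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades,
                       n_points)


def select_lambda1(table: FeatureTable, y, roles: FeatureRoles,
                   cfg: em_fit.FitConfig, grid=None,
                   plan: CVPlan | None = None, method: str = "gemlr"):
    """Non-nested CV choice of lambda1; ties resolve to the sparser value."""
    if grid is None:
        grid = default_lambda1_grid(table, y, roles, cfg.lambda2)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise SchemaError("lambda1 grid must be nonempty")
    if plan is None:
        plan = make_folds(y, seed=cfg.seed)
    results = {}
    for lam in grid:
        res = cv_evaluate(table, y, roles, replace(cfg, lambda1=float(lam)),
                          plan, method=method)
        results[float(lam)] = res
    # argmax CV AUC; ties -> larger lambda1 (sparser model)
    best = max(results, key=lambda lam: (round(results[lam].cv_auc, 12), lam))
    return best, results


def select_C(table: FeatureTable, y, roles: FeatureRoles,
             cfg: em_fit.FitConfig, C_grid, plan: CVPlan | None = None):
    """CV choice of the cluster count; ties resolve to the smaller C.

    Values of C that leave an empty cluster are reported as infeasible
    and excluded from the comparison.
    """
    C_grid = [int(c) for c in C_grid]
    if not C_grid:
        raise SchemaError("C grid must be nonempty")
    if plan is None:
        plan = make_folds(y, seed=cfg.seed)
    results, infeasible = {}, []
    for C in C_grid:
        try:
            results[C] = cv_evaluate(table, y, roles, replace(cfg, C=C), plan)
        except InfeasibleClusterError:
            infeasible.append(C)
    if not results:
        raise InfeasibleClusterError(
            min(C_grid), message=f"every requested C in {C_grid} is infeasible")
    best = max(results, key=lambda C: (round(results[C].cv_auc, 12), -C))
    return best, results, infeasible


def top_variance_features(X, k: int) -> list[int]:
    """Indices of the k largest-variance columns (ties -> lowest index)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if k > X.shape[1]:
        raise SchemaError(f"k={k} exceeds the number of features {X.shape[1]}")
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    order = np.argsort(-var, kind="stable")
    return [int(j) for j in order[:k]]


def paired_cv_test(result_a: CVResult, result_b: CVResult):
    """Two-sided paired t-test comparing two methods' repeated CV AUCs.

    Pairs are per-repeat CV AUCs when repeats > 1 (both results must come
    from the same fold plan), otherwise per-fold AUCs.
    """
    if len(result_a.repeat_means) > 1:
        a, b = result_a.repeat_means, result_b.repeat_means
    else:
        a = [x for rep in result_a.fold_aucs for x in rep]
        b = [x for rep in result_b.fold_aucs for x in rep]
    if len(a) != len(b):
        raise SchemaError("paired test requires results from the same plan")
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p_value": float(p),
            "mean_diff": float(np.mean(a) - np.mean(b)), "n_pairs": len(a)}
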