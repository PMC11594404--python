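"""EM estimation: initialization, E/M steps, penalties, and the full loop."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import logit

from gemlr import FitConfig, fit, make_scenario, generate
from gemlr.em_fit import (
    e_step,
    init_gate,
    kkt_violation,
    m_step_gate,
    m_step_heads,
    regularize_covariance,
)
from gemlr.exceptions import InfeasibleClusterError, SchemaError
from gemlr.model_core import (
    FeatureRoles,
    FeatureTable,
    FrequencyHead,
    GaussianComponent,
    LogisticHead,
    MixtureGate,
)


class TestInitGate:
    def test_single_component_is_sample_moments(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 1.5, size=(200, 1))
        gate = init_gate(X, C=1, seed=0)
        assert gate.priors[0] == pytest.approx(1.0)
        assert gate.components[0].mean[0] == pytest.approx(X.mean(), abs=1e-6)
        assert gate.components[0].covariance[0, 0] == pytest.approx(
            X.var(), rel=1e-3)

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(-10, 1, 100),
                            rng.normal(10, 1, 100)])[:, None]
        gate = init_gate(X, C=2, seed=1)
        means = sorted(c.mean[0] for c in gate.components)
        assert abs(means[0] + 10) < 0.5 and abs(means[1] - 10) < 0.5

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, size=(60, 2))
        g1 = init_gate(X, C=3, seed=42)
        g2 = init_gate(X, C=3, seed=42)
        np.testing.assert_array_equal(g1.priors, g2.priors)
        for a, b in zip(g1.components, g2.components):
            np.testing.assert_array_equal(a.mean, b.mean)
            np.testing.assert_array_equal(a.covariance, b.covariance)

    def test_refuses_more_clusters_than_points(self):
        with pytest.raises(InfeasibleClusterError):
            init_gate(np.zeros((3, 1)), C=5)


class TestRegularizeCovariance:
    def test_identity_when_unshrunk(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(regularize_covariance(S, "full", 0.0), S)

    def test_diagonal_matrix_is_fixed_point(self):
        S = np.diag([2.0, 3.0])
        for a in [0.0, 0.5, 0.9]:
            np.testing.assert_allclose(
                regularize_covariance(S, "full", a), S)

    def test_shrinkage_scales_off_diagonal(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = regularize_covariance(S, "full", 0.9)
        assert out[0, 1] == pytest.approx(0.05)

    def test_diagonal_structure_zeroes_covariances(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = regularize_covariance(S, "diagonal", 0.0)
        np.testing.assert_allclose(out, np.eye(2))

    def test_rejects_asymmetric_input(self):
        with pytest.raises(SchemaError):
            regularize_covariance(np.array([[1.0, 0.5], [0.1, 1.0]]), "full", 0.0)

    def test_variance_floor_applied(self):
        S = np.array([[1e-12]])
        out = regularize_covariance(S, "full", 0.0, var_floor=1e-6)
        assert out[0, 0] >= 1e-6


def _sym_gate_and_heads(C=2):
    comps = [GaussianComponent([0.0], [[1.0]]) for _ in range(C)]
    gate = MixtureGate(np.ones(C) / C, comps)
    heads = [LogisticHead([0.3], 0.1) for _ in range(C)]
    return gate, heads


class TestEStep:
    def test_full_symmetry_gives_uniform_rows(self):
        gate, heads = _sym_gate_and_heads(3)
        X = np.array([[0.2], [1.0], [-0.5]])
        R = e_step(X, X, [1, 0, 1], gate, heads)
        np.testing.assert_allclose(R, 1.0 / 3.0, atol=1e-12)

    def test_degenerate_prior(self):
        gate = MixtureGate([1.0, 0.0],
                           [GaussianComponent([0.0], [[1.0]]),
                            GaussianComponent([0.0], [[1.0]])])
        heads = [LogisticHead([0.0], 0.0)] * 2
        R = e_step(np.zeros((4, 1)), np.zeros((4, 1)), [0, 1, 0, 1], gate, heads)
        np.testing.assert_allclose(R, np.tile([1.0, 0.0], (4, 1)), atol=1e-12)

    def test_direct_normalization_oracle(self):
        # equal priors; unequal gate densities; heads symmetric (prob 1/2):
        # responsibilities follow the density ratio (0.2, 0.1) -> (2/3, 1/3)
        gate = MixtureGate([0.5, 0.5],
                           [GaussianComponent([0.0], [[1.0]]),
                            GaussianComponent([2.0], [[2.0]])])
        heads = [LogisticHead([0.0], 0.0)] * 2
        x = np.array([[0.7]])
        d = np.exp(gate.component_log_pdfs(x))[0]
        expected = d / d.sum()
        R = e_step(x, x, [1], gate, heads)
        np.testing.assert_allclose(R[0], expected, atol=1e-12)


class TestMStepGate:
    def test_single_cluster_moments(self):
        X = np.array([[0.0], [2.0]])
        R = np.ones((2, 1))
        gate = m_step_gate(X, R, FitConfig(C=1))
        assert gate.priors[0] == pytest.approx(1.0)
        assert gate.components[0].mean[0] == pytest.approx(1.0)
        # ((0-1)^2 + (2-1)^2) / 2 = 1
        assert gate.components[0].covariance[0, 0] == pytest.approx(1.0)

    def test_one_hot_reduces_to_group_moments(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 2))
        z = rng.integers(0, 2, 50)
        R = np.eye(2)[z]
        gate = m_step_gate(X, R, FitConfig(C=2))
        for c in range(2):
            grp = X[z == c]
            np.testing.assert_allclose(gate.components[c].mean, grp.mean(0),
                                       atol=1e-10)
            dev = grp - grp.mean(0)
            np.testing.assert_allclose(gate.components[c].covariance,
                                       dev.T @ dev / len(grp), atol=1e-8)

    def test_tied_pooling_identity(self):
        # two clusters with identical scatter: pooled covariance equals each
        X = np.array([[-1.0], [1.0], [9.0], [11.0]])
        R = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        full = m_step_gate(X, R, FitConfig(C=2, covariance_structure="full"))
        tied = m_step_gate(X, R, FitConfig(C=2, covariance_structure="tied"))
        np.testing.assert_allclose(tied.components[0].covariance,
                                   full.components[0].covariance, atol=1e-10)
        np.testing.assert_allclose(tied.components[0].covariance,
                                   tied.components[1].covariance)


class TestMStepHeads:
    def test_heavy_penalty_shrinks_to_base_rate(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 2))
        y = rng.integers(0, 2, 100)
        R = np.ones((100, 1))
        heads = m_step_heads(X, y, R, FitConfig(C=1, lambda1=1e3, lambda2=0.8))
        h = heads[0]
        np.testing.assert_allclose(h.coefficients, 0.0, atol=1e-4)
        assert h.intercept == pytest.approx(logit(y.mean()), abs=1e-2)

    def test_unpenalized_single_cluster_equals_mle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < 1 / (1 + np.exp(-(X @ [1.0, -0.5])))).astype(int)
        heads = m_step_heads(X, y, np.ones((200, 1)),
                             FitConfig(C=1, lambda1=0.0))
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert heads[0].intercept == pytest.approx(ref.params[0], abs=1e-5)
        np.testing.assert_allclose(heads[0].coefficients, ref.params[1:],
                                   atol=1e-5)

    def test_zero_weights_equal_subset_refit(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 2))
        y = (rng.random(120) < 0.5).astype(int)
        half = np.zeros(120)
        half[:60] = 1.0
        cfg = FitConfig(C=1, lambda1=0.1, lambda2=0.8, min_cluster_ess=3)
        head_w = m_step_heads(X, y, half[:, None], cfg)[0]
        head_s = m_step_heads(X[:60], y[:60], np.ones((60, 1)), cfg)[0]
        np.testing.assert_allclose(head_w.coefficients, head_s.coefficients,
                                   atol=1e-5)
        assert head_w.intercept == pytest.approx(head_s.intercept, abs=1e-5)

    def test_small_cluster_falls_back_to_frequency(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1, 0, 1])
        R = np.column_stack([np.ones(3), np.zeros(3)])
        heads = m_step_heads(X, y, R, FitConfig(C=2, min_cluster_ess=2))
        assert isinstance(heads[1], FrequencyHead)

    def test_kkt_conditions_at_optimum(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(150, 4))
        y = (rng.random(150) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        lam1, lam2 = 0.5, 0.8
        heads = m_step_heads(X, y, np.ones((150, 1)),
                             FitConfig(C=1, lambda1=lam1, lambda2=lam2))
        v = kkt_violation(X, y, np.ones(150), heads[0], lam1, lam2)
        assert v < 1e-4


class TestFit:
    def test_c1_reduces_to_plain_elastic_net(self, het_data):
        sc, table, y, _ = het_data
        cfg = FitConfig(C=1, lambda1=0.1, lambda2=0.8)
        model = fit(table, y, sc.default_roles(), cfg)
        Z = model.standardizer.transform(table)
        X_L = Z.values[:, sc.default_roles().classifier_features]
        ref = m_step_heads(X_L, y, np.ones((table.n, 1)), cfg)[0]
        np.testing.assert_allclose(model.heads[0].coefficients,
                                   ref.coefficients, atol=1e-6)

    def test_recovers_heterogeneous_partition(self):
        import gemlr
        sc = make_scenario("heterogeneous", n=500, seed=11)
        table, y, truth = generate(sc)
        model = fit(table, y, sc.default_roles(),
                    FitConfig(C=2, lambda1=0.05, seed=11))
        rep = gemlr.recovery_report(model, truth, table)
        assert rep["ari"] >= 0.9

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_nondecreasing(self, seed):
        sc = make_scenario("heterogeneous", n=150, seed=seed)
        table, y, _ = generate(sc)
        model = fit(table, y, sc.default_roles(),
                    FitConfig(C=2, lambda1=0.05, seed=seed))
        tr = model.diagnostics["objective_trace"]
        diffs = np.diff(tr)
        assert np.all(diffs >= -1e-8)

    def test_infeasible_c_raises_with_feasible_maximum(self):
        sc = make_scenario("heterogeneous", n=40, seed=3)
        table, y, _ = generate(sc)
        with pytest.raises(InfeasibleClusterError) as exc:
            fit(table, y, sc.default_roles(), FitConfig(C=39, n_init=1))
        assert exc.value.max_feasible is not None
        assert exc.value.max_feasible < 39

    def test_deterministic_given_seed(self, het_data):
        sc, table, y, _ = het_data
        cfg = FitConfig(C=2, lambda1=0.05, seed=9)
        m1 = fit(table, y, sc.default_roles(), cfg)
        m2 = fit(table, y, sc.default_roles(), cfg)
        assert m1.to_dict() == m2.to_dict()

    def test_sampling_weights_change_the_fit(self, het_data):
        sc, table, y, _ = het_data
        w = np.ones(table.n)
        w[y == 1] = 3.0
        cfg0 = FitConfig(C=1, lambda1=0.05, seed=1)
        cfg1 = FitConfig(C=1, lambda1=0.05, seed=1, sample_weights=w)
        m0 = fit(table, y, sc.default_roles(), cfg0)
        m1 = fit(table, y, sc.default_roles(), cfg1)
        assert m1.heads[0].intercept > m0.heads[0].intercept
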