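"""Latent structure: precision matrices, linear predictor, log joint."""

import networkx as nx
import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import poisson

from anomort.errors import ValidationError
from anomort.model import (
    LatentState,
    ModelSpec,
    build_cyclic_rw1_precision,
    build_icar_precision,
    linear_predictor,
    linear_predictor_matrix,
    log_joint,
    time_covariate,
)
from anomort.synth import make_lattice_states, simulate_latents


class TestCyclicRW1:
    def test_n3_matrix(self):
        expect = np.array([[2.0, -1, -1], [-1, 2, -1], [-1, -1, 2]])
        assert np.array_equal(build_cyclic_rw1_precision(3), expect)

    def test_n12_rank_rowsums_nullspace(self):
        R = build_cyclic_rw1_precision(12)
        assert np.allclose(R.sum(axis=1), 0.0)
        assert np.linalg.matrix_rank(R) == 11
        const = np.ones(12)
        assert const @ R @ const == pytest.approx(0.0)
        assert np.allclose(R, R.T)
        assert np.all(np.linalg.eigvalsh(R) > -1e-12)  # PSD

    def test_quadratic_form_is_cyclic_difference_sum(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        R = build_cyclic_rw1_precision(12)
        direct = sum((x[i] - x[(i + 1) % 12]) ** 2 for i in range(12))
        assert x @ R @ x == pytest.approx(direct)

    def test_too_short_cycle_errors(self):
        with pytest.raises(ValidationError):
            build_cyclic_rw1_precision(2)


class TestICAR:
    def test_path_graph_matrix(self):
        G = nx.path_graph(3)
        expect = np.array([[1.0, -1, 0], [-1, 2, -1], [0, -1, 1]])
        assert np.array_equal(build_icar_precision(G, nodelist=[0, 1, 2]), expect)

    def test_connected_graph_rank_deficiency_one(self):
        G, labels = make_lattice_states(3, 4)
        R = build_icar_precision(G, nodelist=labels)
        assert np.linalg.matrix_rank(R) == len(labels) - 1
        assert np.allclose(R.sum(axis=1), 0.0)

    def test_quadratic_form_equals_edge_sum(self):
        rng = np.random.default_rng(9)
        G = nx.gnp_random_graph(10, 0.4, seed=4)
        nodes = sorted(G.nodes)
        R = build_icar_precision(G, nodelist=nodes)
        x = rng.normal(size=10)
        edge_sum = sum((x[i] - x[j]) ** 2 for i, j in G.edges)
        assert x @ R @ x == pytest.approx(edge_sum)

    def test_isolated_node_warns(self):
        G = nx.Graph()
        G.add_edge("a", "b")
        G.add_node("c")
        with pytest.warns(UserWarning):
            build_icar_precision(G, nodelist=["a", "b", "c"])


def _spec(n_states=4, n_years=2):
    G, labels = make_lattice_states(2, n_states // 2)
    return ModelSpec(adjacency=G, n_times=12 * n_years, state_labels=labels)


class TestLinearPredictor:
    def test_intercept_only(self):
        spec = _spec()
        latent = LatentState.zeros(spec)
        latent.alpha0 = -8.0
        assert linear_predictor(latent, spec, 0, 0, anomaly=0.0) == pytest.approx(-8.0)

    def test_single_anomaly_term(self):
        spec = _spec()
        latent = LatentState.zeros(spec)
        latent.alpha0 = -8.0
        latent.gamma = np.full(12, 0.01)
        t = 12  # midpoint of 24 months has time covariate 0.5, so use gamma only
        val = linear_predictor(latent, spec, 1, t, anomaly=1.5)
        assert val == pytest.approx(-8.0 + 0.01 * 1.5)

    def test_matches_independent_term_by_term_sum(self):
        spec = _spec()
        rng = np.random.default_rng(17)
        latent = simulate_latents(spec, seed=rng)
        x = time_covariate(spec.n_times)
        rng2 = np.random.default_rng(3)
        for _ in range(25):
            s = rng2.integers(spec.n_states)
            t = rng2.integers(spec.n_times)
            a = float(rng2.normal())
            m = t % 12
            # independently coded sum of the eight term groups
            expect = (
                latent.alpha0 + latent.beta0 * x[t]
                + (latent.u_alpha[s] + latent.v_alpha[s])
                + (latent.u_beta[s] + latent.v_beta[s]) * x[t]
                + latent.alpha_month[m] + latent.beta_month[m] * x[t]
                + latent.zeta[s, m] + latent.psi[s, m] * x[t]
                + latent.nu[t] + latent.gamma[m] * a + latent.epsilon[s, t]
            )
            assert linear_predictor(latent, spec, s, t, a) == pytest.approx(expect)

    def test_vectorised_matches_scalar(self):
        spec = _spec()
        latent = simulate_latents(spec, seed=2)
        rng = np.random.default_rng(0)
        A = rng.normal(size=(spec.n_states, spec.n_times))
        eta = linear_predictor_matrix(latent, spec, A)
        for s in (0, 3):
            for t in (0, 11, 23):
                assert eta[s, t] == pytest.approx(
                    linear_predictor(latent, spec, s, t, A[s, t])
                )

    def test_all_random_effects_zero_is_plain_glm(self):
        spec = _spec()
        latent = LatentState.zeros(spec)
        latent.alpha0, latent.beta0 = -7.0, 0.002
        latent.gamma = np.full(12, 0.02)
        rng = np.random.default_rng(1)
        A = rng.normal(size=(spec.n_states, spec.n_times))
        eta = linear_predictor_matrix(latent, spec, A)
        x = time_covariate(spec.n_times)
        expect = -7.0 + 0.002 * x + 0.02 * A
        assert np.allclose(eta, expect)


class TestLogJoint:
    def _inputs(self, spec, latent, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(spec.n_states, spec.n_times))
        P = np.full((spec.n_states, spec.n_times), 1e5)
        mu = np.exp(linear_predictor_matrix(latent, spec, A)) * P
        y = rng.poisson(mu)
        return y, P, A

    def test_poisson_zero_count_limit(self):
        # with deaths = 0 the log likelihood term is exactly -rate*pop
        spec = _spec()
        latent = LatentState.zeros(spec)
        latent.alpha0 = -10.0
        latent.log_precisions = {b: 0.0 for b in spec.active_blocks()}
        y = np.zeros((spec.n_states, spec.n_times))
        P = np.full_like(y, 1e4)
        A = np.zeros_like(y)
        lj = log_joint(latent, spec, y, P, A)
        # subtract the same model's priors by zeroing the data term
        lj0 = log_joint(latent, spec, y, P * 0.0, A)
        assert lj - lj0 == pytest.approx(-(np.exp(-10.0) * 1e4 * y.size))

    def test_single_observation_closed_form(self):
        # deaths=2 with rate*pop=2: loglik = 2 log 2 - 2 - log 2!
        assert poisson.logpmf(2, 2.0) == pytest.approx(2 * np.log(2) - 2 - np.log(2))

    def test_matches_independent_reference_implementation(self):
        spec = _spec(n_states=4, n_years=1)
        latent = simulate_latents(spec, seed=8)
        y, P, A = self._inputs(spec, latent, seed=4)
        got = log_joint(latent, spec, y, P, A)

        # --- reference implementation, written independently ---
        from anomort.model import BLOCK_INFO, structure_matrix, structure_rank

        eta = linear_predictor_matrix(latent, spec, A)
        ref = float(np.sum(poisson.logpmf(y, np.exp(eta) * P)))
        ref += -0.5 * latent.alpha0**2 / 1e6 - 0.5 * np.log(2 * np.pi * 1e6)
        ref += -0.5 * latent.beta0**2 / 1e3 - 0.5 * np.log(2 * np.pi * 1e3)
        for name in spec.active_blocks():
            tau = np.exp(latent.log_precisions[name])
            R = structure_matrix(spec, name)
            x = latent.block(name)
            ev = np.linalg.eigvalsh(R)
            pos = ev[ev > 1e-9]
            rank = structure_rank(spec, name)
            if BLOCK_INFO[name][1] and rank == len(x):
                rank -= 1
            ref += (
                0.5 * rank * np.log(tau)
                + 0.5 * np.sum(np.log(pos))
                - 0.5 * rank * np.log(2 * np.pi)
                - 0.5 * tau * float(x @ R @ x)
            )
            lt = latent.log_precisions[name]
            ref += np.log(0.001) + lt - 0.001 * np.exp(lt) - gammaln(1.0)
        assert got == pytest.approx(ref, rel=1e-10)

    def test_negative_inputs_error(self):
        spec = _spec()
        latent = simulate_latents(spec, seed=1)
        y, P, A = self._inputs(spec, latent)
        with pytest.raises(ValidationError):
            log_joint(latent, spec, -y - 1, P, A)
        with pytest.raises(ValidationError):
            log_joint(latent, spec, y, -P, A)


class TestModelSpec:
    def test_asymmetric_adjacency_rejected(self):
        G = nx.DiGraph([("a", "b")])
        with pytest.raises((ValidationError, nx.NetworkXError)):
            ModelSpec(adjacency=G, n_times=12)

    def test_bad_hyperprior_rejected(self):
        G, _ = make_lattice_states(1, 2)
        with pytest.raises(ValidationError):
            ModelSpec(adjacency=G, n_times=12, hyper_rate=-1.0)

    def test_active_blocks_follow_component_toggles(self):
        G, _ = make_lattice_states(1, 2)
        spec = ModelSpec(
            adjacency=G, n_times=12,
            components={"spatial": False, "seasonal": True, "interaction": False,
                        "time_rw": False, "anomaly": True, "overdispersion": False},
        )
        assert spec.active_blocks() == ["alpha_month", "beta_month", "gamma"]
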