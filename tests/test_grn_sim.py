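"""Unit and property tests for the toggle-switch network simulator."""

import numpy as np
import pytest
from scipy.optimize import brentq

from bifurscan import (
    GRNParams,
    build_network,
    critical_control,
    drift,
    find_driver_fixed_points,
    jacobian,
    simulate,
    slowest_mode,
    sweep,
)
from bifurscan.errors import (
    BracketingError,
    DomainError,
    InvalidNetworkError,
)
from bifurscan.grn_sim import noise_diffusion, responder_steady_state


def core(m1=1.0, m2=1.0, k_D=1.0, **kw):
    return build_network(n_g=2, m1=m1, m2=m2, k_D=k_D, **kw)


class TestBuildNetwork:
    def test_degenerate_two_gene_network_has_no_responders(self):
        p = core()
        assert p.n_responders == 0
        assert p.alpha.size == 0

    def test_too_few_genes_rejected(self):
        with pytest.raises(InvalidNetworkError):
            build_network(n_g=1)

    def test_default_network_is_balanced_and_reproducible(self):
        a = build_network(n_g=102, seed=7)
        b = build_network(n_g=102, seed=7)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.sum(a.driver_of == 1) == 50
        assert np.sum(a.driver_of == 2) == 50
        assert np.all((a.alpha >= 0) & (a.alpha <= 1))
        c = build_network(n_g=102, seed=8)
        assert not np.array_equal(a.alpha, c.alpha)

    def test_constant_alpha_sampling(self):
        p = build_network(n_g=4, alpha_sampling=0.0)
        assert np.all(p.alpha == 0.0)
        # alpha = 0 is full inhibition: responder synthesis falls with driver
        lo = drift(np.array([0.0, 0.0, 0.0, 0.0]), p)
        hi = drift(np.array([5.0, 5.0, 0.0, 0.0]), p)
        assert np.all(hi[2:] < lo[2:])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidNetworkError):
            core(k_D=-1.0)
        with pytest.raises(InvalidNetworkError):
            build_network(n_g=4, alpha_sampling=2.0)


class TestDrift:
    def test_balanced_driver_state_has_zero_drift(self):
        # -0.5 * 1 + 1 / (1 + 1) = 0 for both drivers
        p = core(k_D=0.5)
        np.testing.assert_allclose(drift(np.array([1.0, 1.0]), p), 0.0, atol=1e-15)

    def test_origin_drift_is_pure_synthesis(self):
        p = core(k_D=1.0)
        np.testing.assert_allclose(drift(np.zeros(2), p), [1.0, 1.0])

    def test_responder_activation_branch_steady_value(self):
        # alpha = 1, k_i = 1, driver at 1, m_d = 2: steady value 2*(1/2)/1 = 1
        p = build_network(n_g=3, m1=2.0, m2=2.0, alpha_sampling=1.0)
        assert p.driver_of[0] == 1
        rs = responder_steady_state(1.0, 1.0, p)
        np.testing.assert_allclose(rs, [1.0])
        state = np.array([1.0, 1.0, 1.0])
        np.testing.assert_allclose(drift(state, p)[2], 0.0, atol=1e-15)

    def test_negative_state_rejected(self):
        with pytest.raises(DomainError):
            drift(np.array([-0.1, 1.0]), core())


class TestJacobian:
    def test_pitchfork_driver_block_is_singular(self):
        p = core(k_D=0.5)
        J = jacobian(np.array([1.0, 1.0]), p)
        np.testing.assert_allclose(J, [[-0.5, -0.5], [-0.5, -0.5]])
        lam, v = slowest_mode(J)
        assert lam == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.abs(v), np.ones(2) / np.sqrt(2))

    def test_diagonal_is_negated_degradation(self):
        p = build_network(n_g=10, seed=3, k_D=0.7, k_resp_value=1.3)
        J = jacobian(np.linspace(0.1, 2.0, 10), p)
        np.testing.assert_allclose(np.diag(J)[:2], -0.7)
        np.testing.assert_allclose(np.diag(J)[2:], -1.3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        p = build_network(n_g=8, seed=seed, m1=2.0, m2=3.0)
        state = rng.uniform(0.2, 3.0, 8)
        J = jacobian(state, p)
        h = 1e-6
        num = np.empty_like(J)
        for j in range(8):
            up, dn = state.copy(), state.copy()
            up[j] += h
            dn[j] -= h
            num[:, j] = (drift(up, p) - drift(dn, p)) / (2 * h)
        np.testing.assert_allclose(J, num, rtol=1e-6, atol=1e-6)


class TestFixedPoints:
    def test_monostable_symmetric_point(self):
        # g* solves g (1 + g^2) = 1; independent 1-D bisection oracle
        g_star = brentq(lambda g: g * (1 + g**2) - 1, 0, 2, xtol=1e-14)
        fps = find_driver_fixed_points(core(m1=1.0, m2=1.0, k_D=1.0))
        assert len(fps) == 1
        assert fps[0].stable
        np.testing.assert_allclose(fps[0].drivers, [g_star, g_star], atol=1e-8)
        assert g_star == pytest.approx(0.6823, abs=1e-4)

    def test_bistable_regime_has_three_points(self):
        fps = find_driver_fixed_points(core(m1=3.0, m2=3.0, k_D=1.0))
        assert len(fps) == 3
        stables = [fp for fp in fps if fp.stable]
        assert len(stables) == 2
        saddle = next(fp for fp in fps if not fp.stable)
        assert saddle.drivers[0] == pytest.approx(saddle.drivers[1], abs=1e-8)

    def test_pitchfork_threshold_point(self):
        fps = find_driver_fixed_points(core(k_D=0.5))
        central = min(fps, key=lambda fp: abs(fp.drivers[0] - 1.0))
        np.testing.assert_allclose(central.drivers, [1.0, 1.0], atol=1e-5)
        assert central.lambda_d == pytest.approx(0.0, abs=1e-5)

    def test_responders_at_closed_form_values(self):
        p = build_network(n_g=6, seed=1, m1=2.0, m2=2.0)
        fps = find_driver_fixed_points(p)
        for fp in fps:
            g1, g2 = fp.drivers
            np.testing.assert_allclose(
                fp.state[2:], responder_steady_state(g1, g2, p), atol=1e-8
            )
            # drift vanishes at every reported fixed point
            assert np.max(np.abs(drift(fp.state, p))) < 1e-6


class TestCriticalControl:
    def test_pitchfork_degradation_threshold(self):
        value = critical_control(core(), "k_D", (0.24, 5.0))
        assert value == pytest.approx(0.5, abs=1e-6)

    def test_saddle_node_balance_point(self):
        value = critical_control(core(m1=2.0, m2=3.0), "m1", (2.0, 4.0))
        assert value == pytest.approx(3.0, abs=1e-6)

    def test_bracket_without_crossing_raises(self):
        with pytest.raises(BracketingError):
            critical_control(core(), "k_D", (1.0, 5.0))


class TestSimulate:
    def test_same_seed_reproduces_matrix(self):
        p = build_network(n_g=10, seed=5, n_c=20, n_steps=500)
        a = simulate(p)
        b = simulate(p)
        assert np.array_equal(a.values, b.values)
        assert a.cell_ids == b.cell_ids

    def test_noiseless_limit_reaches_fixed_points(self):
        # huge s: every cell must settle onto a deterministic fixed point
        p = build_network(n_g=6, seed=2, n_c=30, m1=3.0, m2=3.0,
                          s=1e16, n_steps=8000)
        G = simulate(p)
        fps = find_driver_fixed_points(p)
        stable = np.array([fp.state for fp in fps if fp.stable])
        for row in G.values:
            assert min(np.max(np.abs(row - s)) for s in stable) < 1e-3
            assert np.max(np.abs(drift(row, p))) < 1e-6

    def test_bimodal_driver_distribution_at_balanced_point(self):
        from bifurscan.eigvec import is_bimodal

        p = build_network(n_g=2, seed=11, n_c=100, m1=3.0, m2=3.0, n_steps=5000)
        g1 = simulate(p).values[:, 0]
        flag, _ = is_bimodal(g1, delta_bic=10.0, seed=0)
        assert flag

    def test_driver_exchange_symmetry(self):
        # with m1 = m2 the two drivers are statistically exchangeable
        p = build_network(n_g=2, seed=9, n_c=400, m1=1.0, m2=1.0, n_steps=3000)
        G = simulate(p).values
        m1_mean, m2_mean = G[:, 0].mean(), G[:, 1].mean()
        pooled_sd = G.std() / np.sqrt(G.shape[0])
        assert abs(m1_mean - m2_mean) < 5 * pooled_sd


class TestSweep:
    def test_single_point_grid_matches_simulate(self):
        p = build_network(n_g=4, seed=3, n_c=10, n_steps=200)
        [(value, G)] = sweep(p, "m1", [2.5])
        assert value == 2.5
        assert G.values.shape == (10, 4)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(DomainError):
            sweep(core(), "m1", [3.0, 2.0])

    def test_mean_driver_expression_jumps_across_balance(self, saddle_sweep):
        _, results = saddle_sweep
        means = {m1: G.values[:, 0].mean() for m1, G in results}
        # g1 is low before the transition, high after, with a large jump
        assert means[4.0] > 5 * means[2.0]
        jumps = np.diff([means[k] for k in sorted(means)])
        i = int(np.argmax(jumps))
        assert sorted(means)[i] in (2.75, 3.0, 3.25)

    def test_pitchfork_branch_splitting_below_threshold(self):
        p = build_network(n_g=2, seed=13, n_c=60, m1=1.0, m2=1.0, n_steps=4000)
        results = sweep(p, "k_D", [0.3, 1.0])
        low = results[0][1].values[:, 0]
        high = results[1][1].values[:, 0]
        # above threshold: one tight mode; below: two branches, far apart
        assert low.std() > 3 * high.std()


class TestOUConsistency:
    def test_steady_state_covariance_matches_lyapunov_prediction(self):
        """Fluctuations around a stable fixed point follow the OU law."""
        from bifurscan import covariance_eig, solve_lyapunov

        # weak noise keeps fluctuations inside the linear neighbourhood
        # of the fixed point, where the OU description is exact
        p = build_network(n_g=6, seed=21, n_c=3000, m1=1.0, m2=1.0,
                          k_D=1.0, s=2000.0, n_steps=2000)
        fp = find_driver_fixed_points(p)[0]
        J = jacobian(fp.state, p)
        Q = np.diag(noise_diffusion(fp.state, p))
        C = solve_lyapunov(J, Q).C
        G = simulate(p)
        omega_pred = np.linalg.eigvalsh(C)[-1]
        omega_obs = covariance_eig(G).omega1
        # top eigenvalue of a Wishart-like estimate: ~3 relative standard
        # errors at n_c = 3000
        assert abs(omega_obs - omega_pred) < 3 * omega_pred * np.sqrt(2 / p.n_c)
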