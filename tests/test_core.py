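"""Connectivity, Hebbian storage, softmax updates and the threshold dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pottsbuffer.core import (
    Connectivity,
    NetworkParams,
    NetworkState,
    PottsNetwork,
    build_connectivity,
    compute_field,
    store_autoassociative,
    update_activations,
    wm_kick_mask,
)
from pottsbuffer.patterns import PatternSet, generate_random_patterns


def small_params(**kw):
    base = dict(N=12, S=3, a=0.5, C_m=6, beta=10.0, U=0.1, w=0.5)
    base.update(kw)
    return NetworkParams(**base)


class TestConnectivity:
    def test_row_degree_and_no_self(self):
        c = build_connectivity(200, 200, 150, seed=0)
        assert np.all(c.c.sum(axis=1) == 150)
        assert not np.any(np.diag(c.c))

    def test_all_to_all_when_self_allowed(self):
        c = build_connectivity(5, 5, 5, self_allowed=True, seed=0)
        assert np.all(c.c)

    def test_deterministic(self):
        a = build_connectivity(50, 50, 20, seed=3)
        b = build_connectivity(50, 50, 20, seed=3)
        assert np.array_equal(a.c, b.c)

    def test_too_many_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_connectivity(10, 10, 10, self_allowed=False)


class TestStorage:
    def test_no_patterns_zero_weights(self):
        pats = PatternSet(states=np.zeros((0, 12), dtype=int), S=3, a=0.5)
        W = store_autoassociative(pats, build_connectivity(12, 12, 6, seed=0),
                                  small_params())
        assert np.all(W.W == 0)

    def test_hand_evaluated_two_unit_weight(self):
        # one pattern xi = (1, 2) on 2 units, S=2, a=0.5, C_m=1:
        # J_12^{1,2} = (1 - a/S)^2 / (C_m a (1 - a/S)) = 0.75^2 / 0.375 = 1.5
        pats = PatternSet(states=np.array([[1, 2]]), S=2, a=0.5)
        conn = Connectivity(c=np.array([[False, True], [True, False]]))
        W = store_autoassociative(pats, conn, NetworkParams(N=2, S=2, a=0.5, C_m=1))
        J = W.W.reshape(2, 2, 2, 2)
        assert J[0, 0, 1, 1] == pytest.approx(1.5)
        # zero where the connectivity is zero
        assert np.all(J[0, :, 0, :] == 0) and np.all(J[1, :, 1, :] == 0)

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(7)
        N, S, a, p, Cm = 14, 3, 0.5, 5, 7
        pats = generate_random_patterns(N, S, a, p, rng)
        conn = build_connectivity(N, N, Cm, seed=rng)
        W = store_autoassociative(pats, conn, small_params(N=N, C_m=Cm))
        J = np.zeros((N, S, N, S))
        for i in range(N):
            for j in range(N):
                if conn.c[i, j]:
                    for k in range(1, S + 1):
                        for l in range(1, S + 1):
                            J[i, k - 1, j, l - 1] = sum(
                                ((pats.states[mu, i] == k) - a / S)
                                * ((pats.states[mu, j] == l) - a / S)
                                for mu in range(p)
                            ) / (Cm * a * (1 - a / S))
        assert np.allclose(J.reshape(N * S, N * S), W.W, atol=1e-5)

    def test_weights_mean_zero_over_pattern_draws(self):
        # the mean-subtracted kernel makes E[J] ~ 0 over random pattern draws
        # (exact-count sparsity leaves an O(1/N) anticorrelation, hence the
        # small additive allowance on top of the Monte-Carlo standard error)
        N, S, a = 40, 3, 0.5
        vals = []
        conn = Connectivity(c=np.eye(N, k=1, dtype=bool) | np.eye(N, k=1 - N, dtype=bool))
        params = NetworkParams(N=N, S=S, a=a, C_m=1)
        for seed in range(1200):
            pats = generate_random_patterns(N, S, a, 1, seed)
            W = store_autoassociative(pats, conn, params)
            vals.append(W.W.reshape(N, S, N, S)[0, 0, 1, 1])
        se = np.std(vals) / np.sqrt(len(vals))
        bias_bound = (a / S) ** 2 / (N - 1) / (a * (1 - a / S))
        assert abs(np.mean(vals)) < 3 * se + bias_bound


class TestField:
    def test_zero_activity_zero_field(self):
        params = small_params()
        pats = generate_random_patterns(12, 3, 0.5, 4, seed=0)
        W = store_autoassociative(pats, build_connectivity(12, 12, 6, seed=1), params)
        sigma = np.zeros((12, 4))
        sigma[:, 0] = 1.0
        assert np.allclose(compute_field(sigma, W, params), 0.0)

    def test_signal_positive_on_stored_pattern(self):
        # clamped at the single stored pattern with full connectivity and w=0,
        # the field is positive exactly on the pattern's own (unit, state) pairs
        N, S, a = 10, 3, 0.5
        params = NetworkParams(N=N, S=S, a=a, C_m=N - 1, w=0.0)
        pats = generate_random_patterns(N, S, a, 1, seed=5)
        conn = build_connectivity(N, N, N - 1, seed=0)
        W = store_autoassociative(pats, conn, params)
        sigma = np.zeros((N, S + 1))
        sigma[:, 0] = 1.0
        xi = pats.states[0]
        on = xi > 0
        sigma[on, 0] = 0.0
        sigma[on, xi[on]] = 1.0
        h = compute_field(sigma, W, params)
        for i in range(N):
            for k in range(1, S + 1):
                if xi[i] == k:
                    assert h[i, k - 1] > 0
                else:
                    assert h[i, k - 1] <= 1e-9

    def test_uniform_sigma_kills_feedback_term(self):
        params = small_params(w=0.9)
        pats = PatternSet(states=np.zeros((0, 12), dtype=int), S=3, a=0.5)
        W = store_autoassociative(pats, build_connectivity(12, 12, 6, seed=0), params)
        sigma = np.full((12, 4), 0.25)
        assert np.allclose(compute_field(sigma, W, params), 0.0, atol=1e-12)


class TestActivations:
    def test_symmetric_case_uniform_simplex(self):
        S, thr = 4, 0.3
        r = np.full((1, 6, S), thr)
        sig = update_activations(r, np.zeros((1, 6)), thr * 0, 8.0)
        # r equal to the quiescent threshold for every state: all S+1 options tie
        sig2 = update_activations(np.full((1, 6, S), 0.3), np.zeros((1, 6)), 0.3, 8.0)
        assert np.allclose(sig2, 1.0 / (S + 1))

    def test_winner_take_all_at_large_beta(self):
        r = np.array([[[0.5, 0.1, 0.1]]])
        sig = update_activations(r, np.zeros((1, 1)), 0.2, 500.0)
        assert sig[0, 0, 1] > 0.999

    def test_hand_evaluated_softmax(self):
        # beta=12.5, S=2, r=(0.2, 0.0), theta0+U = 0.1
        num = np.exp(np.array([12.5 * 0.1, 12.5 * 0.2, 0.0]))
        expected = num / num.sum()
        sig = update_activations(np.array([[[0.2, 0.0]]]), np.zeros((1, 1)), 0.1, 12.5)
        assert np.allclose(sig[0, 0], expected, atol=1e-12)

    def test_overflow_stabilization(self):
        r = np.array([[[4000.0, 3999.0]]])
        sig = update_activations(r, np.zeros((1, 1)), 0.1, 12.5)
        assert np.all(np.isfinite(sig))
        shifted = update_activations(r - 3999.0, np.zeros((1, 1)), 0.1 - 3999.0, 12.5)
        assert np.allclose(sig, shifted, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rows_always_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.normal(0, 2, size=(3, 5, 4))
        theta0 = rng.uniform(0, 1, size=(3, 5))
        sig = update_activations(r, theta0, rng.uniform(0, 0.5), 12.5)
        assert np.allclose(sig.sum(axis=-1), 1.0, atol=1e-10)
        assert np.all(sig >= 0) and np.all(sig <= 1)
        assert np.all(np.isfinite(sig))


def quiet_network(dynamic_threshold=False, **kw):
    params = small_params(dynamic_threshold=dynamic_threshold, **kw)
    pats = generate_random_patterns(params.N, params.S, params.a, 3, seed=2)
    conn = build_connectivity(params.N, params.N, params.C_m, seed=2)
    return PottsNetwork(params, store_autoassociative(pats, conn, params)), pats


class TestDynamics:
    def test_relaxation_from_preloaded_inhibition(self):
        net, _ = quiet_network(dynamic_threshold=True, gamma_A=0.5, tau_B=50.0)
        state = net.null_state()
        state.theta_A[:] = 0.7
        state.theta_B[:] = 0.7
        state.U_hat[:] = 0.8
        thA0, thB0, u0 = state.theta_A.mean(), state.theta_B.mean(), state.U_hat[0]
        for _ in range(200):
            net.step(state, net.fields(state.sigma))
        # with the network quiescent all inhibition decays toward its small
        # resting level
        assert state.theta_A.mean() < 0.2 * thA0
        assert state.theta_B.mean() < thB0
        assert state.U_hat[0] < 0.5 * u0

    def test_dynamic_threshold_fixed_point_under_clamped_activity(self):
        # with exactly a*N units fully active the drive is (a*N)/(a*N) = 1,
        # so U^ relaxes to 1
        net, pats = quiet_network(dynamic_threshold=True)
        params = net.params
        state = net.null_state()
        n_active = int(params.a * params.N)
        sigma = np.zeros((params.N, params.S + 1))
        sigma[:, 0] = 1.0
        sigma[:n_active, 0] = 0.0
        sigma[:n_active, 1] = 1.0
        for _ in range(100):
            state.sigma = sigma.copy()  # clamp
            net.step(state, net.fields(state.sigma))
        assert state.U_hat[0] == pytest.approx(1.0, rel=1e-3)

    def test_ablated_dynamic_threshold_stays_zero(self):
        net, pats = quiet_network(dynamic_threshold=False, U=0.216)
        state = net.null_state()
        for _ in range(50):
            net.step(state, net.fields(state.sigma))
        assert np.all(state.U_hat == 0.0)

    def test_simplex_conserved_along_trajectory(self):
        net, pats = quiet_network(dynamic_threshold=True, gamma_A=0.3)
        state = net.null_state((2,))
        for _ in range(100):
            net.step(state, net.fields(state.sigma))
            assert np.allclose(state.sigma.sum(axis=-1), 1.0, atol=1e-10)

    def test_nonfinite_state_raises(self):
        net, _ = quiet_network()
        state = net.null_state()
        with pytest.raises(FloatingPointError):
            net.step(state, np.full((net.params.N, net.params.S), np.nan))


class TestWMKick:
    def test_mask_size_single_pattern(self):
        pats = generate_random_patterns(200, 7, 0.25, 10, seed=1)
        mask = wm_kick_mask(pats, [4])
        assert mask.sum() == 50  # aN active (unit, state) pairs

    def test_mask_fraction_matches_union_probability(self):
        # fraction of kicked (unit,state) pairs ~ 1 - (1 - a/S)^M
        pats = generate_random_patterns(400, 7, 0.25, 40, seed=3)
        for M in (1, 5, 20):
            mask = wm_kick_mask(pats, range(M))
            frac = mask.mean()
            expect = 1 - (1 - 0.25 / 7) ** M
            assert frac == pytest.approx(expect, rel=0.1)

    def test_zero_kick_identical_dynamics(self):
        params = small_params(gamma_A=0.2)
        pats = generate_random_patterns(params.N, params.S, params.a, 3, seed=2)
        conn = build_connectivity(params.N, params.N, params.C_m, seed=2)
        W = store_autoassociative(pats, conn, params)
        mask = wm_kick_mask(pats, [0, 1])
        base = PottsNetwork(params, W)
        kicked = PottsNetwork(params, W, kick_mask=mask, delta_theta=0.0)
        s1, s2 = base.null_state(), kicked.null_state()
        for _ in range(50):
            base.step(s1, base.fields(s1.sigma))
            kicked.step(s2, kicked.fields(s2.sigma))
        assert np.array_equal(s1.sigma, s2.sigma)

    def test_empty_wm_set_rejected(self):
        pats = generate_random_patterns(20, 3, 0.5, 2, seed=0)
        with pytest.raises(ValueError):
            wm_kick_mask(pats, [])
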