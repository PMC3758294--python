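"""Bayesian-Hebbian learning rule: traces, gated estimates, log-odds
weights, bias, and the structural invariants (sign structure, symmetry,
palimpsest forgetting)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latchnet import (ModelParams, compute_bias, compute_weights,
                      init_state, step, update_p_estimates,
                      update_z_traces)


class TestZTraces:
    def test_fixed_point(self):
        z = np.full(5, 0.4)
        assert np.allclose(update_z_traces(z, z.copy(), 0.24, 0.001), z)

    def test_relaxation_matches_analytic(self):
        """o=1 held from z=0: z(tau_z) = 1 - 1/e within 1%."""
        z = np.zeros(5)
        o = np.ones(5)
        for _ in range(240):
            z = update_z_traces(z, o, 0.240, 0.001)
        assert np.allclose(z, 1 - np.exp(-1), rtol=0.01)

    def test_default_time_constant(self, params):
        assert params.tau_zi == 0.240
        assert params.tau_zj == 0.240

    def test_background_floor_binds(self):
        z = np.full(3, 0.05)
        z = update_z_traces(z, np.zeros(3), 0.24, 0.001, z_floor=0.05)
        assert np.all(z == 0.05)


class TestPEstimates:
    def test_kappa_zero_freezes_exactly(self, rng):
        p_i = rng.uniform(0.01, 0.9, 10)
        p_j = rng.uniform(0.01, 0.9, 10)
        p_ij = rng.uniform(0.001, 0.5, (10, 10))
        z = rng.uniform(0, 1, 10)
        for _ in range(50):
            out = update_p_estimates(p_i, p_j, p_ij, z, z, 0.0, 10.0,
                                     0.001)
        assert out[0] is p_i and out[1] is p_j and out[2] is p_ij

    def test_saturating_drive_matches_analytic(self):
        """kappa=1, z_i=z_j=1 held: p_ij relaxes from 1/M^2 toward 1 with
        time constant tau_p; value at t=tau_p within 1% of analytic."""
        M, tau_p, dt = 12, 10.0, 0.001
        p_i = np.full(2, 1 / M)
        p_j = np.full(2, 1 / M)
        p_ij = np.full((2, 2), 1 / M**2)
        z = np.ones(2)
        for _ in range(round(tau_p / dt)):
            p_i, p_j, p_ij = update_p_estimates(p_i, p_j, p_ij, z, z,
                                                1.0, tau_p, dt)
        expect = 1 + (1 / M**2 - 1) * np.exp(-1)
        assert np.allclose(p_ij, expect, rtol=0.01)

    def test_uniform_stationary_activity_keeps_independence(self, rng):
        """o = 1/M forever: estimates stay at chance, weights at zero."""
        params = ModelParams(H=2, M=4)
        st_ = init_state(params)
        for _ in range(2000):
            step(st_, params, rng, kappa=1.1, g_w=2.0,
                 clamp_o=np.full(8, 0.25))
        assert np.allclose(st_.p_i, 0.25, atol=1e-12)
        assert np.allclose(st_.p_ij, 0.0625, atol=1e-12)
        assert np.allclose(st_.w, 0.0, atol=1e-9)


class TestWeightsAndBias:
    def test_independence_gives_zero(self):
        p = np.array([0.3, 0.5])
        w = compute_weights(p, p, np.outer(p, p), 2.0, 1e-38)
        assert np.allclose(w, 0.0, atol=1e-12)

    def test_perfect_correlation_value(self):
        """p_i = p_j = p_ij = 0.5, g_w = 2: w = 2 log 2."""
        p = np.array([0.5])
        w = compute_weights(p, p, np.array([[0.5]]), 2.0, 1e-38)
        assert np.isclose(w[0, 0], 2 * np.log(2))
        assert np.isclose(w[0, 0], 1.3863, atol=1e-4)

    def test_anticorrelation_is_strongly_inhibitory(self):
        p = np.full(2, 1 / 12)
        pij = np.full((2, 2), 1.17549e-38)
        w = compute_weights(p, p, pij, 2.0, 1.17549e-38)
        assert np.all(w < -100)

    def test_bias_values(self):
        assert compute_bias(np.array([1.0]), 12.0, 1e-38)[0] == 0.0
        b = compute_bias(np.array([1 / 12]), 12.0, 1e-38)[0]
        assert np.isclose(b, 12 * np.log(1 / 12))
        assert np.isclose(b, -29.82, atol=0.01)

    def test_bias_monotone_in_activity(self):
        b = compute_bias(np.array([0.01, 0.1, 0.5]), 12.0, 1e-38)
        assert b[0] < b[1] < b[2]


def _encode_sequence(params, patterns_dense, clamp_steps):
    """Deterministically hard-clamp a sequence of patterns with the
    plasticity gate open (no noise, no free dynamics)."""
    st_ = init_state(params)
    r = np.random.default_rng(0)
    for pat in patterns_dense:
        for _ in range(clamp_steps):
            step(st_, params, r, kappa=params.kappa_encode,
                 g_w=params.g_w_encode, clamp_o=pat)
    return st_


class TestStructure:
    def test_two_disjoint_patterns_sign_structure(self):
        """Within-pattern weights excitatory, between-pattern inhibitory,
        and the within mean exceeds the between magnitude comparison."""
        params = ModelParams(H=4, M=4)
        a = np.zeros(16); a[[0, 4, 8, 12]] = 1.0
        b = np.zeros(16); b[[1, 5, 9, 13]] = 1.0
        st_ = _encode_sequence(params, [a, b], 1000)
        ia, ib = np.flatnonzero(a), np.flatnonzero(b)
        within = np.concatenate([st_.w[np.ix_(ia, ia)].ravel(),
                                 st_.w[np.ix_(ib, ib)].ravel()])
        between = st_.w[np.ix_(ia, ib)].ravel()
        assert np.all(within > 0)
        assert np.all(between < 0)
        assert within.mean() > 0 > between.mean()

    def test_palimpsest_earliest_weaker_than_latest(self):
        """After a long encoded sequence the earliest item's mean
        within-pattern weight is below the latest item's (new memories
        overwrite old ones as estimates relax to background)."""
        params = ModelParams(H=4, M=6)
        r = np.random.default_rng(3)
        n_items = 30
        pats = []
        for _ in range(n_items):
            d = np.zeros(24)
            d[np.arange(4) * 6 + r.integers(0, 6, 4)] = 1.0
            pats.append(d)
        st_ = _encode_sequence(params, pats, 1000)
        def within_mean(d):
            idx = np.flatnonzero(d)
            return st_.w[np.ix_(idx, idx)].mean()
        assert within_mean(pats[0]) < within_mean(pats[-1])

    def test_weight_symmetry_under_shared_history(self, rng):
        """tau_zi = tau_zj and identical trace histories make the weight
        matrix symmetric."""
        params = ModelParams(H=3, M=4)
        st_ = init_state(params)
        for _ in range(800):
            step(st_, params, rng, kappa=1.1, g_w=2.0)
        assert np.allclose(st_.w, st_.w.T, atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_boundedness(self, seed):
        """z stays in [floor, 1] and p in (0, 1] under arbitrary valid
        output sequences."""
        r = np.random.default_rng(seed)
        params = ModelParams(H=2, M=3)
        st_ = init_state(params)
        for _ in range(300):
            o = r.dirichlet(np.ones(3), size=2).ravel()
            step(st_, params, r, kappa=1.1, g_w=2.0, clamp_o=o)
        for z in (st_.z_i, st_.z_j):
            assert np.all(z >= params.z_floor - 1e-12)
            assert np.all(z <= 1.0 + 1e-12)
        for p in (st_.p_i, st_.p_j):
            assert np.all((p > 0) & (p <= 1.0 + 1e-12))
        assert np.all((st_.p_ij > 0) & (st_.p_ij <= 1.0 + 1e-12))
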