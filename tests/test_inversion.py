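"""Inverse-retrieval tests: algebra, cost/gradient oracles, recovery."""

import numpy as np
import pytest

from tfflim import CMOSImage, IRConfig, SystemConfig, simulate_cmos, simulate_iccd
from tfflim.forward import decay_gate_integral, valid_region
from tfflim.inversion import amplitude_from_cmos, cost, gradient, retrieve


@pytest.fixture(scope="module")
def small_instance(small_cfg):
    """Random 8x8 instance on the 3-replica system (margin 4)."""
    rng = np.random.default_rng(0)
    H, Ws = 8, 8 + small_cfg.margin
    tau_t = rng.uniform(0.8, 3.0, (H, Ws))
    amp = rng.uniform(50, 200, (H, Ws))
    s = simulate_iccd(tau_t, amp, small_cfg).s
    q = simulate_cmos(tau_t, amp, small_cfg).q
    return tau_t, amp, q, s


class TestAmplitudeFromCMOS:
    def test_algebra(self):
        a = amplitude_from_cmos(np.full((2, 2), 6.0), np.full((2, 2), 3.0), 1.0)
        assert np.array_equal(a.a, np.full((2, 2), 2.0))

    def test_inverse_of_forward(self, cfg, rng):
        shape = (3, cfg.margin + 5)
        tau = rng.uniform(0.5, 5, shape)
        amp = rng.uniform(1, 100, shape)
        q = simulate_cmos(tau, amp, cfg)
        rec = amplitude_from_cmos(q, tau[:, cfg.margin:], cfg.k)
        assert np.allclose(rec.a, amp[:, cfg.margin:], rtol=1e-14)

    def test_zero_intensity_gives_zero_amplitude(self):
        a = amplitude_from_cmos(np.zeros((2, 2)), np.full((2, 2), 3.0), 2.0)
        assert np.array_equal(a.a, np.zeros((2, 2)))

    def test_below_floor_rejected(self):
        with pytest.raises(ValueError):
            amplitude_from_cmos(np.ones((2, 2)), np.full((2, 2), 1e-9), 1.0,
                                tau_floor=0.02)


class TestCost:
    def test_zero_at_truth_without_regularizer(self, small_cfg, small_instance):
        tau_t, amp, q, s = small_instance
        ir = IRConfig(alpha=0.0, integrator="quad")
        assert cost(tau_t[:, small_cfg.margin:], q, s, small_cfg, ir) \
            == pytest.approx(0.0, abs=1e-9)

    def test_regularizer_only_at_truth(self, small_cfg, small_instance):
        tau_t, amp, q, s = small_instance
        tt = tau_t[:, small_cfg.margin:]
        ir = IRConfig(alpha=2e-3, integrator="quad")
        assert cost(tt, q, s, small_cfg, ir) \
            == pytest.approx(2e-3 * np.sum(tt ** 2), rel=1e-6)

    def test_brute_force_recomputation(self, small_cfg, small_instance):
        # independent oracle: explicit per-pixel loops over replicas
        tau_t, amp, q, s = small_instance
        rng = np.random.default_rng(5)
        tau = rng.uniform(0.5, 4.0, q.shape)
        ir = IRConfig(alpha=1e-3, integrator="quad")
        y, m = small_cfg.y, small_cfg.margin
        H, W = q.shape
        pred = np.zeros_like(q)
        for i in range(H):
            for j in range(W):
                for n in range(small_cfg.n_replicas):
                    jj = j - n * y
                    if jj < 0:
                        continue
                    I = decay_gate_integral(np.array([tau[i, jj]]),
                                            small_cfg.delays[n], small_cfg)[0]
                    pred[i, j] += (small_cfg.weights[n]
                                   * q[i, jj] / (small_cfg.k * tau[i, jj]) * I)
        mask = valid_region(small_cfg, q.shape)
        expect = np.sqrt(np.sum(((pred - s) * mask) ** 2)) \
            + 1e-3 * np.sum(tau ** 2)
        assert cost(tau, q, s, small_cfg, ir) == pytest.approx(expect, rel=1e-10)

    def test_nan_inputs_rejected(self, small_cfg, small_instance):
        tau_t, amp, q, s = small_instance
        bad = s.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            cost(np.ones_like(q), q, bad, small_cfg, IRConfig())


class TestGradient:
    def test_zero_at_global_minimum(self, small_cfg, small_instance):
        tau_t, amp, q, s = small_instance
        ir = IRConfig(alpha=0.0, integrator="quad", squared_data_term=True)
        g = gradient(tau_t[:, small_cfg.margin:], q, s, small_cfg, ir)
        assert np.allclose(g, 0.0, atol=1e-8)

    def test_matches_central_finite_differences(self, small_cfg,
                                                small_instance):
        tau_t, amp, q, s = small_instance
        rng = np.random.default_rng(3)
        tau0 = rng.uniform(0.5, 4.0, q.shape)
        ir = IRConfig(alpha=1e-3, integrator="quad")
        g = gradient(tau0, q, s, small_cfg, ir)
        eps = 1e-5
        worst = 0.0
        for i in (0, 3, 7):
            for j in (0, 2, 5, 7):
                tp, tm = tau0.copy(), tau0.copy()
                tp[i, j] += eps
                tm[i, j] -= eps
                fd = (cost(tp, q, s, small_cfg, ir)
                      - cost(tm, q, s, small_cfg, ir)) / (2 * eps)
                denom = max(abs(fd), abs(g[i, j]), 1e-12)
                worst = max(worst, abs(fd - g[i, j]) / denom)
        assert worst < 1e-4

    def test_regularizer_term_per_pixel(self, small_cfg, small_instance):
        # with the data term zeroed (s_hat == prediction) only the ridge
        # gradient 2*alpha*tau remains
        tau_t, amp, q, s = small_instance
        tt = tau_t[:, small_cfg.margin:]
        ir = IRConfig(alpha=0.05, integrator="quad", squared_data_term=True)
        g = gradient(tt, q, s, small_cfg, ir)
        assert np.allclose(g, 2 * 0.05 * tt, atol=1e-7)


class TestRetrieve:
    def test_flat_phantom_noise_free_recovery(self, cfg):
        shape = (16, cfg.margin + 160)
        tau_t = np.full(shape, 1.0)
        amp = np.full(shape, 100.0)
        s = simulate_iccd(tau_t, amp, cfg)
        q = simulate_cmos(tau_t, amp, cfg)
        ir = IRConfig(alpha=1e-3, init="constant", init_range=(2.0, 2.0),
                      max_iter=400, rel_tol=1e-9)
        res = retrieve(q, s, cfg, ir)
        med = np.median(res.tau[res.mask])
        assert abs(med - 1.0) < 0.01

    def test_init_at_truth_terminates_immediately(self, small_cfg,
                                                  small_instance):
        tau_t, amp, q, s = small_instance
        ir = IRConfig(alpha=0.0, init="provided", integrator="quad",
                      max_iter=50)
        res = retrieve(q, s, small_cfg, ir,
                       tau_init=tau_t[:, small_cfg.margin:])
        assert res.converged
        assert res.n_iter <= 2
        assert res.cost_trace[0] == pytest.approx(0.0, abs=1e-9)

    def test_cost_trace_non_increasing(self, cfg, rng):
        shape = (8, cfg.margin + 60)
        tau_t = rng.uniform(0.8, 3.0, shape)
        amp = rng.uniform(50, 150, shape)
        s = simulate_iccd(tau_t, amp, cfg)
        q = simulate_cmos(tau_t, amp, cfg)
        ir = IRConfig(init="random", seed=2, max_iter=60)
        res = retrieve(q, s, cfg, ir)
        assert np.all(np.diff(res.cost_trace) <= 1e-10)
        assert np.all(res.tau >= ir.tau_floor)

    def test_row_permutation_equivariance(self, cfg, rng):
        shape = (10, cfg.margin + 60)
        tau_t = rng.uniform(0.8, 3.0, shape)
        amp = rng.uniform(50, 150, shape)
        s = simulate_iccd(tau_t, amp, cfg).s
        q = simulate_cmos(tau_t, amp, cfg).q
        perm = rng.permutation(10)
        ir = IRConfig(init="constant", init_range=(2.0, 2.0), max_iter=40)
        r1 = retrieve(CMOSImage(q), s, cfg, ir).tau
        r2 = retrieve(CMOSImage(q[perm]), s[perm], cfg, ir).tau
        # rows are independent; only float summation order differs
        assert np.allclose(r2, r1[perm], rtol=0, atol=1e-12)

    def test_error_decreases_with_photon_budget(self, cfg, det):
        from tfflim.noise import sample_noisy_iccd
        shape = (12, cfg.margin + 100)
        tau_t = np.full(shape, 1.0)
        mads = []
        for photons in (500, 5000, 50000):
            amp = np.full(shape, photons / det.dqe)   # tau = 1 ns
            clean = simulate_iccd(tau_t, amp, cfg)
            noisy = sample_noisy_iccd(clean, det, seed=17)
            q = simulate_cmos(tau_t, amp, cfg)
            ir = IRConfig(init="constant", init_range=(2.0, 2.0),
                          max_iter=250, rel_tol=1e-8)
            res = retrieve(q, noisy, cfg, ir)
            mads.append(np.median(np.abs(res.tau[res.mask] - 1.0)))
        assert mads[0] > mads[1] > mads[2]
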