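"""Forward-model unit and property tests.

Oracles: closed-form antiderivatives of gated mono-exponential decays
(rectangular gates admit exact integrals), and a brute-force per-replica
render for the shear bookkeeping.
"""

import numpy as np
import pytest

from tfflim import (ConfigError, GateProfile, SystemConfig, gate_values,
                    replica_weights, reliable_region, simulate_cmos,
                    simulate_iccd, valid_region)
from tfflim.forward import decay_gate_integral, replica_integrals

from conftest import rect_cfg


def rect_integral(tau, delay, a, b):
    """Exact integral of e^{-(t-delay)/tau} over [max(a, delay), b]."""
    lo = max(a, delay)
    if b <= lo:
        return 0.0
    return tau * (np.exp(-(lo - delay) / tau) - np.exp(-(b - delay) / tau))


class TestReplicaWeights:
    @pytest.mark.parametrize("ra,rb,n,expected", [
        (0.5, 0.5, 3, (0.5, 0.25, 0.125)),
        (1.0, 0.0, 2, (1.0, 0.0)),
    ])
    def test_geometric_law(self, ra, rb, n, expected):
        assert np.allclose(replica_weights(ra, rb, n), expected)

    def test_measured_splitting_ratio(self):
        w = replica_weights(0.515, 0.485, 6)
        assert w[0] == pytest.approx(0.515)
        assert w[5] == pytest.approx(0.515 * 0.485 ** 5)
        assert np.all(np.diff(w) < 0)

    def test_non_normalized_ratios_rejected(self):
        with pytest.raises(ConfigError):
            replica_weights(0.6, 0.5, 3)


class TestGateValues:
    def test_rectangular_window(self):
        gate = GateProfile(shape="rectangular", t_start=1.0, width=2.0,
                           edge_sigma=0.0)
        t = np.array([0.5, 1.0, 1.5, 2.9, 3.0, 3.5])
        assert np.array_equal(gate_values(gate, t), [0, 1, 1, 1, 0, 0])

    def test_smoothed_limits_to_rectangular(self):
        t = np.linspace(-1, 5, 301)
        rect = gate_values(GateProfile(shape="rectangular", t_start=1.0,
                                       width=2.0, edge_sigma=0.0), t)
        for sig in (1e-4, 1e-6):
            smooth = gate_values(GateProfile(shape="smoothed_flat_top",
                                             t_start=1.0, width=2.0,
                                             edge_sigma=sig), t)
            # identical except exactly on the (half-open) edges
            inner = (np.abs(t - 1.0) > 1e-2) & (np.abs(t - 3.0) > 1e-2)
            assert np.allclose(smooth[inner], rect[inner], atol=1e-9)

    def test_values_within_unit_interval(self):
        gate = GateProfile()
        t = np.linspace(-5, 10, 500)
        g = gate_values(gate, t)
        assert np.all((g >= 0) & (g <= 1))

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            gate_values(GateProfile(), np.array([1.0, 1.0, 2.0]))


class TestSimulateICCD:
    def test_zero_amplitude_gives_zero_signal(self, cfg):
        shape = (4, cfg.margin + 8)
        s = simulate_iccd(np.ones(shape), np.zeros(shape), cfg)
        assert np.array_equal(s.s, np.zeros((4, 8)))

    def test_single_replica_closed_form(self):
        # gate covering [0, 10*tau], direct pass only, A=1, tau=1
        cfg1 = rect_cfg(0.0, 10.0, n_replicas=1, replica_weights=(1.0,), y=0)
        tau = np.ones((2, 3))
        amp = np.ones((2, 3))
        s = simulate_iccd(tau, amp, cfg1)
        assert s.s == pytest.approx(1.0 - np.exp(-10.0), rel=1e-4)

    def test_late_gate_replica_ratio(self):
        # gate opening after every replica start: ratio of successive
        # replica signals is (r_{n+1}/r_n) * exp(t_c / tau)
        tau0 = 1.7
        cfg = rect_cfg(4.0, 3.0, y=10)
        shape = (1, cfg.margin + 60)
        w = cfg.weights
        # a single-pixel object isolates the replicas spatially
        amp = np.zeros(shape)
        amp[0, cfg.margin] = 1.0
        s = simulate_iccd(np.full(shape, tau0), amp, cfg).s[0]
        peaks = np.array([s[n * 10] for n in range(cfg.n_replicas)])
        ratios = np.diff(np.log(peaks))
        expect = np.log(w[1] / w[0]) + cfg.t_c / tau0
        assert np.allclose(ratios, expect, rtol=1e-6)

    def test_linearity_in_amplitude(self, cfg, rng):
        shape = (3, cfg.margin + 12)
        tau = rng.uniform(0.5, 4.0, shape)
        amp = rng.uniform(0, 100, shape)
        s1 = simulate_iccd(tau, amp, cfg).s
        s2 = simulate_iccd(tau, 3.5 * amp, cfg).s
        assert np.allclose(s2, 3.5 * s1, rtol=1e-12)

    def test_quadrature_error_halves_with_dt(self):
        # rectangular-gate discretization error is O(dt^2) on an aligned
        # grid; halving dt must at least halve the discrepancy
        tau = np.array([[0.7]])
        errs = []
        for dt in (0.08, 0.04):
            c = rect_cfg(0.3, 2.0, n_replicas=1, replica_weights=(1.0,),
                         y=0, dt=dt)
            val = simulate_iccd(tau, np.ones((1, 1)), c).s[0, 0]
            exact = rect_integral(0.7, 0.0, 0.3, 2.3)
            errs.append(abs(val - exact))
        assert errs[1] <= errs[0] / 2 + 1e-14

    def test_replica_bookkeeping_brute_force(self):
        # shear larger than the object: each replica is spatially
        # isolated and must equal r_n times the n-delayed gate integral
        cfg = rect_cfg(0.5, 2.5, y=25, n_replicas=3,
                       replica_weights=(0.5, 0.3, 0.2))
        shape = (1, cfg.margin + 60)
        amp = np.zeros(shape)
        amp[0, cfg.margin] = 7.0
        tau0 = 1.3
        s = simulate_iccd(np.full(shape, tau0), amp, cfg).s[0]
        for n in range(3):
            expect = cfg.weights[n] * 7.0 * rect_integral(
                tau0, n * cfg.t_c, 0.5, 3.0)
            assert s[n * 25] == pytest.approx(expect, rel=1e-4)

    def test_seed_too_small_raises(self, cfg):
        shape = (2, cfg.margin)  # not wider than the shear extent
        with pytest.raises(ValueError):
            simulate_iccd(np.ones(shape), np.ones(shape), cfg)

    def test_nonpositive_lifetime_rejected(self, cfg):
        shape = (2, cfg.margin + 4)
        tau = np.ones(shape)
        tau[0, 0] = 0.0
        with pytest.raises(ValueError):
            simulate_iccd(tau, np.ones(shape), cfg)


class TestSimulateCMOS:
    def test_closed_form(self, cfg):
        shape = (2, cfg.margin + 3)
        q = simulate_cmos(np.full(shape, 3.0), np.full(shape, 2.0),
                          SystemConfig(k=1.0))
        assert np.array_equal(q.q, np.full((2, 3), 6.0))

    def test_zero_amplitude(self, cfg):
        shape = (2, cfg.margin + 3)
        q = simulate_cmos(np.ones(shape), np.zeros(shape), cfg)
        assert np.array_equal(q.q, np.zeros((2, 3)))

    def test_quadrature_agrees_with_closed_form(self):
        cfg = SystemConfig(dt=0.005)
        shape = (2, cfg.margin + 4)
        tau = np.full(shape, 1.9)
        amp = np.full(shape, 5.0)
        qc = simulate_cmos(tau, amp, cfg, method="closed").q
        qn = simulate_cmos(tau, amp, cfg, method="quad").q
        assert np.allclose(qn, qc, rtol=1e-3)
        assert np.max(np.abs(qn / qc - 1)) < 1e-3

    def test_cmos_iccd_consistency_bitwise(self, cfg):
        # A = q/(k*tau) re-inserted reproduces s exactly when the
        # algebra is float-exact (power-of-two lifetimes)
        shape = (3, cfg.margin + 6)
        tau = np.full(shape, 2.0)
        amp = np.linspace(1, 50, shape[0] * shape[1]).reshape(shape)
        q_seed = cfg.k * amp * tau          # CMOS closed form on the seed
        amp_rec = q_seed / (cfg.k * tau)
        s1 = simulate_iccd(tau, amp, cfg).s
        s2 = simulate_iccd(tau, amp_rec, cfg).s
        assert np.array_equal(s1, s2)


class TestRegions:
    def test_upstream_band_excluded(self):
        cfg = SystemConfig(y=10)   # margin 50
        mask = valid_region(cfg, (4, 220))
        assert not mask[:, :50].any()
        assert mask[:, 50:].all()

    def test_single_replica_full_fov(self):
        cfg = SystemConfig(n_replicas=1, replica_weights=(1.0,))
        assert valid_region(cfg, (4, 30)).all()

    def test_zero_shear_full_fov(self):
        cfg = SystemConfig(y=0)
        assert valid_region(cfg, (4, 30)).all()

    def test_too_narrow_fov_raises(self, cfg):
        with pytest.raises(ValueError):
            valid_region(cfg, (4, cfg.margin))

    def test_reliable_region_is_centre_band(self, cfg):
        mask = reliable_region(cfg, (2, 220))
        assert not mask[:, :50].any() and not mask[:, 170:].any()
        assert mask[:, 50:170].all()


class TestReplicaIntegrals:
    def test_table_matches_quadrature(self, cfg, rng):
        tau = rng.uniform(0.05, 15.0, 2000)
        Iq = replica_integrals(tau, cfg, method="quad")
        It = replica_integrals(tau, cfg, method="table")
        assert np.allclose(It, Iq, rtol=2e-4)

    def test_derivative_consistent_with_difference(self, cfg):
        tau = np.array([0.4, 1.0, 3.0])
        h = 1e-5
        for delay in cfg.delays:
            I, dI = decay_gate_integral(tau, delay, cfg, derivative=True)
            fd = (decay_gate_integral(tau + h, delay, cfg)
                  - decay_gate_integral(tau - h, delay, cfg)) / (2 * h)
            assert np.allclose(dI, fd, rtol=1e-5, atol=1e-12)
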