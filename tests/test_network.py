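"""Tuning curves, connectivity, weight init, and population dynamics."""

import numpy as np
import pytest

from helpers import SMALL, algebraic_fixed_point, euler_equilibrium, \
    frozen_inputs
from remapnet.network import (Network, build_connectivity, gaussian_tuning,
                              indicator, init_weights,
                              remapping_preferences, sample_gamma_delays,
                              sigmoid_rate, step_saccade)
from remapnet.params import ModelParams
from remapnet.engine import integrate_trial
from remapnet.protocol import TrialSpec


class TestTuning:
    def test_gaussian_center_and_shoulder(self):
        assert gaussian_tuning(5.0, 5.0, 3.0) == 1.0
        assert gaussian_tuning(0.0, 3.0, 3.0) == pytest.approx(
            np.exp(-0.5), abs=1e-12)

    def test_absent_location_gives_exact_zero(self):
        assert gaussian_tuning(np.arange(-45.0, 46.0), np.nan, 3.0).sum() == 0

    @pytest.mark.parametrize("x,y,z,out", [
        (0, 70, 300, 1.0), (-70, 70, 300, 1.0), (-71, 70, 300, 0.0),
        (300, 70, 300, 1.0), (301, 70, 300, 0.0)])
    def test_indicator_boundary_inclusive(self, x, y, z, out):
        assert indicator(x, y, z) == out

    def test_sigmoid_midpoint_and_closed_forms(self):
        assert sigmoid_rate(15.0, 100.0, 15.0) == 0.5
        assert sigmoid_rate(15.05, 100.0, 15.0) == pytest.approx(
            1 / (1 + np.exp(-10.0)), rel=1e-12)
        assert sigmoid_rate(0.0, 0.5, 3.0) == pytest.approx(
            1 / (1 + np.exp(3.0)), rel=1e-12)


class TestConnectivity:
    def test_afferent_counts_match_rounded_fractions(self, params):
        masks = build_connectivity(params, np.random.default_rng(0))
        assert (masks["mask_VC"].sum(axis=1) == 5).all()    # round(91*0.05)
        assert (masks["mask_SC"].sum(axis=1) == 12).all()   # round(61*0.20)
        assert (masks["mask_CR"].sum(axis=1) == 1000).all()  # phi_C = 1

    def test_diluted_remapping_afferents(self):
        p = ModelParams(phi_C=0.1)
        masks = build_connectivity(p, np.random.default_rng(0))
        assert (masks["mask_CR"].sum(axis=1) == 100).all()

    def test_weights_unit_rows_on_mask_support(self, params):
        rng = np.random.default_rng(1)
        masks = build_connectivity(params, rng)
        W = init_weights(masks, np.random.default_rng(2))
        for wkey, mkey in (("W_VC", "mask_VC"), ("W_SC", "mask_SC"),
                           ("W_CR", "mask_CR")):
            np.testing.assert_allclose(
                (W[wkey] ** 2).sum(axis=1), 1.0, atol=1e-12)
            assert (W[wkey][~masks[mkey]] == 0).all()
            assert (W[wkey] >= 0).all()

    def test_build_is_seed_deterministic(self, params):
        n1, n2 = Network.build(params, 7), Network.build(params, 7)
        for k in ("W_VC", "W_SC", "W_CR", "mask_VC", "gamma"):
            np.testing.assert_array_equal(getattr(n1, k), getattr(n2, k))

    def test_large_remapping_population_cycles_preferences(self):
        p = ModelParams(n_R=5000)
        prefs = remapping_preferences(p)
        assert len(prefs) == 5000
        assert set(prefs) == set(np.arange(-45.0, 46.0))
        np.testing.assert_array_equal(prefs[:91], np.arange(-45.0, 46.0))

    def test_hdf5_roundtrip(self, params, tmp_path):
        net = Network.build(params, 3)
        net.save(tmp_path / "net.h5")
        back = Network.load(tmp_path / "net.h5")
        np.testing.assert_array_equal(net.W_CR, back.W_CR)
        np.testing.assert_array_equal(net.mask_SC, back.mask_SC)
        assert back.params == params and back.seed == 3


class TestGammaDelays:
    def test_range_and_determinism(self, params):
        g1 = sample_gamma_delays(params, np.random.default_rng(5))
        g2 = sample_gamma_delays(params, np.random.default_rng(5))
        np.testing.assert_array_equal(g1, g2)
        assert (g1 >= 0).all() and (g1 <= 80.0).all()

    def test_mean_matches_folded_normal_oracle(self, params):
        """Monte-Carlo oracle with an independent generator: the delays are
        |N(0, 50)| clipped at 80 ms."""
        rng = np.random.default_rng(99)
        oracle = np.minimum(np.abs(rng.standard_normal(200_000) * 50.0), 80.0)
        p = params.replace(n_R=100_000)
        g = sample_gamma_delays(p, np.random.default_rng(6))
        assert g.mean() == pytest.approx(oracle.mean(), rel=0.02)


class TestEquilibria:
    def test_saccade_population_relaxes_to_drive(self):
        net, _, gauss_S, _ = frozen_inputs()
        st = euler_equilibrium(net, np.zeros(SMALL.n_V), gauss_S,
                               np.zeros(SMALL.n_R), n_iter=2000)
        np.testing.assert_allclose(st.v_S[0], gauss_S, atol=1e-6)

    def test_saccade_population_decays_exponentially(self):
        p = SMALL
        v = np.full((1, p.n_S), 0.8)
        dt, tau, n = 0.05, p.tau_v_S, 4000   # 200 ms of decay
        for _ in range(n):
            v = step_saccade(v, 0.0, 0.0, dt, tau)
        # first-order Euler decay tracks the closed form to O(dt/tau)
        np.testing.assert_allclose(v, 0.8 * np.exp(-n * dt / tau), rtol=0.02)

    def test_euler_matches_algebraic_fixed_point(self):
        """Iterated Euler states converge to the self-consistent algebraic
        fixed points of the saccade/combination/remapping equations."""
        net, v_V, gauss_S, gauss_R = frozen_inputs()
        p = net.params
        st = euler_equilibrium(net, v_V, gauss_S, gauss_R)
        x0 = np.concatenate([st.h_C[0], st.h_R[0]])
        h_C_star, h_R_star, K_star = algebraic_fixed_point(
            net, v_V, gauss_S, gauss_R, x0)
        np.testing.assert_allclose(st.h_C[0], h_C_star, atol=1e-6)
        np.testing.assert_allclose(st.h_R[0], h_R_star, atol=1e-6)
        np.testing.assert_allclose(st.v_S[0], gauss_S, atol=1e-6)
        np.testing.assert_allclose(st.K[0], K_star, atol=1e-6)

    def test_zero_input_baselines(self):
        net = Network.build(SMALL, seed=1)
        z = np.zeros(SMALL.n_V)
        st = euler_equilibrium(net, z, np.zeros(SMALL.n_S),
                               np.zeros(SMALL.n_R), n_iter=5000)
        assert st.v_C.max() < 1e-12
        # baseline rate self-consistently below the zero-inhibition bound
        assert 0 < st.v_R[0].mean() < 1 / (1 + np.exp(3.0))


class TestSymmetry:
    def test_mirrored_network_mirrors_trajectories(self, params):
        """Mirroring preferences, stimulus and saccade about 0 deg mirrors
        every state trajectory (with connectivity mirrored to match)."""
        net = Network.build(params, seed=21)
        mirror = Network.build(params, seed=21)
        mirror.W_VC = net.W_VC[:, ::-1].copy()
        mirror.mask_VC = net.mask_VC[:, ::-1].copy()
        mirror.W_SC = net.W_SC[:, ::-1].copy()
        mirror.mask_SC = net.mask_SC[:, ::-1].copy()
        mirror.W_CR = net.W_CR[::-1, :].copy()
        mirror.mask_CR = net.mask_CR[::-1, :].copy()
        mirror.gamma = net.gamma[::-1].copy()

        t = TrialSpec(h=10.0, s=-20.0, t_stim_on=0.0, t_stim_off=700.0,
                      t_sacc=200.0, duration=700.0)
        tm = TrialSpec(h=-10.0, s=20.0, t_stim_on=0.0, t_stim_off=700.0,
                       t_sacc=200.0, duration=700.0)
        tr = integrate_trial(net, t, record=("v_V", "v_S", "v_R"))
        trm = integrate_trial(mirror, tm, record=("v_V", "v_S", "v_R"))
        for pop in ("v_V", "v_S", "v_R"):
            np.testing.assert_allclose(
                trm.pops[pop][0], tr.pops[pop][0][:, ::-1], atol=1e-12)


class TestRateBounds:
    def test_rates_bounded_in_training_trial(self, net):
        from remapnet.protocol import make_training_trial

        tr = integrate_trial(net, make_training_trial(-5, 15),
                             record=("v_V", "v_S", "v_C", "v_R"))
        # sigmoid rates saturate to exactly 0/1 in float64 at these slopes
        for pop in ("v_V", "v_S", "v_C", "v_R"):
            arr = tr.pops[pop]
            assert arr.min() >= 0.0 and arr.max() <= 1.0
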