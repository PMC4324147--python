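"""Shared test utilities: frozen-drive equilibria on a reduced network."""

import numpy as np
from scipy.optimize import fsolve
from scipy.special import expit

from remapnet.network import (Network, NetworkState, gaussian_tuning,
                              step_combination, step_K_P, step_remapping,
                              step_saccade)
from remapnet.params import ModelParams

#: Reduced population sizes: same dynamics, cheap fixed-point solves.
SMALL = ModelParams(n_V=31, n_S=21, n_C=40, n_R=31)


def frozen_inputs(stim=-5.0, sacc=15.0, seed=11):
    """A small network plus frozen visual/saccade/remapping drive patterns."""
    net = Network.build(SMALL, seed=seed)
    v_V = gaussian_tuning(net.prefs_V, stim, SMALL.sigma_V)
    gauss_S = gaussian_tuning(net.prefs_S, sacc, SMALL.sigma_S)
    gauss_R = gaussian_tuning(net.prefs_R, stim, SMALL.sigma_R)
    return net, v_V, gauss_S, gauss_R


def euler_equilibrium(net, v_V, gauss_S, gauss_R, n_iter=40_000, dt=2.0):
    """Iterate the Euler updates with frozen drives until stationary."""
    p = net.params
    st = NetworkState.zeros(p, 1)
    st.v_V[0] = v_V
    gate = np.ones((1, p.n_R))
    for _ in range(n_iter):
        st.v_S = step_saccade(st.v_S, gauss_S[None, :], 1.0, dt, p.tau_v_S)
        st.h_C = step_combination(st, net, dt)
        st.K, st.P = step_K_P(st, net, gauss_R[None, :], gate, dt)
        st.h_R = step_remapping(st, net, dt)
        st.apply_rates(p)
    return st


def algebraic_fixed_point(net, v_V, gauss_S, gauss_R, x0):
    """Independent oracle: solve the self-consistent stationary equations
    of the combination and remapping populations with fsolve."""
    p = net.params
    K_star = p.psi_K * gauss_R
    drive_C = (p.psi_VC * net.W_VC @ v_V + p.psi_SC * net.W_SC @ gauss_S)

    def residual(x):
        h_C, h_R = x[:p.n_C], x[p.n_C:]
        v_C = expit(2 * p.slope_C * (h_C - p.theta_C))
        v_R = expit(2 * p.slope_R * (h_R - p.theta_R))
        rc = drive_C - p.w_inhb_C * v_C.sum() - h_C
        rr = (p.psi_CR * net.W_CR @ v_C - p.w_inhb_R * v_R.sum()
              + K_star - h_R)
        return np.concatenate([rc, rr])

    x_star = fsolve(residual, x0, xtol=1e-13)
    return x_star[:p.n_C], x_star[p.n_C:], K_star
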