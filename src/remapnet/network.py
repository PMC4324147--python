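"""Four-population rate network: tuning curves, connectivity, state updates.

Populations
-----------
visual (``v_V``): event-driven retinal map with a memory trace — its rate
  jumps at stimulus onset and is re-evaluated (after clearing) a fixed delay
  ``delta_V`` after saccade onset; there is no leak in between.
saccade (``v_S``): leaky units driven by a Gaussian of the saccade target
  within a perisaccadic window [t_sacc - delta_S_pre, t_sacc + delta_S_post].
combination (``h_C``/``v_C``): leaky integrators of weighted visual and
  saccade input with global lateral inhibition and a steep sigmoid, so they
  fire only when both inputs coincide.
remapping (``h_R``/``v_R``): leaky integrators of weighted combination input,
  lateral inhibition, and a direct visual drive ``K`` with tonic trace ``P``
  that is truncated ``delta_K`` after saccade onset.

All updates are forward-Euler steps on a batch of trials: state arrays have
shape ``(B, N)``; per-trial scalars broadcast as ``(B, 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields

import numpy as np
from scipy.special import expit

from .params import ModelParams

__all__ = [
    "gaussian_tuning", "indicator", "sigmoid_rate",
    "visual_preferences", "saccade_preferences", "remapping_preferences",
    "build_connectivity", "init_weights", "sample_gamma_delays",
    "Network", "NetworkState",
    "step_visual_events", "step_saccade", "step_combination",
    "step_K_P", "step_remapping",
]


def gaussian_tuning(pref, loc, sigma):
    """Gaussian drive exp(-(pref - loc)^2 / (2 sigma^2)).

    ``loc`` may be NaN (absent stimulus/saccade), which yields exactly 0.
    Broadcasts ``pref`` against ``loc``.
    """
    pref = np.asarray(pref, dtype=float)
    loc = np.asarray(loc, dtype=float)
    d = pref - loc
    out = np.zeros(np.broadcast_shapes(pref.shape, loc.shape))
    ok = np.isfinite(d)
    out[ok] = np.exp(-np.square(d[ok]) / (2.0 * sigma * sigma))
    return out


def indicator(x, y, z):
    """Boundary-inclusive window indicator: 1 if -y <= x <= z, else 0."""
    x = np.asarray(x, dtype=float)
    return ((x >= -y) & (x <= z)).astype(float)


def sigmoid_rate(h, slope, theta):
    """Sigmoid rate 1 / (1 + exp(-2 slope (h - theta)))."""
    return expit(2.0 * slope * (np.asarray(h, dtype=float) - theta))


def visual_preferences(params: ModelParams) -> np.ndarray:
    """Integer retinal preferences of the visual population (deg)."""
    return np.linspace(-45.0, 45.0, params.n_V)


def saccade_preferences(params: ModelParams) -> np.ndarray:
    """Integer saccade-target preferences of the saccade population (deg)."""
    return np.linspace(-30.0, 30.0, params.n_S)


def remapping_preferences(params: ModelParams) -> np.ndarray:
    """Retinal preferences of the remapping population (deg).

    For n_R = 91 these are the unique integers [-45, 45]; larger populations
    cycle over the same 91 integer locations.
    """
    base = np.arange(-45.0, 46.0)
    reps = -(-params.n_R // base.size)
    return np.tile(base, reps)[: params.n_R]


def _afferent_count(n: int, phi: float) -> int:
    # round-half-up with a guard against binary representation of n*phi
    return int(np.floor(n * phi + 0.5 + 1e-9))


def build_connectivity(params: ModelParams, rng: np.random.Generator) -> dict:
    """Random diluted connectivity masks.

    Each combination neuron draws round(n_V * phi_V) visual and
    round(n_S * phi_S) saccade afferents uniformly without replacement; each
    remapping neuron draws round(n_C * phi_C) combination afferents.
    Masks are (post, pre) boolean matrices.
    """
    def mask(n_post, n_pre, phi):
        k = _afferent_count(n_pre, phi)
        m = np.zeros((n_post, n_pre), dtype=bool)
        for i in range(n_post):
            m[i, rng.choice(n_pre, size=k, replace=False)] = True
        return m

    return {
        "mask_VC": mask(params.n_C, params.n_V, params.phi_V),
        "mask_SC": mask(params.n_C, params.n_S, params.phi_S),
        "mask_CR": mask(params.n_R, params.n_C, params.phi_C),
    }


def init_weights(masks: dict, rng: np.random.Generator) -> dict:
    """Uniform(0, 1) weights on the mask support, each postsynaptic row
    scaled to unit L2 norm."""
    from .plasticity import normalize_rows

    out = {}
    for key, wkey in (("mask_VC", "W_VC"), ("mask_SC", "W_SC"),
                      ("mask_CR", "W_CR")):
        m = masks[key]
        W = rng.uniform(0.0, 1.0, size=m.shape) * m
        out[wkey] = normalize_rows(W, m)
    return out


def sample_gamma_delays(params: ModelParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-remapping-neuron visual onset delays (ms): |Normal(0, gamma_sd)|
    clipped at gamma_clip."""
    g = np.abs(rng.normal(0.0, params.gamma_sd, size=params.n_R))
    return np.minimum(g, params.gamma_clip)


@dataclass
class Network:
    """Parameters, preferences, connectivity, weights and onset delays."""

    params: ModelParams
    prefs_V: np.ndarray
    prefs_S: np.ndarray
    prefs_R: np.ndarray
    mask_VC: np.ndarray
    mask_SC: np.ndarray
    mask_CR: np.ndarray
    W_VC: np.ndarray
    W_SC: np.ndarray
    W_CR: np.ndarray
    gamma: np.ndarray
    seed: int = 0

    @classmethod
    def build(cls, params: ModelParams, seed: int) -> "Network":
        """Construct a freshly initialized network. The seed is split into
        independent streams for connectivity, weights and onset delays."""
        ss = np.random.SeedSequence(seed)
        rng_conn, rng_w, rng_gamma = (np.random.default_rng(s)
                                      for s in ss.spawn(3))
        masks = build_connectivity(params, rng_conn)
        weights = init_weights(masks, rng_w)
        return cls(params=params,
                   prefs_V=visual_preferences(params),
                   prefs_S=saccade_preferences(params),
                   prefs_R=remapping_preferences(params),
                   gamma=sample_gamma_delays(params, rng_gamma),
                   seed=seed, **masks, **weights)

    def weight_snapshot(self) -> dict:
        return {"W_VC": self.W_VC.copy(), "W_SC": self.W_SC.copy(),
                "W_CR": self.W_CR.copy()}

    def restore_weights(self, snap: dict) -> None:
        self.W_VC = snap["W_VC"].copy()
        self.W_SC = snap["W_SC"].copy()
        self.W_CR = snap["W_CR"].copy()

    def save(self, path) -> None:
        """Serialize weights, masks, preferences and delays to HDF5."""
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("W_VC", "W_SC", "W_CR", "mask_VC", "mask_SC",
                         "mask_CR", "prefs_V", "prefs_S", "prefs_R", "gamma"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["seed"] = self.seed
            f.attrs["params"] = json.dumps(self.params.to_dict())
            f.attrs["params_hash"] = self.params.content_hash()

    @classmethod
    def load(cls, path) -> "Network":
        import h5py

        with h5py.File(path, "r") as f:
            params = ModelParams.from_dict(json.loads(f.attrs["params"]))
            kw = {name: f[name][...] for name in
                  ("W_VC", "W_SC", "W_CR", "mask_VC", "mask_SC", "mask_CR",
                   "prefs_V", "prefs_S", "prefs_R", "gamma")}
            for m in ("mask_VC", "mask_SC", "mask_CR"):
                kw[m] = kw[m].astype(bool)
            return cls(params=params, seed=int(f.attrs["seed"]), **kw)


@dataclass
class NetworkState:
    """Instantaneous state of a batch of B independent trials."""

    v_V: np.ndarray   # (B, n_V) visual rates
    v_S: np.ndarray   # (B, n_S) saccade rates
    h_C: np.ndarray   # (B, n_C) combination activations
    v_C: np.ndarray   # (B, n_C) combination rates
    h_R: np.ndarray   # (B, n_R) remapping activations
    v_R: np.ndarray   # (B, n_R) remapping rates
    K: np.ndarray     # (B, n_R) direct visual drive
    P: np.ndarray     # (B, n_R) tonic trace drive

    @classmethod
    def zeros(cls, params: ModelParams, batch: int) -> "NetworkState":
        z = lambda n: np.zeros((batch, n))
        st = cls(v_V=z(params.n_V), v_S=z(params.n_S), h_C=z(params.n_C),
                 v_C=z(params.n_C), h_R=z(params.n_R), v_R=z(params.n_R),
                 K=z(params.n_R), P=z(params.n_R))
        st.apply_rates(params)
        return st

    def apply_rates(self, params: ModelParams) -> None:
        """Recompute sigmoid rates from the current activations."""
        self.v_C = sigmoid_rate(self.h_C, params.slope_C, params.theta_C)
        self.v_R = sigmoid_rate(self.h_R, params.slope_R, params.theta_R)

    def is_finite(self) -> bool:
        return all(np.isfinite(getattr(self, f.name)).all()
                   for f in fields(self))


# ---------------------------------------------------------------------------
# forward-Euler updates (continuous parts; event jumps live in the engine)

def step_saccade(v_S, gauss_S, active, dt, tau):
    """Euler step of the saccade population: leak toward the Gaussian drive
    gated by the perisaccadic window (``active``: (B, 1) in {0, 1})."""
    return v_S + dt / tau * (-v_S + active * gauss_S)


def step_combination(state: NetworkState, net: Network, dt: float):
    """Euler step of the combination activations using previous-step rates.

    Excitation: psi_VC * W_VC v_V + psi_SC * W_SC v_S.
    Inhibition: w_inhb_C * sum of all combination rates (self included).
    """
    p = net.params
    drive = (p.psi_VC * state.v_V @ net.W_VC.T
             + p.psi_SC * state.v_S @ net.W_SC.T
             - p.w_inhb_C * state.v_C.sum(axis=1, keepdims=True))
    return state.h_C + dt / p.tau_h_C * (-state.h_C + drive)


def step_K_P(state: NetworkState, net: Network, gauss_R, gate, dt: float):
    """Euler step of the direct visual drive K and its tonic trace P.

    ``gate`` (B, n_R): 1 where t is inside the neuron's delayed stimulus
    window [t_stim_on + gamma_i, t_stim_off]. Event jumps (trace transfer at
    stimulus offset, truncation after saccade onset) are applied separately.
    """
    p = net.params
    K = state.K + dt / p.tau_K * (-state.K + p.psi_K * gate * gauss_R
                                  + state.P)
    P = state.P + dt / p.tau_P * (-state.P)
    return K, P


def step_remapping(state: NetworkState, net: Network, dt: float,
                   cr_scale=None):
    """Euler step of the remapping activations using previous-step rates.

    ``cr_scale``: optional per-row scale of W_CR kept implicit during
    training (the engine renormalizes lazily); effective weights are
    ``cr_scale[:, None] * W_CR``.
    """
    p = net.params
    exc = state.v_C @ net.W_CR.T
    if cr_scale is not None:
        exc = exc * cr_scale
    drive = (p.psi_CR * exc
             - p.w_inhb_R * state.v_R.sum(axis=1, keepdims=True)
             + state.K)
    return state.h_R + dt / p.tau_h_R * (-state.h_R + drive)


def step_visual_events(v_V, prefs_V, sigma_V, psi_now, onset_mask, supp_mask):
    """Apply the visual population's event jumps for one step.

    ``psi_now`` (B,): retinal stimulus location at the new sample (NaN if
    not visible). ``onset_mask`` (B,): trials whose stimulus onset falls on
    this step — rates jump up by the Gaussian of the stimulus location.
    ``supp_mask`` (B,): trials reaching t_sacc + delta_V — rates are cleared
    and re-set to the Gaussian of the current (post-saccadic) stimulus
    location, zero if the stimulus is gone. Between events there is no leak;
    stimulus offset alone leaves the memory trace untouched.
    """
    if onset_mask.any():
        g = gaussian_tuning(prefs_V[None, :], psi_now[onset_mask, None],
                            sigma_V)
        v_V[onset_mask] += g
    if supp_mask.any():
        g = gaussian_tuning(prefs_V[None, :], psi_now[supp_mask, None],
                            sigma_V)
        v_V[supp_mask] = g
    return v_V
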