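"""Forward-Euler integration of trials, the training loop, and batteries.

The integrator advances a whole batch of trials that share one time grid,
so the large test batteries (notably the 5551-trial probe battery) reduce
to a few hundred matrix products. Update order within a step follows a
synchronous convention: (1) continuous Euler updates of every state
variable using previous-sample rates, (2) discrete event jumps, (3) the
sigmoid rate nonlinearities, (4) plasticity (training only). An event whose
time falls between samples fires at the first sample at or after it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .network import (Network, NetworkState, gaussian_tuning,
                      step_combination, step_K_P, step_remapping,
                      step_saccade, step_visual_events)
from .params import ModelParams
from .plasticity import LearningConfig
from .protocol import (TrainingSet, TrialSpec, make_training_trial,
                       saccade_duration_ms)

__all__ = ["timestep", "RateTraces", "integrate_trials", "integrate_trial",
           "run_battery", "train", "RunManifest"]


def timestep(params: ModelParams) -> float:
    """Integration step: one tenth of the smallest neuronal time constant."""
    taus = (params.tau_v_V, params.tau_v_S, params.tau_h_C, params.tau_h_R,
            params.tau_K, params.tau_P)
    return min(taus) / 10.0


@dataclass
class RateTraces:
    """Time-sampled rate records for a batch of trials.

    ``pops[name]`` has shape (B, n_samples, n_neurons) — or a neuron subset
    if ``neuron_indices`` was given to the integrator.
    """

    times: np.ndarray
    pops: dict
    trials: list

    def trial(self, pop: str, b: int) -> np.ndarray:
        return self.pops[pop][b]

    def to_hdf5(self, path) -> None:
        """Write the recorded traces (times in ms, one dataset per
        population) and the trial specifications to HDF5."""
        import json

        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times_ms", data=self.times)
            for pop, arr in self.pops.items():
                f.create_dataset(pop.replace(":", "_"), data=arr)
            f.attrs["trials"] = json.dumps(
                [t.to_dict() for t in self.trials])


def _event_index(t: float, dt: float) -> int:
    """Sample index at which an event at time t fires (first sample >= t)."""
    if not math.isfinite(t):
        return -1
    return math.ceil(t / dt - 1e-9)


def _trial_arrays(trials: Sequence[TrialSpec], params: ModelParams,
                  dt: float):
    """Vectorized per-trial geometry on a common time grid."""
    durations = {t.duration for t in trials}
    if len(durations) > 1:
        raise ValueError("all trials in a batch must share one duration")
    duration = durations.pop()
    n_steps = round(duration / dt)
    times = np.arange(n_steps + 1) * dt

    B = len(trials)
    h = np.array([t.h if t.h is not None else np.nan for t in trials])
    s = np.array([t.s if t.s is not None else np.nan for t in trials])
    t_on = np.array([t.t_stim_on if t.h is not None else np.inf
                     for t in trials])
    t_off = np.array([t.t_stim_off if t.h is not None else np.inf
                      for t in trials])
    t_sacc = np.array([t.t_sacc if t.s is not None else np.inf
                       for t in trials])

    # eye position (T+1, B): constant-velocity ramp from 0 to s
    sacc_dur = saccade_duration_ms(np.nan_to_num(s), params.saccade_speed)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (times[:, None] - t_sacc[None, :]) / np.where(
            sacc_dur > 0, sacc_dur, np.inf)[None, :]
    eye = np.nan_to_num(s)[None, :] * np.clip(np.nan_to_num(frac), 0.0, 1.0)

    # retinal stimulus location (T+1, B): h - e(t) while visible, else NaN
    visible = (times[:, None] >= t_on[None, :]) & (times[:, None]
                                                   < t_off[None, :])
    psi = np.where(visible, h[None, :] - eye, np.nan)

    ev = {
        "onset": np.array([_event_index(x, dt) for x in t_on]),
        "offset": np.array([_event_index(x, dt) for x in t_off]),
        "vsupp": np.array([_event_index(x + params.delta_V, dt)
                           for x in t_sacc]),
        "trunc": np.array([_event_index(x + params.delta_K, dt)
                           for x in t_sacc]),
    }
    return times, n_steps, h, s, t_on, t_off, t_sacc, psi, ev


def integrate_trials(net: Network, trials: Sequence[TrialSpec],
                     dt: Optional[float] = None,
                     learning: Optional[LearningConfig] = None,
                     record: Sequence[str] = ("v_R",),
                     neuron_indices: Optional[dict] = None,
                     window_average: Optional[dict] = None):
    """Integrate a batch of trials from a zeroed state.

    ``record``: population fields to sample at full resolution
    ("v_V", "v_S", "v_C", "v_R", "K", "P").
    ``neuron_indices``: optional {pop: index array} restricting which
    neurons are recorded for that population.
    ``window_average``: optional {pop: (t1, t2)} — instead of (or besides)
    full traces, accumulate the trapezoidal time average of the rates over
    [t1, t2] ms; returned under ``window`` keys as (B, n_neurons) arrays.
    ``learning`` enables Hebbian plasticity with renormalization after every
    step in which an update occurred (requires a batch of one trial).

    Returns a :class:`RateTraces`; window averages, if requested, are in
    ``traces.pops["window:" + pop]`` with shape (B, n_neurons).
    """
    p = net.params
    if dt is None:
        dt = timestep(p)
    if learning is not None and learning.enabled and len(trials) != 1:
        raise ValueError("plasticity requires single-trial integration")

    times, n_steps, h, s, t_on, t_off, t_sacc, psi, ev = _trial_arrays(
        trials, p, dt)
    B = len(trials)

    gauss_S = gaussian_tuning(net.prefs_S[None, :], s[:, None], p.sigma_S)
    gamma_on = t_on[:, None] + net.gamma[None, :]        # (B, n_R)

    state = NetworkState.zeros(p, B)

    def sel(pop, arr):
        if neuron_indices and pop in neuron_indices:
            return arr[:, neuron_indices[pop]]
        return arr

    rec = {pop: np.empty((B, n_steps + 1,
                          sel(pop, getattr(state, pop)).shape[1]))
           for pop in record}
    win = {}
    win_idx = {}
    if window_average:
        for pop, (t1, t2) in window_average.items():
            i1, i2 = round(t1 / dt), round(t2 / dt)
            if not (0 <= i1 < i2 <= n_steps):
                raise ValueError(
                    f"window [{t1}, {t2}] ms outside trial for pop {pop}")
            win[pop] = np.zeros((B, getattr(state, pop).shape[1]))
            win_idx[pop] = (i1, i2, t2 - t1)

    def apply_events(k):
        onset = ev["onset"] == k
        offset = ev["offset"] == k
        supp = ev["vsupp"] == k
        trunc = ev["trunc"] == k
        if onset.any() or supp.any():
            step_visual_events(state.v_V, net.prefs_V, p.sigma_V,
                               psi[k], onset, supp)
        if offset.any():
            state.P[offset] += state.K[offset]
        if trunc.any():
            state.K[trunc] = 0.0
            state.P[trunc] = 0.0

    def sample(k):
        for pop in record:
            rec[pop][:, k, :] = sel(pop, getattr(state, pop))
        for pop, (i1, i2, span) in win_idx.items():
            if i1 <= k <= i2:
                w = dt if i1 < k < i2 else 0.5 * dt
                win[pop] += (w / span) * getattr(state, pop)

    learn = learning is not None and learning.enabled
    cr_scale = np.ones(p.n_R) if learn else None

    apply_events(0)
    state.apply_rates(p)
    sample(0)

    for k in range(n_steps):
        t = times[k]
        sacc_active = (((t - t_sacc >= -p.delta_S_pre)
                        & (t - t_sacc <= p.delta_S_post))
                       .astype(float)[:, None])
        gauss_R = gaussian_tuning(net.prefs_R[None, :], psi[k][:, None],
                                  p.sigma_R)
        gate = ((t >= gamma_on) & (t <= t_off[:, None])).astype(float)

        v_S = step_saccade(state.v_S, gauss_S, sacc_active, dt, p.tau_v_S)
        h_C = step_combination(state, net, dt)
        K, P = step_K_P(state, net, gauss_R, gate, dt)
        h_R = step_remapping(state, net, dt, cr_scale)
        state.v_S, state.h_C, state.K, state.P, state.h_R = v_S, h_C, K, P, h_R

        apply_events(k + 1)
        state.apply_rates(p)

        if learn:
            _learning_step(net, state, learning, dt, cr_scale)

        sample(k + 1)

    if learn:
        # fold the implicit W_CR row scale in and renormalize exactly
        net.W_CR *= cr_scale[:, None]
        net.W_CR /= np.sqrt(
            np.einsum("ij,ij->i", net.W_CR, net.W_CR))[:, None]

    if not state.is_finite():
        bad = [f for f in ("v_V", "v_S", "h_C", "v_C", "h_R", "v_R", "K", "P")
               if not np.isfinite(getattr(state, f)).all()]
        raise FloatingPointError(
            f"non-finite state in {bad} after integrating "
            f"{len(trials)} trial(s) of {times[-1]} ms at dt={dt}")

    pops = dict(rec)
    for pop, acc in win.items():
        pops["window:" + pop] = acc
    return RateTraces(times=times, pops=pops, trials=list(trials))


def _learning_step(net: Network, state: NetworkState,
                   learning: LearningConfig, dt: float,
                   cr_scale: np.ndarray) -> None:
    """One Hebbian update + renormalization, restricted to combination
    neurons with a nonzero rate.

    Mathematically equivalent to dense
    :func:`remapnet.plasticity.hebbian_step` +
    :func:`remapnet.plasticity.normalize_rows` on all three projections:
    rows of W_VC/W_SC whose postsynaptic rate is zero receive a zero
    increment and are already unit-norm, and columns of W_CR whose
    presynaptic rate is zero are unchanged. W_CR renormalization is kept in
    ``cr_scale`` (effective weights cr_scale[:, None] * W_CR, unit-norm by
    construction each step) and folded into the matrix at the end of the
    trial. Learning rates are per second.
    """
    v_C = state.v_C[0]
    act = np.flatnonzero(v_C)
    if act.size == 0:
        return
    dt_s = dt / 1000.0
    vCa = v_C[act]
    W = net.W_VC[act]
    W += (dt_s * learning.rho_VC) * (vCa[:, None] * state.v_V[0][None, :])
    W *= net.mask_VC[act]
    W /= np.sqrt(np.einsum("ij,ij->i", W, W))[:, None]
    net.W_VC[act] = W
    W = net.W_SC[act]
    W += (dt_s * learning.rho_SC) * (vCa[:, None] * state.v_S[0][None, :])
    W *= net.mask_SC[act]
    W /= np.sqrt(np.einsum("ij,ij->i", W, W))[:, None]
    net.W_SC[act] = W
    # W_CR: increment on the active columns, renormalize via the scale
    dcr = (dt_s * learning.rho_CR) * (state.v_R[0][:, None] * vCa[None, :])
    dcr *= net.mask_CR[:, act]
    Ra = net.W_CR[:, act]
    w_eff = cr_scale[:, None] * Ra
    # effective rows are unit-norm before the update, so the new squared
    # norm is 1 + 2 w.dW + |dW|^2
    n2 = (1.0 + 2.0 * np.einsum("ij,ij->i", w_eff, dcr)
          + np.einsum("ij,ij->i", dcr, dcr))
    net.W_CR[:, act] = Ra + dcr / cr_scale[:, None]
    cr_scale /= np.sqrt(n2)


def integrate_trial(net: Network, trial: TrialSpec, **kw) -> RateTraces:
    """Single-trial convenience wrapper around :func:`integrate_trials`."""
    return integrate_trials(net, [trial], **kw)


def run_battery(net: Network, battery: Sequence[TrialSpec],
                dt: Optional[float] = None,
                record: Sequence[str] = ("v_R",),
                neuron_indices: Optional[dict] = None,
                window_average: Optional[dict] = None,
                chunk: int = 256) -> RateTraces:
    """Run a test battery with plasticity off, batching trials in chunks.

    All trials in a battery share one duration, so results are concatenated
    along the batch axis in battery order.
    """
    if dt is None:
        dt = timestep(net.params)
    parts = []
    for i in range(0, len(battery), chunk):
        parts.append(integrate_trials(
            net, battery[i:i + chunk], dt=dt, record=record,
            neuron_indices=neuron_indices, window_average=window_average))
    pops = {key: np.concatenate([p.pops[key] for p in parts], axis=0)
            for key in parts[0].pops}
    return RateTraces(times=parts[0].times, pops=pops, trials=list(battery))


@dataclass
class RunManifest:
    """Everything needed to re-run a training bit-identically."""

    params_hash: str
    network_seed: int
    training_seed: int
    shuffle_seed: int
    epochs: int
    dt: float
    pairs: list = field(default_factory=list)
    batteries: list = field(default_factory=list)
    version: str = __version__

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def train(net: Network, training_set: TrainingSet,
          epochs: Optional[int] = None, dt: Optional[float] = None,
          shuffle_seed: int = 0,
          learning: Optional[LearningConfig] = None,
          log=None) -> RunManifest:
    """Train the network in place: each epoch runs every training pair as a
    full training trial with plasticity on, in a freshly shuffled order.

    Weight rows remain unit-norm throughout (renormalization after every
    update). ``log``, if given, is called as ``log(epoch, audit)`` after
    each epoch with the maximum deviation of any weight row from unit norm.
    """
    p = net.params
    if epochs is None:
        epochs = p.epochs
    if dt is None:
        dt = timestep(p)
    if learning is None:
        learning = LearningConfig(rho_VC=p.rho_VC, rho_SC=p.rho_SC,
                                  rho_CR=p.rho_CR)
    rng = np.random.default_rng(shuffle_seed)
    trials = [make_training_trial(h, s, dt=dt, speed=p.saccade_speed)
              for h, s in training_set.pairs]
    for epoch in range(epochs):
        for i in rng.permutation(len(trials)):
            integrate_trials(net, [trials[i]], dt=dt, learning=learning,
                             record=())
        if log is not None:
            audit = max(
                np.abs(np.einsum("ij,ij->i", W, W) - 1.0).max()
                for W in (net.W_VC, net.W_SC, net.W_CR))
            log(epoch, audit)
    return RunManifest(params_hash=p.content_hash(), network_seed=net.seed,
                       training_seed=training_set.seed,
                       shuffle_seed=shuffle_seed, epochs=epochs, dt=dt,
                       pairs=[list(pr) for pr in training_set.pairs])
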