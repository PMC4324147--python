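"""Response statistics: period responses, latencies, remapping indices,
probe-task decoding, and per-neuron classification.

The central quantity is the *remapping index* of a remapping neuron. For a
single-step trial that remaps a stimulus into the neuron's receptive field,
the remapping activity is its mean rate over a 300 ms epoch aligned on
saccade onset. Subtracting the matched stimulus-control response gives the
visual index, subtracting the matched saccade-control response gives the
saccade index, and the remapping index is the Euclidean norm of the two:
zero means every spike is explained by a control, larger values mean
activity attributable to remapping alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["period_response", "response_latency", "remapping_index",
           "decode_preference", "classify_remapping",
           "ResponsivenessCurve", "responsiveness_curves",
           "multidirection_counts", "summarize_report"]

#: Minimal per-ms rate slope that counts as a response (rate units / ms).
LATENCY_SLOPE_THRESHOLD = 0.002
#: Length of the window over which the slope must stay above threshold (ms).
LATENCY_WINDOW_MS = 30.0
#: Silence floor below which a probe-decoded preference is undecodable.
DECODE_EPS = 1e-6


def period_response(rates: np.ndarray, dt: float, t1: float, t2: float,
                    pad: bool = False) -> float:
    """Mean rate over [t1, t2]: trapezoidal integral divided by t2 - t1.

    ``rates`` is sampled on the grid 0, dt, 2dt, ... With ``pad=True`` a
    window reaching past the end of the trace treats the missing samples as
    silence (the trial is over), which is how stimulus-aligned windows of
    late-onset flashes are handled.
    """
    if not t1 < t2:
        raise ValueError("need t1 < t2")
    i1, i2 = round(t1 / dt), round(t2 / dt)
    if abs(i1 * dt - t1) > 1e-9 or abs(i2 * dt - t2) > 1e-9:
        raise ValueError(f"window [{t1}, {t2}] not on the dt={dt} grid")
    if i1 < 0 or (i2 >= len(rates) and not pad):
        raise ValueError(f"window [{t1}, {t2}] outside trace")
    y = np.asarray(rates, dtype=float)[max(i1, 0):i2 + 1]
    if len(y) < i2 - i1 + 1:
        y = np.concatenate([y, np.zeros(i2 - i1 + 1 - len(y))])
    return float(np.trapezoid(y, dx=dt) / (t2 - t1))


def response_latency(rates: np.ndarray, dt: float,
                     slope_threshold: float = LATENCY_SLOPE_THRESHOLD,
                     window_ms: float = LATENCY_WINDOW_MS) -> Optional[float]:
    """Earliest time from which the per-ms rate slope stays above threshold
    for a full ``window_ms`` window; ``None`` if the neuron never responds.
    """
    y = np.asarray(rates, dtype=float)
    n_win = round(window_ms / dt)
    slopes = np.diff(y) / dt
    if len(slopes) < n_win:
        return None
    above = slopes > slope_threshold
    # run of n_win consecutive super-threshold slopes starting at k
    csum = np.concatenate([[0], np.cumsum(above)])
    runs = csum[n_win:] - csum[:-n_win]
    hits = np.flatnonzero(runs == n_win)
    if len(hits) == 0:
        return None
    return float(hits[0] * dt)


def remapping_index(single_step: np.ndarray, stim_control: np.ndarray,
                    sacc_control: np.ndarray, dt: float,
                    t_sacc: float = 600.0, t_sacc_control: float = 100.0,
                    epoch_ms: float = 300.0,
                    stim_control_window=(600.0, 900.0)):
    """Visual index, saccade index and remapping index of one neuron.

    ``single_step``: the neuron's rate trace in the single-step trial whose
    saccade remaps the stimulus into its receptive field. ``stim_control``:
    its trace when the pre-saccadic stimulus location is flashed without a
    saccade. ``sacc_control``: its trace when the same saccade is executed
    without a stimulus. Remapping activity is the period response over
    [t_sacc, t_sacc + epoch_ms] of the single-step trial; each index
    subtracts the matched control response; the remapping index is the
    Euclidean norm of the pair.
    """
    remap = period_response(single_step, dt, t_sacc, t_sacc + epoch_ms)
    vis = remap - period_response(stim_control, dt, *stim_control_window)
    sac = remap - period_response(sacc_control, dt, t_sacc_control,
                                  t_sacc_control + epoch_ms)
    return vis, sac, float(np.hypot(vis, sac))


def decode_preference(responses: np.ndarray, r: np.ndarray, s: np.ndarray,
                      eps: float = DECODE_EPS):
    """Center-of-mass preference decoding from probe-task period responses.

    ``responses[i]`` is the neuron's period response in the i-th probe
    trial with initial retinal stimulus location ``r[i]`` and saccade
    ``s[i]``. Returns (retinal_pref, saccade_pref), or ``None`` if the
    neuron was essentially silent across the battery.
    """
    v = np.asarray(responses, dtype=float)
    total = v.sum()
    if total < eps:
        return None
    return (float(np.dot(r, v) / total), float(np.dot(s, v) / total))


def classify_remapping(remapping_latency: Optional[float],
                       stim_control_latency: Optional[float]):
    """Predictive: saccade-aligned remapping latency shorter than the pure
    visual-onset latency. Pre-saccadic: remapping begins before saccade
    onset. An undecodable remapping latency makes both False."""
    if remapping_latency is None or stim_control_latency is None:
        return False, False
    return (remapping_latency < stim_control_latency,
            remapping_latency < 0.0)


@dataclass(frozen=True)
class ResponsivenessCurve:
    """Population response vs stimulus onset time for one trial family."""

    family: str
    onset_times: np.ndarray           # ms, 13 values
    mean: np.ndarray                  # mean response across neurons
    sd: np.ndarray                    # standard deviation across neurons

    def __post_init__(self):
        if not (len(self.onset_times) == len(self.mean) == len(self.sd)):
            raise ValueError("curve arrays must share one length")


def responsiveness_curves(responses: dict) -> dict:
    """Aggregate per-neuron delayed-flash responses into population curves.

    ``responses``: {family: (n_neurons, n_onsets) array of period responses
    aligned 50 ms after stimulus onset}, keyed by "current_RF"/"future_RF",
    plus an "onsets" entry with the onset times. Returns
    {family: ResponsivenessCurve}.
    """
    onsets = np.asarray(responses["onsets"], dtype=float)
    out = {}
    for family in ("current_RF", "future_RF"):
        arr = np.asarray(responses[family], dtype=float)
        if arr.shape[1] != len(onsets):
            raise ValueError("response matrix does not match onset times")
        out[family] = ResponsivenessCurve(
            family=family, onset_times=onsets,
            mean=arr.mean(axis=0), sd=arr.std(axis=0))
    return out


def multidirection_counts(trained_indices: np.ndarray,
                          untrained_indices: np.ndarray):
    """Per-neuron count of remappable pre-saccadic locations.

    ``trained_indices`` / ``untrained_indices``: matched
    (n_neurons, n_locations) remapping-index arrays. A location counts if
    its trained index is greater than zero and larger than the untrained
    index from the same trial. Returns (per-neuron counts, histogram over
    0..n_locations).
    """
    tr = np.asarray(trained_indices, dtype=float)
    un = np.asarray(untrained_indices, dtype=float)
    if tr.shape != un.shape:
        raise ValueError("trained/untrained index arrays must be matched")
    counts = ((tr > 0) & (tr > un)).sum(axis=1)
    hist = np.bincount(counts, minlength=tr.shape[1] + 1)
    return counts, hist


def summarize_report(report: pd.DataFrame) -> dict:
    """Population summary of a per-neuron remapping report: mean index,
    mean latency, and predictive / pre-saccadic counts and percentages.

    Latency averages include only neurons with a decodable latency.
    """
    n = len(report)
    lat = report["remapping_latency"].dropna()
    pred = int(report["is_predictive"].sum())
    pre = int(report["is_presaccadic"].sum())
    return {
        "n_neurons": n,
        "mean_remapping_index": float(report["remapping_index"].mean()),
        "mean_remapping_latency_ms": (float(lat.mean()) if len(lat) else None),
        "n_latency_decodable": int(len(lat)),
        "predictive_count": pred,
        "predictive_pct": 100.0 * pred / n if n else 0.0,
        "presaccadic_count": pre,
        "presaccadic_pct": 100.0 * pre / n if n else 0.0,
    }
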