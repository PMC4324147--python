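"""End-to-end experiment drivers.

Experiment 1 — predictive / pre-saccadic remapping: train on 17 random
remappings, evaluate each matched remapping neuron's indices, latencies and
classification before and after training; optionally decode combination
preferences from the probe battery before and after training.

Experiment 2 — perisaccadic responsiveness shift: delayed-stimulus-flash
batteries (current vs future receptive field) on the trained network of
Experiment 1, population response curves vs stimulus onset time.

Experiment 3 — remapping from multiple directions: four training pairs per
post-saccadic target location (68 trials), swept over the combination-to-
remapping connectivity fraction phi_C; per-neuron counts of remappable
pre-saccadic locations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import RunManifest, run_battery, timestep, train
from .metrics import (classify_remapping, multidirection_counts,
                      period_response, remapping_index, response_latency,
                      responsiveness_curves, summarize_report)
from .network import Network
from .params import ModelParams
from .protocol import (TrainingSet, build_task_battery,
                       sample_multidirection_pairs, sample_training_set)

__all__ = ["ExperimentConfig", "child_seeds", "evaluate_pairs",
           "decode_combination_preferences", "preference_correlations",
           "run_experiment_1", "run_experiment_2", "run_experiment_3"]

PROBE_DECODE_WINDOW_MS = 50.0
FLASH_RESPONSE_DELAY_MS = 50.0
FLASH_RESPONSE_WINDOW_MS = 300.0


def child_seeds(seed: int, n: int) -> list:
    """Independent integer sub-seeds (< 2**31) derived from one master seed."""
    return [int(c.generate_state(1)[0] % (2 ** 31))
            for c in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class ExperimentConfig:
    """Configuration shared by the experiment drivers."""

    params: ModelParams = field(default_factory=ModelParams)
    seed: int = 1
    epochs: Optional[int] = None            # None: params.epochs
    locations_per_target: int = 4           # experiment 3
    phi_C_sweep: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5,
                                    0.6, 0.7, 0.8, 0.9, 1.0)
    flash_duration_ms: float = 50.0
    probe_duration_ms: float = 700.0

    def __post_init__(self) -> None:
        for v in self.phi_C_sweep:
            if not 0 < v <= 1:
                raise ValueError(f"phi_C sweep value {v} outside (0, 1]")


def _analysis_neuron(net: Network, post_loc: float) -> int:
    idx = np.flatnonzero(net.prefs_R == post_loc)
    if len(idx) == 0:
        raise ValueError(f"no remapping neuron with preference {post_loc}")
    return int(idx[0])


def evaluate_pairs(net: Network, pairs, dt: Optional[float] = None,
                   latencies: bool = True) -> pd.DataFrame:
    """Per-remapping report: for each (h, s) pair, analyze the remapping
    neuron whose retinal preference equals the post-saccadic stimulus
    location h - s.

    Runs the single-step battery for the pairs plus the full stimulus- and
    saccade-control batteries, and computes the visual/saccade/remapping
    indices, the saccade-aligned remapping latency, the stimulus-aligned
    control latency, and the predictive / pre-saccadic classification.
    """
    p = net.params
    if dt is None:
        dt = timestep(p)
    ts = TrainingSet(tuple(pairs), seed=-1) if not isinstance(
        pairs, TrainingSet) else pairs
    single = build_task_battery("single_step", ts)
    stim_ctrl = build_task_battery("stimulus_control")
    sacc_ctrl = build_task_battery("saccade_control")

    tr_single = run_battery(net, single, dt=dt)
    tr_stim = run_battery(net, stim_ctrl, dt=dt)
    tr_sacc = run_battery(net, sacc_ctrl, dt=dt)

    rows = []
    for i, (h, s) in enumerate(ts.pairs):
        r_post = h - s
        j = _analysis_neuron(net, r_post)
        ss = tr_single.pops["v_R"][i, :, j]
        # control with the pre-saccadic stimulus location flashed, no saccade
        stim = tr_stim.pops["v_R"][int(h) + 45, :, j]
        # control with the same saccade, no stimulus
        sacc = tr_sacc.pops["v_R"][int(s) + 30, :, j]
        vis, sac, idx = remapping_index(ss, stim, sacc, dt)
        row = {"pair": i, "h": h, "s": s, "post_loc": r_post, "neuron": j,
               "visual_index": vis, "saccade_index": sac,
               "remapping_index": idx}
        if latencies:
            # visual-onset latency from the flash at the neuron's own RF
            pref = tr_stim.pops["v_R"][int(r_post) + 45, :, j]
            lat_ss = response_latency(ss, dt)
            lat_pref = response_latency(pref, dt)
            remap_lat = None if lat_ss is None else lat_ss - 600.0
            stim_lat = None if lat_pref is None else lat_pref - 100.0
            pred, pre = classify_remapping(remap_lat, stim_lat)
            row.update(remapping_latency=remap_lat,
                       stim_control_latency=stim_lat,
                       is_predictive=pred, is_presaccadic=pre)
        rows.append(row)
    return pd.DataFrame(rows)


def decode_combination_preferences(net: Network,
                                   dt: Optional[float] = None,
                                   probe_duration_ms: float = 700.0):
    """Decode every combination neuron's (retinal, saccade) preference from
    the 5551-trial probe battery by center of mass of its period responses
    over the 50 ms saccade-aligned window.

    Returns (retinal_prefs, saccade_prefs) arrays with NaN where the neuron
    was silent across the whole battery.
    """
    from .metrics import DECODE_EPS

    p = net.params
    if dt is None:
        dt = timestep(p)
    probe = build_task_battery("probe", probe_duration_ms=probe_duration_ms)
    t_sacc = 200.0
    tr = run_battery(net, probe, dt=dt, record=(),
                     window_average={"v_C": (t_sacc,
                                             t_sacc + PROBE_DECODE_WINDOW_MS)})
    resp = tr.pops["window:v_C"]                       # (5551, n_C)
    r = np.array([t.tag["r"] for t in probe], dtype=float)
    s = np.array([t.tag["s"] for t in probe], dtype=float)
    totals = resp.sum(axis=0)
    ok = totals >= DECODE_EPS
    r_pref = np.full(p.n_C, np.nan)
    s_pref = np.full(p.n_C, np.nan)
    r_pref[ok] = (r @ resp[:, ok]) / totals[ok]
    s_pref[ok] = (s @ resp[:, ok]) / totals[ok]
    return r_pref, s_pref


def preference_correlations(before, after):
    """Pearson correlations of decoded (retinal, saccade) preferences over
    neurons decodable both before and after training."""
    out = {}
    for key, (pre, post) in (("retinal", (before[0], after[0])),
                             ("saccade", (before[1], after[1]))):
        ok = np.isfinite(pre) & np.isfinite(post)
        out[key] = float(np.corrcoef(pre[ok], post[ok])[0, 1])
        out[f"n_{key}"] = int(ok.sum())
    return out


@dataclass
class Experiment1Result:
    network: Network
    training_set: TrainingSet
    report_untrained: pd.DataFrame
    report_trained: pd.DataFrame
    summary: dict
    manifest: RunManifest
    untrained_weights: dict
    probe_correlations: Optional[dict] = None


def run_experiment_1(cfg: Optional[ExperimentConfig] = None,
                     decode_probe: bool = False) -> Experiment1Result:
    """Train and test the default network on 17 random remappings."""
    cfg = cfg or ExperimentConfig()
    p = cfg.params
    dt = timestep(p)
    net_seed, ts_seed, shuf_seed, _ = child_seeds(cfg.seed, 4)

    net = Network.build(p, net_seed)
    # one analysis neuron per trial: posts are distinct across the M pairs
    training_set = sample_training_set(p.M, ts_seed, distinct_posts=True)
    untrained = net.weight_snapshot()

    report_un = evaluate_pairs(net, training_set, dt=dt)
    decoded_before = (decode_combination_preferences(
        net, dt=dt, probe_duration_ms=cfg.probe_duration_ms)
        if decode_probe else None)

    manifest = train(net, training_set, epochs=cfg.epochs, dt=dt,
                     shuffle_seed=shuf_seed)
    report_tr = evaluate_pairs(net, training_set, dt=dt)
    corr = None
    if decode_probe:
        decoded_after = decode_combination_preferences(
            net, dt=dt, probe_duration_ms=cfg.probe_duration_ms)
        corr = preference_correlations(decoded_before, decoded_after)

    summary = {"untrained": summarize_report(report_un),
               "trained": summarize_report(report_tr)}
    if corr is not None:
        summary["probe_correlations"] = corr
    return Experiment1Result(network=net, training_set=training_set,
                             report_untrained=report_un,
                             report_trained=report_tr, summary=summary,
                             manifest=manifest, untrained_weights=untrained,
                             probe_correlations=corr)


def _delayed_flash_responses(net: Network, training_set: TrainingSet,
                             dt: float, flash_duration_ms: float) -> dict:
    """Period responses of each analysis neuron in both delayed-flash
    families, aligned 50 ms after stimulus onset (300 ms window, silence-
    padded past the trial end)."""
    onsets = None
    out = {"current_RF": [], "future_RF": []}
    for pair in training_set.pairs:
        sub = TrainingSet((pair,), seed=-1)
        battery = build_task_battery("delayed_flash", sub,
                                     flash_duration_ms=flash_duration_ms)
        j = _analysis_neuron(net, pair[0] - pair[1])
        tr = run_battery(net, battery, dt=dt,
                         neuron_indices={"v_R": np.array([j])})
        if onsets is None:
            onsets = sorted({t.tag["onset"] for t in battery})
        by_fam = {"current_RF": {}, "future_RF": {}}
        for b, t in enumerate(battery):
            by_fam[t.tag["family"]][t.tag["onset"]] = tr.pops["v_R"][b, :, 0]
        for fam in ("current_RF", "future_RF"):
            out[fam].append([
                period_response(by_fam[fam][on], dt,
                                on + FLASH_RESPONSE_DELAY_MS,
                                on + FLASH_RESPONSE_DELAY_MS
                                + FLASH_RESPONSE_WINDOW_MS, pad=True)
                for on in onsets])
    return {"onsets": np.asarray(onsets),
            "current_RF": np.asarray(out["current_RF"]),
            "future_RF": np.asarray(out["future_RF"])}


@dataclass
class Experiment2Result:
    curves_trained: dict
    curves_untrained: dict
    responses_trained: dict
    responses_untrained: dict


def run_experiment_2(exp1: Experiment1Result,
                     cfg: Optional[ExperimentConfig] = None
                     ) -> Experiment2Result:
    """Perisaccadic responsiveness shift on the Experiment-1 network.

    Runs both delayed-flash families at all 13 onset times for the 17
    analysis neurons, on the trained network and on the matched untrained
    weights."""
    cfg = cfg or ExperimentConfig()
    net = exp1.network
    dt = timestep(net.params)

    resp_tr = _delayed_flash_responses(net, exp1.training_set, dt,
                                       cfg.flash_duration_ms)
    trained = net.weight_snapshot()
    net.restore_weights(exp1.untrained_weights)
    try:
        resp_un = _delayed_flash_responses(net, exp1.training_set, dt,
                                           cfg.flash_duration_ms)
    finally:
        net.restore_weights(trained)
    return Experiment2Result(
        curves_trained=responsiveness_curves(resp_tr),
        curves_untrained=responsiveness_curves(resp_un),
        responses_trained=resp_tr, responses_untrained=resp_un)


@dataclass
class Experiment3Result:
    phi_C_values: list
    histograms: dict          # phi_C -> counts over 0..locations_per_target
    counts: dict              # phi_C -> per-neuron counts
    mean_locations: dict      # phi_C -> mean remapped-location count


def run_experiment_3(cfg: Optional[ExperimentConfig] = None
                     ) -> Experiment3Result:
    """Remapping from multiple pre-saccadic locations, swept over phi_C.

    For each phi_C the network is rebuilt and trained on four pairs per
    post-saccadic target location (68 trials at the default M = 17); each
    analysis neuron is scored by how many of its four locations pass the
    classification rule (trained index > 0 and > the untrained index from
    the same trial)."""
    cfg = cfg or ExperimentConfig()
    p = cfg.params
    net_seed, ts_seed, shuf_seed, multi_seed = child_seeds(cfg.seed, 4)
    base = sample_training_set(p.M, ts_seed, distinct_posts=True)
    posts = base.post_saccadic_locations()
    multi = sample_multidirection_pairs(posts, cfg.locations_per_target,
                                        multi_seed)

    hists, counts, means = {}, {}, {}
    for phi in cfg.phi_C_sweep:
        params = p.replace(phi_C=phi)
        dt = timestep(params)
        net = Network.build(params, net_seed)
        rep_un = evaluate_pairs(net, multi, dt=dt, latencies=False)
        train(net, multi, epochs=cfg.epochs, dt=dt, shuffle_seed=shuf_seed)
        rep_tr = evaluate_pairs(net, multi, dt=dt, latencies=False)
        k = cfg.locations_per_target
        tr = rep_tr["remapping_index"].to_numpy().reshape(-1, k)
        un = rep_un["remapping_index"].to_numpy().reshape(-1, k)
        c, h = multidirection_counts(tr, un)
        counts[phi], hists[phi] = c, h
        means[phi] = float(c.mean())
    return Experiment3Result(phi_C_values=list(cfg.phi_C_sweep),
                             histograms=hists, counts=counts,
                             mean_locations=means)


def write_exp1_outputs(result: Experiment1Result, outdir) -> None:
    """CSV per-neuron reports, JSON population summary, JSON manifest."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.report_trained.to_csv(out / "report_trained.csv", index=False)
    result.report_untrained.to_csv(out / "report_untrained.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1)
    result.manifest.to_json(out / "manifest.json")
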