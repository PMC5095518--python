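"""End-to-end experiment pipelines and figure presets.

Each preset reproduces one of the model's experiments from a single call,
using only the built-in synthetic naturalistic stimuli: development of the
network, frozen-network response clustering, receptive-field/connectivity
statistics, spontaneous-activity pattern matching, stimulus-mixture
morphing, network manipulations, the shuffled-pixel control, the spike-
blocking prediction, the +/-20% robustness sweep, and the quadrupled
network.  All pipelines are deterministic functions of (seed, config).

The preset training horizon is a scaled-down default (tens of thousands of
presentations rather than a million); the stabilization checkpoint
statistic quantifies how far development has converged at that horizon.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from . import analysis, engine, network as net_mod, stimuli
from .config import load_config, materialize
from .engine import Protocol, apply_manipulation, record_spontaneous, \
    test_responses, train
from .network import build_network, perturb_config, scale_for_size
from .stimuli import PatchStream


def _stream(cfg: dict, seed: int, shuffle: bool = False) -> PatchStream:
    s = cfg["stimuli"]
    return PatchStream(np.random.default_rng(seed),
                       image_size=s["image_size"],
                       spectral_exponent=s["spectral_exponent"],
                       patches_per_image=s["patches_per_image"],
                       shuffle=shuffle)


def _seeds(seed: int, *labels: str) -> dict:
    """Fan one seed out into independent named streams."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labels))
    out = {}
    for lab, child in zip(labels, children):
        out[lab] = int(child.generate_state(1)[0] & 0x7FFFFFFF)
    return out


def develop(cfg: dict, seed: int, n_presentations: int | None = None,
            shuffle: bool = False, size_factor: int = 1,
            perturb: float | None = None, log_every: int = 0):
    """Build a network and train it on synthetic naturalistic patches.

    Returns (trained network, checkpoint dict of flattened lateral-weight
    snapshots at half and full training).  ``shuffle`` applies the per-frame
    pixel shuffle control; ``size_factor`` scales the population (dividing
    A_lat); ``perturb`` multiplies the seven free parameters (robustness).
    """
    net_cfg, neuron, plast = materialize(cfg)
    if size_factor > 1:
        net_cfg = scale_for_size(net_cfg, size_factor)
    if perturb is not None:
        net_cfg, plast = perturb_config(net_cfg, plast, perturb)
    seeds = _seeds(seed, "build", "stimuli", "train")
    rng = np.random.default_rng(seeds["build"])
    net = build_network(net_cfg, neuron_params=neuron,
                        plasticity_params=plast, rng=rng)
    n_pres = cfg["training"]["n_presentations"] \
        if n_presentations is None else n_presentations
    proto = Protocol(stim_duration=cfg["protocol"]["stim_duration"],
                     blank_duration=cfg["protocol"]["blank_duration"],
                     n_presentations=max(n_pres, 1), plastic=True)
    stream = _stream(cfg, seeds["stimuli"], shuffle=shuffle)
    checkpoints = train(net, stream, n_pres, seed=seeds["train"],
                        protocol=proto, log_every=log_every)
    return net, checkpoints


def evoked_test(cfg: dict, net, seed: int, n_test: int | None = None,
                shuffle: bool = False, record_potentials: bool = False):
    """Frozen-network responses to fresh synthetic stimuli.

    Returns (ResponseMatrix, list of normalized patches presented).
    """
    seeds = _seeds(seed, "stimuli", "test")
    stream = _stream(cfg, seeds["stimuli"], shuffle=shuffle)
    n = cfg["training"]["n_test"] if n_test is None else n_test
    patches = [stream.next_patch() for _ in range(n)]
    on_off = [stimuli.split_on_off(p) for p in patches]
    proto = Protocol(stim_duration=cfg["protocol"]["stim_duration"],
                     blank_duration=cfg["protocol"]["blank_duration"],
                     n_presentations=n,
                     record_potentials=record_potentials)
    rm = test_responses(net, on_off, seed=seeds["test"], protocol=proto)
    return rm, patches


def connectivity_stats(net, checkpoints: dict) -> dict:
    """Connectivity statistics of a trained network.

    Keys: lateral transpose correlation, top-10%/top-5% weight shares,
    median RF correlation of the top-10% most strongly connected pairs, and
    the half-vs-full training stabilization correlation.
    """
    W = net.W_lat_EE
    half = checkpoints.get(0.5)
    full = checkpoints.get(1.0, W.flatten())
    if half is None or half.std() == 0 or full.std() == 0:
        stab = float("nan")
    else:
        stab = float(np.corrcoef(half, full)[0, 1])
    return {
        "lateral_transpose_corr": analysis.weight_symmetry(W),
        "top10pct_weight_share": analysis.weight_concentration(W, 0.10),
        "top5pct_weight_share": analysis.weight_concentration(W, 0.05),
        "rf_similarity_top_pairs": analysis.rf_pair_similarity(
            net.W_ff, W, top_weight_fraction=0.10),
        "half_vs_full_weight_corr": stab,
    }


def response_stats(net, rm) -> dict:
    """Firing-rate and correlated-pair statistics of a frozen test run."""
    med, mx, med_max = analysis.rate_stats(rm)
    return {
        "median_rate_hz": med,
        "max_rate_hz": mx,
        "median_max_rate_hz": med_max,
        "correlated_pair_weight_share": analysis.correlated_pair_weight_share(
            rm, net.W_lat_EE, top_pair_fraction=0.05),
    }


def pick_mixture_pair(rm, patches) -> tuple[np.ndarray, np.ndarray]:
    """Choose the two source stimuli for the mixture experiment.

    Presentations are clustered; within each of the two largest clusters the
    stimulus that evoked the highest single-cell response is selected
    (stimulus 1 from the largest cluster, stimulus 2 from the second).
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    M = rm.counts
    sd = M.std(axis=0)
    ok = np.flatnonzero(sd > 0)
    if len(ok) < 4:
        raise ValueError("too few active presentations to pick a pair")
    C = analysis._corr_columns(M[:, ok])
    D = np.clip(1.0 - C, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    k = max(analysis.count_response_clusters(rm), 2)
    labels = hierarchy.fcluster(Z, k, criterion="maxclust")
    sizes = np.bincount(labels)[1:]
    order = np.argsort(sizes)[::-1] + 1
    picks = []
    for lab in order[:2]:
        members = ok[labels == lab]
        best = members[np.argmax(M[:, members].max(axis=0))]
        picks.append(best)
    return patches[picks[0]], patches[picks[1]]


def mixture_experiment(cfg: dict, net, s1: np.ndarray, s2: np.ndarray,
                       seed: int, condition: str = "full",
                       n_mixtures: int = 30) -> dict:
    """Morph between two stimuli and decompose the responses.

    Conditions: ``full`` (spike counts, intact network), ``no_lateral``
    (spike counts, all lateral connections disabled), ``subthreshold``
    (mean potential deviation from the blank-period baseline, intact
    network), ``blocked`` (same, with spiking blocked in every cell).
    Returns responses, the (beta1, beta2) series and the transition
    sharpness.
    """
    run_net = net
    use_potential = condition in ("subthreshold", "blocked")
    if condition == "no_lateral":
        run_net = apply_manipulation(net, "disable_lateral", "all")
    elif condition == "blocked":
        run_net = apply_manipulation(net, "block_spikes")
    elif condition not in ("full", "subthreshold"):
        raise ValueError(f"unknown condition {condition!r}")
    series = analysis.mixture_series(s1, s2, n=n_mixtures)
    proto = Protocol(stim_duration=cfg["protocol"]["stim_duration"],
                     blank_duration=cfg["protocol"]["blank_duration"],
                     n_presentations=n_mixtures,
                     record_potentials=use_potential)
    rm = test_responses(run_net, series, seed=seed, protocol=proto)
    if use_potential:
        # stimulus-driven depolarization relative to the noise-only baseline
        base_rm = test_responses(
            run_net, [np.zeros(stimuli.N_CHANNELS)], seed=seed,
            protocol=dataclasses.replace(proto, n_presentations=1))
        baseline = base_rm.potentials[:, 0]
        responses = rm.potentials - baseline[:, None]
    else:
        responses = rm.counts
    b1, b2 = analysis.mixture_regression_series(responses)
    return {
        "condition": condition,
        "responses": responses,
        "beta1": b1,
        "beta2": b2,
        "sharpness": analysis.transition_sharpness(b1),
    }


def manipulation_experiment(cfg: dict, net, seed: int,
                            duration: int = 5_000) -> dict:
    """E-cell firing rates under ongoing stimulation, three conditions.

    full: intact network; no_inhibition: all I cells silenced;
    no_inhibition_no_lateral: I cells silenced and all lateral connections
    removed.  Each condition is driven by the same sequence of naturalistic
    patches (300 ms on / 50 ms blank) filling ``duration`` ms; rates in Hz,
    averaged over E cells and the run.  Ongoing drive is what exposes the
    circuit's stability: the runaway after silencing inhibition is a
    property of the recurrently amplified evoked state, not of the sparse
    noise-driven resting state.
    """
    proto = Protocol(stim_duration=cfg["protocol"]["stim_duration"],
                     blank_duration=cfg["protocol"]["blank_duration"])
    period = proto.stim_duration + proto.blank_duration
    n_pres = max(int(duration) // period, 1)
    stream = _stream(cfg, seed)
    stims = [stream.next_on_off() for _ in range(n_pres)]
    conditions = {
        "full": net,
        "no_inhibition": apply_manipulation(net, "silence_inhibition"),
        "no_inhibition_no_lateral": apply_manipulation(
            apply_manipulation(net, "silence_inhibition"),
            "disable_lateral", "all"),
    }
    out = {}
    for name, n in conditions.items():
        sim = engine.Simulation(n, seed=seed, plastic=False)
        for vec in stims:
            sim.run(proto.stim_duration, n.config.rate_scale * vec)
            sim.run(proto.blank_duration, None)
        e_spikes = int(sim.spike_counts[:n.n_E].sum())
        out[name] = e_spikes / n.n_E / (n_pres * period * 1e-3)
    return out


def offset_decay_experiment(cfg: dict, net, stimulus_on_off: np.ndarray,
                            seed: int, stim_ms: int = 100,
                            post_ms: int = 300, bin_ms: int = 10) -> dict:
    """Population-rate time course around stimulus offset, full vs ablated.

    Presents a stimulus for ``stim_ms``, then records ``post_ms`` of null
    input; returns binned E-population rates and the time for the rate to
    fall below twice the spontaneous level after offset, for the full
    network and with all lateral connections disabled.
    """
    rates = net.config.rate_scale * np.asarray(stimulus_on_off, dtype=float)
    out = {}
    for name, n in (("full", net),
                    ("no_lateral", apply_manipulation(net, "disable_lateral",
                                                      "all"))):
        sim = engine.Simulation(n, seed=seed, plastic=False)
        cap = (stim_ms + post_ms) * n.n_total
        sim.run(stim_ms, rates, record_raster=True, raster_capacity=cap)
        sim.run(post_ms, None, record_raster=True, raster_capacity=cap)
        raster = sim.raster()
        nE = n.n_E
        sel = raster.neurons < nE
        t = raster.times[sel]
        n_bins = (stim_ms + post_ms) // bin_ms
        hist = np.bincount(np.minimum(t // bin_ms, n_bins - 1),
                           minlength=n_bins).astype(float)
        rate = hist / nE / (bin_ms * 1e-3)
        spont = record_spontaneous(n, duration=2_000, seed=seed)
        base = (spont.neurons < nE).sum() / nE / 2.0
        floor = max(2.0 * base, 1.0)
        post = rate[stim_ms // bin_ms:]
        below = np.flatnonzero(post <= floor)
        decay = float((below[0] + 1) * bin_ms) if len(below) else float(
            post_ms)
        out[name] = {"rate_hz": rate, "decay_ms": decay,
                     "spontaneous_hz": base}
    return out


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("fig2_clustering", "fig3_connectivity", "fig4_spontaneous",
                "fig5_mixture", "fig6_shuffled", "fig7_manipulations",
                "fig8_blocking", "robustness_sweep", "size_x4")


def run_preset(name: str, seed: int = 0, config_path=None,
               out_dir="v1net_out", n_presentations: int | None = None,
               n_test: int | None = None, log_every: int = 0) -> dict:
    """Run one figure preset end to end and write its artifacts.

    Every preset trains (or reuses a cached trained network in ``out_dir``)
    on synthetic stimuli, runs its experiment, writes the outputs (HDF5
    network, JSON statistics) under ``out_dir`` and returns a manifest of
    files and headline statistics.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; expected one of "
                         f"{PRESET_NAMES}")
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stats: dict = {"preset": name, "seed": seed}
    files: list[str] = []

    shuffle = name == "fig6_shuffled"
    size_factor = 4 if name == "size_x4" else 1
    perturbs = (1.2, 0.8) if name == "robustness_sweep" else (None,)

    for perturb in perturbs:
        tag = name if perturb is None else f"{name}_x{perturb}"
        net, checkpoints = develop(cfg, seed, n_presentations=n_presentations,
                                   shuffle=shuffle, size_factor=size_factor,
                                   perturb=perturb, log_every=log_every)
        net_path = out / f"{tag}_network.h5"
        net_mod.save_network(net, net_path)
        files.append(str(net_path))
        rm, patches = evoked_test(cfg, net, seed + 1, n_test=n_test,
                                  shuffle=shuffle)
        stats[f"{tag}_connectivity"] = connectivity_stats(net, checkpoints)
        stats[f"{tag}_responses"] = response_stats(net, rm)
        stats[f"{tag}_n_clusters"] = analysis.count_response_clusters(rm)

        if name == "fig4_spontaneous":
            raster = record_spontaneous(net, duration=100_000, seed=seed + 2)
            raster_path = out / f"{tag}_spontaneous_raster.txt"
            raster.to_text(raster_path)
            files.append(str(raster_path))
            spont = analysis.spontaneous_patterns(raster)
            evoked = rm.counts
            best, overall = analysis.pattern_match_score(spont, evoked)
            stats[f"{tag}_pattern_match"] = {
                "best_match_corr": best, "overall_corr": overall}
        if name in ("fig5_mixture", "fig8_blocking"):
            s1, s2 = pick_mixture_pair(rm, patches)
            conds = ("full", "no_lateral") if name == "fig5_mixture" \
                else ("subthreshold", "blocked")
            for cond in conds:
                res = mixture_experiment(cfg, net, s1, s2, seed + 3,
                                         condition=cond)
                stats[f"{tag}_sharpness_{cond}"] = res["sharpness"]
        if name == "fig7_manipulations":
            stats[f"{tag}_spontaneous_rates"] = manipulation_experiment(
                cfg, net, seed + 2)
            idx = int(np.argmax(rm.counts.max(axis=0)))
            res = offset_decay_experiment(
                cfg, net, stimuli.split_on_off(patches[idx]), seed + 4)
            stats[f"{tag}_offset_decay_ms"] = {
                k: v["decay_ms"] for k, v in res.items()}

    stats["runtime_s"] = round(time.time() - t0, 1)
    manifest = {"preset": name, "seed": seed, "files": files,
                "config": cfg, "stats": _jsonable(stats)}
    manifest_path = out / f"{name}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
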