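"""End-to-end orchestration of the three headline analyses.

Given a multi-participant TrialSet, the pipeline runs, per participant,
the channel-selection / peak-detection preamble and then:

* the cueing contrast (precue vs retro-cue, correct trials only):
  baseline-normalized alpha/beta band power, 1-6 Hz intertrial phase
  coherence, and planar ERFs, each tested at the group level with the
  cluster permutation test;
* the RT contrast (all responded trials, five RT quantile bins,
  slowest vs fastest): the same four measures (power normalized to the
  across-bin mean) plus an across-trial PAC contrast on an ROI;
* the decoding suite: time-resolved decoding of cue instruction and
  sample features, LOOCV single-trial estimates binned by prestimulus
  band power, and temporal generalization with early-training-window
  averaging.

Every stage records its parameters and seed so a report is reproducible
from (data, config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .binning import (CANONICAL_BANDS, extreme_bin_contrast,
                      prestim_power_per_trial, quantile_bins)
from .cluster_stats import ClusterResult, cluster_permutation_test
from .containers import TrialSet
from .decoding import (average_train_window, auc, loocv_estimates,
                       power_binned_decoding_contrast, temporal_generalization,
                       timewise_decode)
from .erf import (average_erf, baseline_correct, planar_gradient,
                  select_max_erf_channels)
from .phase_coupling import itc, itc_band_average, pac_across_trials
from .preprocessing import lowpass
from .simulate import occipital_channels
from .spectral import (band_timecourse, estimate_peaks, normalize_power,
                       power_spectrum, tfr)

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "participant_peaks",
    "run_cueing_contrast",
    "run_rt_contrast",
    "run_decoding_suite",
    "run_all",
    "report_to_json",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters; defaults mirror the standard protocol."""

    baseline_window: tuple = (-0.1, 0.0)
    erf_select_k: int = 20
    erf_select_window: tuple | None = None   # default: 0.2 s after sample onset
    prestim_window: tuple = (-1.0, 0.0)
    power_baseline: tuple = (-0.4, -0.2)
    alpha_band_hz: float = 2.0               # bandwidth around the alpha peak
    beta_band_hz: float = 4.0                # bandwidth around the beta peak
    itc_band: tuple = (1.0, 6.0)
    tfr_step_s: float = 0.02
    n_rt_bins: int = 5
    pac_phase_band: tuple = (1.0, 3.0)
    pac_amp_band: tuple = (30.0, 35.0)
    pac_window_s: float = 1.0
    pac_step_s: float = 0.25
    n_perm: int = 500
    alpha: float = 0.05
    threshold_p: float = 0.05
    decode_lowpass_hz: float = 35.0
    decode_decim: int = 4
    decode_window: tuple | None = None       # None: full epoch
    loocv_window: tuple = (0.0, 0.6)
    tgm_window: tuple | None = None          # default: sample onset .. +2.5 s
    tgm_train_avg_s: float = 0.3
    n_folds: int = 4
    run_pac: bool = True
    seed: int = 0


@dataclass
class AnalysisReport:
    """Structured result container with provenance."""

    peaks: pd.DataFrame | None = None
    cueing: dict = field(default_factory=dict)
    rt: dict = field(default_factory=dict)
    decoding: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _participants(ts: TrialSet):
    if "participant_id" not in ts.meta.columns:
        raise ValueError("TrialSet metadata lacks a participant_id column")
    return list(dict.fromkeys(ts.meta["participant_id"]))


def _sample_onset(ts: TrialSet) -> float:
    # first-cue onset is epoch time 0; the sample follows one SOA later
    return 1.5


def participant_peaks(ts: TrialSet, config: PipelineConfig = PipelineConfig()):
    """Channel selection and individualized peak detection.

    Baseline-corrected grand ERF -> planar transform -> the k channels
    with maximal post-sample (grating) response -> prestimulus Hanning
    spectrum on those channels -> alpha/beta peak estimates. Falls back
    to 10 / 20 Hz when a spectrum has no in-band local maximum.
    """
    s0 = _sample_onset(ts)
    window = config.erf_select_window or (s0, s0 + 0.2)
    bc = baseline_correct(ts, config.baseline_window)
    erf = average_erf(bc)
    planar = planar_gradient(erf, ts.layout)
    chans = select_max_erf_channels(planar, window, min(config.erf_select_k, ts.n_channels))
    spec = power_spectrum(ts, chans, config.prestim_window)
    pk = estimate_peaks(spec)
    alpha_hz = pk.alpha_hz if pk.alpha_hz is not None else 10.0
    beta_hz = pk.beta_hz if pk.beta_hz is not None else 20.0
    return alpha_hz, beta_hz, chans


def _band_freqs(center: float, bandwidth: float) -> np.ndarray:
    lo = np.ceil(center - bandwidth / 2)
    hi = np.floor(center + bandwidth / 2)
    return np.arange(lo, hi + 1e-9)


def _band_map(sub: TrialSet, center, bandwidth, step_s) -> tuple[np.ndarray, np.ndarray]:
    t = tfr(sub, _band_freqs(center, bandwidth), step_s=step_s)
    bt = band_timecourse(t, center, bandwidth)
    return bt, t.times


def _erf_map(sub: TrialSet, config: PipelineConfig, grid_times) -> np.ndarray:
    erf = average_erf(baseline_correct(sub, config.baseline_window))
    planar = planar_gradient(erf, sub.layout)
    idx = [np.argmin(np.abs(sub.times - t)) for t in grid_times]
    return planar.amplitude[:, idx]


def run_cueing_contrast(ts: TrialSet, config: PipelineConfig = PipelineConfig()) -> dict:
    """Precue vs retro-cue group contrast on four measures.

    Correct trials only. Alpha/beta band power is baseline-ratio
    normalized; ITC is averaged over 1-6 Hz; ERFs are planar. Each
    measure gets a channels x time cluster permutation test.
    """
    per = {m: {"pre": [], "retro": []} for m in ("alpha", "beta", "itc", "erf")}
    peaks_rows = []
    grid_times = None
    for p in _participants(ts):
        tsp = ts.select_trials(
            (ts.meta["participant_id"] == p).to_numpy()
            & ts.meta["correct"].to_numpy(dtype=bool))
        if not {"pre", "retro"} <= set(tsp.meta["cue_condition"]):
            raise ValueError(f"participant {p} lacks a cue condition")
        a_hz, b_hz, chans = participant_peaks(tsp, config)
        peaks_rows.append({"participant": p, "alpha_hz": a_hz, "beta_hz": b_hz})
        for cond in ("pre", "retro"):
            sub = tsp.select_trials((tsp.meta["cue_condition"] == cond).to_numpy())
            for name, center, bw in (("alpha", a_hz, config.alpha_band_hz),
                                     ("beta", b_hz, config.beta_band_hz)):
                bt, times = _band_map(sub, center, bw, config.tfr_step_s)
                bt = normalize_power(bt, "baseline_ratio", config.power_baseline)
                per[name][cond].append(bt.power)
                grid_times = times
            m = itc(sub, np.arange(config.itc_band[0], config.itc_band[1] + 1e-9),
                    step_s=config.tfr_step_s)
            per["itc"][cond].append(itc_band_average(m, *config.itc_band))
            per["erf"][cond].append(_erf_map(sub, config, grid_times))
    results = {}
    for name, conds in per.items():
        results[name] = cluster_permutation_test(
            np.stack(conds["pre"]), np.stack(conds["retro"]), ts.layout,
            n_perm=config.n_perm, alpha=config.alpha,
            threshold_p=config.threshold_p, seed=config.seed)
    return {"tests": results, "times": grid_times,
            "peaks": pd.DataFrame(peaks_rows)}


def run_rt_contrast(ts: TrialSet, config: PipelineConfig = PipelineConfig()) -> dict:
    """Slowest vs fastest RT-bin group contrast.

    All responded trials (correct and incorrect) are pooled and split
    into RT quantile bins per participant; band power is normalized to
    the across-bin mean. The PAC contrast runs on the occipital ROI.
    """
    measures = ("alpha", "beta", "itc", "erf")
    bin_maps = {m: [dict() for _ in range(config.n_rt_bins)] for m in measures}
    pac_maps = [dict() for _ in range(config.n_rt_bins)]
    grid_times = None
    pac_obj = None
    for p in _participants(ts):
        tsp = ts.select_trials(
            (ts.meta["participant_id"] == p).to_numpy()
            & np.isfinite(ts.meta["rt_s"].to_numpy(dtype=float)))
        if tsp.n_trials < config.n_rt_bins * 2:
            raise ValueError(f"participant {p}: too few responded trials for "
                             f"{config.n_rt_bins} RT bins")
        a_hz, b_hz, chans = participant_peaks(tsp, config)
        bins = quantile_bins(tsp.meta["rt_s"], config.n_rt_bins, "rt")
        roi = occipital_channels(tsp.layout)
        alpha_bts, beta_bts = [], []
        for b in range(1, config.n_rt_bins + 1):
            sub = tsp.select_trials(bins.mask(b))
            bt_a, times = _band_map(sub, a_hz, config.alpha_band_hz, config.tfr_step_s)
            bt_b, _ = _band_map(sub, b_hz, config.beta_band_hz, config.tfr_step_s)
            alpha_bts.append(bt_a)
            beta_bts.append(bt_b)
            grid_times = times
            m = itc(sub, np.arange(config.itc_band[0], config.itc_band[1] + 1e-9),
                    step_s=config.tfr_step_s)
            bin_maps["itc"][b - 1][p] = itc_band_average(m, *config.itc_band)
            bin_maps["erf"][b - 1][p] = _erf_map(sub, config, grid_times)
            if config.run_pac:
                pm = pac_across_trials(
                    sub, config.pac_phase_band, config.pac_amp_band, roi,
                    config.pac_window_s, config.pac_step_s)
                pac_maps[b - 1][p] = pm.mi
                pac_obj = pm
        for name, bts in (("alpha", alpha_bts), ("beta", beta_bts)):
            for b, bt in enumerate(normalize_power(bts, "bin_mean_ratio")):
                bin_maps[name][b][p] = bt.power
    results = {}
    for name in measures:
        slow, fast, subjects, excluded = extreme_bin_contrast(
            list(reversed(bin_maps[name])))   # bin n (slowest) first
        results[name] = cluster_permutation_test(
            slow, fast, ts.layout, n_perm=config.n_perm, alpha=config.alpha,
            threshold_p=config.threshold_p, seed=config.seed)
    out = {"tests": results, "times": grid_times}
    if config.run_pac:
        slow, fast, subjects, excluded = extreme_bin_contrast(
            list(reversed(pac_maps)))
        out["tests"]["pac"] = cluster_permutation_test(
            slow, fast, None, n_perm=config.n_perm, alpha=config.alpha,
            threshold_p=config.threshold_p, seed=config.seed)
        out["pac_grid"] = {"phase_freqs": pac_obj.phase_freqs.tolist(),
                           "amp_freqs": pac_obj.amp_freqs.tolist(),
                           "times": pac_obj.times.tolist()}
    return out


def _decim_window(ts: TrialSet, window, decim):
    sl = ts.time_slice(window) if window else slice(None)
    data = ts.data[:, :, sl][:, :, ::decim]
    times = ts.times[sl][::decim]
    return data, times


def run_decoding_suite(ts: TrialSet, config: PipelineConfig = PipelineConfig()) -> dict:
    """Decoding analyses: cue instruction, sample features, power-binned
    contrasts, and temporal generalization.

    The broadband signal is low-passed at 35 Hz before decoding and
    decimated to keep desk-scale runtimes; per participant the LOOCV
    single-trial scores are binned by prestimulus occipital band power
    and the lowest/highest-bin AUC curves are cluster-tested over time
    at the group level.
    """
    s0 = _sample_onset(ts)
    tgm_window = config.tgm_window or (s0, min(s0 + 2.5, float(ts.times[-1])))
    per_subject = {
        "cue_auc": {"pre": [], "retro": []},
        "binned": {band: {"low": [], "high": []} for band in CANONICAL_BANDS},
        "tgm_avg": {"low": [], "high": []},
    }
    decode_times = loocv_times = tgm_times = None
    for p in _participants(ts):
        tsp = ts.select_trials((ts.meta["participant_id"] == p).to_numpy())
        low = lowpass(tsp, config.decode_lowpass_hz)
        roi = occipital_channels(tsp.layout)
        # 1) time-resolved decoding of cue instruction, per cue condition
        for cond in ("pre", "retro"):
            mask = (low.meta["cue_condition"] == cond).to_numpy()
            sub = low.select_trials(mask)
            data, decode_times = _decim_window(sub, config.decode_window,
                                               config.decode_decim)
            res = timewise_decode(data, sub.meta["feature"].to_numpy(),
                                  config.n_folds, seed=config.seed)
            res.times = decode_times
            per_subject["cue_auc"][cond].append(res.auc)
        # 2) LOOCV cue-instruction scores binned by prestimulus power
        data, loocv_times = _decim_window(low, config.loocv_window,
                                          config.decode_decim)
        est = loocv_estimates(data, low.meta["feature"].to_numpy())
        est.times = loocv_times
        for band in CANONICAL_BANDS:
            power = prestim_power_per_trial(tsp, band, config.prestim_window, roi)
            bins = quantile_bins(power, config.n_rt_bins, band)
            bd = power_binned_decoding_contrast(est, bins)
            per_subject["binned"][band]["low"].append(bd.lowest)
            per_subject["binned"][band]["high"].append(bd.highest)
        # 3) temporal generalization of the sample's spatial frequency,
        #    beta-binned via held-out scores
        data, tgm_times = _decim_window(low, tgm_window, config.decode_decim * 2)
        tg = temporal_generalization(data, low.meta["stim_frequency"].to_numpy(),
                                     config.n_folds, seed=config.seed,
                                     keep_scores=True)
        tg.train_times = tg.test_times = tgm_times
        train_mask = tgm_times <= tgm_times[0] + config.tgm_train_avg_s + 1e-9
        beta_power = prestim_power_per_trial(
            tsp, "beta", (s0 - 1.0, s0), roi)
        bbins = quantile_bins(beta_power, config.n_rt_bins, "beta")
        for which, b in (("low", 1), ("high", config.n_rt_bins)):
            mask = bbins.mask(b)
            yb = tg.labels[mask]
            if len(np.unique(yb)) < 2:
                curve = np.full(len(tgm_times), np.nan)
            else:
                curve = np.array([
                    auc(tg.held_out_scores[mask][:, train_mask, jt].mean(axis=1), yb)
                    for jt in range(len(tgm_times))])
            per_subject["tgm_avg"][which].append(curve)
    tests = {}
    for band in CANONICAL_BANDS:
        tests[f"binned_{band}"] = cluster_permutation_test(
            np.stack(per_subject["binned"][band]["low"]),
            np.stack(per_subject["binned"][band]["high"]),
            None, n_perm=config.n_perm, alpha=config.alpha,
            threshold_p=config.threshold_p, seed=config.seed)
    tests["tgm_beta"] = cluster_permutation_test(
        np.stack(per_subject["tgm_avg"]["low"]),
        np.stack(per_subject["tgm_avg"]["high"]),
        None, n_perm=config.n_perm, alpha=config.alpha,
        threshold_p=config.threshold_p, seed=config.seed)
    return {
        "cue_auc": {c: np.stack(v) for c, v in per_subject["cue_auc"].items()},
        "binned": per_subject["binned"],
        "tgm_avg": {k: np.stack(v) for k, v in per_subject["tgm_avg"].items()},
        "tests": tests,
        "times": {"decode": decode_times, "loocv": loocv_times, "tgm": tgm_times},
    }


def run_all(ts: TrialSet, config: PipelineConfig = PipelineConfig()) -> AnalysisReport:
    """Run all three analysis families and assemble a report."""
    cueing = run_cueing_contrast(ts, config)
    rt = run_rt_contrast(ts, config)
    dec = run_decoding_suite(ts, config)
    cfg_blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return AnalysisReport(
        peaks=cueing.pop("peaks"),
        cueing=cueing,
        rt=rt,
        decoding=dec,
        provenance={
            "config": json.loads(cfg_blob),
            "config_sha256": hashlib.sha256(cfg_blob.encode()).hexdigest(),
            "seed": config.seed,
            "oscpipe_version": __version__,
            "n_trials": ts.n_trials,
            "n_channels": ts.n_channels,
        },
    )


def _jsonify(obj):
    if isinstance(obj, ClusterResult):
        return {
            "n_perm": obj.n_perm,
            "alpha": obj.alpha,
            "threshold_p": obj.threshold_p,
            "exhaustive": obj.exhaustive,
            "warnings": obj.warnings,
            "null_max_quantiles": np.quantile(
                obj.null_max, [0.5, 0.95, 0.99]).tolist() if len(obj.null_max) else [],
            "clusters": [
                {"sign": c.sign, "sum_t": c.sum_t, "p_value": c.p_value,
                 "size": c.size,
                 "cells": [a.tolist() for a in c.cells]}
                for c in obj.clusters[:20]
            ],
        }
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, np.ndarray):
        return np.where(np.isfinite(obj), obj, None).tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def report_to_json(report: AnalysisReport) -> str:
    """Serialize a report (cluster tests summarized, arrays inlined)."""
    return json.dumps(_jsonify({
        "peaks": report.peaks,
        "cueing": report.cueing,
        "rt": report.rt,
        "decoding": report.decoding,
        "provenance": report.provenance,
    }))
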