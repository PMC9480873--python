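"""Intertrial phase coherence and across-trial phase-amplitude coupling.

ITC at a (channel, frequency, time) cell is the resultant length of the
unit phase vectors across trials, |N^-1 sum_n exp(i phi_n)|: 0 for
uniform phases (expectation sqrt(pi)/2 * N^-1/2 at finite N), 1 for
perfect alignment. Phases come from the same 5-cycle Hanning sliding
windows as the TFR.

PAC is measured ACROSS TRIALS at each latency: at a given time window,
the amplitude envelope samples of the fast band are binned by the
concurrent slow-band phase (pooled over trials), and the normalized
Kullback-Leibler modulation index MI = (log K - H(p)) / log K is
computed from the phase-binned mean-amplitude distribution p (K bins).
MI is 0 for phase-independent amplitude and 1 when all amplitude mass
falls in a single phase bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import TrialSet
from .spectral import nanmean_quiet, sliding_fourier

__all__ = [
    "ITCMap",
    "PACMap",
    "itc",
    "itc_band_average",
    "modulation_index",
    "pac_across_trials",
    "pac_trial_shuffle_null",
]


@dataclass
class ITCMap:
    """Intertrial phase coherence (channels x freqs x times) in [0, 1]."""

    itc: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_trials: int


@dataclass
class PACMap:
    """Across-trial modulation index (phase_freqs x amp_freqs x times)."""

    mi: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    times: np.ndarray
    phase_band: tuple
    amp_band: tuple
    n_bins: int
    n_trials: int


def itc(ts: TrialSet, freqs=None, channels=None, step_s: float = 0.02,
        n_cycles: float = 5.0) -> ITCMap:
    """Intertrial phase coherence per channel, frequency, and time."""
    if ts.n_trials < 2:
        raise ValueError("ITC requires at least 2 trials")
    if freqs is None:
        freqs = np.arange(1.0, 31.0)
    chan = ts.channel_indices(channels)
    coefs, out_idx = sliding_fourier(ts.data[:, chan, :], ts.fs, freqs, step_s, n_cycles)
    mag = np.abs(coefs)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag > 0, coefs / mag, np.nan + 0j)
        resultant = np.abs(np.mean(unit, axis=0))
    return ITCMap(resultant, np.atleast_1d(np.asarray(freqs, float)),
                  ts.times[out_idx], ts.n_trials)


def itc_band_average(m: ITCMap, lo: float, hi: float) -> np.ndarray:
    """Mean ITC over defined in-band frequency rows -> (channels x times)."""
    mask = (m.freqs >= lo - 1e-9) & (m.freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] Hz is empty on the ITC grid")
    return nanmean_quiet(m.itc[:, mask, :], axis=1)


# -- modulation index -----------------------------------------------------

def modulation_index(phases, amplitudes, n_bins: int = 18) -> float:
    """Tort-style normalized MI of amplitudes binned by phase.

    Returns NaN (an undefined, reported cell) when any phase bin is
    empty. Invariant to global amplitude scaling.
    """
    phases = np.asarray(phases).ravel()
    amplitudes = np.asarray(amplitudes).ravel()
    if phases.shape != amplitudes.shape:
        raise ValueError("phases and amplitudes must have equal length")
    bins = np.floor((np.mod(phases + np.pi, 2 * np.pi)) / (2 * np.pi / n_bins)).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    if np.any(counts == 0):
        return np.nan
    mean_amp = np.bincount(bins, weights=amplitudes, minlength=n_bins) / counts
    total = mean_amp.sum()
    if total <= 0:
        return 0.0
    p = mean_amp / total
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(p > 0, p * np.log(p), 0.0))
    return float((np.log(n_bins) - h) / np.log(n_bins))


def _bandpass(x, fs, lo, hi, order=3):
    lo = max(lo, 0.1)
    sos = sps.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _phase_amp_series(ts: TrialSet, channels, phase_band, amp_band,
                      phase_bw: float = 1.0, amp_bw: float = 3.0):
    """Slow-band phases and fast-band amplitude envelopes of the
    ROI-averaged virtual signal, on 1 Hz grids within each band."""
    chan = ts.channel_indices(channels)
    virtual = ts.data[:, chan, :].mean(axis=1)
    phase_freqs = np.arange(np.ceil(phase_band[0]), np.floor(phase_band[1]) + 1e-9)
    amp_freqs = np.arange(np.ceil(amp_band[0]), np.floor(amp_band[1]) + 1e-9)
    phases = np.empty((len(phase_freqs),) + virtual.shape)
    amps = np.empty((len(amp_freqs),) + virtual.shape)
    for i, f in enumerate(phase_freqs):
        phases[i] = np.angle(sps.hilbert(
            _bandpass(virtual, ts.fs, f - phase_bw, f + phase_bw), axis=-1))
    for i, f in enumerate(amp_freqs):
        amps[i] = np.abs(sps.hilbert(
            _bandpass(virtual, ts.fs, f - amp_bw, f + amp_bw), axis=-1))
    return phase_freqs, amp_freqs, phases, amps


def _window_centers(times, fs, window_s, step_s):
    half = window_s / 2
    centers, slices = [], []
    t = times[0] + half
    n = len(times)
    w = int(round(window_s * fs))
    while t <= times[-1] - half + 1e-9:
        i0 = int(round((t - half - times[0]) * fs))
        i0 = max(0, min(i0, n - w))
        centers.append(t)
        slices.append(slice(i0, i0 + w))
        t += step_s
    return np.asarray(centers), slices


def pac_across_trials(
    ts: TrialSet,
    phase_band=(1.0, 3.0),
    amp_band=(30.0, 35.0),
    channels=None,
    window_s: float = 1.0,
    step_s: float = 0.1,
    n_bins: int = 18,
) -> PACMap:
    """Time-resolved across-trial PAC comodulogram on an ROI.

    Phase via zero-phase band-pass plus analytic signal of the slow
    band, amplitude envelope of the fast band; at each sliding window
    the (trial x in-window sample) pairs are pooled and the modulation
    index computed. Cells with an empty phase bin are NaN.
    """
    if ts.n_trials < 20:
        raise ValueError("across-trial PAC needs >= 20 trials for stable bins")
    if phase_band[1] >= amp_band[0]:
        raise ValueError("amplitude band must lie above the phase band")
    pf, af, phases, amps = _phase_amp_series(ts, channels, phase_band, amp_band)
    centers, slices = _window_centers(ts.times, ts.fs, window_s, step_s)
    mi = np.empty((len(pf), len(af), len(centers)))
    for wi, sl in enumerate(slices):
        for i in range(len(pf)):
            ph = phases[i, :, sl]
            for j in range(len(af)):
                mi[i, j, wi] = modulation_index(ph, amps[j, :, sl], n_bins)
    return PACMap(mi, pf, af, centers, tuple(phase_band), tuple(amp_band),
                  n_bins, ts.n_trials)


def pac_trial_shuffle_null(
    ts: TrialSet,
    phase_band=(1.0, 3.0),
    amp_band=(30.0, 35.0),
    channels=None,
    window_s: float = 1.0,
    step_s: float = 0.1,
    n_bins: int = 18,
    n_surrogates: int = 200,
    seed: int = 0,
):
    """Trial-shuffle surrogate distribution of the maximum MI.

    Amplitude trials are permuted relative to phase trials, preserving
    both marginals while destroying their coupling. Returns the
    surrogate array (n_surrogates,) of map-max MI values.
    """
    rng = np.random.default_rng(seed)
    pf, af, phases, amps = _phase_amp_series(ts, channels, phase_band, amp_band)
    centers, slices = _window_centers(ts.times, ts.fs, window_s, step_s)
    null = np.empty(n_surrogates)
    for s in range(n_surrogates):
        perm = rng.permutation(ts.n_trials)
        best = 0.0
        for wi, sl in enumerate(slices):
            for i in range(len(pf)):
                ph = phases[i, :, sl]
                for j in range(len(af)):
                    v = modulation_index(ph, amps[j, perm, sl], n_bins)
                    if np.isfinite(v) and v > best:
                        best = v
        null[s] = best
    return null
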