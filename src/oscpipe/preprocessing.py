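"""Epoching and basic filtering.

All filters are zero-phase (forward-backward IIR): downstream decoding
uses instantaneous spatial patterns, and phase distortion would smear
them across time.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .containers import SensorLayout, TrialSet

__all__ = ["epoch", "notch_and_downsample", "lowpass", "drop_variance_outliers"]


def epoch(
    continuous: np.ndarray,
    fs: float,
    event_samples,
    window_s,
    layout: SensorLayout | None = None,
    meta: pd.DataFrame | None = None,
) -> TrialSet:
    """Cut a continuous (channels x time) record into event-locked trials.

    The window is half-open, ``[start, end)`` in seconds relative to each
    event; the sample at offset 0 is the event sample. Events whose
    window does not fit inside the record are rejected with a warning and
    their metadata rows dropped.
    """
    continuous = np.atleast_2d(np.asarray(continuous))
    n_ch, n_samp = continuous.shape
    start_off = int(round(window_s[0] * fs))
    n_win = int(round((window_s[1] - window_s[0]) * fs))
    if n_win <= 0:
        raise ValueError("epoch window must have positive length")
    event_samples = [int(e) for e in event_samples]
    kept, trials = [], []
    for i, ev in enumerate(event_samples):
        lo = ev + start_off
        if lo < 0 or lo + n_win > n_samp:
            continue
        kept.append(i)
        trials.append(continuous[:, lo:lo + n_win])
    rejected = sorted(set(range(len(event_samples))) - set(kept))
    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} event(s) too close to the record edge: "
            f"indices {rejected}", stacklevel=2,
        )
    data = np.stack(trials) if trials else np.empty((0, n_ch, n_win))
    times = (np.arange(n_win) + start_off) / fs
    if layout is None:
        layout = SensorLayout.grid(n_ch, 1) if n_ch > 1 else SensorLayout(
            ("ch0000",), np.zeros((1, 2)), np.zeros((1, 1), bool))
    if meta is not None:
        meta = meta.iloc[kept]
    return TrialSet(data, fs, times, layout, meta)


def _filtfilt(ts: TrialSet, sos) -> TrialSet:
    return ts.copy_with(data=signal.sosfiltfilt(sos, ts.data, axis=-1))


def notch_and_downsample(
    ts: TrialSet,
    line_hz: float = 50.0,
    harmonics: int = 3,
    target_fs: float = 300.0,
    quality: float = 30.0,
) -> TrialSet:
    """Remove line noise (fundamental + harmonics) and resample.

    Notch filters are second-order IIR sections applied forward-backward;
    resampling is band-limited polyphase (:func:`scipy.signal.resample_poly`).
    """
    if target_fs > ts.fs:
        raise ValueError(f"target_fs {target_fs} exceeds sampling rate {ts.fs}")
    if line_hz * harmonics >= ts.fs / 2:
        raise ValueError("highest notch harmonic is at or above Nyquist")
    data = ts.data
    for k in range(1, harmonics + 1):
        b, a = signal.iirnotch(k * line_hz, quality, fs=ts.fs)
        data = signal.filtfilt(b, a, data, axis=-1)
    if target_fs == ts.fs:
        return ts.copy_with(data=data)
    frac = Fraction(target_fs / ts.fs).limit_denominator(1000)
    data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    times = ts.times[0] + np.arange(data.shape[-1]) / target_fs
    return ts.copy_with(data=data, fs=target_fs, times=times)


def lowpass(ts: TrialSet, cutoff_hz: float, order: int = 4) -> TrialSet:
    """Zero-phase Butterworth low-pass filter."""
    if cutoff_hz >= ts.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above Nyquist ({ts.fs / 2} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=ts.fs, output="sos")
    return _filtfilt(ts, sos)


def drop_variance_outliers(ts: TrialSet, z_threshold: float = 4.0) -> TrialSet:
    """Optional trial filter: drop trials of extreme broadband variance.

    The per-trial variance (pooled over channels and samples) is
    z-scored across trials; trials beyond ``z_threshold`` are removed.
    The threshold is a configuration choice, not a calibrated constant.
    """
    v = ts.data.reshape(ts.n_trials, -1).var(axis=1)
    z = (v - v.mean()) / (v.std() + 1e-30)
    return ts.select_trials(np.abs(z) <= z_threshold)
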