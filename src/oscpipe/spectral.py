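"""Power spectra, individualized peak detection, adaptive
time-frequency decomposition, band time courses, and normalization.

The time-frequency transform follows the adaptive sliding-window
convention: at each frequency f the window is five cycles long
(dt = 5/f), Hanning-tapered, stepped at 20 ms. Cells whose window does
not fit inside the epoch are undefined (NaN), never silently zero, and
stay excluded through any averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .containers import TrialSet


def nanmean_quiet(a, axis=None, keepdims=False):
    """nanmean that stays silent on all-NaN slices (they stay NaN)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(a, axis=axis, keepdims=keepdims)

__all__ = [
    "Spectrum",
    "PeakEstimate",
    "TFR",
    "BandTimecourse",
    "power_spectrum",
    "detect_alpha_peak",
    "detect_beta_peak",
    "estimate_peaks",
    "tfr",
    "band_timecourse",
    "normalize_power",
]


@dataclass
class Spectrum:
    """Trial-averaged power spectrum on a 1 Hz grid (channels x freqs)."""

    freqs: np.ndarray
    power: np.ndarray
    window_s: tuple
    taper: str = "hann"

    def channel_mean(self) -> np.ndarray:
        return self.power.mean(axis=0)


@dataclass
class PeakEstimate:
    """Individual alpha/beta peak frequencies; None where no local
    maximum exists in the search band."""

    alpha_hz: float | None
    beta_hz: float | None
    detrend_slope: float = np.nan
    detrend_intercept: float = np.nan


@dataclass
class TFR:
    """Time-frequency power; undefined cells are NaN.

    ``power`` is ``(n_trials, n_channels, n_freqs, n_times)`` when
    ``keep_trials`` was requested, else ``(n_channels, n_freqs, n_times)``.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_cycles: float = 5.0
    normalization: str = "none"

    @property
    def has_trials(self) -> bool:
        return self.power.ndim == 4


@dataclass
class BandTimecourse:
    """Mean power over a frequency band (…channels x times)."""

    band_center: float
    bandwidth: float
    power: np.ndarray
    times: np.ndarray
    normalization: str = "none"


# -- spectra and peaks ----------------------------------------------------

def power_spectrum(
    ts: TrialSet,
    channels=None,
    window_s=(-1.0, 0.0),
    fmin: float = 1.0,
    fmax: float = 30.0,
    df: float = 1.0,
) -> Spectrum:
    """Trial-averaged Hanning-tapered FFT power on a regular Hz grid."""
    if (window_s[1] - window_s[0]) < 1.0 / fmin - 1e-9:
        raise ValueError("window too short for the requested frequency resolution")
    sl = ts.time_slice(window_s)
    chan = ts.channel_indices(channels)
    x = ts.data[:, chan, sl]
    n = x.shape[-1]
    taper = np.hanning(n)
    spec = np.fft.rfft(x * taper, axis=-1)
    fft_freqs = np.fft.rfftfreq(n, 1.0 / ts.fs)
    # amplitude-calibrated power: a unit-amplitude tone -> 0.5
    power = np.abs(2.0 * spec / taper.sum()) ** 2 / 2.0
    grid = np.arange(fmin, fmax + df / 2, df)
    idx = np.array([np.argmin(np.abs(fft_freqs - f)) for f in grid])
    return Spectrum(freqs=grid, power=power[:, :, idx].mean(axis=0), window_s=tuple(window_s))


def _strict_local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima (band edges ineligible)."""
    if len(y) < 3:
        return np.array([], dtype=int)
    interior = np.arange(1, len(y) - 1)
    return interior[(y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])]


def _highest_peak(freqs, y) -> float | None:
    idx = _strict_local_maxima(y)
    if len(idx) == 0:
        return None
    best = idx[np.argmax(y[idx])]     # argmax returns first -> lower-frequency tie-break
    return float(freqs[best])


def detect_alpha_peak(spec: Spectrum, band=(7.0, 14.0)) -> float | None:
    """Frequency of the highest strict local maximum in the alpha band.

    Returns None (an explicit no-peak result) when the in-band spectrum
    is monotone.
    """
    mask = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if mask.sum() < 3:
        raise ValueError(f"spectrum does not cover the {band} Hz band")
    return _highest_peak(spec.freqs[mask], spec.channel_mean()[mask])


def detect_beta_peak(spec: Spectrum, band=(15.0, 30.0)):
    """Beta peak after removing the 1/f trend by a log-linear fit.

    A least-squares line is fit to log(power) against frequency over the
    beta range and subtracted; the peak is the highest strict local
    maximum of the residual. Returns ``(peak_hz_or_None, (slope, intercept))``.
    """
    mask = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if mask.sum() < 3:
        raise ValueError(f"spectrum does not cover the {band} Hz band")
    f = spec.freqs[mask]
    p = spec.channel_mean()[mask]
    if np.any(p <= 0):
        raise ValueError("non-positive power in the beta band; cannot log-transform")
    logp = np.log(p)
    slope, intercept = np.polyfit(f, logp, 1)
    residual = logp - (slope * f + intercept)
    return _highest_peak(f, residual), (float(slope), float(intercept))


def estimate_peaks(spec: Spectrum) -> PeakEstimate:
    """Convenience wrapper combining alpha and beta peak detection."""
    beta, (slope, intercept) = detect_beta_peak(spec)
    return PeakEstimate(
        alpha_hz=detect_alpha_peak(spec),
        beta_hz=beta,
        detrend_slope=slope,
        detrend_intercept=intercept,
    )


# -- time-frequency -------------------------------------------------------

def sliding_fourier(
    data: np.ndarray,
    fs: float,
    freqs,
    step_s: float = 0.02,
    n_cycles: float = 5.0,
):
    """Complex sliding-window Fourier coefficients.

    ``data`` is (..., n_times). Returns ``(coefs, out_idx)`` where
    ``coefs`` has shape (..., n_freqs, n_out) with NaN where the
    centered ``n_cycles``-long Hanning window does not fit, and
    ``out_idx`` are the source sample indices of the output grid.
    Coefficients are amplitude-calibrated: a unit tone at f gives |c|=1.
    """
    data = np.asarray(data, dtype=np.float64)
    n_times = data.shape[-1]
    step = max(1, int(round(step_s * fs)))
    out_idx = np.arange(0, n_times, step)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    out = np.full(data.shape[:-1] + (len(freqs), len(out_idx)), np.nan, dtype=np.complex128)
    flat = data.reshape(-1, n_times)
    for fi, f in enumerate(freqs):
        n_win = int(round(n_cycles / f * fs))
        n_win = min(n_win, n_times)
        if n_win % 2 == 0:
            n_win += 1
        if n_win > n_times:
            continue
        half = n_win // 2
        taper = np.hanning(n_win)
        t_rel = (np.arange(n_win) - half) / fs
        kernel = taper * np.exp(-2j * np.pi * f * t_rel)
        scale = 2.0 / taper.sum()
        # convolution with the conjugated, reversed kernel = windowed DFT
        conv = sps.fftconvolve(flat, kernel[None, ::-1].conj(), mode="same", axes=-1)
        valid = (out_idx >= half) & (out_idx <= n_times - 1 - half)
        vals = conv[:, out_idx[valid]] * scale
        block = np.full((flat.shape[0], len(out_idx)), np.nan, dtype=np.complex128)
        block[:, valid] = vals
        out[..., fi, :] = block.reshape(data.shape[:-1] + (len(out_idx),))
    return out, out_idx


def tfr(
    ts: TrialSet,
    freqs=None,
    step_s: float = 0.02,
    n_cycles: float = 5.0,
    channels=None,
    keep_trials: bool = False,
) -> TFR:
    """Adaptive 5-cycle Hanning time-frequency power.

    Power is trial-averaged unless ``keep_trials``; undefined cells
    (incomplete windows) are NaN.
    """
    if freqs is None:
        freqs = np.arange(1.0, 31.0)
    chan = ts.channel_indices(channels)
    coefs, out_idx = sliding_fourier(ts.data[:, chan, :], ts.fs, freqs, step_s, n_cycles)
    power = (np.abs(coefs) ** 2 / 2.0).astype(np.float32)
    if not keep_trials:
        power = power.mean(axis=0)
    return TFR(power=power, freqs=np.atleast_1d(np.asarray(freqs, float)),
               times=ts.times[out_idx], n_cycles=n_cycles)


def band_timecourse(t: TFR, center: float, bandwidth: float) -> BandTimecourse:
    """Mean power over the frequency rows inside ``center +- bandwidth/2``.

    Undefined (NaN) cells are excluded from the mean; a time point where
    every in-band row is undefined stays undefined.
    """
    lo, hi = center - bandwidth / 2, center + bandwidth / 2
    mask = (t.freqs >= lo - 1e-9) & (t.freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] Hz outside the TFR frequency grid")
    sub = t.power[..., mask, :]
    mean = nanmean_quiet(sub, axis=-2)
    return BandTimecourse(center, bandwidth, mean, t.times, t.normalization)


# -- normalization --------------------------------------------------------

def _baseline_ratio(power, times, window_s):
    t0, t1 = window_s
    mask = (times >= t0 - 1e-9) & (times < t1 - 1e-9)
    if not mask.any():
        raise ValueError(f"baseline window {window_s} contains no TFR samples")
    ref = nanmean_quiet(power[..., mask], axis=-1, keepdims=True)
    if np.any(~np.isfinite(ref)) or np.any(ref <= 0):
        raise ValueError("baseline reference undefined or non-positive")
    return power / ref


def normalize_power(x, mode: str, reference=None):
    """Normalize TFR/band power.

    mode="baseline_ratio": divide by the mean power in the baseline
    window ``reference`` (a (t0, t1) pair), per channel (and frequency).

    mode="bin_mean_ratio": ``x`` is a sequence of same-shaped
    TFR/BandTimecourse objects (one per bin); each is divided by the
    across-bin mean at every cell, so the across-bin mean of the output
    is exactly 1 wherever defined.
    """
    if mode == "baseline_ratio":
        if reference is None:
            raise ValueError("baseline_ratio requires a (t0, t1) reference window")
        out = replace(x, power=_baseline_ratio(x.power, x.times, reference))
        out.normalization = "baseline_ratio"
        return out
    if mode == "bin_mean_ratio":
        bins = list(x)
        if len(bins) < 2:
            raise ValueError("bin_mean_ratio requires >= 2 bins")
        stack = np.stack([b.power for b in bins])
        ref = stack.mean(axis=0)
        bad = np.isfinite(ref) & (ref <= 0)
        if bad.any():
            raise ValueError("across-bin mean power is non-positive at some cells")
        out = []
        for b in bins:
            o = replace(b, power=b.power / ref)
            o.normalization = "bin_mean_ratio"
            out.append(o)
        return out
    raise ValueError(f"unknown normalization mode: {mode!r}")
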