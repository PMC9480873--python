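"""Quantile binning of trials by RT or prestimulus band power, and
extreme-bin contrasts.

Binning is always within participant (downstream group statistics take
one map per bin per participant). Default five quantile bins; bin sizes
differ by at most one, larger bins first, and ties are resolved by
stable order of occurrence so the assignment is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialSet

__all__ = [
    "BinAssignment",
    "quantile_bins",
    "prestim_power_per_trial",
    "extreme_bin_contrast",
    "CANONICAL_BANDS",
]

#: canonical fixed bands (Hz) for prestimulus power binning
CANONICAL_BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (15.0, 25.0)}


@dataclass
class BinAssignment:
    """Per-trial quantile bin indices.

    ``bin_index`` is 1..n_bins in ascending value order; 0 marks trials
    excluded for a missing value.
    """

    variable: str
    n_bins: int
    bin_index: np.ndarray

    def mask(self, b: int) -> np.ndarray:
        return self.bin_index == b


def quantile_bins(values, n_bins: int = 5, variable: str = "value") -> BinAssignment:
    """Ascending-value quantile partition with sizes as equal as possible.

    Trials with non-finite values get bin 0 (excluded). With ``m``
    finite values the bin sizes are the ``np.array_split`` partition of
    ``m`` (e.g. 393 trials in 5 bins -> 79/79/79/78/78).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    m = int(finite.sum())
    if m < n_bins:
        raise ValueError(f"need at least {n_bins} finite values, got {m}")
    order = np.flatnonzero(finite)[np.argsort(values[finite], kind="stable")]
    bin_index = np.zeros(len(values), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
        bin_index[chunk] = b
    return BinAssignment(variable, n_bins, bin_index)


def prestim_power_per_trial(
    ts: TrialSet,
    band,
    window_s=(-1.0, 0.0),
    channels=None,
) -> np.ndarray:
    """Single-trial Hanning-tapered band power in a prestimulus window.

    ``band`` is a (low, high) Hz pair, a canonical band name
    ("theta"/"alpha"/"beta"), or a (center, bandwidth) pair passed as
    ``{"center": c, "bandwidth": bw}``. Power is averaged over the
    selected channels and in-band FFT bins. Bands must lie within the
    1-30 Hz analysis grid.
    """
    if isinstance(band, str):
        band = CANONICAL_BANDS[band]
    elif isinstance(band, dict):
        band = (band["center"] - band["bandwidth"] / 2,
                band["center"] + band["bandwidth"] / 2)
    lo, hi = band
    if not (1.0 <= lo < hi <= 30.0):
        raise ValueError(f"band ({lo}, {hi}) outside the 1-30 Hz analysis grid")
    sl = ts.time_slice(window_s)
    chan = ts.channel_indices(channels)
    x = ts.data[:, chan, sl]
    n = x.shape[-1]
    taper = np.hanning(n)
    spec = np.fft.rfft(x * taper, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / ts.fs)
    power = np.abs(2.0 * spec / taper.sum()) ** 2 / 2.0
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError("window too short to resolve the requested band")
    return power[:, :, mask].mean(axis=(1, 2))


def extreme_bin_contrast(bin_maps):
    """Lowest- and highest-bin maps per subject, ready for paired testing.

    ``bin_maps`` is a sequence over bins (ascending) of dicts mapping
    subject id -> map array. Subjects missing either extreme bin are
    excluded and reported. Returns ``(low_maps, high_maps, subjects,
    excluded)`` with maps stacked over the common subjects.
    """
    if len(bin_maps) < 2:
        raise ValueError("need at least 2 bins to contrast")
    low, high = bin_maps[0], bin_maps[-1]
    all_subjects = sorted(set(low) | set(high))
    subjects = [s for s in all_subjects if s in low and s in high]
    excluded = [s for s in all_subjects if s not in subjects]
    if not subjects:
        raise ValueError("no subject has both extreme bins")
    a = np.stack([np.asarray(low[s], dtype=float) for s in subjects])
    b = np.stack([np.asarray(high[s], dtype=float) for s in subjects])
    return a, b, subjects, excluded
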