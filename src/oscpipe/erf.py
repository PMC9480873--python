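"""Event-related fields: baseline correction, averaging, planar
transform, max-ERF channel selection, and evoked subtraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SensorLayout, TrialSet

__all__ = [
    "ERF",
    "baseline_correct",
    "average_erf",
    "planar_gradient",
    "select_max_erf_channels",
    "subtract_evoked",
]


@dataclass
class ERF:
    """Trial-averaged event-related field (channels x time)."""

    amplitude: np.ndarray
    times: np.ndarray
    n_trials: int
    baseline_window: tuple | None = None
    channel_ids: tuple = ()


def baseline_correct(ts: TrialSet, window_s=(-0.1, 0.0)) -> TrialSet:
    """Subtract the per-trial, per-channel mean over ``window_s``."""
    sl = ts.time_slice(window_s)
    base = ts.data[:, :, sl].mean(axis=-1, keepdims=True)
    return ts.copy_with(data=ts.data - base)


def average_erf(ts: TrialSet, selector=None) -> ERF:
    """Arithmetic mean over (selected) trials.

    ``selector`` may be None (all trials), a boolean mask, or a callable
    applied to the metadata table returning a mask.
    """
    if selector is None:
        mask = np.ones(ts.n_trials, dtype=bool)
    elif callable(selector):
        mask = np.asarray(selector(ts.meta), dtype=bool)
    else:
        mask = np.asarray(selector, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("selector matches no trials")
    return ERF(
        amplitude=ts.data[mask].mean(axis=0),
        times=ts.times,
        n_trials=n,
        channel_ids=ts.layout.channel_ids,
    )


def _planar_operators(layout: SensorLayout):
    """Per-channel least-squares gradient operators.

    For channel c with neighbour set N(c), fit the local linear field
    model ``b(x, y) ~ b0 + gx*dx + gy*dy`` over {c} u N(c) by least
    squares; the rows of the returned operator map the neighbourhood's
    values to (gx, gy).
    """
    ops = []
    neigh = layout.neighbor_lists()
    for c in range(layout.n_channels):
        idx = np.concatenate(([c], neigh[c]))
        if len(idx) < 3:
            raise ValueError(
                f"channel {layout.channel_ids[c]} has too few neighbours "
                "for a planar gradient fit")
        d = layout.positions[idx] - layout.positions[c]
        A = np.column_stack([np.ones(len(idx)), d])
        if np.linalg.matrix_rank(A) < 3:
            raise ValueError(
                f"neighbours of channel {layout.channel_ids[c]} are collinear")
        pinv = np.linalg.pinv(A)
        ops.append((idx, pinv[1:, :]))   # rows for gx, gy
    return ops


def planar_gradient(erf: ERF, layout: SensorLayout) -> ERF:
    """Planar (gradient-magnitude) representation of an axial field map.

    Nearest-neighbour method: per channel, the two orthogonal spatial
    derivatives are estimated from a least-squares local plane fit over
    the channel and its layout neighbours; the output is their
    Euclidean magnitude, which peaks above a source and is >= 0.
    """
    out = np.empty_like(erf.amplitude)
    for idx, op in zip(range(layout.n_channels), _planar_operators(layout)):
        sel, mat = op
        g = mat @ erf.amplitude[sel]       # (2, n_times)
        out[idx] = np.sqrt((g ** 2).sum(axis=0))
    return ERF(out, erf.times, erf.n_trials, erf.baseline_window, erf.channel_ids)


def select_max_erf_channels(erf: ERF, window_s, k: int) -> list[str]:
    """The ``k`` channels with the largest RMS amplitude in ``window_s``.

    Deterministic: ties are broken by channel label order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > erf.amplitude.shape[0]:
        raise ValueError("k exceeds the number of channels")
    t0, t1 = window_s
    mask = (erf.times >= t0 - 1e-9) & (erf.times < t1 - 1e-9)
    if not mask.any():
        raise ValueError(f"window {window_s} contains no samples")
    rms = np.sqrt((erf.amplitude[:, mask] ** 2).mean(axis=1))
    ids = list(erf.channel_ids) or [str(i) for i in range(len(rms))]
    order = sorted(range(len(rms)), key=lambda i: (-rms[i], ids[i]))
    return [ids[i] for i in order[:k]]


def subtract_evoked(ts: TrialSet, grouping=None) -> TrialSet:
    """Subtract each trial's group-mean ERF from the trial.

    ``grouping`` is a list of metadata column names defining the groups
    (None = one global group). After subtraction the group mean is
    exactly zero at every sample.
    """
    data = ts.data.astype(np.float64, copy=True)
    if grouping:
        groups = ts.meta.groupby(list(grouping), sort=False).indices.values()
    else:
        groups = [np.arange(ts.n_trials)]
    for idx in groups:
        idx = np.asarray(idx)
        if len(idx) < 2:
            raise ValueError(
                "evoked subtraction needs >= 2 trials per group "
                "(singleton group would be zeroed)")
        data[idx] -= data[idx].mean(axis=0, keepdims=True)
    return ts.copy_with(data=data)
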