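"""Core data containers for epoched multichannel trial data.

The universal exchange object is the :class:`TrialSet`: a
``(n_trials, n_channels, n_times)`` array on a uniform time grid with
per-trial metadata and a :class:`SensorLayout` describing sensor positions
and their neighbourhood graph (the adjacency used by the cluster-based
permutation statistics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
import h5py
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

__all__ = [
    "SensorLayout",
    "EventTiming",
    "TrialSet",
    "save_trialset",
    "load_trialset",
]

#: canonical per-trial metadata columns
META_COLUMNS = (
    "participant_id",
    "cue_condition",   # {"pre", "retro"}
    "feature",         # {"orientation", "frequency"}
    "stim_orientation",  # {"cw", "ccw"}
    "stim_frequency",    # {"low", "high"}
    "rt_s",            # float, NaN where no response
    "correct",         # bool
)


@dataclass(frozen=True)
class SensorLayout:
    """Sensor labels, 2-D positions, and a symmetric neighbour graph.

    Parameters
    ----------
    channel_ids
        Unique channel labels, one per sensor.
    positions
        ``(n_channels, 2)`` planar coordinates (arbitrary units).
    adjacency
        ``(n_channels, n_channels)`` boolean matrix; symmetric with a
        zero diagonal.
    """

    channel_ids: tuple[str, ...]
    positions: np.ndarray
    adjacency: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        adj = np.asarray(self.adjacency, dtype=bool)
        n = len(self.channel_ids)
        if len(set(self.channel_ids)) != n:
            raise ValueError("channel_ids must be unique")
        if pos.shape != (n, 2):
            raise ValueError(f"positions must have shape ({n}, 2), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("sensor positions must be finite")
        if adj.shape != (n, n):
            raise ValueError("adjacency shape does not match channel count")
        if np.any(np.diag(adj)):
            raise ValueError("adjacency must be irreflexive (zero diagonal)")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if n >= 2 and not np.all(adj.any(axis=1)):
            orphans = [self.channel_ids[i] for i in np.flatnonzero(~adj.any(axis=1))]
            raise ValueError(f"channels without neighbours: {orphans}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def neighbor_lists(self) -> list[np.ndarray]:
        """Neighbour indices per channel (index order of ``channel_ids``)."""
        return [np.flatnonzero(row) for row in self.adjacency]

    def index(self, channel_id: str) -> int:
        return self.channel_ids.index(channel_id)

    @classmethod
    def from_positions(
        cls,
        channel_ids,
        positions,
        max_edge_factor: float = 1.5,
    ) -> "SensorLayout":
        """Build the neighbour graph by Delaunay triangulation.

        Edges longer than ``max_edge_factor`` times the median Delaunay
        edge length are removed (they span holes at the layout rim). A
        channel left isolated by the cap is reconnected to its nearest
        neighbour so every sensor participates in clustering.
        """
        pos = np.asarray(positions, dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ValueError("sensor positions must be finite")
        n = pos.shape[0]
        adj = np.zeros((n, n), dtype=bool)
        centered = pos - pos.mean(axis=0, keepdims=True)
        collinear = n > 2 and np.linalg.matrix_rank(centered, tol=1e-9) < 2
        if n == 2 or collinear:
            # degenerate (line) layout: chain adjacency along the line
            order = np.argsort(centered @ (centered[np.argmax(
                np.linalg.norm(centered, axis=1))] + 1e-30))
            for i, j in zip(order[:-1], order[1:]):
                adj[i, j] = adj[j, i] = True
        elif n > 2:
            tri = Delaunay(pos, qhull_options="QJ")
            edges = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = sorted((simplex[a], simplex[b]))
                        edges.add((i, j))
            edges = np.array(sorted(edges))
            lengths = np.linalg.norm(pos[edges[:, 0]] - pos[edges[:, 1]], axis=1)
            cap = max_edge_factor * np.median(lengths)
            for (i, j), ln in zip(edges, lengths):
                if ln <= cap:
                    adj[i, j] = adj[j, i] = True
            for i in np.flatnonzero(~adj.any(axis=1)):
                d = np.linalg.norm(pos - pos[i], axis=1)
                d[i] = np.inf
                j = int(np.argmin(d))
                adj[i, j] = adj[j, i] = True
        return cls(tuple(channel_ids), pos, adj)

    @classmethod
    def grid(cls, nx: int, ny: int, spacing: float = 1.0) -> "SensorLayout":
        """Regular ``nx x ny`` grid layout with Delaunay neighbours.

        Channels are labelled ``ch{row:02d}{col:02d}``; row index grows
        with y (row 0 is the most "posterior" row by convention of the
        synthetic generator).
        """
        ids, pos = [], []
        for iy in range(ny):
            for ix in range(nx):
                ids.append(f"ch{iy:02d}{ix:02d}")
                pos.append((ix * spacing, iy * spacing))
        return cls.from_positions(ids, np.array(pos, dtype=float))


@dataclass(frozen=True)
class EventTiming:
    """Task event latencies (s) relative to epoch time zero (first cue)."""

    cue1_s: float = 0.0
    sample_s: float = 1.5
    cue2_s: float = 3.0
    probe_s: float = 4.5

    def __post_init__(self):
        ev = self.event_times()
        if not np.all(np.diff(ev) > 0):
            raise ValueError("event times must be strictly increasing")
        gaps = np.diff(ev)
        if not np.allclose(gaps, gaps[0]):
            raise ValueError("events must be separated by a fixed SOA")

    @property
    def soa_s(self) -> float:
        return self.sample_s - self.cue1_s

    def event_times(self) -> np.ndarray:
        return np.array([self.cue1_s, self.sample_s, self.cue2_s, self.probe_s])


class TrialSet:
    """Epoched trials x channels x time with per-trial metadata.

    Parameters
    ----------
    data
        ``(n_trials, n_channels, n_times)`` real array, arbitrary field
        units.
    fs
        Sampling frequency in Hz.
    times
        ``(n_times,)`` seconds, uniformly spaced at ``1/fs``; time 0 is
        the epoching event (first-cue onset in the task).
    layout
        Sensor layout; must match the channel dimension.
    meta
        Per-trial metadata table with ``n_trials`` rows.
    """

    def __init__(self, data, fs, times, layout: SensorLayout, meta: pd.DataFrame | None = None):
        data = np.asarray(data)
        times = np.asarray(times, dtype=float)
        if data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite samples")
        if times.shape != (data.shape[2],):
            raise ValueError("times length must match data's last axis")
        if len(times) > 1:
            dt = np.diff(times)
            if not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced at 1/fs")
        if layout.n_channels != data.shape[1]:
            raise ValueError("layout channel count does not match data")
        if meta is None:
            meta = pd.DataFrame(index=range(data.shape[0]))
        if len(meta) != data.shape[0]:
            raise ValueError("metadata length must equal n_trials")
        if "rt_s" in meta.columns:
            rt = meta["rt_s"].to_numpy(dtype=float)
            if np.any(rt[np.isfinite(rt)] <= 0):
                raise ValueError("rt_s must be positive where present")
        self.data = data
        self.fs = float(fs)
        self.times = times
        self.layout = layout
        self.meta = meta.reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def __repr__(self):
        return (
            f"<TrialSet {self.n_trials} trials x {self.n_channels} channels x "
            f"{self.n_times} samples @ {self.fs:g} Hz, "
            f"t = [{self.times[0]:.3f}, {self.times[-1]:.3f}] s>"
        )

    # -- indexing helpers -------------------------------------------------
    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (s)."""
        return int(np.argmin(np.abs(self.times - t)))

    def time_slice(self, window_s) -> slice:
        """Half-open sample slice [start, end) for a window in seconds."""
        t0, t1 = window_s
        if t1 <= t0:
            raise ValueError("window end must exceed start")
        i0 = int(np.searchsorted(self.times, t0 - 1e-9))
        i1 = int(np.searchsorted(self.times, t1 - 1e-9))
        if i0 == i1:
            raise ValueError(f"window {window_s} contains no samples")
        if t0 < self.times[0] - 0.5 / self.fs or t1 > self.times[-1] + 1.5 / self.fs:
            raise ValueError(f"window {window_s} lies outside the epoch")
        return slice(i0, i1)

    def channel_indices(self, channels) -> np.ndarray:
        """Resolve channel labels (or indices) to integer indices."""
        if channels is None:
            return np.arange(self.n_channels)
        out = []
        for c in channels:
            out.append(c if isinstance(c, (int, np.integer)) else self.layout.index(c))
        return np.asarray(out, dtype=int)

    def select_trials(self, mask) -> "TrialSet":
        """Sub-TrialSet of trials where ``mask`` is True (or index array)."""
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.shape != (self.n_trials,):
            raise ValueError("boolean mask length must equal n_trials")
        return TrialSet(
            self.data[mask], self.fs, self.times, self.layout,
            self.meta.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask],
        )

    def copy_with(self, data=None, fs=None, times=None, meta=None) -> "TrialSet":
        return TrialSet(
            self.data if data is None else data,
            self.fs if fs is None else fs,
            self.times if times is None else times,
            self.layout,
            self.meta if meta is None else meta,
        )


# -- container I/O --------------------------------------------------------

_FORMAT_VERSION = 1


def save_trialset(ts: TrialSet, path) -> None:
    """Write a TrialSet to a single HDF5 container.

    Arrays are stored losslessly; the metadata table and the sensor
    layout are stored as JSON sidecar blocks inside the file.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "oscpipe-trialset"
        f.attrs["version"] = _FORMAT_VERSION
        f.attrs["fs"] = ts.fs
        f.create_dataset("data", data=ts.data)
        f.create_dataset("times", data=ts.times)
        grp = f.create_group("meta")
        grp.attrs["columns"] = json.dumps(list(map(str, ts.meta.columns)))
        grp.attrs["n_rows"] = len(ts.meta)
        for col in ts.meta.columns:
            arr = ts.meta[col].to_numpy()
            if arr.dtype.kind in "fiub":
                grp.create_dataset(str(col), data=arr)   # bit-exact numerics
            else:
                grp.create_dataset(
                    str(col), data=json.dumps([None if v is None else v
                                               for v in arr.tolist()]))
        layout_json = json.dumps(
            {
                "channel_ids": list(ts.layout.channel_ids),
                "positions": ts.layout.positions.tolist(),
                "edges": [
                    [int(i), int(j)]
                    for i, j in zip(*np.nonzero(np.triu(ts.layout.adjacency)))
                ],
            }
        )
        f.create_dataset("layout_json", data=layout_json)


def load_trialset(path) -> TrialSet:
    """Read a TrialSet written by :func:`save_trialset`."""
    with h5py.File(path, "r") as f:
        for key in ("fs",):
            if key not in f.attrs:
                raise ValueError(f"malformed container {path}: missing field '{key}'")
        for key in ("data", "times", "meta", "layout_json"):
            if key not in f:
                raise ValueError(f"malformed container {path}: missing field '{key}'")
        data = f["data"][()]
        times = f["times"][()]
        fs = float(f.attrs["fs"])
        grp = f["meta"]
        columns = json.loads(grp.attrs["columns"])
        n_rows = int(grp.attrs["n_rows"])
        cols = {}
        for col in columns:
            ds = grp[col][()]
            cols[col] = (json.loads(ds.decode()) if isinstance(ds, bytes) else ds)
        layout_blob = json.loads(f["layout_json"][()].decode())
    meta = pd.DataFrame(cols, index=range(n_rows)) if columns else \
        pd.DataFrame(index=range(n_rows))
    n = len(layout_blob["channel_ids"])
    adj = np.zeros((n, n), dtype=bool)
    for i, j in layout_blob["edges"]:
        adj[i, j] = adj[j, i] = True
    layout = SensorLayout(
        tuple(layout_blob["channel_ids"]),
        np.asarray(layout_blob["positions"], dtype=float),
        adj,
    )
    return TrialSet(data, fs, times, layout, meta)
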