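"""Cluster-based permutation testing for paired condition contrasts.

The test first computes a paired-t map over subjects, thresholds it at
a two-tailed cell-level p, partitions the supra-threshold cells into
maximal connected components under spatio-(spectro-)temporal adjacency
(positive and negative cells separately), and scores each component by
its summed t value against the permutation distribution of the maximum
|cluster sum| obtained by randomizing the condition assignment within
each subject (sign flips of the paired differences). This controls the
family-wise error rate over the whole map.

Adjacency: when a sensor layout is supplied, the first map axis is
channels and two cells are neighbours if they share all other
coordinates and their sensors are layout neighbours, or if they share
the sensor and differ by one step on a remaining (frequency/time) axis.
Without a layout, every axis is treated as an ordered lattice axis
(rook adjacency) — appropriate for time-only or train x test maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import SensorLayout

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterResult",
    "paired_t_map",
    "find_clusters",
    "cluster_permutation_test",
]


@dataclass
class StatMap:
    """Paired-t statistic map with labelled dimensions."""

    t: np.ndarray
    n_subjects: int
    dims: tuple[str, ...] = ()


@dataclass
class Cluster:
    """One connected supra-threshold component."""

    cells: tuple          # tuple of index arrays, one per map axis
    sign: int             # +1 or -1
    sum_t: float
    p_value: float = np.nan

    @property
    def size(self) -> int:
        return len(self.cells[0])


@dataclass
class ClusterResult:
    clusters: list
    null_max: np.ndarray
    threshold_p: float
    alpha: float
    n_perm: int
    seed: int | None = None
    exhaustive: bool = False
    warnings: list = field(default_factory=list)

    def significant(self):
        return [c for c in self.clusters if c.p_value <= self.alpha]


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray, dims=()) -> StatMap:
    """Per-cell paired t over subjects of (a - b).

    Zero-variance cells are undefined (NaN), not clipped to infinity.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition maps must have matching shapes")
    if a.shape[0] < 2:
        raise ValueError("paired t needs >= 2 subjects")
    d = a - b
    return StatMap(_t_from_diffs(d), a.shape[0], tuple(dims))


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def _as_cft(shape):
    """Normalize a map shape to (C, F, T) with dummy axes where absent."""
    if len(shape) == 1:
        return (1, 1, shape[0])
    if len(shape) == 2:
        return (1, shape[0], shape[1])
    if len(shape) == 3:
        return shape
    raise ValueError(f"maps of dimension {len(shape)} are not supported")


def _reshape_cft(arr, layout):
    """Map array -> (C, F, T) view consistent with the adjacency rule."""
    if layout is not None:
        if arr.ndim == 2:
            return arr.reshape(arr.shape[0], 1, arr.shape[1])
        if arr.ndim == 3:
            return arr
        raise ValueError("with a layout the map must be (channels, [freqs,] times)")
    return arr.reshape(_as_cft(arr.shape))


def _chan_neighbors(layout: SensorLayout | None, n_chan: int):
    if layout is None:
        # lattice adjacency on the leading axis
        return [
            [c for c in (i - 1, i + 1) if 0 <= c < n_chan] for i in range(n_chan)
        ]
    if layout.n_channels != n_chan:
        raise ValueError("layout channel count does not match the map")
    return [list(map(int, nb)) for nb in layout.neighbor_lists()]


def _components(tf, maskf, shape, chan_nb):
    """Connected components of a sign-homogeneous flat mask.

    ``tf``/``maskf`` are flat over a (C, F, T) map; returns a list of
    (member_index_array, sum_t).
    """
    C, F, T = shape
    FT = F * T
    visited = np.zeros(maskf.size, dtype=bool)
    out = []
    for start in np.flatnonzero(maskf):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        members = []
        total = 0.0
        while stack:
            u = stack.pop()
            members.append(u)
            total += tf[u]
            t_i = u % T
            f_i = (u // T) % F
            c_i = u // FT
            if t_i > 0 and maskf[u - 1] and not visited[u - 1]:
                visited[u - 1] = True
                stack.append(u - 1)
            if t_i < T - 1 and maskf[u + 1] and not visited[u + 1]:
                visited[u + 1] = True
                stack.append(u + 1)
            if F > 1:
                if f_i > 0 and maskf[u - T] and not visited[u - T]:
                    visited[u - T] = True
                    stack.append(u - T)
                if f_i < F - 1 and maskf[u + T] and not visited[u + T]:
                    visited[u + T] = True
                    stack.append(u + T)
            base = u - c_i * FT
            for c2 in chan_nb[c_i]:
                v = base + c2 * FT
                if maskf[v] and not visited[v]:
                    visited[v] = True
                    stack.append(v)
        out.append((np.asarray(members), total))
    return out


def _threshold(t_crit, tmap):
    with np.errstate(invalid="ignore"):
        pos = tmap > t_crit
        neg = tmap < -t_crit
    return pos, neg


def find_clusters(stat_map: StatMap, threshold_p: float = 0.05,
                  layout: SensorLayout | None = None) -> list:
    """Sign-separated connected supra-threshold components.

    The cell threshold is the two-tailed t critical value at
    ``threshold_p`` with df = n_subjects - 1. Clusters are returned
    sorted by |sum of t| descending.
    """
    if not 0 < threshold_p < 1:
        raise ValueError("threshold_p must be in (0, 1)")
    tmap = np.asarray(stat_map.t, dtype=float)
    arr = _reshape_cft(tmap, layout)
    shape = arr.shape
    chan_nb = _chan_neighbors(layout, shape[0])
    t_crit = stats.t.ppf(1 - threshold_p / 2, df=stat_map.n_subjects - 1)
    tf = arr.ravel()
    pos, neg = _threshold(t_crit, tf)
    clusters = []
    for maskf, sign in ((pos, 1), (neg, -1)):
        for members, total in _components(tf, maskf, shape, chan_nb):
            cells = np.unravel_index(members, shape)
            # drop dummy axes so cells index the original map shape
            keep = tuple(cells[i] for i in range(3) if shape[i] > 1 or tmap.ndim == 3)
            if len(keep) != tmap.ndim:           # all-dummy corner cases
                keep = tuple(cells[-tmap.ndim:])
            clusters.append(Cluster(keep, sign, float(total)))
    clusters.sort(key=lambda c: -abs(c.sum_t))
    return clusters


def _max_cluster_sum(tf, shape, chan_nb, t_crit):
    pos, neg = _threshold(t_crit, tf)
    best = 0.0
    for maskf in (pos, neg):
        if maskf.any():
            for _, total in _components(tf, maskf, shape, chan_nb):
                if abs(total) > best:
                    best = abs(total)
    return best


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    layout: SensorLayout | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    threshold_p: float = 0.05,
    seed: int | None = 0,
) -> ClusterResult:
    """Paired cluster-based permutation test (max cluster-sum null).

    Permutation randomizes the condition assignment within each subject
    (sign flips of the paired difference maps). With <= 12 subjects and
    ``n_perm >= 2**n_subjects`` the full sign-flip set is enumerated and
    p-values are exact; otherwise ``n_perm`` random flips are drawn and
    Monte-Carlo p-values use the plus-one correction, so p is never 0.
    """
    warnings_ = []
    if n_perm < 100:
        warnings_.append(f"n_perm={n_perm} < 100: permutation p-values are coarse")
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition maps must have matching shapes")
    n = a.shape[0]
    d = (a - b).astype(np.float64)
    flat_d = d.reshape(n, -1)
    ssq = (flat_d ** 2).sum(axis=0)

    def t_rows(signs):
        # one-pass paired t for sign-flipped differences; shared by the
        # observed map (identity flip) and the null so the identity
        # permutation reproduces the observed statistics exactly
        m = signs @ flat_d / n
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.maximum((ssq[None, :] - n * m ** 2) / (n - 1), 0.0)
            t = m / np.sqrt(var / n)
        t[~np.isfinite(t)] = np.nan
        return t

    obs_t = t_rows(np.ones((1, n)))[0].reshape(d.shape[1:])
    obs = StatMap(obs_t, n)
    clusters = find_clusters(obs, threshold_p, layout)

    arr = _reshape_cft(obs_t, layout)
    shape = arr.shape
    chan_nb = _chan_neighbors(layout, shape[0])
    t_crit = stats.t.ppf(1 - threshold_p / 2, df=n - 1)

    exhaustive = n <= 12 and n_perm >= 2 ** n
    if exhaustive:
        signs = np.array(
            [[1 if (k >> i) & 1 == 0 else -1 for i in range(n)]
             for k in range(2 ** n)], dtype=float)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_all = t_rows(signs)

    null_max = np.empty(len(signs))
    for k in range(len(signs)):
        null_max[k] = _max_cluster_sum(t_all[k], shape, chan_nb, t_crit)

    for c in clusters:
        exceed = int(np.sum(null_max >= abs(c.sum_t) - 1e-12))
        if exhaustive:
            c.p_value = exceed / len(signs)
        else:
            c.p_value = (1 + exceed) / (1 + len(signs))
    return ClusterResult(clusters, null_max, threshold_p, alpha,
                         len(signs), seed, exhaustive, warnings_)
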