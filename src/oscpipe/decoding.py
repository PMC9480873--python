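"""Time-resolved multivariate decoding and temporal generalization.

A linear L2-regularized logistic-regression classifier is fit on the
channel vector at each time point under stratified k-fold (default 4)
cross-validation; performance is the area under the ROC curve (AUC)
computed from held-out probabilistic class scores, so chance is 0.5
regardless of class balance. Features are standardized per training
fold (statistics estimated on the training folds only). LOOCV variants
give unbiased single-trial scores that support binning analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .binning import BinAssignment
from .containers import TrialSet

__all__ = [
    "DecodingResult",
    "SingleTrialEstimates",
    "TemporalGeneralizationMatrix",
    "BinnedDecoding",
    "auc",
    "timewise_decode",
    "shuffle_null",
    "loocv_estimates",
    "power_binned_decoding_contrast",
    "temporal_generalization",
    "average_train_window",
]


@dataclass
class DecodingResult:
    auc: np.ndarray            # (n_times,)
    times: np.ndarray
    n_folds: int
    C: float
    seed: int
    null_auc: np.ndarray | None = None   # (n_shuffles, n_times)
    p: np.ndarray | None = None


@dataclass
class SingleTrialEstimates:
    """Held-out probabilistic class scores per trial and time point."""

    scores: np.ndarray         # (n_trials, n_times)
    labels: np.ndarray
    times: np.ndarray


@dataclass
class TemporalGeneralizationMatrix:
    auc: np.ndarray            # (n_train_times, n_test_times)
    train_times: np.ndarray
    test_times: np.ndarray
    train_window_average: np.ndarray | None = None
    held_out_scores: np.ndarray | None = None   # (n_trials, n_train, n_test)
    labels: np.ndarray | None = None


@dataclass
class BinnedDecoding:
    """Per-bin AUC time courses from binned LOOCV scores."""

    auc_per_bin: np.ndarray    # (n_bins, n_times), NaN where a bin lacks a class
    times: np.ndarray
    n_bins: int

    @property
    def lowest(self):
        return self.auc_per_bin[0]

    @property
    def highest(self):
        return self.auc_per_bin[-1]


# -- primitives -----------------------------------------------------------

def auc(scores, labels) -> float:
    """Probability a random positive outranks a random negative.

    Rank-based (normalized Mann-Whitney U); ties count one half.
    Invariant under strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"AUC needs exactly two classes, got {classes}")
    pos = labels == classes[1]
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _as_data(x) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, TrialSet):
        return x.data, x.times
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError("expected (n_trials, n_channels, n_times)")
    return x, np.arange(x.shape[-1], dtype=float)


def _make_clf(C: float):
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=C, solver="lbfgs", max_iter=1000),
    )


def _check_labels(labels, n_trials):
    labels = np.asarray(labels)
    if len(labels) != n_trials:
        raise ValueError("labels length must equal n_trials")
    if len(np.unique(labels)) < 2:
        raise ValueError("decoding needs two classes in the labels")
    return labels


# -- cross-validated decoding ---------------------------------------------

def timewise_decode(ts, labels, n_folds: int = 4, C: float = 1.0,
                    seed: int = 0) -> DecodingResult:
    """Stratified k-fold decoding at every time point.

    At each time the channel vectors are standardized per training fold,
    an L2 logistic regression is fit on k-1 folds, and the held-out
    fold's probabilistic scores are pooled; AUC compares pooled held-out
    scores against the true labels.
    """
    data, times = _as_data(ts)
    labels = _check_labels(labels, data.shape[0])
    y = (labels == np.unique(labels)[1]).astype(int)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(np.zeros(len(y)), y))
    n_times = data.shape[-1]
    out = np.empty(n_times)
    scores = np.empty(len(y))
    for it in range(n_times):
        X = data[:, :, it]
        for train, test in folds:
            clf = _make_clf(C)
            clf.fit(X[train], y[train])
            scores[test] = clf.predict_proba(X[test])[:, 1]
        out[it] = auc(scores, y)
    return DecodingResult(out, times, n_folds, C, seed)


def shuffle_null(ts, labels, n_shuffles: int = 100, n_folds: int = 4,
                 C: float = 1.0, seed: int = 0) -> DecodingResult:
    """Label-shuffle null distribution of the time-resolved AUC.

    The full cross-validation is repeated per shuffle; the per-time
    p-value is (1 + #{null >= observed}) / (1 + n_shuffles).
    """
    if n_shuffles < 50:
        raise ValueError("n_shuffles must be >= 50 for a usable null")
    data, times = _as_data(ts)
    labels = _check_labels(labels, data.shape[0])
    observed = timewise_decode(data, labels, n_folds, C, seed)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, len(times)))
    for s in range(n_shuffles):
        null[s] = timewise_decode(
            data, labels[rng.permutation(len(labels))], n_folds, C, seed).auc
    p = (1 + (null >= observed.auc[None, :]).sum(axis=0)) / (1 + n_shuffles)
    observed.null_auc = null
    observed.p = p
    return observed


def loocv_estimates(ts, labels, C: float = 1.0) -> SingleTrialEstimates:
    """Leave-one-out held-out probabilistic scores at every time point.

    Each trial's score comes from a model fit to all other trials, so
    the per-trial estimates are unbiased and can be binned post hoc.
    """
    data, times = _as_data(ts)
    n = data.shape[0]
    if n < 10:
        raise ValueError("LOOCV needs >= 10 trials")
    labels = _check_labels(labels, n)
    y = (labels == np.unique(labels)[1]).astype(int)
    n_times = data.shape[-1]
    scores = np.empty((n, n_times))
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        for it in range(n_times):
            clf = _make_clf(C)
            clf.fit(data[train, :, it], y[train])
            scores[i, it] = clf.predict_proba(data[i : i + 1, :, it])[0, 1]
    return SingleTrialEstimates(scores, y, times)


def power_binned_decoding_contrast(est: SingleTrialEstimates,
                                   bins: BinAssignment) -> BinnedDecoding:
    """AUC time courses recomputed within each power bin.

    Bins are applied to the already held-out LOOCV scores, so no refit
    is needed; a (bin, time) cell where the bin lacks one of the classes
    is undefined (NaN). The lowest/highest rows are the pair passed to
    the cluster permutation test (temporal adjacency).
    """
    n_times = est.scores.shape[1]
    out = np.full((bins.n_bins, n_times), np.nan)
    for b in range(1, bins.n_bins + 1):
        mask = bins.mask(b)
        if mask.sum() == 0:
            continue
        yb = est.labels[mask]
        if len(np.unique(yb)) < 2:
            continue
        for it in range(n_times):
            out[b - 1, it] = auc(est.scores[mask, it], yb)
    return BinnedDecoding(out, est.times, bins.n_bins)


def temporal_generalization(ts, labels, n_folds: int = 4, C: float = 1.0,
                            seed: int = 0,
                            keep_scores: bool = False) -> TemporalGeneralizationMatrix:
    """Train at time T, test at all times T' (cross-validated).

    Fold assignment matches :func:`timewise_decode` for the same seed,
    so the diagonal reproduces the time-resolved AUC.
    """
    data, times = _as_data(ts)
    labels = _check_labels(labels, data.shape[0])
    y = (labels == np.unique(labels)[1]).astype(int)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(np.zeros(len(y)), y))
    n_times = data.shape[-1]
    scores = np.empty((len(y), n_times, n_times))   # (trial, train_t, test_t)
    for train, test in folds:
        for it in range(n_times):
            clf = _make_clf(C)
            clf.fit(data[train, :, it], y[train])
            flat = data[test].transpose(0, 2, 1).reshape(-1, data.shape[1])
            proba = clf.predict_proba(flat)[:, 1].reshape(len(test), n_times)
            scores[test, it, :] = proba
    mat = np.empty((n_times, n_times))
    for it in range(n_times):
        for jt in range(n_times):
            mat[it, jt] = auc(scores[:, it, jt], y)
    return TemporalGeneralizationMatrix(
        mat, times, times,
        held_out_scores=scores if keep_scores else None,
        labels=y if keep_scores else None,
    )


def average_train_window(tg: TemporalGeneralizationMatrix,
                         window_s) -> np.ndarray:
    """Mean AUC over training times inside ``window_s`` -> per test time."""
    t0, t1 = window_s
    mask = (tg.train_times >= t0 - 1e-9) & (tg.train_times <= t1 + 1e-9)
    if not mask.any():
        raise ValueError(f"train window {window_s} overlaps no training times")
    avg = tg.auc[mask].mean(axis=0)
    tg.train_window_average = avg
    return avg
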