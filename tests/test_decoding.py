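import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

import oscpipe as op
from oscpipe.decoding import BinnedDecoding


def brute_force_auc(scores, labels):
    """Pairwise-enumeration oracle: wins + half-ties over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert op.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_chance(self):
        assert op.auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_enumerated_example(self):
        # pairs: (.9,.5)+ (.9,.1)+ (.4,.5)- (.4,.1)+ -> 3/4
        assert op.auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            op.auc([0.1, 0.9], [1, 1])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 10), min_size=4, max_size=40))
    def test_matches_pairwise_enumeration(self, raw):
        """Rank formula equals brute-force pair counting, ties included."""
        scores = np.asarray(raw, dtype=float) / 10.0
        rng = np.random.default_rng(len(raw))
        labels = rng.integers(0, 2, len(scores))
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert op.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = op.auc(scores, labels)
        assert op.auc(np.exp(scores), labels) == pytest.approx(a)
        assert op.auc(2 * scores - 7, labels) == pytest.approx(a)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(1)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        assert op.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))


class TestTimewiseDecode:
    def test_label_independent_data_is_chance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 10, 8))
        y = rng.permutation(np.repeat([0, 1], 100))
        res = op.timewise_decode(X, y, seed=0)
        assert abs(res.auc.mean() - 0.5) < 0.05

    def test_gaussian_classes_approach_bayes_auc(self):
        """d'=2 with one informative of 20 features: held-out AUC within
        0.05 of Phi(2/sqrt(2)) ~ 0.921 at n=400 (mean over datasets)."""
        aucs = []
        for seed in range(4):
            X, y = op.make_two_class_set(400, 2.0, 20, seed=seed)
            aucs.append(op.timewise_decode(X[:, :, None], y, seed=0).auc[0])
        assert abs(np.mean(aucs) - norm.cdf(np.sqrt(2))) < 0.05

    def test_separable_classes_reach_one(self):
        y = np.repeat([0, 1], 20)
        X = np.where(y[:, None, None] == 1, 5.0, -5.0) + \
            0.01 * np.random.default_rng(4).standard_normal((40, 4, 2))
        res = op.timewise_decode(X, y, seed=0)
        assert np.all(res.auc == 1.0)

    def test_single_class_rejected(self):
        X = np.zeros((20, 4, 2))
        with pytest.raises(ValueError):
            op.timewise_decode(X, np.zeros(20), seed=0)


class TestShuffleNull:
    def test_null_centered_on_chance_and_p_calibration(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 6, 3))
        y = rng.permutation(np.repeat([0, 1], 30))
        res = op.shuffle_null(X, y, n_shuffles=50, seed=0)
        assert abs(res.null_auc.mean() - 0.5) < 0.03
        assert np.all(res.p > 1 / 51) and np.all(res.p <= 1.0)

    def test_informative_data_small_p(self):
        X, y = op.make_two_class_set(120, 3.0, 5, seed=6)
        res = op.shuffle_null(X[:, :, None], y, n_shuffles=50, seed=0)
        assert res.p[0] == pytest.approx(1 / 51)


class TestLOOCV:
    def naive_refit(self, X, y, C=1.0):
        """From-scratch per-trial refit loop (the definitional oracle)."""
        n, _, n_times = X.shape
        out = np.empty((n, n_times))
        idx = np.arange(n)
        for i in range(n):
            tr = idx != i
            for t in range(n_times):
                sc = StandardScaler().fit(X[tr, :, t])
                clf = LogisticRegression(C=C, solver="lbfgs",
                                         max_iter=1000).fit(
                    sc.transform(X[tr, :, t]), y[tr])
                out[i, t] = clf.predict_proba(
                    sc.transform(X[i:i + 1, :, t]))[0, 1]
        return out

    def test_matches_naive_refit_exactly(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((12, 3, 2))
        y = np.tile([0, 1], 6)
        est = op.loocv_estimates(X, y)
        np.testing.assert_allclose(est.scores, self.naive_refit(X, y),
                                   rtol=0, atol=1e-10)

    def test_held_out_scores_track_class(self):
        X, y = op.make_two_class_set(40, 3.0, 4, seed=8)
        est = op.loocv_estimates(X[:, :, None], y)
        assert est.scores[y == 1, 0].mean() > 0.7
        assert est.scores[y == 0, 0].mean() < 0.3

    def test_label_independent_scores_near_prior(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 4, 2))
        y = np.tile([0, 1], 20)
        est = op.loocv_estimates(X, y)
        assert abs(est.scores.mean() - 0.5) < 0.1

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            op.loocv_estimates(np.zeros((6, 2, 1)), np.tile([0, 1], 3))


class TestPowerBinnedContrast:
    def test_bin_independent_scores_contrast_near_zero(self):
        rng = np.random.default_rng(10)
        n = 200
        y = rng.permutation(np.repeat([0, 1], n // 2))
        scores = np.clip(0.5 + 0.3 * (y[:, None] - 0.5)
                         + 0.1 * rng.standard_normal((n, 4)), 0, 1)
        est = op.SingleTrialEstimates(scores, y, np.arange(4.0))
        bins = op.quantile_bins(rng.random(n), 5)
        bd = op.power_binned_decoding_contrast(est, bins)
        assert np.nanmax(np.abs(bd.lowest - bd.highest)) < 0.25

    def test_bin_dependent_snr_recovered(self):
        """Scores are more informative in high bins -> higher AUC there."""
        rng = np.random.default_rng(11)
        n = 300
        y = rng.permutation(np.repeat([0, 1], n // 2))
        power = rng.random(n)
        snr = 0.05 + 0.5 * power
        scores = np.clip(0.5 + snr[:, None] * (y[:, None] - 0.5)
                         + 0.15 * rng.standard_normal((n, 3)), 0, 1)
        est = op.SingleTrialEstimates(scores, y, np.arange(3.0))
        bins = op.quantile_bins(power, 5)
        bd = op.power_binned_decoding_contrast(est, bins)
        assert np.nanmean(bd.highest) > np.nanmean(bd.lowest)

    def test_single_class_bin_undefined(self):
        y = np.array([0] * 10 + [1] * 10)
        scores = np.tile(y[:, None].astype(float), (1, 2))
        est = op.SingleTrialEstimates(scores, y, np.arange(2.0))
        bins = op.quantile_bins(np.arange(20.0), 2)  # bin1 all class 0
        bd = op.power_binned_decoding_contrast(est, bins)
        assert np.all(np.isnan(bd.auc_per_bin[0]))


class TestTemporalGeneralization:
    def test_sustained_pattern_generalizes_in_block(self):
        rng = np.random.default_rng(12)
        n, n_ch, n_t = 80, 6, 10
        y = rng.permutation(np.repeat([0, 1], n // 2))
        X = rng.standard_normal((n, n_ch, n_t))
        pattern = rng.standard_normal(n_ch)
        X[:, :, 3:8] += 2.0 * np.where(y[:, None, None] == 1, 1, -1) * \
            pattern[None, :, None]
        tg = op.temporal_generalization(X, y, seed=0)
        assert tg.auc[3:8, 3:8].mean() > 0.8
        assert tg.auc[:2, :2].mean() < 0.65

    def test_transient_orthogonal_patterns_stay_diagonal(self):
        rng = np.random.default_rng(13)
        n, n_t = 80, 6
        y = rng.permutation(np.repeat([0, 1], n // 2))
        X = rng.standard_normal((n, 2, n_t))
        s = np.where(y == 1, 1.0, -1.0)
        X[:, 0, :3] += 2.5 * s[:, None]   # early pattern on channel 0
        X[:, 1, 3:] += 2.5 * s[:, None]   # late pattern on channel 1
        tg = op.temporal_generalization(X, y, seed=0)
        on_diag = (tg.auc[:3, :3].mean() + tg.auc[3:, 3:].mean()) / 2
        off_diag = (tg.auc[:3, 3:].mean() + tg.auc[3:, :3].mean()) / 2
        assert on_diag - off_diag > 0.2

    def test_null_data_near_chance(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((60, 4, 5))
        y = rng.permutation(np.repeat([0, 1], 30))
        tg = op.temporal_generalization(X, y, seed=0)
        assert abs(tg.auc.mean() - 0.5) < 0.06

    def test_diagonal_equals_timewise_decode(self):
        X, y = op.make_two_class_set(60, 1.5, 4, seed=15)
        Xt = np.concatenate([X[:, :, None], X[:, :, None] * 0.5], axis=2)
        tg = op.temporal_generalization(Xt, y, seed=3)
        res = op.timewise_decode(Xt, y, seed=3)
        np.testing.assert_allclose(np.diag(tg.auc), res.auc, atol=1e-12)


class TestAverageTrainWindow:
    def make_tg(self, mat):
        mat = np.asarray(mat, dtype=float)
        t = np.arange(mat.shape[0]) * 0.1
        return op.TemporalGeneralizationMatrix(mat, t, t)

    def test_constant_matrix(self):
        tg = self.make_tg(np.full((4, 4), 0.7))
        np.testing.assert_allclose(op.average_train_window(tg, (0, 0.3)), 0.7)

    def test_two_rows_mean(self):
        mat = np.zeros((4, 2))
        mat[1] = 0.6
        mat[2] = 0.8
        tg = self.make_tg(mat)
        np.testing.assert_allclose(
            op.average_train_window(tg, (0.1, 0.2)), [0.7, 0.7])

    def test_full_window_is_column_mean(self):
        rng = np.random.default_rng(16)
        mat = rng.random((5, 5))
        tg = self.make_tg(mat)
        np.testing.assert_allclose(
            op.average_train_window(tg, (0.0, 0.4)), mat.mean(axis=0))

    def test_empty_overlap_rejected(self):
        tg = self.make_tg(np.ones((3, 3)))
        with pytest.raises(ValueError):
            op.average_train_window(tg, (5.0, 6.0))
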