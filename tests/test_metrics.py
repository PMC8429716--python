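"""Evaluation metrics against independent textbook implementations."""

import numpy as np
import pytest

from sigclone import metrics, random_signature_matrix
from sigclone.metrics import ClusteringTruthPair


def w1_sorted_cdf(values_a, weights_a, values_b, weights_b):
    """O(n log n) Wasserstein-1 oracle via the difference of CDFs."""
    points = np.sort(np.concatenate([values_a, values_b]))
    total = 0.0
    for lo, hi in zip(points, points[1:]):
        cdf_a = weights_a[values_a <= lo].sum()
        cdf_b = weights_b[values_b <= lo].sum()
        total += abs(cdf_a - cdf_b) * (hi - lo)
    return total


def pearson_textbook(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())


def mcc_textbook(truth, pred):
    tp = np.sum(truth & pred)
    tn = np.sum(~truth & ~pred)
    fp = np.sum(~truth & pred)
    fn = np.sum(truth & ~pred)
    denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


def v_measure_textbook(truth, pred):
    def entropy(labels):
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        return -(p * np.log(p)).sum()

    def conditional_entropy(a, b):
        # H(a | b)
        total = len(a)
        h = 0.0
        for vb in np.unique(b):
            mask = b == vb
            for va in np.unique(a[mask]):
                n = np.sum(a[mask] == va)
                h -= (n / total) * np.log(n / np.sum(mask))
        return h

    h_c, h_k = entropy(truth), entropy(pred)
    hom = 1.0 if h_c == 0 else 1.0 - conditional_entropy(truth, pred) / h_c
    com = 1.0 if h_k == 0 else 1.0 - conditional_entropy(pred, truth) / h_k
    if hom + com == 0:
        return 0.0
    return 2 * hom * com / (hom + com)


class TestScore1b:
    @pytest.mark.parametrize(
        "jt, jp, expected", [(3, 3, 1.0), (3, 5, 0.5), (1, 8, 0.0), (2, 3, 2 / 3)]
    )
    def test_printed_formula(self, jt, jp, expected):
        assert metrics.score1b(jt, jp) == pytest.approx(expected)

    def test_bounds(self):
        for jt in range(1, 9):
            for jp in range(1, 9):
                assert 0.0 <= metrics.score1b(jt, jp) <= 1.0


class TestScore1c:
    def test_identical_distributions(self):
        pair = ClusteringTruthPair(
            true_labels=[0, 0, 1], pred_labels=[1, 1, 0],
            true_ccfs=[1.0, 0.4], pred_ccfs=[0.4, 1.0],
        )
        assert metrics.score1c(pair) == pytest.approx(1.0)

    def test_point_mass_shift(self):
        pair = ClusteringTruthPair(
            true_labels=[0, 0], pred_labels=[0, 0],
            true_ccfs=[0.5], pred_ccfs=[0.6],
        )
        assert metrics.score1c(pair) == pytest.approx(0.9)

    def test_split_mass_transport(self):
        # two equal clones at 0.4 / 1.0 vs one clone at 0.7: move each half 0.3
        pair = ClusteringTruthPair(
            true_labels=[0, 1], pred_labels=[0, 0],
            true_ccfs=[0.4, 1.0], pred_ccfs=[0.7],
        )
        assert metrics.score1c(pair) == pytest.approx(0.7)

    def test_matches_sorted_cdf_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            kt, kp = rng.integers(1, 5), rng.integers(1, 5)
            n = 30
            pair = ClusteringTruthPair(
                true_labels=rng.integers(0, kt, n),
                pred_labels=rng.integers(0, kp, n),
                true_ccfs=rng.uniform(0.1, 1.2, kt),
                pred_ccfs=rng.uniform(0.1, 1.2, kp),
            )
            wt = np.bincount(pair.true_labels, minlength=kt) / n
            wp = np.bincount(pair.pred_labels, minlength=kp) / n
            oracle = w1_sorted_cdf(pair.true_ccfs, wt, pair.pred_ccfs, wp)
            assert metrics.score1c(pair) == pytest.approx(1 - oracle, abs=1e-10)


class TestScore2a:
    def _pair(self, truth, pred):
        kt, kp = max(truth) + 1, max(pred) + 1
        return ClusteringTruthPair(
            true_labels=truth, pred_labels=pred,
            true_ccfs=np.linspace(1, 0.3, kt), pred_ccfs=np.linspace(1, 0.3, kp),
        )

    def test_perfect_prediction(self):
        pair = self._pair([0, 0, 1, 1, 2], [2, 2, 0, 0, 1])
        assert metrics.score2a(pair) == pytest.approx(1.0)

    def test_degenerate_prediction_scores_zero(self):
        pair = self._pair([0, 0, 0, 1, 1, 1], [0, 0, 0, 0, 0, 0])
        assert metrics.score2a(pair) == pytest.approx(0.0, abs=1e-12)

    def test_sub_scores_match_textbook_formulas(self):
        from sigclone.metrics import _co_clustering, _score2a_raw

        rng = np.random.default_rng(1)
        for _ in range(30):
            truth = rng.integers(0, 4, 15)
            pred = rng.integers(0, 4, 15)
            raw = _score2a_raw(truth, pred)
            mt = _co_clustering(truth).ravel().astype(bool)
            mp = _co_clustering(pred).ravel().astype(bool)
            assert raw[0] == pytest.approx(pearson_textbook(mt, mp), abs=1e-8)
            assert raw[1] == pytest.approx(mcc_textbook(mt, mp), abs=1e-8)
            assert raw[2] == pytest.approx(v_measure_textbook(truth, pred), abs=1e-8)

    def test_label_permutation_invariance(self):
        pair_a = self._pair([0, 0, 1, 1, 2, 2], [0, 1, 1, 1, 2, 2])
        pair_b = self._pair([2, 2, 0, 0, 1, 1], [1, 0, 0, 0, 2, 2])
        assert metrics.score2a(pair_a) == pytest.approx(metrics.score2a(pair_b))

    def test_memory_bound_enforced(self):
        n = 20_001
        pair = ClusteringTruthPair(
            true_labels=np.zeros(n, int), pred_labels=np.zeros(n, int),
            true_ccfs=[1.0], pred_ccfs=[1.0],
        )
        with pytest.raises(ValueError):
            metrics.score2a(pair)


class TestScore2c:
    def test_perfect_prediction(self):
        pair = ClusteringTruthPair(
            true_labels=[0, 0, 1, 1], pred_labels=[0, 0, 1, 1],
            true_ccfs=[1.0, 0.4], pred_ccfs=[1.0, 0.4],
        )
        s = metrics.score2c(pair)
        assert s.accuracy == 1.0 and s.auc == 1.0

    def test_all_predicted_clonal(self):
        pair = ClusteringTruthPair(
            true_labels=[0, 0, 1, 1], pred_labels=[0, 0, 0, 0],
            true_ccfs=[1.0, 0.4], pred_ccfs=[1.0],
        )
        s = metrics.score2c(pair)
        assert s.accuracy == 0.5 and s.sensitivity == 1.0 and s.specificity == 0.0

    def test_label_swap_gives_zero_accuracy(self):
        pair = ClusteringTruthPair(
            true_labels=[0, 0, 1, 1], pred_labels=[1, 1, 0, 0],
            true_ccfs=[1.0, 0.4], pred_ccfs=[1.0, 0.4],
        )
        assert metrics.score2c(pair).accuracy == 0.0

    def test_one_class_truth_has_no_auc(self):
        pair = ClusteringTruthPair(
            true_labels=[0, 0], pred_labels=[0, 1],
            true_ccfs=[1.0], pred_ccfs=[1.0, 0.5],
        )
        assert metrics.score2c(pair).auc is None


class TestSignatureScores:
    def test_sig_1a_zero_for_exact_reconstruction(self):
        sigs = random_signature_matrix(3, 2)
        act = np.array([0.2, 0.5, 0.3])
        profile = act @ sigs.mu
        counts = profile * 10_000
        assert metrics.score_sig_1a(counts, act, sigs) == pytest.approx(0.0, abs=1e-12)

    def test_sig_1b_disjoint_one_hot_swap(self, disjoint_sigs):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        expected = np.linalg.norm(disjoint_sigs.mu[0] - disjoint_sigs.mu[1])
        assert metrics.score_sig_1b(a, b, disjoint_sigs) == pytest.approx(expected)
        assert metrics.score_sig_1b(a, a, disjoint_sigs) == 0.0

    def test_sig_1b_profile_level_degeneracy(self):
        mu = np.tile(np.full(96, 1 / 96), (2, 1))
        from sigclone import SignatureMatrix

        same = SignatureMatrix(names=("a", "b"), mu=mu)
        assert metrics.score_sig_1b([1, 0], [0, 1], same) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "activities, expected",
        [
            ([0.96, 0.04], [True, False]),
            ([0.5, 0.5], [True, True]),
            ([0.0, 1.0, 0.0], [False, True, False]),
            ([0.4, 0.3, 0.2, 0.1], [True, True, True, True]),
            ([0.5, 0.3, 0.18, 0.02], [True, True, True, False]),
        ],
    )
    def test_signature_present_cumulative_rule(self, activities, expected):
        assert metrics.signature_present(np.array(activities)).tolist() == expected

    def test_sig_1c_ranking(self):
        s = metrics.score_sig_1c([True, True, False, False], [0.4, 0.3, 0.2, 0.1])
        assert s.auc == 1.0
        s = metrics.score_sig_1c([False, False, True, True], [0.4, 0.3, 0.2, 0.1])
        assert s.auc == 0.0

    def test_sig_1d_fraction_correct(self):
        assert metrics.score_sig_1d([0, 1, 2, 1], [0, 1, 2, 0]) == 0.75
        assert metrics.score_sig_1d([1, 1], [1, 1]) == 1.0

    def test_sig_1e_constant_distance(self, disjoint_sigs):
        true_pi = np.eye(2)
        pred_pi = np.eye(2)[::-1]  # every SNV's clone profile swapped
        d = metrics.cosine_distance(disjoint_sigs.mu[0], disjoint_sigs.mu[1])
        out = metrics.score_sig_1e(
            [0, 0, 1, 1], [0, 0, 1, 1], true_pi, pred_pi, disjoint_sigs
        )
        assert out.median == pytest.approx(d)
        assert out.std == pytest.approx(0.0, abs=1e-12)

    def test_sig_1e_identical_reconstruction(self, sigs5):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(5), size=2)
        out = metrics.score_sig_1e([0, 1, 1], [0, 1, 1], pi, pi, sigs5)
        assert out.median == pytest.approx(0.0, abs=1e-12)

    def test_sig_1e_matches_per_snv_hand_computation(self, sigs5):
        rng = np.random.default_rng(4)
        true_pi = rng.dirichlet(np.ones(5), size=2)
        pred_pi = rng.dirichlet(np.ones(5), size=2)
        true_c = rng.integers(0, 2, 10)
        pred_c = rng.integers(0, 2, 10)
        out = metrics.score_sig_1e(true_c, pred_c, true_pi, pred_pi, sigs5)
        hand = [
            metrics.cosine_distance(
                true_pi[true_c[i]] @ sigs5.mu, pred_pi[pred_c[i]] @ sigs5.mu
            )
            for i in range(10)
        ]
        assert out.median == pytest.approx(np.median(hand), abs=1e-12)
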