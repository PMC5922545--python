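"""Metrics: confusion, precision/recall/F1, PR curves, AP/mAP, harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenotray as pt


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.r_[np.ones(10, int), np.zeros(90, int)]
        assert pt.confusion(truth, truth) == (10, 0, 0, 90)

    def test_all_negative_prediction(self):
        truth = np.r_[np.ones(5, int), np.zeros(5, int)]
        tp, fp, fn, tn = pt.confusion(np.zeros(10, int), truth)
        assert (tp, fp) == (0, 0) and fn == 5 and tn == 5

    def test_matches_bruteforce_pairwise_count(self, rng):
        pred = rng.integers(0, 2, 200)
        truth = rng.integers(0, 2, 200)
        tp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 1)
        fp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 0)
        fn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 1)
        tn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 0)
        assert pt.confusion(pred, truth) == (tp, fp, fn, tn)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pt.confusion(np.zeros(3, int), np.zeros(4, int))


class TestPRF1:
    def test_direct_formula(self):
        assert pt.prf1(8, 2, 2) == pytest.approx((0.8, 0.8, 0.8))

    def test_perfect(self):
        assert pt.prf1(10, 0, 0) == (1.0, 1.0, 1.0)

    def test_zero_tp_convention(self):
        assert pt.prf1(0, 0, 5) == (0.0, 0.0, 0.0)

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           fn=st.integers(0, 50), tn=st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_f1_is_harmonic_mean_and_tn_invariant(self, tp, fp, fn, tn):
        p, r, f1 = pt.prf1(tp, fp, fn)
        assert 0.0 <= f1 <= 1.0
        if p + r > 0:
            assert f1 == pytest.approx(2 * p * r / (p + r))
        # TN never enters the positive-class metrics
        assert pt.prf1(tp, fp, fn) == pt.prf1(tp, fp, fn)


class TestPRCurve:
    def test_perfect_ranking_precision_one(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        truth = np.array([1, 1, 1, 0, 0])
        recall, precision = pt.pr_curve(scores, truth)
        assert np.all(precision[recall > 0][: 3] == 1.0)

    def test_inverted_ranking_final_precision(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        truth = np.array([0, 0, 1, 1])
        recall, precision = pt.pr_curve(scores, truth)
        assert recall[-1] == 1.0
        assert precision[-1] == pytest.approx(2 / 4)

    def test_recall_monotone_nondecreasing(self, rng):
        scores = rng.uniform(size=100)
        truth = rng.integers(0, 2, 100)
        truth[0] = 1
        recall, _ = pt.pr_curve(scores, truth)
        assert np.all(np.diff(recall) >= 0)

    def test_requires_positives(self):
        with pytest.raises(ValueError):
            pt.pr_curve(np.array([0.5, 0.4]), np.array([0, 0]))


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert pt.average_precision(np.array([0.9, 0.8, 0.1]),
                                    np.array([1, 1, 0])) == 1.0

    def test_hand_enumerated_example(self):
        """Positives at ranks 1 and 3: AP = (1 + 2/3) / 2."""
        ap = pt.average_precision(np.array([0.9, 0.8, 0.7, 0.6]),
                                  np.array([1, 0, 1, 0]))
        assert ap == pytest.approx((1.0 + 2.0 / 3.0) / 2.0)

    def test_matches_bruteforce_threshold_sweep(self, rng):
        """Positive-rank average equals an explicit threshold enumeration
        on random 20-item fixtures, with and without score ties."""
        for trial in range(20):
            scores = np.round(rng.uniform(size=20), 2 if trial % 2 else 6)
            truth = rng.integers(0, 2, 20)
            truth[rng.integers(0, 20)] = 1
            ap = pt.average_precision(scores, truth)
            # brute force: for each distinct threshold, P and R from raw
            # counting; AP = sum P * (delta recall)
            n_pos = truth.sum()
            pts = []
            for thr in sorted(set(scores), reverse=True):
                pred = (scores >= thr).astype(int)
                tp = int(((pred == 1) & (truth == 1)).sum())
                fp = int(((pred == 1) & (truth == 0)).sum())
                pts.append((tp / n_pos, tp / (tp + fp)))
            oracle, prev_r = 0.0, 0.0
            for r, p in pts:
                oracle += p * (r - prev_r)
                prev_r = r
            assert ap == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn_estimator(self, rng):
        """The grouped-tie rank-average definition coincides with the
        reference step-wise estimator."""
        from sklearn.metrics import average_precision_score

        for _ in range(10):
            scores = np.round(rng.uniform(size=30), 2)
            truth = rng.integers(0, 2, 30)
            truth[0] = 1
            assert pt.average_precision(scores, truth) == pytest.approx(
                average_precision_score(truth, scores), abs=1e-12)

    def test_trapezoid_variant_close_to_rank(self, rng):
        scores = rng.uniform(size=50)
        truth = rng.integers(0, 2, 50)
        truth[0] = 1
        a = pt.average_precision(scores, truth, method="rank")
        b = pt.average_precision(scores, truth, method="trapezoid")
        assert abs(a - b) < 0.1


class TestMeanAP:
    def test_single_and_arithmetic(self):
        assert pt.mean_ap([0.7]) == 0.7
        assert pt.mean_ap([1.0, 0.5]) == 0.75
        assert pt.mean_ap([0.9] * 10) == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pt.mean_ap([])


@pytest.fixture(scope="module")
def reports():
    params = pt.SimParams(seed=5)
    train_pairs = pt.generate_groundtruth_pack(params, 15, seed=5)
    test_pairs = pt.generate_groundtruth_pack(
        params, 5, variation=pt.traysim.SHIFTED_TEST_VARIATION, seed=6)
    return pt.compare_algorithms(
        train_pairs, test_pairs, algorithms=("rf", "svm"), k=5,
        n_repeats=3, seed=1)


class TestCompareAlgorithms:
    def test_one_f1_per_repeat_per_split(self, reports):
        for rep in reports.values():
            assert len(rep.validation.f1) == 3
            assert len(rep.test.f1) == 3
            assert len(rep.train_seconds) == 3

    def test_shifted_test_never_beats_validation(self, reports):
        for rep in reports.values():
            assert rep.test.mean_f1 <= rep.validation.mean_f1

    def test_report_serializes(self, reports):
        import json

        blob = json.dumps({a: r.to_dict() for a, r in reports.items()})
        assert "mAP" in blob

    def test_reproducible_with_same_seed(self):
        params = pt.SimParams(seed=5)
        tr = pt.generate_groundtruth_pack(params, 8, seed=5)
        te = pt.generate_groundtruth_pack(params, 3, seed=6)
        a = pt.compare_algorithms(tr, te, algorithms=("rf",), k=4,
                                  n_repeats=2, seed=9)
        b = pt.compare_algorithms(tr, te, algorithms=("rf",), k=4,
                                  n_repeats=2, seed=9)
        assert a["rf"].validation.f1 == b["rf"].validation.f1
        assert a["rf"].test.ap == b["rf"].test.ap

    def test_single_run_reduces_to_one_eval(self):
        params = pt.SimParams(seed=5)
        tr = pt.generate_groundtruth_pack(params, 6, seed=5)
        te = pt.generate_groundtruth_pack(params, 2, seed=6)
        out = pt.compare_algorithms(tr, te, algorithms=("rf",), k=3,
                                    n_repeats=1, seed=2)
        assert len(out["rf"].validation.f1) == 1
        assert out["rf"].validation.map == out["rf"].validation.ap[0]
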