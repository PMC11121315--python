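import math

import numpy as np
import pytest

from tmhc.contacts import CandidatePair
from tmhc.errors import EvaluationError
from tmhc.evaluation import (
    RankedPredictions,
    auc_roc,
    average_precision,
    binary_average_precision,
    crossvalidate,
    evaluate_ranked,
    feature_statistics,
    topk_precision_recall,
)


# -- independent oracles: exhaustive threshold sweeps --------------------


def sweep_average_precision(scores, labels):
    """AP by sweeping every distinct score as a threshold (ties grouped)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        predicted = scores >= t
        tp = (predicted & labels).sum()
        precision = tp / predicted.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def sweep_auc(scores, labels):
    """Trapezoidal AUC over the grouped-threshold ROC sweep."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    n_pos, n_neg = labels.sum(), (~labels).sum()
    points = []
    for t in thresholds:
        predicted = scores >= t
        points.append(
            ((predicted & ~labels).sum() / n_neg, (predicted & labels).sum() / n_pos)
        )
    area = 0.0
    for (f0, t0), (f1, t1) in zip(points, points[1:]):
        area += (f1 - f0) * (t0 + t1) / 2.0
    return area


def _pairs(n):
    return [CandidatePair(k, k + 10, 1, 2) for k in range(1, n + 1)]


class TestAveragePrecision:
    def test_hand_worked_example(self):
        # ranked labels 1,0,1 -> 0.5*1 + 0.5*(2/3)
        ap = average_precision([0.9, 0.8, 0.7], [1, 0, 1])
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2.0 / 3.0))

    def test_perfect_ranking_is_one(self, rng):
        labels = np.array([1, 1, 1, 0, 0, 0, 0], bool)
        scores = np.linspace(1, 0, 7)
        assert average_precision(scores, labels) == pytest.approx(1.0)

    def test_matches_sweep_oracle_on_random_lists(self, rng):
        for _ in range(50):
            labels = rng.uniform(size=50) < 0.3
            if not labels.any():
                labels[0] = True
            scores = np.round(rng.uniform(size=50), 2)  # force ties
            assert average_precision(scores, labels) == pytest.approx(
                sweep_average_precision(scores, labels), abs=1e-9
            )

    def test_undefined_without_positives(self):
        with pytest.raises(EvaluationError):
            average_precision([0.5, 0.4], [0, 0])

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.uniform(size=40) < 0.25
        labels[0] = True
        scores = rng.uniform(size=40)
        assert average_precision(scores, labels) == pytest.approx(
            average_precision(np.exp(3 * scores), labels), abs=1e-12
        )


class TestBinaryAveragePrecision:
    def test_p_times_r(self):
        # P = 4/5 = 0.8, R = 4/8 = 0.5 -> 0.40
        labels = np.zeros(20, bool)
        labels[:8] = True
        annotations = np.zeros(20, bool)
        annotations[:4] = True  # 4 true positives
        annotations[10] = True  # 1 false positive
        assert binary_average_precision(labels, annotations) == pytest.approx(0.40)

    def test_perfect_annotation_is_one(self, rng):
        labels = rng.uniform(size=30) < 0.4
        labels[0] = True
        assert binary_average_precision(labels, labels) == 1.0

    def test_empty_annotation_is_zero(self):
        labels = np.array([1, 0, 0], bool)
        assert binary_average_precision(labels, np.zeros(3, bool)) == 0.0


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.1], [1, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc_roc([0.5] * 6, [1, 0, 1, 0, 0, 1]) == pytest.approx(0.5)

    def test_matches_mann_whitney_on_random_lists(self, rng):
        for _ in range(30):
            labels = rng.uniform(size=50) < 0.4
            if labels.all() or not labels.any():
                labels[:2] = [True, False]
            scores = np.round(rng.uniform(size=50), 2)
            pos, neg = scores[labels], scores[~labels]
            u = sum(
                1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
            )
            assert auc_roc(scores, labels) == pytest.approx(
                u / (len(pos) * len(neg)), abs=1e-9
            )
            assert auc_roc(scores, labels) == pytest.approx(
                sweep_auc(scores, labels), abs=1e-9
            )

    def test_single_class_undefined(self):
        with pytest.raises(EvaluationError):
            auc_roc([0.5, 0.4], [1, 1])


class TestTopK:
    def test_hand_worked_example(self):
        # 10 pairs, contacts ranked 1st and 3rd, L = 5 -> k = 5
        labels = np.zeros(10, bool)
        scores = np.linspace(1.0, 0.1, 10)
        labels[0] = labels[2] = True
        rp = RankedPredictions("A", _pairs(10), scores, labels)
        out = topk_precision_recall(rp, tm_length=5)
        assert out["L"] == (pytest.approx(2 / 5), pytest.approx(1.0))

    def test_k_floor_minimum_one(self):
        labels = np.zeros(10, bool)
        labels[0] = True
        scores = np.linspace(1.0, 0.1, 10)
        rp = RankedPredictions("A", _pairs(10), scores, labels)
        out = topk_precision_recall(rp, tm_length=5)
        # floor(5/10) = 0 -> clamped to 1; the top pair is a true contact
        assert out["L/10"] == (pytest.approx(1.0), pytest.approx(1.0))

    def test_recall_nondecreasing_in_k(self, rng):
        labels = rng.uniform(size=60) < 0.2
        labels[0] = True
        scores = rng.uniform(size=60)
        rp = RankedPredictions("A", _pairs(60), scores, labels)
        out = topk_precision_recall(rp, tm_length=40)
        recalls = [out["L/10"][1], out["L/5"][1], out["L/2"][1], out["L"][1]]
        assert recalls == sorted(recalls)

    def test_matches_bruteforce_thresholding(self, rng):
        for _ in range(20):
            n = 40
            labels = rng.uniform(size=n) < 0.3
            labels[0] = True
            scores = rng.uniform(size=n)
            rp = RankedPredictions("A", _pairs(n), scores, labels)
            out = topk_precision_recall(rp, tm_length=25)
            for name, frac in [("L", 1.0), ("L/2", 0.5), ("L/5", 0.2), ("L/10", 0.1)]:
                k = min(max(1, math.floor(25 * frac)), n)
                top = np.argsort(-scores)[:k]  # unique scores: order unambiguous
                tp = labels[top].sum()
                assert out[name][0] == pytest.approx(tp / k)
                assert out[name][1] == pytest.approx(tp / labels.sum())


class TestFeatureStatistics:
    def test_constant_matrix(self):
        mean, sd = feature_statistics(np.full((4, 5), -1.0))
        assert (mean, sd) == (-1.0, 0.0)

    def test_balanced_pm_one(self):
        X = np.array([[-1.0, 1.0], [1.0, -1.0]])
        mean, sd = feature_statistics(X)
        assert mean == 0.0 and sd == 1.0

    def test_matches_two_pass_oracle(self, rng):
        X = rng.normal(size=(30, 8))
        mean, sd = feature_statistics(X)
        flat = [v for row in X for v in row]
        m = sum(flat) / len(flat)
        var = sum((v - m) ** 2 for v in flat) / len(flat)
        assert mean == pytest.approx(m, abs=1e-12)
        assert sd == pytest.approx(math.sqrt(var), abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(EvaluationError):
            feature_statistics(np.empty((0, 4)))


class TestEvaluateRanked:
    def test_aggregate_is_mean_over_sequences(self, rng):
        preds = []
        tm = {}
        for cid in ("A", "B", "C"):
            labels = rng.uniform(size=30) < 0.3
            labels[0] = True
            preds.append(
                RankedPredictions(cid, _pairs(30), rng.uniform(size=30), labels)
            )
            tm[cid] = 20
        report = evaluate_ranked(preds, tm)
        aps = report.per_sequence["ap"]
        assert report.mean("ap") == pytest.approx(aps.mean())

    def test_no_contact_chain_flagged_and_excluded(self, rng):
        good = RankedPredictions(
            "A", _pairs(20), rng.uniform(size=20), np.arange(20) < 3
        )
        empty = RankedPredictions(
            "B", _pairs(20), rng.uniform(size=20), np.zeros(20, bool)
        )
        report = evaluate_ranked([good, empty], {"A": 10, "B": 10})
        assert np.isnan(
            report.per_sequence.set_index("chain_id").loc["B", "ap"]
        )
        assert report.mean("ap") == pytest.approx(
            report.per_sequence.set_index("chain_id").loc["A", "ap"]
        )


class TestCrossvalidate:
    @pytest.fixture(scope="class")
    def small_world(self):
        from tmhc.synthetic import make_dataset

        chains, anns, _ = make_dataset(5, seed=2)
        return chains, anns

    def _run(self, world, seed=0):
        from tmhc.model import ModelConfig

        chains, anns = world
        config = ModelConfig(hidden_sizes=(16, 16, 8, 8, 4, 4), epochs=2)
        return crossvalidate(
            chains, anns, "SDF", config, k=5, repeats=2, base_seed=seed
        )

    def test_each_chain_validated_once_per_repeat(self, small_world):
        report = self._run(small_world)
        for rep, group in report.per_sequence.groupby("repeat"):
            assert sorted(group["chain_id"]) == sorted(small_world[0])

    def test_deterministic_given_seeds(self, small_world):
        r1 = self._run(small_world)
        r2 = self._run(small_world)
        assert r1.per_sequence.equals(r2.per_sequence)

    def test_too_few_chains_rejected(self, small_world):
        from tmhc.model import ModelConfig

        chains, anns = small_world
        config = ModelConfig(hidden_sizes=(16, 16, 8, 8, 4, 4), epochs=1)
        with pytest.raises(EvaluationError):
            crossvalidate(
                dict(list(chains.items())[:3]), anns, "SDF", config, k=5, repeats=1
            )
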