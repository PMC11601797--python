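"""Early-recognition metric tests against independent oracles.

The logAUC oracle enumerates the step ROC directly from the ranked
label vector and integrates the piecewise-constant TPR against
d(log10 FPR) — a different construction from the implementation's
tie-grouped ROC with linear segments.  BEDROC is cross-checked against
RDKit's independent implementation, EF and DCG against brute-force
counting.
"""

import math

import numpy as np
import pytest
from rdkit.ML.Scoring import Scoring

from htscurate.metrics import (
    MetricConfig,
    bedroc,
    dcg_at_k,
    enrichment_factor,
    evaluate_all,
    logauc_range,
    rank_by_score,
)

RANDOM_LOGAUC = 0.099 / (2 * math.log(10))  # identity-ROC closed form


def step_roc_logauc(ranked_labels, lo=0.001, hi=0.1):
    """Oracle: exact log-area of the step ROC from a ranked label list."""
    ranked = np.asarray(ranked_labels)
    n_act = ranked.sum()
    n_inact = ranked.size - n_act
    area = 0.0
    tp = 0
    fp = 0
    for lab in ranked:
        if lab == 1:
            tp += 1
        else:
            f0, f1 = fp / n_inact, (fp + 1) / n_inact
            seg_lo, seg_hi = max(f0, lo), min(f1, hi)
            if seg_hi > seg_lo:
                area += (tp / n_act) * math.log10(seg_hi / seg_lo)
            fp += 1
    return area / math.log10(hi / lo)


def brute_force_bedroc(ranked_labels, alpha=20.0):
    """Oracle: RDKit's published BEDROC implementation."""
    ordered = [[0.0, int(lab)] for lab in ranked_labels]
    return Scoring.CalcBEDROC(ordered, 1, alpha)


class TestRanking:
    def test_descending_order(self):
        order = rank_by_score([0, 1, 0], [0.9, 0.1, 0.5])
        assert list(order) == [0, 2, 1]

    def test_all_equal_scores_keep_input_order(self):
        with pytest.warns(UserWarning, match="tied"):
            order = rank_by_score([1, 0, 1], [0.5, 0.5, 0.5])
        assert list(order) == [0, 1, 2]

    def test_pessimistic_ties_sink_actives(self):
        order = rank_by_score([1, 0, 1], [0.5, 0.5, 0.5],
                              tie_policy="average_pessimistic")
        assert list(order) == [1, 0, 2]

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_max_score_ranks_first_all_permutations(self, n):
        import itertools
        scores = np.linspace(0.1, 0.9, n)
        labels = [1] + [0] * (n - 1)
        for perm in itertools.permutations(range(n)):
            permuted = scores[list(perm)]
            order = rank_by_score(labels, permuted)
            assert permuted[order[0]] == permuted.max()

    def test_nan_score_rejected(self):
        with pytest.raises(ValueError):
            rank_by_score([0, 1], [0.1, float("nan")])


class TestLogAUC:
    def test_identity_roc_calibration(self):
        """A score-independent classifier scores 0.099/(2 ln 10)."""
        labels = np.array([1] * 50 + [0] * 950)
        value = logauc_range(labels, np.zeros(labels.size))
        assert value == pytest.approx(RANDOM_LOGAUC, abs=1e-12)

    def test_perfect_ranking_scores_one(self):
        n = 20000
        labels = np.zeros(n, int)
        labels[:200] = 1
        value = logauc_range(labels, np.linspace(1, 0, n))
        assert value == pytest.approx(1.0, abs=1e-9)

    def test_matches_step_roc_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(20, 500))
            labels = (rng.random(n) < 0.2).astype(int)
            if labels.min() == labels.max():
                continue
            scores = rng.permutation(n).astype(float)  # distinct scores
            ranked = labels[np.argsort(-scores, kind="stable")]
            assert logauc_range(labels, scores) == pytest.approx(
                step_roc_logauc(ranked), abs=1e-9)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            logauc_range([1, 1, 1], [0.3, 0.2, 0.1])


class TestBEDROC:
    def test_matches_rdkit_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(10, 400))
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.min() == labels.max():
                continue
            scores = rng.permutation(n).astype(float)
            ranked = labels[np.argsort(-scores, kind="stable")]
            assert bedroc(labels, scores) == pytest.approx(
                brute_force_bedroc(ranked), abs=1e-9)

    def test_limiting_cases(self):
        n, m = 1000, 10
        labels = np.zeros(n, int)
        labels[:m] = 1
        best = np.linspace(1, 0, n)
        assert bedroc(labels, best) > 0.99
        worst = np.linspace(0, 1, n)
        assert bedroc(labels, worst) < 0.01

    def test_hand_worked_small_case(self):
        # n=10, actives at ranks 1 and 6, alpha=20
        labels = np.array([1, 0, 0, 0, 0, 1, 0, 0, 0, 0])
        scores = np.linspace(1.0, 0.1, 10)
        expected = brute_force_bedroc(labels, alpha=20.0)
        assert bedroc(labels, scores) == pytest.approx(expected, abs=1e-12)


class TestEFandDCG:
    def test_ef_perfect_selection(self):
        labels = np.array([1] * 100 + [0] * 900)
        scores = np.linspace(1, 0, 1000)
        assert enrichment_factor(labels, scores) == pytest.approx(10.0)

    def test_ef_no_actives_in_top_k(self):
        labels = np.array([0] * 900 + [1] * 100)
        scores = np.linspace(1, 0, 1000)
        assert enrichment_factor(labels, scores) == 0.0

    def test_ef_brute_force_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(50, 500))
            k = int(rng.integers(1, n))
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() == 0:
                continue
            scores = rng.permutation(n).astype(float)
            ranked = labels[np.argsort(-scores, kind="stable")]
            expected = (sum(ranked[:k]) / k) / (sum(ranked) / n)
            got = enrichment_factor(labels, scores, MetricConfig(k=k))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_ef_errors(self):
        with pytest.raises(ValueError, match="no actives"):
            enrichment_factor([0, 0, 0], [1, 2, 3], MetricConfig(k=2))
        with pytest.raises(ValueError, match="list-shorter"):
            enrichment_factor([1, 0], [1.0, 0.5], MetricConfig(k=100))

    def test_dcg_hand_worked(self):
        # actives at ranks 1 and 3: 1/log2(2) + 1/log2(4) = 1.5
        got = dcg_at_k([1, 0, 1, 0], [4.0, 3.0, 2.0, 1.0], MetricConfig(k=3))
        assert got == pytest.approx(1.5)

    def test_dcg_all_topk_active(self):
        n, k = 500, 100
        labels = np.array([1] * k + [0] * (n - k))
        expected = sum(1 / math.log2(i + 1) for i in range(1, k + 1))
        got = dcg_at_k(labels, np.linspace(1, 0, n), MetricConfig(k=k))
        assert got == pytest.approx(expected, abs=1e-9)


class TestEvaluateAll:
    def test_consistency_with_individual_metrics(self):
        rng = np.random.default_rng(8)
        labels = (rng.random(300) < 0.1).astype(int)
        labels[0] = 1
        labels[1] = 0
        scores = rng.permutation(300).astype(float)
        report = evaluate_all(labels, scores)
        assert report.logauc == logauc_range(labels, scores)
        assert report.bedroc == bedroc(labels, scores)
        assert report.ef_k == enrichment_factor(labels, scores)
        assert report.dcg_k == dcg_at_k(labels, scores)

    def test_monotone_score_transform_invariance(self):
        rng = np.random.default_rng(9)
        labels = (rng.random(400) < 0.1).astype(int)
        labels[:2] = [1, 0]
        scores = rng.random(400)
        base = evaluate_all(labels, scores)
        for transform in (lambda s: 3 * s + 1, np.exp,
                          lambda s: np.arctan(s) - 5):
            other = evaluate_all(labels, transform(scores))
            for key, value in base.as_dict().items():
                assert other.as_dict()[key] == pytest.approx(value, abs=1e-9)

    def test_degenerate_labels_single_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            evaluate_all(np.ones(200, int), np.linspace(0, 1, 200))
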