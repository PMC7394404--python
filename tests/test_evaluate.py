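import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from misvote.evaluate import (
    ConfusionCounts,
    auc_score,
    confusion,
    handle_missing_scores,
    metric_panel,
    model_concordance,
    repeated_balanced_eval,
    score_distribution_export,
)


def brute_force_auc(labels, scores):
    """All-pairs AUC: ties between a positive and a negative count 0.5."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_total_disagreement(self):
        c = confusion([1, 0], [0, 1])
        assert (c.FN, c.FP, c.TP, c.TN) == (1, 1, 0, 0)

    def test_constructed_counts(self):
        labels = [1] * 10 + [0] * 10
        classes = [1] * 9 + [0] + [0] * 8 + [1] * 2
        c = confusion(labels, classes)
        assert (c.TP, c.TN, c.FP, c.FN) == (9, 8, 2, 1)
        assert c.total == 20

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetricPanel:
    def test_hand_arithmetic_example(self):
        """TP=9 TN=8 FP=2 FN=1: closed forms checked by hand."""
        r = metric_panel(ConfusionCounts(TP=9, FP=2, TN=8, FN=1))
        assert r.sensitivity == pytest.approx(0.9)
        assert r.specificity == pytest.approx(0.8)
        assert r.precision == pytest.approx(9 / 11)
        assert r.dor == pytest.approx(36.0)
        assert r.mcc == pytest.approx(70 / math.sqrt(9900))
        assert r.f1 == pytest.approx(2 * (9 / 11) * 0.9 / ((9 / 11) + 0.9))
        assert r.fpr == pytest.approx(0.2)
        assert r.fnr == pytest.approx(0.1)

    def test_perfect_separation(self):
        labels = np.array([1] * 5 + [0] * 5)
        scores = np.array([0.9] * 5 + [0.1] * 5)
        r = metric_panel(confusion(labels, (scores > 0.5).astype(int)), scores, labels)
        assert r.auc == 1.0 and r.mcc == 1.0

    def test_inverted_classifier_mcc_minus_one(self):
        labels = np.array([1] * 5 + [0] * 5)
        classes = 1 - labels
        assert metric_panel(confusion(labels, classes)).mcc == -1.0

    def test_dor_infinite_with_zero_errors(self):
        r = metric_panel(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert r.dor == float("inf")

    def test_zero_denominator_reported_as_nan(self):
        # no predicted positives: precision undefined, not 0
        r = metric_panel(ConfusionCounts(TP=0, FP=0, TN=5, FN=5))
        assert math.isnan(r.precision)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metric_panel(ConfusionCounts(0, 0, 0, 0))

    def test_hard_label_log_loss_tracks_error_rate(self):
        # 2 errors in 20 at eps=1e-15: loss = 0.1 * -ln(1e-15) ~ 3.45
        r = metric_panel(ConfusionCounts(TP=9, FP=1, TN=9, FN=1), log_loss_mode="hard")
        assert r.log_loss == pytest.approx(0.1 * -math.log(1e-15), rel=1e-6)

    def test_oracle_equivalence_random_instances(self):
        """Panel matches direct closed forms and all-pairs AUC to 1e-12."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(10, 201))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            classes = (scores > 0.5).astype(int)
            c = confusion(labels, classes)
            r = metric_panel(c, scores, labels)
            tp = int(((labels == 1) & (classes == 1)).sum())
            fp = int(((labels == 0) & (classes == 1)).sum())
            tn = int(((labels == 0) & (classes == 0)).sum())
            fn = int(((labels == 1) & (classes == 0)).sum())
            assert r.auc == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)
            if tp + fn:
                assert r.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
            if tn + fp:
                assert r.specificity == pytest.approx(tn / (tn + fp), abs=1e-12)
            den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            if den:
                assert r.mcc == pytest.approx((tp * tn - fp * fn) / den, abs=1e-12)
            expected_ll = -np.mean(
                labels * np.log(np.clip(scores, 1e-15, 1 - 1e-15))
                + (1 - labels) * np.log(np.clip(1 - scores, 1e-15, 1))
            )
            assert r.log_loss == pytest.approx(expected_ll, abs=1e-10)

    def test_dor_identity_with_rates(self):
        r = metric_panel(ConfusionCounts(TP=40, FP=7, TN=35, FN=9))
        expected = (r.sensitivity / (1 - r.sensitivity)) * (
            r.specificity / (1 - r.specificity)
        )
        assert r.dor == pytest.approx(expected)


class TestAucInvariances:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, width=32), min_size=4, max_size=60))
    def test_monotone_transform_invariance(self, scores):
        scores = np.asarray(scores)
        labels = (np.arange(len(scores)) % 2).astype(int)
        a1 = auc_score(labels, scores)
        a2 = auc_score(labels, np.exp(3 * scores) - 0.5)
        assert a1 == pytest.approx(a2, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_label_swap_score_flip_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = rng.random(n)
        a1 = auc_score(labels, scores)
        a2 = auc_score(1 - labels, 1 - scores)
        assert a1 == pytest.approx(a2, abs=1e-12)
        # swapping everything leaves the confusion structure identical
        c1 = confusion(labels, (scores > 0.5).astype(int))
        c2 = confusion(1 - labels, (1 - scores > 0.5).astype(int))
        m1 = metric_panel(c1).mcc
        m2 = metric_panel(c2).mcc
        if not (math.isnan(m1) or math.isnan(m2)):
            assert m1 == pytest.approx(m2, abs=1e-12)


class TestRepeatedBalancedEval:
    def _pools(self, rng):
        del_scores = rng.beta(5, 2, 40)
        return del_scores, {"<0.01": rng.beta(2, 5, 200), "<0.001": rng.beta(2, 5, 120)}

    def test_reproducible_under_seed(self, rng):
        d, pools = self._pools(rng)
        r1 = repeated_balanced_eval(d, pools, n_rep=5, seed=3)
        r2 = repeated_balanced_eval(d, pools, n_rep=5, seed=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_indistinguishable_classes_auc_half(self, rng):
        d = rng.random(50)
        out = repeated_balanced_eval(d, {"clone": d.copy()}, n_rep=1, seed=0)
        auc = out.loc[out.metric == "auc", "mean"].item()
        # the clone pool contains the same scores; AUC hovers at chance
        assert 0.35 < auc < 0.65

    def test_single_rep_sd_is_zero(self, rng):
        d, pools = self._pools(rng)
        out = repeated_balanced_eval(d, pools, n_rep=1, seed=1)
        assert (out["sd"] == 0).all()

    def test_insufficient_pool_names_bin(self, rng):
        d = rng.random(50)
        with pytest.raises(ValueError, match="tiny"):
            repeated_balanced_eval(d, {"tiny": rng.random(10)}, n_rep=2, seed=0)


class TestHandleMissingScores:
    def test_partial_missingness(self):
        df = pd.DataFrame(
            {"toolA": [1.0] * 10, "toolB": [1.0] * 8 + [np.nan] * 2}
        )
        kept, report = handle_missing_scores(df, ["toolA", "toolB"])
        assert len(kept) == 8
        assert report == {"toolA": 0.0, "toolB": pytest.approx(20.0)}

    def test_no_missingness_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        kept, report = handle_missing_scores(df, ["a"])
        pd.testing.assert_frame_equal(kept, df)

    def test_all_missing_empties_table(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        kept, report = handle_missing_scores(df, ["a", "b"])
        assert len(kept) == 0 and report["a"] == 100.0


class TestModelConcordance:
    def test_identical_vectors(self):
        out = model_concordance([1, 0, 1], [1, 0, 1], [1, 0, 0])
        assert out == {"overall": 100.0, "positives": 100.0, "negatives": 100.0}

    def test_complementary_vectors(self):
        out = model_concordance([1, 0], [0, 1], [1, 0])
        assert out["overall"] == 0.0

    def test_partial_agreement_counting(self):
        a = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        b = [1, 1, 1, 1, 0, 1, 0, 0, 0, 0]
        y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        out = model_concordance(a, b, y)
        assert out["overall"] == pytest.approx(80.0)
        assert out["positives"] == pytest.approx(80.0)
        assert out["negatives"] == pytest.approx(80.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            model_concordance([1], [1, 0], [1, 0])


class TestScoreDistributionExport:
    def test_rows_and_classes(self, tmp_path):
        path = tmp_path / "dist.tsv"
        df = score_distribution_export([0.9, 0.4, 0.6, 0.1], [1, 0, 0, 1], 0.5, path)
        assert len(df) == 4
        assert list(df["predicted_class"]) == [
            "deleterious", "benign", "deleterious", "benign",
        ]
        assert list(df["true_class"]) == ["deleterious", "benign", "benign", "deleterious"]

    def test_empty_input_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        score_distribution_export([], [], 0.5, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("score")

    def test_threshold_column_constant(self, tmp_path):
        df = score_distribution_export([0.2, 0.8], [0, 1], 0.42, tmp_path / "t.tsv")
        assert (df["threshold"] == 0.42).all()
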