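"""Confusion tables, the five per-class metrics and their invariants."""

import numpy as np
import pytest

from rtcb import evaluation
from rtcb.evaluation import (ConfusionTable, accuracy_delta, confusion,
                             metric_correlation, overall_accuracy,
                             per_class_metrics, read_counts_csv, report,
                             round_half_up)

CLASSES5 = ("botrytis", "rust", "blight", "purple", "healthy")

# published per-class test-set totals and correct counts for four models
TOTALS = dict(botrytis=392, rust=375, blight=325, purple=358, healthy=369)
CORRECT = {
    "OverLoCK-S": dict(botrytis=386, rust=371, blight=312, purple=346,
                       healthy=368),
    "EfficientFormer": dict(botrytis=384, rust=369, blight=311, purple=345,
                            healthy=368),
    "MobileMamba": dict(botrytis=386, rust=371, blight=314, purple=349,
                        healthy=366),
    "Proposed": dict(botrytis=390, rust=373, blight=318, purple=350,
                     healthy=368),
}
PRINTED = {"OverLoCK-S": 98.02, "EfficientFormer": 97.69,
           "MobileMamba": 98.19, "Proposed": 98.90}


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        ct = confusion([0, 1, 2, 1], [0, 1, 2, 1], 3)
        np.testing.assert_array_equal(ct.counts, np.diag([1, 2, 1]))

    def test_single_offdiagonal_sample(self):
        ct = confusion(preds=[4], labels=[2], classes=5)
        assert ct.counts[2, 4] == 1 and ct.counts.sum() == 1

    def test_matches_pair_counting_oracle(self, rng):
        labels = rng.integers(0, 4, 200)
        preds = rng.integers(0, 4, 200)
        ct = confusion(preds, labels, 4)
        for i in range(4):
            for j in range(4):
                tally = sum(1 for t, p in zip(labels, preds)
                            if t == i and p == j)
                assert ct.counts[i, j] == tally

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion([5], [0], 5)


class TestOverallAccuracy:
    @pytest.mark.parametrize("model,printed", PRINTED.items())
    def test_published_test_set_accuracies(self, model, printed):
        ct = ConfusionTable.from_class_counts(TOTALS, CORRECT[model])
        assert round_half_up(100 * overall_accuracy(ct), 2) == printed

    def test_identity_table_is_perfect(self):
        ct = ConfusionTable(np.diag([3, 4, 5]), ("a", "b", "c"))
        assert overall_accuracy(ct) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            overall_accuracy(ConfusionTable(np.zeros((2, 2)), ("a", "b")))


class TestPerClassMetrics:
    def test_diagonal_table_all_ones(self):
        mt = per_class_metrics(ConfusionTable(np.diag([5, 7, 9]),
                                              ("a", "b", "c")))
        for c in ("a", "b", "c"):
            for m in evaluation.METRIC_NAMES:
                assert mt.per_class[c][m] == 1.0
        assert mt.overall_accuracy == 1.0

    def test_never_predicted_class_flagged(self):
        counts = np.array([[0, 3], [0, 5]])
        with pytest.warns(RuntimeWarning, match="undefined"):
            mt = per_class_metrics(ConfusionTable(counts, ("a", "b")))
        assert np.isnan(mt.per_class["a"]["precision"])
        assert mt.per_class["a"]["sensitivity"] == 0.0
        assert ("a", "precision") in mt.undefined

    def test_matches_one_vs_rest_recount(self, rng):
        counts = rng.integers(1, 30, (3, 3))
        ct = ConfusionTable(counts, ("x", "y", "z"))
        mt = per_class_metrics(ct)
        total = counts.sum()
        for i, c in enumerate(ct.classes):
            tp = counts[i, i]
            fp = sum(counts[r, i] for r in range(3) if r != i)
            fn = sum(counts[i, r] for r in range(3) if r != i)
            tn = total - tp - fp - fn
            assert mt.per_class[c]["precision"] == pytest.approx(tp / (tp + fp))
            assert mt.per_class[c]["sensitivity"] == pytest.approx(tp / (tp + fn))
            assert mt.per_class[c]["specificity"] == pytest.approx(tn / (tn + fp))
            p, r = tp / (tp + fp), tp / (tp + fn)
            assert mt.per_class[c]["f1"] == pytest.approx(2 * p * r / (p + r))
            assert mt.per_class[c]["accuracy"] == pytest.approx((tp + tn) / total)

    def test_specificity_equals_complement_sensitivity(self, rng):
        """Specificity of class i = sensitivity of the merged not-i class in
        the 2-class collapse."""
        counts = rng.integers(0, 25, (4, 4)) + np.eye(4, dtype=int)
        ct = ConfusionTable(counts, ("a", "b", "c", "d"))
        mt = per_class_metrics(ct)
        for i, c in enumerate(ct.classes):
            rest = [r for r in range(4) if r != i]
            collapsed_tp = counts[np.ix_(rest, rest)].sum()
            collapsed_fn = counts[rest, i].sum()
            expected = collapsed_tp / (collapsed_tp + collapsed_fn)
            assert mt.per_class[c]["specificity"] == pytest.approx(expected)

    def test_metric_bounds(self, rng):
        counts = rng.integers(0, 40, (5, 5)) + np.eye(5, dtype=int)
        mt = per_class_metrics(ConfusionTable(counts, CLASSES5))
        vals = mt.matrix()
        finite = vals[~np.isnan(vals)]
        assert (finite >= 0).all() and (finite <= 1).all()


class TestAccuracyDelta:
    def test_published_improvement(self):
        a = overall_accuracy(ConfusionTable.from_class_counts(
            TOTALS, CORRECT["Proposed"]))
        b = overall_accuracy(ConfusionTable.from_class_counts(
            TOTALS, CORRECT["EfficientFormer"]))
        assert accuracy_delta(a, b) == 1.21

    def test_equal_inputs_zero(self):
        assert accuracy_delta(0.5, 0.5) == 0.0

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.random(2)
            assert accuracy_delta(a, b) == pytest.approx(-accuracy_delta(b, a),
                                                         abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            accuracy_delta(1.2, 0.5)


class TestMetricCorrelation:
    def test_duplicated_column_perfectly_correlated(self, rng):
        col = rng.random(6)
        m = np.column_stack([col, col, rng.random(6)])
        corr = metric_correlation(m)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_negated_column_anticorrelated(self, rng):
        col = rng.random(6)
        corr = metric_correlation(np.column_stack([col, -col]))
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        m = rng.random((6, 5))
        corr = metric_correlation(m)
        for i in range(5):
            for j in range(5):
                xi, xj = m[:, i], m[:, j]
                cov = ((xi - xi.mean()) * (xj - xj.mean())).mean()
                expected = cov / (xi.std() * xj.std())
                assert corr[i, j] == pytest.approx(expected, abs=1e-10)

    def test_symmetric_psd_unit_diagonal(self, rng):
        corr = metric_correlation(rng.random((8, 5)))
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        eigs = np.linalg.eigvalsh(corr)
        assert eigs.min() > -1e-8

    def test_zero_variance_column_flagged(self, rng):
        m = np.column_stack([np.full(5, 0.3), rng.random(5)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            corr = metric_correlation(m)
        assert np.isnan(corr[0, 1]) and np.isnan(corr[0, 0])
        assert corr[1, 1] == 1.0

    def test_degenerate_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            metric_correlation(rng.random((1, 5)))


class TestReport:
    def test_files_and_marginal_roundtrip(self, tmp_path, rng):
        labels = rng.integers(0, 5, 300)
        preds = rng.integers(0, 5, 300)
        ct = confusion(preds, labels, CLASSES5)
        mt = per_class_metrics(ct)
        corr = metric_correlation(mt.matrix())
        paths = report(ct, mt, tmp_path, corr=corr)
        for key in ("counts", "confusion", "metrics", "correlation"):
            assert paths[key].exists(), key
        totals, correct = read_counts_csv(paths["counts"])
        for i, c in enumerate(CLASSES5):
            assert totals[c] == int(ct.counts[i].sum())
            assert correct[c] == int(ct.counts[i, i])
        # Cor + Inc == Tot in every written row
        import csv
        with open(paths["counts"]) as fh:
            for row in csv.DictReader(fh):
                assert int(row["Cor"]) + int(row["Inc"]) == int(row["Tot"])

    def test_optional_plots_rendered(self, tmp_path, rng):
        labels = rng.integers(0, 5, 50)
        ct = confusion(labels, labels, CLASSES5)
        mt = per_class_metrics(ct)
        paths = report(ct, mt, tmp_path, corr=None, plots=True)
        assert paths["radar"].exists()
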