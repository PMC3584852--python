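from collections import Counter

import numpy as np
import pytest

import textfunc as tf
from textfunc.classify import Prediction


def _labels(spec):
    """spec: class_id -> count; returns single-label protein map."""
    labels = {}
    for cid, count in spec.items():
        for i in range(count):
            labels[f"{cid}_{i:03d}"] = frozenset({cid})
    return labels


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        folds = tf.stratified_folds(_labels({"A": 100}), k=5, seed=0)
        assert sorted(len(f) for f in folds) == [20] * 5

    def test_class_of_seven_pigeonholes(self):
        folds = tf.stratified_folds(_labels({"A": 7}), k=5, seed=1)
        assert sorted(len(f) for f in folds) == [1, 1, 1, 2, 2]

    def test_partition_property(self):
        labels = _labels({"A": 33, "B": 17, "C": 50})
        folds = tf.stratified_folds(labels, k=5, seed=3)
        union = set().union(*folds)
        assert union == set(labels)
        assert sum(len(f) for f in folds) == len(labels)

    @pytest.mark.parametrize("seed", range(5))
    def test_per_class_counts_differ_by_at_most_one(self, seed):
        labels = _labels({"A": 41, "B": 23, "C": 98, "D": 15})
        folds = tf.stratified_folds(labels, k=5, seed=seed)
        for cid in "ABCD":
            counts = [sum(1 for p in f if cid in labels.get(p, ())) for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_seed_reproducible(self):
        labels = _labels({"A": 30, "B": 30})
        assert tf.stratified_folds(labels, 5, 9) == tf.stratified_folds(labels, 5, 9)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            tf.stratified_folds(_labels({"A": 10}), k=1, seed=0)


def _preds(pairs, confidence=0.9):
    return [Prediction(pid, cid, 3, confidence) for pid, cid in pairs]


class TestPerClassMetrics:
    def test_perfect_predictions(self):
        truth = _labels({"A": 3, "B": 2})
        preds = _preds([(p, next(iter(ls))) for p, ls in truth.items()])
        for m in tf.per_class_metrics(preds, truth, ["A", "B"]):
            assert m.precision == m.recall == m.f_measure == 1.0

    def test_no_predictions_boundary_conventions(self):
        truth = _labels({"A": 3, "B": 2})
        for m in tf.per_class_metrics([], truth, ["A", "B"]):
            assert m.precision == 0.0 and m.recall == 0.0 and m.f_measure == 0.0
            assert m.specificity == 1.0

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValueError):
            tf.per_class_metrics(_preds([("ghost", "A")]), _labels({"A": 2}), ["A"])

    def test_matches_confusion_tally_oracle(self):
        rng = np.random.default_rng(17)
        classes = ["A", "B", "C"]
        truth = {
            f"P{i}": frozenset(rng.choice(classes, size=rng.integers(1, 3),
                                          replace=False))
            for i in range(60)
        }
        preds = [
            Prediction(f"P{i}", rng.choice(classes), 3, 0.5)
            for i in range(60)
            if rng.random() < 0.8
        ]
        metrics = {m.class_id: m for m in tf.per_class_metrics(preds, truth, classes)}
        predicted = {}
        for p in preds:
            predicted.setdefault(p.protein_id, set()).add(p.class_id)
        for c in classes:
            tally = Counter()
            for pid, ls in truth.items():
                hit, present = c in predicted.get(pid, set()), c in ls
                tally["tp" if hit and present else
                      "fp" if hit else "fn" if present else "tn"] += 1
            m = metrics[c]
            assert (m.tp, m.fp, m.fn, m.tn) == (
                tally["tp"], tally["fp"], tally["fn"], tally["tn"]
            )
            assert m.tp + m.fp + m.fn + m.tn == len(truth)


class TestOverallAccuracy:
    def test_all_correct(self):
        truth = _labels({"A": 4})
        preds = _preds([(p, "A") for p in truth])
        assert tf.overall_accuracy(preds, truth) == 1.0

    def test_no_predictions(self):
        assert tf.overall_accuracy([], _labels({"A": 4})) == 0.0

    def test_three_of_five_correct(self):
        truth = _labels({"A": 5})
        pids = sorted(truth)
        preds = _preds([(p, "A") for p in pids[:3]] + [(p, "B") for p in pids[3:]])
        assert tf.overall_accuracy(preds, truth) == 0.6

    def test_any_overlap_vs_all_mode(self):
        truth = {"P1": frozenset({"A", "B"})}
        preds = _preds([("P1", "A")])
        assert tf.overall_accuracy(preds, truth, "any") == 1.0
        assert tf.overall_accuracy(preds, truth, "all") == 0.0

    def test_empty_test_set_errors(self):
        with pytest.raises(ValueError):
            tf.overall_accuracy([], {})


class TestThresholdSweep:
    def _random_predictions(self, truth, rng):
        return [
            Prediction(pid, cid, 3, float(rng.random()))
            for pid in truth
            for cid in ("A", "B")
            if rng.random() < 0.7
        ]

    def test_boundaries(self):
        truth = _labels({"A": 5, "B": 5})
        rng = np.random.default_rng(0)
        preds = self._random_predictions(truth, rng)
        reports = tf.threshold_sweep(preds, [0.0, 1.0], truth, ["A", "B"])
        kept_at_zero = sum(m.tp + m.fp for m in reports[0].per_class)
        assert kept_at_zero == len(preds)  # confidences are strictly > 0 here
        assert all(m.tp + m.fp == 0 for m in reports[1].per_class)

    def test_monotone_in_threshold(self):
        truth = _labels({"A": 20, "B": 20})
        rng = np.random.default_rng(8)
        preds = self._random_predictions(truth, rng)
        grid = sorted({p.confidence for p in preds}) + [1.0]
        reports = tf.threshold_sweep(preds, grid, truth, ["A", "B"])
        kept = [sum(m.tp + m.fp for m in r.per_class) for r in reports]
        recalls = {
            c: [next(m for m in r.per_class if m.class_id == c).recall for r in reports]
            for c in ("A", "B")
        }
        assert kept == sorted(kept, reverse=True)
        for series in recalls.values():
            assert series == sorted(series, reverse=True)


class TestCrossValidate:
    def test_text_knn_on_small_fixture(self, small_dataset):
        result = tf.cross_validate(
            small_dataset.labels, small_dataset.docs(), seed=2, k_folds=5
        )
        assert result.mean_overall_accuracy > 0.8
        assert len(result.reports) == 5

    def test_bit_reproducible_under_master_seed(self, small_dataset):
        run = lambda: tf.cross_validate(
            small_dataset.labels, small_dataset.docs(), seed=5, k_folds=5
        )
        a, b = run(), run()
        assert a.mean_overall_accuracy == b.mean_overall_accuracy
        for ra, rb in zip(a.reports, b.reports):
            assert [(m.tp, m.fp, m.fn, m.tn) for m in ra.per_class] == [
                (m.tp, m.fp, m.fn, m.tn) for m in rb.per_class
            ]

    def test_base_prior_runs(self, small_dataset):
        result = tf.cross_validate(
            small_dataset.labels, small_dataset.docs(),
            classifier="base_prior", seed=2,
        )
        # a 3-class prior fixture: accuracy near sum of squared priors
        assert 0.15 < result.mean_overall_accuracy < 0.55

    def test_base_seq_requires_sequences(self, small_dataset):
        with pytest.raises(ValueError):
            tf.cross_validate(
                small_dataset.labels, small_dataset.docs(), classifier="base_seq"
            )

    def test_repeats_use_distinct_folds(self, small_dataset):
        result = tf.cross_validate(
            small_dataset.labels, small_dataset.docs(), seed=2, repeats=2
        )
        assert len(result.reports) == 10
        assert {r.repeat_id for r in result.reports} == {0, 1}
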