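"""Stratified sampling, metrics, and the nested-CV learning-curve engine."""

import numpy as np
import pandas as pd
import pytest

from subtypecurves import (ClassifierSpec, ConfigurationError, CurveConfig,
                           DatasetDef, StructuralError, evaluate_round,
                           metrics, normalize_counts, run_learning_curve,
                           stratified_split, stratified_subsample,
                           summarize_records)

from _oracles import largest_remainder


def _labels(counts: dict) -> pd.Series:
    values = [c for c, n in counts.items() for _ in range(n)]
    return pd.Series(values, index=[f"S{i}" for i in range(len(values))])


class TestStratifiedSplit:
    def test_reference_cohort_ten_percent_apportionment(self):
        """132/65/393/190/105 at 10% gives a test set of 89 split
        13/7/39/19/11 — the largest-remainder apportionment by hand."""
        labels = _labels({"Basal": 132, "Her2": 65, "LumA": 393,
                          "LumB": 190, "Normal": 105})
        train, test = stratified_split(labels, 0.10, seed=0)
        test_counts = labels.loc[test].value_counts()
        assert len(test) == 89
        assert [test_counts[c] for c in ("Basal", "Her2", "LumA", "LumB", "Normal")] \
            == [13, 7, 39, 19, 11]
        assert largest_remainder(89, [132, 65, 393, 190, 105]) == [13, 7, 39, 19, 11]
        assert set(train) | set(test) == set(labels.index)
        assert not set(train) & set(test)

    def test_zero_fraction_gives_empty_test(self):
        labels = _labels({"a": 10, "b": 5})
        train, test = stratified_split(labels, 0.0, seed=1)
        assert test == [] and len(train) == 15

    def test_two_balanced_classes_get_one_each(self):
        labels = _labels({"a": 10, "b": 10})
        _, test = stratified_split(labels, 0.10, seed=2)
        assert sorted(labels.loc[test]) == ["a", "b"]


class TestStratifiedSubsample:
    def test_full_pool_returns_everything(self):
        labels = _labels({"a": 8, "b": 4})
        pool = list(labels.index)
        assert stratified_subsample(pool, labels, 12, seed=0) == pool

    def test_subset_tracks_pool_proportions(self):
        labels = _labels({"Basal": 119, "Her2": 58, "LumA": 354,
                          "LumB": 171, "Normal": 94})
        pool = list(labels.index)
        sub = stratified_subsample(pool, labels, 100, seed=3)
        counts = labels.loc[sub].value_counts()
        assert counts.sum() == 100
        for cls, n_cls in labels.value_counts().items():
            assert abs(counts.get(cls, 0) - 100 * n_cls / len(labels)) <= 1

    def test_seed_determinism_and_pool_membership(self):
        labels = _labels({"a": 30, "b": 20})
        pool = list(labels.index)[5:]
        first = stratified_subsample(pool, labels, 20, seed=7)
        second = stratified_subsample(pool, labels, 20, seed=7)
        assert first == second and set(first) <= set(pool)

    def test_oversized_request_is_rejected(self):
        labels = _labels({"a": 4})
        with pytest.raises(ConfigurationError):
            stratified_subsample(list(labels.index), labels, 9, seed=0)


class TestMetrics:
    def test_perfect_prediction(self):
        y = ["LumA", "Basal", "Her2", "Normal", "LumB"]
        m = metrics(y, y)
        assert m.accuracy == 1.0 and m.balanced_accuracy == 1.0
        assert (np.diag(m.confusion.rates.to_numpy()) == 1.0).all()

    def test_balanced_accuracy_of_reported_confusion(self):
        """A confusion matrix with diagonal rates (0.902, 0.961, 0.901,
        0.832, 0.905) has balanced accuracy 0.9002 — realized here from
        label vectors rebuilt from the rates at 1000 samples per class."""
        rates = {
            "Her2": [0.902, 0.008, 0.022, 0.068, 0.0],
            "Basal": [0.038, 0.961, 0.0, 0.001, 0.0],
            "LumA": [0.018, 0.0, 0.901, 0.062, 0.02],
            "LumB": [0.031, 0.0, 0.137, 0.832, 0.0],
            "Normal": [0.018, 0.019, 0.04, 0.019, 0.905],
        }
        classes = ["Her2", "Basal", "LumA", "LumB", "Normal"]
        assert round(float(np.mean([rates[c][i] for i, c in
                                    enumerate(classes)])), 4) == 0.9002
        y_true, y_pred = [], []
        for true_cls, row in rates.items():
            for pred_cls, rate in zip(classes, row):
                n = round(rate * 1000)
                y_true += [true_cls] * n
                y_pred += [pred_cls] * n
        m = metrics(y_true, y_pred, classes=classes)
        assert abs(m.balanced_accuracy - 0.9002) < 1e-3
        # row-normalized rows sum to 1
        np.testing.assert_allclose(m.confusion.rates.sum(axis=1), 1.0, atol=1e-9)

    def test_majority_prediction_on_balanced_classes(self):
        y_true = ["a", "b", "c", "d", "e"] * 4
        m = metrics(y_true, ["a"] * 20)
        assert m.accuracy == pytest.approx(0.2)
        assert m.balanced_accuracy == pytest.approx(0.2)

    def test_balanced_equals_overall_on_balanced_test(self):
        rng = np.random.default_rng(0)
        y_true = np.array(["x"] * 30 + ["y"] * 30)
        y_pred = y_true.copy()
        flip = rng.choice(30, size=5, replace=False)
        y_pred[flip] = "y"
        y_pred[30 + flip] = "x"  # symmetric errors keep the test balanced
        m = metrics(y_true, y_pred)
        assert m.accuracy == pytest.approx(m.balanced_accuracy)

    def test_unknown_label_is_rejected(self):
        with pytest.raises(StructuralError):
            metrics(["a", "b"], ["a", "zzz"], classes=("a", "b"))


@pytest.fixture(scope="module")
def expr_labels(small_cohort):
    expr, _ = normalize_counts(small_cohort.counts)
    return expr, small_cohort.annotation["subtype"]


class TestEngine:
    def test_round_is_deterministic(self, expr_labels):
        expr, labels = expr_labels
        spec = ClassifierSpec("nsc", {"threshold": [0.0, 1.0]})
        a, _ = evaluate_round(expr, labels, 80, spec, round_seed=99, inner_folds=3)
        b, _ = evaluate_round(expr, labels, 80, spec, round_seed=99, inner_folds=3)
        assert a == b

    def test_separable_cohort_reaches_full_accuracy(self, expr_labels):
        expr, labels = expr_labels
        spec = ClassifierSpec("nsc", {"threshold": [0.0]})
        record, confusion = evaluate_round(expr, labels, 100, spec,
                                           round_seed=5, inner_folds=3)
        assert record["accuracy"] == 1.0
        assert np.trace(confusion.counts.to_numpy()) == confusion.counts.to_numpy().sum()

    def test_zero_effect_accuracy_tracks_largest_prior(self, null_cohort):
        """On a cohort with no class signal every classifier falls back to
        the majority class: accuracy stays within 3 SE of the largest
        class prior."""
        expr, _ = normalize_counts(null_cohort.counts)
        labels = null_cohort.annotation["subtype"]
        spec = ClassifierSpec("nsc", {"threshold": [0.0, 2.0, 4.0, 8.0]})
        accs, n_test = [], 0
        for r in range(10):
            record, confusion = evaluate_round(expr, labels, 100, spec,
                                               round_seed=700 + r, inner_folds=3)
            accs.append(record["accuracy"])
            n_test += confusion.counts.to_numpy().sum()
        prior = labels.value_counts(normalize=True).max()
        se = np.sqrt(prior * (1 - prior) / n_test)
        assert abs(np.mean(accs) - prior) <= 3 * se + 0.02

    def test_learning_curve_is_reproducible_and_skips_infeasible(self, small_cohort):
        config = CurveConfig(
            training_sizes=(60, 120, 500), n_rounds=2,
            classifier_specs=(ClassifierSpec("nsc", {"threshold": [0.0]}),),
            datasets=(("Panel", DatasetDef("informative_panel", panel_size=40)),),
            inner_folds=3, master_seed=13)
        with pytest.warns(UserWarning, match="infeasible"):
            first = run_learning_curve(small_cohort, config)
        with pytest.warns(UserWarning, match="infeasible"):
            second = run_learning_curve(small_cohort, config)
        pd.testing.assert_frame_equal(first.records, second.records)
        assert set(first.records["size"]) == {60, 120}  # 500 > pool, skipped
        assert ((first.records["accuracy"] >= 0) & (first.records["accuracy"] <= 1)).all()

    def test_single_round_summary_has_zero_sem(self):
        records = pd.DataFrame([{"dataset": "d", "depth": "full",
                                 "classifier": "nsc", "size": 50,
                                 "accuracy": 0.8, "balanced_accuracy": 0.7}])
        summary = summarize_records(records)
        assert summary.loc[0, "accuracy_sem"] == 0.0

    def test_sem_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(21)
        accs = rng.binomial(20, 0.8, size=100) / 20
        records = pd.DataFrame({
            "dataset": "d", "depth": "full", "classifier": "nsc",
            "size": 50, "accuracy": accs, "balanced_accuracy": accs})
        summary = summarize_records(records)
        assert summary.loc[0, "accuracy_sem"] == pytest.approx(
            np.std(accs, ddof=1) / np.sqrt(100), abs=1e-12)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            CurveConfig(training_sizes=(100, 100))
        with pytest.raises(ConfigurationError):
            CurveConfig(n_rounds=0)
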