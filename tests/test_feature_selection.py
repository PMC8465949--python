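"""Monte-Carlo splits, drop-one importance, consensus, rule extraction."""

import numpy as np
import pandas as pd
import pytest

from crsml import (
    ClassifierSpec,
    consensus_vote,
    default_classifier_specs,
    extract_simple_rule,
    mc_splits,
    run_harness,
)
from crsml.feature_selection import (
    ImportanceProfile,
    PerformanceSummary,
    _confusion_metrics,
    evaluate_feature_set,
    performance_summary,
)

FAST_SPECS = [ClassifierSpec("logistic_a"), ClassifierSpec("cart"),
              ClassifierSpec("naive_bayes")]


class TestMcSplits:
    def test_class_proportional_two_thirds(self):
        labels = np.array(["baseline"] * 90 + ["post"] * 90)
        splits = mc_splits(labels, runs=5, seed=1)
        for train, test in splits:
            assert train.size == 120 and test.size == 60
            assert (labels[train] == "baseline").sum() == 60
            assert (labels[test] == "baseline").sum() == 30
            assert np.intersect1d(train, test).size == 0
            assert np.union1d(train, test).size == 180

    def test_determinism_and_run_count(self):
        labels = np.array([0] * 30 + [1] * 30)
        a = mc_splits(labels, runs=3, seed=9)
        b = mc_splits(labels, runs=3, seed=9)
        assert all(np.array_equal(x[0], y[0]) and np.array_equal(x[1], y[1])
                   for x, y in zip(a, b))
        assert len(mc_splits(labels, runs=1, seed=0)) == 1

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            mc_splits(np.array([0, 0, 0, 1, 1]), runs=1, seed=0)


class TestMetrics:
    def test_hand_computed_confusion_matrix(self):
        # 30 test cases: TP 12, FN 3, TN 14, FP 1 -> 26 correct
        truth = np.array([1] * 15 + [0] * 15)
        pred = np.concatenate([np.ones(12), np.zeros(3), np.zeros(14), np.ones(1)])
        m = _confusion_metrics(truth, pred, None)
        assert m["sensitivity"] == pytest.approx(100 * 12 / 15)
        assert m["specificity"] == pytest.approx(100 * 14 / 15)
        assert m["ppv"] == pytest.approx(100 * 12 / 13)
        assert m["npv"] == pytest.approx(100 * 14 / 17)
        assert m["f1"] == pytest.approx(100 * 24 / (24 + 1 + 3))
        assert m["accuracy"] == pytest.approx(100 * 26 / 30)
        assert m["balanced_accuracy"] == pytest.approx(
            (m["sensitivity"] + m["specificity"]) / 2)

    def test_perfect_and_inverted_predictions(self):
        truth = np.array([1, 1, 0, 0])
        perfect = _confusion_metrics(truth, truth.copy(), truth.astype(float))
        assert all(perfect[k] == 100.0 for k in
                   ("sensitivity", "specificity", "accuracy", "roc_auc"))
        inverted = _confusion_metrics(truth, 1 - truth, None)
        assert inverted["accuracy"] == 0.0

    def test_single_class_run_excluded(self):
        runs = [_confusion_metrics(np.array([1, 1]), np.array([1, 1]), None),
                _confusion_metrics(np.array([1, 0]), np.array([1, 0]), None)]
        assert runs[0] is None
        summary = performance_summary(runs)
        assert summary.n_runs == 1 and summary.n_excluded == 1

    def test_summary_percentiles_bracket_median(self, rng):
        runs = []
        for _ in range(100):
            truth = rng.integers(0, 2, 40)
            pred = np.where(rng.random(40) < 0.8, truth, 1 - truth)
            runs.append(_confusion_metrics(truth, pred, None))
        s = performance_summary(runs)
        for metric in ("accuracy", "f1"):
            assert s.ci_low(metric) <= s.median(metric) <= s.ci_high(metric)


class TestHarness:
    def _planted_design(self, seed, n_noise=9, shift=2.5, n_per_class=90):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_class
        y = np.array([1] * n_per_class + [0] * n_per_class)
        cols = {"signal": rng.standard_normal(n) + shift * y}
        for j in range(n_noise):
            cols[f"noise{j}"] = rng.standard_normal(n)
        return pd.DataFrame(cols), y

    def test_planted_signal_has_top_importance_for_every_classifier(self):
        design, y = self._planted_design(seed=13)
        splits = mc_splits(y, runs=20, seed=5)
        res = run_harness(design, y, default_classifier_specs(forest_trees=32),
                          splits, seed=2)
        for kind, (profile, _) in res.items():
            counts = dict(zip(profile.variables, profile.a_counts))
            assert counts["signal"] == max(counts.values()), kind
            assert profile.selected[0] == "signal", kind

    def test_planted_signal_wins_consensus_across_seeds(self):
        for seed in (3, 4, 5):
            design, y = self._planted_design(seed=seed)
            splits = mc_splits(y, runs=12, seed=seed)
            res = run_harness(design, y, FAST_SPECS, splits, seed=seed)
            cons = consensus_vote({k: v[0] for k, v in res.items()},
                                  {k: v[1] for k, v in res.items()})
            assert cons.selected[0] == "signal", seed

    def test_chance_level_without_signal(self, rng):
        n = 180
        y = np.array([1] * 90 + [0] * 90)
        design = pd.DataFrame({f"n{j}": rng.standard_normal(n) for j in range(5)})
        splits = mc_splits(y, runs=200, seed=8)
        res = evaluate_feature_set(design, y, list(design.columns),
                                   [ClassifierSpec("cart")], splits, seed=1)
        assert 45.0 <= res["cart"].median("accuracy") <= 55.0

    @pytest.mark.parametrize("kind", ["logistic_a", "naive_bayes"])
    def test_ignored_feature_has_zero_delta(self, kind):
        """A constant column carries no class information for models whose
        fit depends on each feature only through its class-conditional
        distribution, so withholding it leaves every run's accuracy
        unchanged (trees are excluded: their tie-breaking among the
        remaining features depends on column order)."""
        design, y = self._planted_design(seed=21, n_noise=2)
        design["dead"] = 1.0
        splits = mc_splits(y, runs=5, seed=3)
        res = run_harness(design, y, [ClassifierSpec(kind)], splits, seed=0)
        profile = res[kind][0]
        j = profile.variables.index("dead")
        assert np.all(profile.delta_acc[:, j] == 0.0)

    def test_single_variable_short_circuit(self):
        design, y = self._planted_design(seed=2, n_noise=0)
        splits = mc_splits(y, runs=4, seed=1)
        res = run_harness(design[["signal"]], y, [ClassifierSpec("cart")],
                          splits, seed=0)
        profile = res["cart"][0]
        assert profile.selected == ("signal",)
        assert profile.modal_a_size == 1

    def test_determinism(self):
        design, y = self._planted_design(seed=6, n_noise=3)
        splits = mc_splits(y, runs=4, seed=2)
        r1 = run_harness(design, y, FAST_SPECS, splits, seed=11)
        r2 = run_harness(design, y, FAST_SPECS, splits, seed=11)
        for kind in r1:
            assert np.array_equal(r1[kind][0].delta_acc, r2[kind][0].delta_acc)
            assert r1[kind][0].selected == r2[kind][0].selected


class TestConsensus:
    def _profile(self, variables, counts, kind):
        return ImportanceProfile(kind=kind, variables=tuple(variables),
                                 delta_acc=np.zeros((1, len(variables))),
                                 a_counts=np.asarray(counts, float),
                                 modal_a_size=1, selected=(variables[0],))

    def _summary(self, median_bal, ci_low):
        table = pd.DataFrame(
            {"median": {"balanced_accuracy": median_bal, "accuracy": median_bal},
             "ci_low": {"balanced_accuracy": ci_low, "accuracy": ci_low},
             "ci_high": {"balanced_accuracy": 100.0, "accuracy": 100.0}})
        return PerformanceSummary(table=table, n_runs=10)

    def test_chance_level_voters_are_silenced(self):
        vars_ = ("a", "b", "c")
        profiles = {"good": self._profile(vars_, [10, 0, 0], "cart"),
                    "bad": self._profile(vars_, [0, 10, 10], "knn")}
        summaries = {"good": self._summary(85.0, 70.0),
                     "bad": self._summary(50.0, 40.0)}
        cons = consensus_vote(profiles, summaries)
        assert cons.selected == ("a",)
        assert cons.weights["bad"] == 0.0

    def test_unanimous_single_variable(self):
        vars_ = ("a", "b", "c")
        profiles = {k: self._profile(vars_, [9, 1, 0], k)
                    for k in ("cart", "knn")}
        summaries = {k: self._summary(80.0, 65.0) for k in ("cart", "knn")}
        assert consensus_vote(profiles, summaries).selected[0] == "a"

    def test_all_chance_flags_empty_selection(self):
        vars_ = ("a", "b", "c")
        profiles = {"cart": self._profile(vars_, [5, 5, 5], "cart")}
        summaries = {"cart": self._summary(50.0, 42.0)}
        cons = consensus_vote(profiles, summaries)
        assert cons.selected == () and cons.chance_level


class TestSimpleRule:
    def test_perfect_separation(self):
        design = pd.DataFrame({"f": [0.0] * 40 + [10.0] * 40})
        y = np.array([0] * 40 + [1] * 40)
        rule, summary = extract_simple_rule(design, y, "f", seed=4)
        assert 0 < rule.threshold < 10
        assert summary["median_accuracy"] == 100.0
        assert (summary["ci_low"], summary["ci_high"]) == (100.0, 100.0)

    def test_uninformative_feature_straddles_chance(self, rng):
        design = pd.DataFrame({"f": rng.standard_normal(200)})
        y = np.array([0, 1] * 100)
        _, summary = extract_simple_rule(design, y, "f", seed=6)
        assert summary["ci_low"] <= 50.0 <= summary["ci_high"]

    def test_constant_feature_rejected(self):
        design = pd.DataFrame({"f": np.ones(20)})
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="constant"):
            extract_simple_rule(design, y, "f", seed=0)

    def test_rule_predicts_with_stated_threshold(self):
        design = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6, 7, 8] * 5})
        y = np.array(([0] * 4 + [1] * 4) * 5)
        rule, _ = extract_simple_rule(design, y, "f", seed=1)
        pred = rule.predict([rule.threshold - 1, rule.threshold + 1])
        assert pred[0] != pred[1]
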