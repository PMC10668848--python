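"""Open-set metrics against brute-force oracles, plus decision-rule and
aggregation semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from openherd.evaluation import (
    MetricReport,
    OpennessConfig,
    UndefinedMetricError,
    aggregate,
    auroc,
    closed_set_report,
    csa,
    decide,
    openness,
    oscr,
)


def make_table(known_scores, unknown_scores, predicted=None, true=None):
    """Assemble a score table; by default all known predictions are correct."""
    n_k, n_u = len(known_scores), len(unknown_scores)
    if true is None:
        true = [f"k{i % 3}" for i in range(n_k)]
    if predicted is None:
        predicted = list(true)
    return pd.DataFrame({
        "known_score": list(known_scores) + list(unknown_scores),
        "predicted_label": predicted + ["k0"] * n_u,
        "true_label": true + [f"u{i}" for i in range(n_u)],
        "is_known": [True] * n_k + [False] * n_u,
    })


def random_table(rng, max_n=12):
    """Small random score table with deliberate ties and wrong predictions."""
    n_k = int(rng.integers(1, max_n - 1))
    n_u = int(rng.integers(1, max_n - n_k))
    scores_k = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], n_k) + rng.normal(0, 0.3, n_k) * (
        rng.random(n_k) < 0.5)
    scores_u = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], n_u) + rng.normal(0, 0.3, n_u) * (
        rng.random(n_u) < 0.5)
    true = [f"k{i}" for i in rng.integers(0, 3, n_k)]
    predicted = [t if rng.random() < 0.7 else f"k{rng.integers(0, 3)}" for t in true]
    return make_table(scores_k, scores_u, predicted=predicted, true=true)


def auroc_oracle(table):
    ks = table.loc[table["is_known"], "known_score"].to_numpy()
    us = table.loc[~table["is_known"], "known_score"].to_numpy()
    wins = sum(1.0 if k > u else 0.5 if k == u else 0.0 for k in ks for u in us)
    return wins / (len(ks) * len(us)) * 100.0


def oscr_oracle(table):
    scores = table["known_score"].to_numpy()
    known = table["is_known"].to_numpy()
    correct = (table["predicted_label"] == table["true_label"]).to_numpy()
    n_k, n_u = known.sum(), (~known).sum()
    area, prev_fpr = 0.0, 0.0
    for s in sorted(set(scores), reverse=True):
        ccr = sum(1 for i in range(len(scores))
                  if known[i] and correct[i] and scores[i] >= s) / n_k
        fpr = sum(1 for i in range(len(scores))
                  if not known[i] and scores[i] >= s) / n_u
        area += ccr * (fpr - prev_fpr)
        prev_fpr = fpr
    return area * 100.0


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc(make_table([0.9, 0.8], [0.1, 0.2])) == 100.0

    def test_all_ties(self):
        assert auroc(make_table([0.5, 0.5], [0.5])) == 50.0

    def test_pairwise_example(self):
        assert auroc(make_table([0.9, 0.4], [0.6, 0.1])) == pytest.approx(75.0)

    def test_one_sided_table_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc(make_table([0.9], []))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = random_table(rng)
            before = auroc(t)
            t2 = t.copy()
            t2["known_score"] = np.exp(3.0 * t2["known_score"]) - 5.0
            assert auroc(t2) == pytest.approx(before, abs=1e-9)


class TestOSCR:
    def test_perfect(self):
        assert oscr(make_table([0.9, 0.8], [0.1])) == pytest.approx(100.0)

    def test_flat_at_classifier_accuracy(self):
        # perfect score separation, 60% of knowns correctly classified
        true = [f"k{i}" for i in range(5)]
        predicted = true[:3] + ["k0", "k1"]
        t = make_table([0.9, 0.85, 0.8, 0.75, 0.7], [0.1, 0.2],
                       predicted=predicted, true=true)
        assert oscr(t) == pytest.approx(60.0)

    def test_matches_enumeration_on_toy_table(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, max_n=8)
        assert oscr(t) == pytest.approx(oscr_oracle(t), abs=1e-9)

    def test_never_exceeds_csa(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            t = random_table(rng)
            assert oscr(t) <= csa(t) + 1e-9


def test_auroc_oscr_brute_force_equivalence():
    rng = np.random.default_rng(42)
    for _ in range(200):
        t = random_table(rng)
        assert auroc(t) == pytest.approx(auroc_oracle(t), abs=1e-9)
        assert oscr(t) == pytest.approx(oscr_oracle(t), abs=1e-9)


class TestCSA:
    def test_all_correct(self):
        assert csa(make_table([1.0, 0.9], [0.1])) == 100.0

    def test_none_correct(self):
        t = make_table([1.0], [0.1], predicted=["k1"], true=["k0"])
        assert csa(t) == 0.0

    def test_partial(self):
        true = [f"k{i % 3}" for i in range(10)]
        predicted = true[:7] + ["wrong"] * 3
        t = make_table(np.linspace(0, 1, 10), [0.5], predicted=predicted, true=true)
        assert csa(t) == pytest.approx(70.0)

    def test_unknowns_excluded(self):
        t = make_table([1.0], [0.0, 0.0, 0.0])
        assert csa(t) == 100.0


class TestDecide:
    def test_vacuous_thresholds(self):
        t = make_table([0.9, 0.4], [0.6, 0.1])
        assert not np.any(decide(t, -np.inf) == "unknown")
        assert np.all(decide(t, np.inf) == "unknown")

    def test_bimodal_midpoint(self):
        t = make_table([0.9, 0.95, 0.85], [0.1, 0.15, 0.05])
        labels = decide(t, 0.5)
        np.testing.assert_array_equal(labels == "unknown",
                                      [False, False, False, True, True, True])

    def test_threshold_reproduces_oscr_point(self):
        rng = np.random.default_rng(3)
        t = random_table(rng)
        known = t["is_known"].to_numpy()
        correct = (t["predicted_label"] == t["true_label"]).to_numpy()
        tau = float(t["known_score"].iloc[2])
        labels = decide(t, tau)
        accepted = labels != "unknown"
        ccr = np.mean(known & accepted & correct) * len(t) / known.sum()
        fpr = np.mean(~known & accepted) * len(t) / (~known).sum()
        # recompute the same point directly from the curve definition
        scores = t["known_score"].to_numpy()
        assert ccr == pytest.approx(np.sum(known & (scores >= tau) & correct) / known.sum())
        assert fpr == pytest.approx(np.sum(~known & (scores >= tau)) / (~known).sum())


class TestClosedSet:
    def test_diagonal(self):
        t = make_table([1.0, 0.9, 0.8], [])
        rep = closed_set_report(t)
        assert rep["acc"] == 100.0 and rep["f1"] == 100.0

    def test_two_class_contingency(self):
        # counts [[9,1],[2,8]]: acc 85, macro F1 = mean(18/21, 16/19)
        true = ["a"] * 10 + ["b"] * 10
        pred = ["a"] * 9 + ["b"] + ["a"] * 2 + ["b"] * 8
        t = make_table(np.ones(20), [], predicted=pred, true=true)
        rep = closed_set_report(t)
        assert rep["acc"] == pytest.approx(85.0)
        assert rep["f1"] == pytest.approx(np.mean([18 / 21, 16 / 19]) * 100, abs=1e-9)
        np.testing.assert_allclose(rep["confusion_counts"], [[9, 1], [2, 8]])
        np.testing.assert_allclose(rep["confusion_percent"], [[90, 10], [20, 80]])

    def test_requires_all_known(self):
        with pytest.raises(ValueError):
            closed_set_report(make_table([1.0], [0.5]))


class TestOpenness:
    def test_closed_world_is_zero(self):
        assert openness(OpennessConfig(k_train=5, k_test=5, variant="ratio")) == 0.0

    def test_ratio_ten_of_seventeen(self):
        v = openness(OpennessConfig(k_train=10, k_test=17, variant="ratio"))
        assert v == pytest.approx(41.18, abs=0.005)

    def test_sqrt_reproduces_printed_value(self):
        v = openness(OpennessConfig(k_train=1, k_test=8, k_target=8, variant="sqrt"))
        assert v == pytest.approx(64.64, abs=0.005)

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            OpennessConfig(k_train=9, k_test=8)

    @given(st.integers(2, 40))
    def test_ratio_strictly_decreasing_in_k_train(self, k_test):
        vals = [openness(OpennessConfig(k_train=k, k_test=k_test, variant="ratio"))
                for k in range(1, k_test + 1)]
        assert np.all(np.diff(vals) < 0)


class TestAggregate:
    def test_single_trial(self):
        rep = aggregate([{"csa": 90.0, "auroc": 80.0}])
        assert rep.mean == {"csa": 90.0, "auroc": 80.0}
        assert rep.spread == {"csa": 0.0, "auroc": 0.0}

    def test_two_trials_both_conventions(self):
        trials = [{"csa": 90.0}, {"csa": 94.0}]
        assert aggregate(trials, "population").spread["csa"] == pytest.approx(2.0)
        assert aggregate(trials, "sample").spread["csa"] == pytest.approx(np.sqrt(8))
        assert aggregate(trials).mean["csa"] == pytest.approx(92.0)

    def test_permutation_invariance(self):
        trials = [{"csa": 90.0}, {"csa": 94.0}, {"csa": 99.0}]
        a = aggregate(trials)
        b = aggregate(trials[::-1])
        assert a.mean == b.mean and a.spread == b.spread

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])
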