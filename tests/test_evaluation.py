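"""ROC/AUC, DeLong, Youden, Spearman and the margin classifier against oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    brute_force_youden,
    jackknife_delta_auc_variance,
    mann_whitney_auc,
)

from fixscore.evaluation import (
    MarginScorer,
    SplitSpec,
    delong_compare,
    evaluate_all,
    one_vs_one_auc,
    roc_auc,
    spearman_matrix,
    train_margin_classifier,
    youden_cutoff,
)


class TestRocAuc:
    def test_half_concordant_pairs(self):
        est = roc_auc([2, 3, 1, 4], [1, 1, 0, 0])
        assert est.auc == 0.5

    def test_perfect_separation_has_zero_se(self):
        est = roc_auc([5, 6, 7, 1, 2], [1, 1, 1, 0, 0])
        assert est.auc == 1.0
        assert est.se == 0.0

    def test_constant_scores_give_half(self):
        assert roc_auc([3, 3, 3, 3], [1, 0, 1, 0]).auc == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, size=500)
        if labels.sum() in (0, 500):  # pragma: no cover - astronomically unlikely
            labels[0] = 1 - labels[0]
        assert abs(roc_auc(scores, labels).auc - 0.5) < 0.07

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_pairwise_count_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            expected = mann_whitney_auc(scores[labels == 1], scores[labels == 0])
            assert roc_auc(scores, labels).auc == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50).map(lambda v: round(v, 3)), st.booleans()
            ),
            min_size=4,
            max_size=40,
        ).filter(lambda d: len({l for _, l in d}) == 2),
        scale=st.floats(0.1, 5.0),
    )
    def test_invariance_under_monotone_transform(self, data, scale):
        scores = np.array([s for s, _ in data])
        labels = np.array([int(l) for _, l in data])
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scale * scores / 50), labels).auc == pytest.approx(base)
        assert roc_auc(scale * scores + 3, labels).auc == pytest.approx(base)


class TestYouden:
    def test_separable_classes(self):
        cut = youden_cutoff([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert cut.youden_j == 1.0
        assert cut.threshold == 3.5

    def test_interleaved_scores(self):
        cut = youden_cutoff([1, 2, 3, 4], [0, 1, 0, 1])
        assert cut.youden_j == pytest.approx(0.5)

    def test_constant_scores_give_zero_j(self):
        cut = youden_cutoff([2, 2, 2, 2], [0, 1, 0, 1])
        assert cut.youden_j == 0.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.normal(size=n) * 3, 1)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            got = youden_cutoff(scores, labels)
            thr, j = brute_force_youden(scores.tolist(), labels.tolist())
            assert got.youden_j == pytest.approx(j, abs=1e-12)
            assert got.threshold == pytest.approx(thr)


class TestDeLong:
    def test_identical_scores_degenerate(self):
        scores = [0.2, 0.9, 0.4, 0.8, 0.1, 0.7]
        labels = [0, 1, 0, 1, 0, 1]
        res = delong_compare(scores, scores, labels)
        assert res.delta_auc == 0.0
        assert res.z == 0.0
        assert res.p == 1.0
        assert res.degenerate

    def test_component_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        sa = rng.normal(size=30) + labels
        sb = rng.normal(size=30)
        res = delong_compare(sa, sb, labels)
        assert res.auc_a == pytest.approx(roc_auc(sa, labels).auc, abs=1e-12)
        assert res.auc_b == pytest.approx(roc_auc(sb, labels).auc, abs=1e-12)

    def test_variance_equals_grouped_jackknife(self):
        # the DeLong estimator coincides with the grouped leave-one-out jackknife
        rng = np.random.default_rng(42)
        labels = np.r_[np.ones(3), np.zeros(3)].astype(int)
        sa = rng.normal(size=6) + labels * 1.0
        sb = 0.6 * sa + rng.normal(size=6) * 0.8
        res = delong_compare(sa, sb, labels)
        oracle = jackknife_delta_auc_variance(sa.tolist(), sb.tolist(), labels.tolist())
        assert res.se_delta**2 == pytest.approx(oracle, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1, 2, 3], [1, 2], [1, 0, 1])

    def test_two_sided_p_in_unit_interval(self):
        rng = np.random.default_rng(5)
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        sa = rng.normal(size=20) + labels * 2
        sb = rng.normal(size=20)
        res = delong_compare(sa, sb, labels)
        assert 0.0 <= res.p <= 1.0
        assert res.delta_auc >= 0.0


class TestOneVsOne:
    def test_ordered_classes_all_perfect(self):
        scores = np.r_[np.zeros(5), np.ones(5) * 5, np.ones(5) * 10]
        labels = np.r_[["a"] * 5, ["b"] * 5, ["c"] * 5]
        out = one_vs_one_auc(scores, labels, classes=["a", "b", "c"])
        assert out["macro_mean_auc"] == 1.0
        for pair in out["pairs"].values():
            for est in pair.values():
                assert est.auc == 1.0

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=900)
        labels = np.repeat(["a", "b", "c"], 300)
        rng.shuffle(labels)
        out = one_vs_one_auc(scores, labels, classes=["a", "b", "c"])
        assert abs(out["macro_mean_auc"] - 0.5) < 0.05

    def test_identical_distributions_vs_separated(self):
        rng = np.random.default_rng(23)
        a = rng.normal(size=200)
        b = rng.normal(size=200)  # same distribution as a
        c = rng.normal(size=200) + 8  # far away
        scores = np.r_[a, b, c]
        labels = np.repeat(["a", "b", "c"], 200)
        out = one_vs_one_auc(scores, labels, classes=["a", "b", "c"])
        assert abs(out["pairs"][("a", "b")]["b"].auc - 0.5) < 0.08
        assert out["pairs"][("a", "c")]["c"].auc > 0.99

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            one_vs_one_auc([1, 2, 3], ["a", "a", "b"], classes=["a", "b", "c"])


class TestMarginClassifier:
    def test_separable_feature_perfect_accuracy(self):
        rng = np.random.default_rng(2)
        feature = np.r_[rng.normal(0, 0.3, 50), rng.normal(10, 0.3, 50)]
        labels = np.r_[np.zeros(50), np.ones(50)].astype(int)
        split = SplitSpec(seed=4)
        scorer, train_idx, test_idx = train_margin_classifier(feature, labels, split)
        acc = (scorer.predict(feature[test_idx]) == labels[test_idx]).mean()
        assert acc == 1.0

    def test_feature_equal_to_labels_threshold_between_classes(self):
        labels = np.r_[np.zeros(20), np.ones(20)].astype(int)
        scorer = MarginScorer(positive_class=1).fit(labels.astype(float), labels)
        assert 0.0 < scorer.threshold_in_feature_units < 1.0

    def test_uninformative_feature_auc_near_half(self):
        rng = np.random.default_rng(31)
        feature = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        split = SplitSpec(seed=31)
        scorer, _, test_idx = train_margin_classifier(feature, labels, split)
        est = roc_auc(scorer.decision(feature[test_idx]), labels[test_idx])
        assert abs(est.auc - 0.5) < 0.05

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            MarginScorer(positive_class=1).fit([1.0, 2.0, 3.0], [0, 0, 0])

    def test_decision_is_monotone_in_feature(self):
        rng = np.random.default_rng(8)
        feature = rng.normal(size=100)
        labels = (feature + rng.normal(size=100) * 0.5 > 0).astype(int)
        scorer = MarginScorer(positive_class=1).fit(feature, labels)
        xs = np.linspace(-3, 3, 50)
        diffs = np.diff(scorer.decision(xs))
        assert (diffs >= 0).all() or (diffs <= 0).all()


class TestSplit:
    def test_stratified_split_preserves_proportions(self):
        labels = np.repeat(["normal", "borderline", "case"], [100, 56, 87])
        split = SplitSpec(seed=13)
        train_idx, test_idx = split.split(len(labels), labels)
        assert len(set(train_idx) & set(test_idx)) == 0
        assert len(train_idx) + len(test_idx) == len(labels)
        for cls, n in (("normal", 100), ("borderline", 56), ("case", 87)):
            got = (labels[train_idx] == cls).sum()
            assert abs(got - 0.7 * n) <= 1


class TestSpearman:
    def test_self_and_negated_correlations(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "neg_x": -x, "y": rng.normal(size=50)})
        r, p, filtered = spearman_matrix(df)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "neg_x"] == pytest.approx(-1.0)
        assert filtered.loc["x", "neg_x"] == pytest.approx(-1.0)

    def test_constant_column_masked_not_raised(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [5.0] * 4})
        r, p, filtered = spearman_matrix(df)
        assert np.isnan(r.loc["x", "c"])
        assert np.isnan(filtered.loc["c", "c"])

    def test_insignificant_entries_filtered(self):
        rng = np.random.default_rng(44)
        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        r, p, filtered = spearman_matrix(df)
        weak = (p > 0.05).to_numpy()
        assert np.isnan(filtered.to_numpy()[weak]).all()
        strong = (p <= 0.05).to_numpy()
        assert np.array_equal(filtered.to_numpy()[strong], r.to_numpy()[strong])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


def toy_cohort(n_per_class=40, seed=0) -> pd.DataFrame:
    """Well-separated cohort table for pipeline smoke tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for cls, mu in (("normal", 10.0), ("borderline", 25.0), ("case", 45.0)):
        for _ in range(n_per_class):
            sa = rng.normal(mu * 40, 30)
            sp = rng.normal(mu * 10, 15)
            acd = rng.normal(mu, 2)
            rows.append(
                {
                    "sa": max(sa, 1.0),
                    "sp": max(sp, 1.0),
                    "acd": max(acd, 0.0),
                    "fis_raw": 0.005 * sa + 0.027 * sp + 0.213 * acd + 4.458,
                    "hads_class": cls,
                }
            )
    return pd.DataFrame(rows)


class TestEvaluateAll:
    def test_full_report_on_separable_cohort(self):
        report = evaluate_all(toy_cohort(), SplitSpec(seed=6))
        assert set(report["auc"]) == {"sa", "sp", "acd", "fis_raw"}
        assert report["auc"]["fis_raw"]["macro_mean_auc"] > 0.95
        assert len(report["delong"]) == 3  # class pairs
        assert len(report["delong"]["normal_vs_borderline"]) == 6  # parameter pairs
        # Youden cutoffs lie between the class score ranges
        nb = report["youden"]["normal_vs_borderline"]["threshold"]
        bc = report["youden"]["borderline_vs_case"]["threshold"]
        assert nb < bc

    def test_missing_class_surfaces_clear_error(self):
        df = toy_cohort()
        df = df[df.hads_class != "case"]
        with pytest.raises(ValueError, match="absent"):
            evaluate_all(df, SplitSpec(seed=0))

    def test_degenerate_cohort_surfaces_error(self):
        df = toy_cohort()
        df["hads_class"] = "normal"
        with pytest.raises(ValueError):
            evaluate_all(df, SplitSpec(seed=0))
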