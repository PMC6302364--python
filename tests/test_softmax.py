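"""Empirical triage on soft-max scores: threshold fitting, rule application,
precision-coverage curves, curve inversion, and the class-count filter."""

import numpy as np
import pytest

from triagekit import (
    REFUSE,
    ScoreMatrix,
    apply_triage,
    bayes_classify,
    class_error_by_count,
    fit_threshold,
    min_count_filter,
    optimal_triage,
    precision_coverage_curve,
    sample,
    threshold_for_precision,
    triage_loss,
    two_class_symmetric,
)

from conftest import random_score_matrix

LABELS3 = ["a_1", "a_2", "a_3"]


def scores_with_maxima(maxima):
    """Three-class rows whose per-row maxima are exactly the given values.

    Splitting the remainder 60/40 keeps the first column the strict winner
    for any max above 0.375, so maxima below 1/2 are representable too.
    """
    return ScoreMatrix(
        values=[[m, (1.0 - m) * 0.6, (1.0 - m) * 0.4] for m in maxima],
        labels=LABELS3,
    )


class TestFitThreshold:
    def test_budget_quarter_refuses_smallest_maximum(self):
        scores = scores_with_maxima([0.9, 0.8, 0.6, 0.4])
        rule = fit_threshold(scores, 0.25)
        res = apply_triage(scores, rule)
        assert list(res.decided) == [True, True, True, False]

    def test_epsilon_zero_classifies_every_row(self):
        scores = scores_with_maxima([0.9, 0.8, 0.6, 0.4])
        rule = fit_threshold(scores, 0.0)
        assert apply_triage(scores, rule).decided.all()

    def test_half_budget_refuses_two_smallest_of_four(self):
        scores = scores_with_maxima([0.9, 0.8, 0.6, 0.4])
        rule = fit_threshold(scores, 0.5)
        res = apply_triage(scores, rule)
        assert list(res.decided) == [True, True, False, False]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ScoreMatrix(values=np.empty((0, 2)), labels=["a_1", "a_2"])

    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.37, 0.8])
    def test_self_consistency_floor_rule(self, eps):
        rng = np.random.default_rng(21)
        scores = random_score_matrix(rng, 53, 4)
        rule = fit_threshold(scores, eps)
        res = apply_triage(scores, rule)
        n = scores.n_items
        assert res.decided.sum() >= (1 - eps) * n - 1e-9
        # untied maxima: exactly floor(eps * n) rows refused
        assert (~res.decided).sum() == int(np.floor(eps * n + 1e-9))


class TestApplyTriage:
    def test_zero_threshold_full_mask_equals_bayes(self):
        rng = np.random.default_rng(8)
        scores = random_score_matrix(rng, 30, 3)
        rule = fit_threshold(scores, 0.0)
        res = apply_triage(scores, rule)
        assert np.array_equal(res.decisions, bayes_classify(scores))

    def test_masked_argmax_class_is_refused_despite_high_score(self):
        scores = ScoreMatrix(
            values=[[0.005, 0.005, 0.99]], labels=["a_1", "a_2", "a_3"]
        )
        rule = fit_threshold(scores, 0.0).with_mask([True, True, False])
        res = apply_triage(scores, rule)
        assert res.decisions[0] == REFUSE

    def test_decided_set_is_exactly_rows_above_threshold(self):
        rng = np.random.default_rng(17)
        scores = random_score_matrix(rng, 200, 3)
        rule = fit_threshold(scores, 0.0)
        rule = type(rule)(threshold_b=0.6, labels=rule.labels)
        res = apply_triage(scores, rule)
        assert np.array_equal(res.decided, scores.row_maxima() > 0.6)

    def test_label_mismatch_names_missing_labels(self):
        scores = scores_with_maxima([0.9])
        rule = fit_threshold(
            ScoreMatrix(values=[[0.5, 0.5]], labels=["a_1", "zz"]), 0.0
        )
        with pytest.raises(ValueError, match="zz"):
            apply_triage(scores, rule)

    def test_no_emitted_label_is_ever_masked(self):
        rng = np.random.default_rng(30)
        scores = random_score_matrix(rng, 150, 4)
        mask = np.array([True, False, True, False])
        rule = fit_threshold(scores, 0.1).with_mask(mask)
        res = apply_triage(scores, rule)
        emitted = set(res.decisions[res.decided])
        assert emitted <= {"a_1", "a_3"}


class TestPrecisionCoverageCurve:
    def test_perfect_scores_give_precision_one_everywhere(self):
        rng = np.random.default_rng(4)
        scores = random_score_matrix(rng, 25, 3)
        truth = bayes_classify(scores)
        curve = precision_coverage_curve(scores, truth).points
        defined = curve["coverage"] > 0
        assert np.allclose(curve.loc[defined, "precision"], 1.0)

    def test_three_row_hand_enumeration(self):
        scores = scores_with_maxima([0.9, 0.6, 0.5])
        truth = ["a_1", "a_2", "a_1"]  # 0.6 row is wrong, others right
        curve = precision_coverage_curve(scores, truth).points
        full = curve.iloc[0]
        assert full["coverage"] == pytest.approx(1.0)
        assert full["precision"] == pytest.approx(2 / 3)
        at = curve.set_index("threshold")
        assert at.loc[0.5, "coverage"] == pytest.approx(2 / 3)
        assert at.loc[0.5, "precision"] == pytest.approx(1 / 2)
        assert at.loc[0.6, "coverage"] == pytest.approx(1 / 3)
        assert at.loc[0.6, "precision"] == pytest.approx(1.0)

    def test_coverage_strictly_decreasing_loss_non_increasing(self):
        rng = np.random.default_rng(2)
        scores = random_score_matrix(rng, 80, 4)
        truth = np.asarray(scores.labels, dtype=object)[
            rng.integers(0, 4, scores.n_items)
        ]
        curve = precision_coverage_curve(scores, truth).points
        assert np.all(np.diff(curve["coverage"]) < 0)
        assert np.all(np.diff(curve["joint_loss"]) <= 1e-15)
        cov = curve["coverage"]
        assert cov.between(0, 1).all()

    def test_length_mismatch_rejected(self):
        scores = scores_with_maxima([0.9, 0.6])
        with pytest.raises(ValueError, match="length"):
            precision_coverage_curve(scores, ["a_1"])

    def test_monotone_precision_on_calibrated_synthetic_scores(self):
        # when scores track the true conditionals, precision rises as
        # coverage falls, up to sampling noise
        s = sample(two_class_symmetric(), 2000, seed=99)
        scores = ScoreMatrix(values=s.probs.values, labels=s.probs.labels)
        curve = precision_coverage_curve(scores, s.true_labels).points
        mid = curve[(curve["coverage"] > 0.2) & (curve["coverage"] <= 1.0)]
        # compare coarse operating points to dodge point-level noise
        p_hi = mid[mid["coverage"] > 0.8]["precision"].mean()
        p_lo = mid[mid["coverage"] <= 0.5]["precision"].mean()
        assert p_lo > p_hi


class TestThresholdForPrecision:
    def test_degenerate_target_zero_gives_full_coverage(self):
        scores = scores_with_maxima([0.9, 0.6, 0.5])
        out = threshold_for_precision(scores, ["a_1", "a_2", "a_1"], 0.0)
        assert out.attainable and out.coverage == pytest.approx(1.0)

    def test_target_point_nine_picks_coverage_third(self):
        scores = scores_with_maxima([0.9, 0.6, 0.5])
        out = threshold_for_precision(scores, ["a_1", "a_2", "a_1"], 0.9)
        assert out.attainable
        assert out.coverage == pytest.approx(1 / 3)
        assert out.precision == pytest.approx(1.0)
        res = apply_triage(scores, out.rule)
        assert list(res.decided) == [True, False, False]

    def test_error_at_top_score_makes_perfect_precision_unattainable(self):
        scores = scores_with_maxima([0.9, 0.6])
        out = threshold_for_precision(scores, ["a_2", "a_2"], 1.0)
        assert not out.attainable
        assert out.rule is None

    def test_out_of_range_target_rejected(self):
        scores = scores_with_maxima([0.9])
        with pytest.raises(ValueError, match="target_precision"):
            threshold_for_precision(scores, ["a_1"], 1.1)


class TestClassErrorByCount:
    def test_hand_count(self):
        from triagekit import TriageResult

        decisions = np.array(["a_1", "a_2", "a_2", "a_2"], dtype=object)
        res = TriageResult(
            decisions=decisions,
            decided=np.ones(4, dtype=bool),
            argmax_label=decisions.copy(),
        )
        table = class_error_by_count(
            res, ["a_1", "a_1", "a_2", "a_2"], {"a_1": 10, "a_2": 20}
        )
        assert table.loc["a_1", "error_rate"] == pytest.approx(0.5)
        assert table.loc["a_2", "error_rate"] == pytest.approx(0.0)
        assert table.loc["a_1", "count"] == 10

    def test_all_correct_class_has_zero_error(self):
        from triagekit import TriageResult

        decisions = np.array(["a_1", "a_1"], dtype=object)
        res = TriageResult(
            decisions=decisions,
            decided=np.ones(2, dtype=bool),
            argmax_label=decisions.copy(),
        )
        table = class_error_by_count(res, ["a_1", "a_1"], {"a_1": 5})
        assert table.loc["a_1", "error_rate"] == 0.0

    def test_pooled_rate_equals_weighted_aggregate(self):
        rng = np.random.default_rng(41)
        scores = random_score_matrix(rng, 120, 3)
        truth = np.asarray(scores.labels, dtype=object)[
            rng.integers(0, 3, scores.n_items)
        ]
        rule = fit_threshold(scores, 0.2)
        res = apply_triage(scores, rule)
        counts = {lab: 100 for lab in scores.labels}
        table = class_error_by_count(res, truth, counts)
        pooled = table["n_errors"].sum() / table["n_decided"].sum()
        loss = triage_loss(res, truth)
        assert pooled == pytest.approx(loss.joint_loss / loss.coverage)

    def test_missing_count_entry_rejected(self):
        from triagekit import TriageResult

        decisions = np.array(["a_1"], dtype=object)
        res = TriageResult(
            decisions=decisions,
            decided=np.ones(1, dtype=bool),
            argmax_label=decisions.copy(),
        )
        with pytest.raises(ValueError, match="a_1"):
            class_error_by_count(res, ["a_1"], {"a_2": 3})


class TestMinCountFilter:
    def test_cutoff_500_masks_rare_class(self):
        mask = min_count_filter(
            {"a_1": 1500, "a_2": 600, "a_3": 50}, 500, ["a_1", "a_2", "a_3"]
        )
        assert list(mask) == [True, True, False]

    def test_zero_cutoff_keeps_everything(self):
        mask = min_count_filter({"a_1": 0, "a_2": 3}, 0, ["a_1", "a_2"])
        assert mask.all()

    @pytest.mark.parametrize("cutoff", [100, 500, 1000])
    def test_named_operating_points_compose_into_rules(self, cutoff):
        rng = np.random.default_rng(55)
        scores = random_score_matrix(rng, 60, 3)
        counts = {"a_1": 1200, "a_2": 400, "a_3": 80}
        mask = min_count_filter(counts, cutoff, scores.labels)
        rule = fit_threshold(scores, 0.1).with_mask(mask)
        res = apply_triage(scores, rule)
        banned = {lab for lab, keep in zip(scores.labels, mask) if not keep}
        assert not (set(res.decisions[res.decided]) & banned)

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError, match="min_count"):
            min_count_filter({"a_1": 5}, -1, ["a_1"])


class TestMConsistencyShadow:
    @pytest.mark.parametrize("eps", [0.1, 0.3])
    def test_monotone_transform_preserves_decided_set(self, eps):
        s = sample(two_class_symmetric(), 500, seed=314)
        from triagekit import corrupt_scores

        scores = corrupt_scores(s, ("power", 3.0))
        emp = apply_triage(scores, fit_threshold(scores, eps))
        _, oracle = optimal_triage(s.probs, eps)
        assert np.array_equal(emp.decided, oracle.decided)
        assert np.array_equal(emp.decisions, oracle.decisions)
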