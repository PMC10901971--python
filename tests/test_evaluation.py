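"""Metrics: AUC vs a pair-counting oracle, CIs, operating points,
relative-percentage-difference arithmetic."""

from __future__ import annotations

import numpy as np
import pytest

from cardiolead.evaluation import (
    best_threshold,
    build_comparison,
    ci_over_runs,
    evaluate_runs,
    macro_average,
    relative_percentage_difference,
    roc_auc,
)


def auc_pair_counting(labels, scores):
    """Independent oracle: exhaustive Mann-Whitney pair counting."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def threshold_enumeration(labels, scores):
    """Independent oracle: best Youden's J over every candidate cut."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        key = (-j, -sens, thr)
        if best is None or key < best[0]:
            best = (key, j, sens, spec)
    return best[1], best[2], best[3]


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_four_sample_case(self):
        # pairs: (0.4,0.1)+ (0.4,0.5)- (0.3,0.1)+ (0.3,0.5)- -> 2/4
        assert roc_auc([0, 1, 1, 0], [0.1, 0.4, 0.3, 0.5]) == 0.5

    def test_matches_pair_counting_oracle_on_small_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            # discrete scores so ties occur often
            scores = rng.integers(0, 5, size=n) / 4.0
            assert roc_auc(labels, scores) == pytest.approx(
                auc_pair_counting(labels, scores), abs=1e-12
            )

    def test_complement_for_tie_free_scores(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.permutation(np.linspace(0, 1, 50))
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.normal(size=40)
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc(labels, np.exp(3 * scores)), abs=1e-12
        )

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestMacroAverage:
    def test_equal_values(self):
        assert macro_average([7.0] * 20) == 7.0

    def test_two_values(self):
        assert macro_average([1.0, 0.5]) == 0.75

    def test_order_invariance(self, rng):
        vals = rng.uniform(0, 1, 20)
        assert macro_average(vals) == pytest.approx(
            macro_average(vals[::-1]), abs=1e-15
        )

    def test_nan_excluded(self):
        assert macro_average([1.0, np.nan, 0.0]) == 0.5

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            macro_average([np.nan, np.nan])


class TestCiOverRuns:
    def test_identical_values_zero_width(self):
        mean, lo, hi = ci_over_runs([91.0, 91.0, 91.0])
        assert (mean, lo, hi) == (91.0, 91.0, 91.0)

    def test_two_value_closed_form(self):
        # sd = sqrt(2), half-width = 1.96 * sqrt(2)/sqrt(2) = 1.96
        mean, lo, hi = ci_over_runs([90.0, 92.0])
        assert mean == 91.0
        assert lo == pytest.approx(89.04)
        assert hi == pytest.approx(92.96)

    def test_symmetric_about_mean(self, rng):
        vals = rng.normal(85, 2, size=9)
        mean, lo, hi = ci_over_runs(vals)
        assert hi - mean == pytest.approx(mean - lo)

    def test_width_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(42)
        widths = {}
        for n in (25, 400):
            vals = rng.normal(90, 1.5, size=n)
            _, lo, hi = ci_over_runs(vals)
            widths[n] = hi - lo
        ratio = widths[400] / widths[25]
        assert ratio == pytest.approx(0.25, rel=0.3)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            ci_over_runs([90.0])


class TestBestThreshold:
    def test_perfect_separation(self):
        thr, sens, spec = best_threshold([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert sens == 1.0 and spec == 1.0

    def test_four_sample_case_matches_enumeration(self):
        labels, scores = [0, 1, 1, 0], [0.1, 0.4, 0.3, 0.5]
        j_oracle, sens_oracle, spec_oracle = threshold_enumeration(labels, scores)
        thr, sens, spec = best_threshold(labels, scores)
        assert sens + spec - 1 == pytest.approx(j_oracle)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200)	:
            n = int(rng.integers(4, 15))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = rng.integers(0, 6, size=n) / 5.0
            j_oracle, _, _ = threshold_enumeration(labels, scores)
            thr, sens, spec = best_threshold(labels, scores)
            assert sens + spec - 1 == pytest.approx(j_oracle, abs=1e-12)

    def test_uninformative_scores_give_small_j(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=4000)
        scores = rng.random(4000)
        _, sens, spec = best_threshold(labels, scores)
        assert sens + spec - 1 < 0.08   # permutation-scale fluctuation at n=4000

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            best_threshold([0, 0], [0.1, 0.2])


class TestRelativePercentageDifference:
    @pytest.mark.parametrize(
        "value, reference, expected",
        [
            (85.12, 93.23, -8.7),
            (90.58, 93.23, -2.8),
            (92.95, 93.23, -0.3),
            (92.25, 93.23, -1.1),
            (80.0, 80.0, 0.0),
        ],
    )
    def test_reported_arithmetic(self, value, reference, expected):
        assert relative_percentage_difference(value, reference) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_percentage_difference(50.0, 0.0)


class TestEvaluateRunsAndComparison:
    @pytest.fixture()
    def runs(self, rng):
        n, c = 80, 20
        labels = rng.integers(0, 2, size=(n, c))
        labels[0, :], labels[1, :] = 0, 1
        scores = [
            np.clip(labels + rng.normal(0, 0.6, size=(n, c)), 1e-3, 1 - 1e-3)
            for _ in range(4)
        ]
        return labels, scores

    def test_report_structure(self, runs):
        labels, scores = runs
        rep = evaluate_runs(scores, labels, setup_name="12lead")
        assert rep.auc_mean.shape == (20,)
        assert np.all(rep.auc_lower <= rep.auc_mean + 1e-12)
        assert np.all(rep.auc_mean <= rep.auc_upper + 1e-12)
        assert 0.0 <= rep.macro_mean <= 100.0
        frame = rep.to_frame()
        assert list(frame.index)[-1] == "Avg" and len(frame) == 21

    def test_reference_vs_itself_all_zeros(self, runs):
        labels, scores = runs
        rep = evaluate_runs(scores, labels, setup_name="12lead")
        table = build_comparison({"12lead": rep}, reference="12lead")
        assert np.all(table.per_class["12lead"] == 0.0)
        assert table.average["12lead"] == 0.0

    def test_missing_reference_rejected(self, runs):
        labels, scores = runs
        rep = evaluate_runs(scores, labels, setup_name="D1")
        with pytest.raises(ValueError):
            build_comparison({"D1": rep}, reference="12lead")
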