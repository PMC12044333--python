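"""ROC/Youden machinery and the two-group baseline tests."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from freeil18.marker_stats import (
    Contingency2x2,
    DegenerateOutcomeError,
    YoudenCutoff,
    chi_square_2x2,
    confusion_at_cutoff,
    mann_whitney_u,
    roc_curve,
    youden_cutoff,
)


class TestROC:
    def test_perfect_separation_auc_one(self):
        marker = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        outcome = np.array([1, 1, 1, 0, 0, 0])
        curve = roc_curve(marker, outcome, "low_predicts_event")
        assert curve.auc == pytest.approx(1.0)
        cut = youden_cutoff(curve)
        assert cut.youden_j == pytest.approx(1.0)
        assert 3.0 < cut.cutoff <= 10.0

    def test_uninformative_marker_auc_half(self, rng):
        marker = rng.normal(size=20_000)
        outcome = rng.random(20_000) < 0.3
        curve = roc_curve(marker, outcome.astype(int))
        assert curve.auc == pytest.approx(0.5, abs=0.02)

    def test_curve_endpoints_and_monotonicity(self, rng):
        marker = rng.normal(size=200)
        outcome = (rng.random(200) < 0.4).astype(int)
        curve = roc_curve(marker, outcome)
        assert (curve.sensitivity[0], curve.specificity[0]) == (0.0, 1.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (1.0, 0.0)
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.specificity) <= 0)

    @pytest.mark.parametrize("orientation, sign", [
        ("low_predicts_event", -1.0), ("high_predicts_event", 1.0),
    ])
    def test_auc_matches_sklearn(self, rng, orientation, sign):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            marker = rng.choice([0.5, 1.0, 2.0, 3.5, 7.0], size=n)  # force ties
            outcome = (rng.random(n) < 0.4).astype(int)
            if outcome.sum() in (0, n):
                continue
            curve = roc_curve(marker, outcome, orientation)
            assert curve.auc == pytest.approx(
                roc_auc_score(outcome, sign * marker), abs=1e-12
            )

    def test_auc_equals_mann_whitney_identity(self, rng):
        """AUC == U / (n1 * n0) with U counting (non-event > event) midranks."""
        for _ in range(50):
            n = int(rng.integers(8, 40))
            marker = np.round(rng.normal(size=n), 1)
            outcome = (rng.random(n) < 0.5).astype(int)
            n1, n0 = outcome.sum(), n - outcome.sum()
            if n1 == 0 or n0 == 0:
                continue
            curve = roc_curve(marker, outcome, "low_predicts_event")
            u, _ = mann_whitney_u(marker[outcome == 0], marker[outcome == 1])
            assert curve.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_degenerate_outcome_raises(self):
        with pytest.raises(DegenerateOutcomeError):
            roc_curve([1.0, 2.0], [1, 1])


class TestYouden:
    def test_two_point_curve_returns_its_threshold(self):
        curve = roc_curve([1.0, 2.0], [1, 0])
        cut = youden_cutoff(curve)
        assert cut.cutoff == 2.0
        assert cut.youden_j == pytest.approx(1.0)

    def test_tie_break_prefers_high_sensitivity_then_small_threshold(self):
        # alternating marker: J is tied at 1/2 for thresholds 2 (sens 1/2)
        # and 4 (sens 1); the rule picks the higher-sensitivity threshold 4
        marker = np.array([1.0, 2.0, 3.0, 4.0])
        outcome = np.array([1, 0, 1, 0])
        curve = roc_curve(marker, outcome)
        j = curve.sensitivity + curve.specificity - 1.0
        assert np.sum(j == j.max()) == 2
        cut = youden_cutoff(curve)
        assert cut.cutoff == 4.0
        assert cut.sensitivity == 1.0

    def test_invariant_under_monotone_transform(self, rng):
        marker = rng.normal(size=300)
        outcome = (marker + rng.normal(size=300) < -0.3).astype(int)
        if outcome.sum() in (0, 300):
            pytest.skip("degenerate draw")
        cut = youden_cutoff(roc_curve(marker, outcome))
        transformed = np.exp(marker)  # strictly increasing
        cut_t = youden_cutoff(roc_curve(transformed, outcome))
        assert cut_t.cutoff == pytest.approx(np.exp(cut.cutoff))
        assert cut_t.sensitivity == cut.sensitivity
        assert cut_t.specificity == cut.specificity


class TestConfusion:
    @pytest.fixture()
    def study_groups(self):
        """Marker/outcome reconstructing the published 2x2 infection counts:
        12 events of 83 below the cutoff, 8 events of 212 at/above."""
        marker = np.concatenate([np.full(83, 5.0), np.full(212, 7.0)])
        outcome = np.concatenate(
            [np.ones(12), np.zeros(71), np.ones(8), np.zeros(204)]
        )
        return marker, outcome

    def test_published_sensitivity_specificity(self, study_groups):
        marker, outcome = study_groups
        res = confusion_at_cutoff(marker, outcome, 6.0)
        assert round(100 * res.sensitivity, 1) == 60.0
        assert round(100 * res.specificity, 1) == 74.2
        assert res.table.n == 295

    def test_margins_and_recomputation_consistency(self, rng):
        marker = rng.normal(size=100)
        outcome = (rng.random(100) < 0.3).astype(int)
        res = confusion_at_cutoff(marker, outcome, 0.0)
        t = res.table
        assert t.n == 100
        assert t.tp + t.fn == outcome.sum()
        if res.sensitivity is not None:
            assert res.sensitivity == t.tp / (t.tp + t.fn)
        if res.specificity is not None:
            assert res.specificity == t.tn / (t.tn + t.fp)

    def test_cutoff_below_all_markers(self):
        res = confusion_at_cutoff([5.0, 6.0], [1, 0], 1.0)
        assert res.sensitivity == 0.0
        assert res.specificity == 1.0

    def test_undefined_metrics_are_none_not_zero(self):
        res = confusion_at_cutoff([5.0, 6.0], [0, 0], 5.5)
        assert res.sensitivity is None
        assert res.specificity == 0.5


class TestChiSquare:
    def test_published_infection_table(self):
        stat, p = chi_square_2x2(Contingency2x2(12, 8, 71, 204))
        assert stat == pytest.approx(10.77, abs=0.01)
        assert p < 0.01

    def test_balanced_table_is_null(self):
        stat, p = chi_square_2x2(Contingency2x2(7, 7, 7, 7))
        assert stat == 0.0
        assert p == 1.0

    def test_matches_scipy(self, rng):
        for _ in range(25):
            cells = rng.integers(1, 80, size=4)
            table = Contingency2x2(*map(int, cells))
            arr = [[table.tp, table.fn], [table.fp, table.tn]]
            for yates in (False, True):
                stat, p = chi_square_2x2(table, yates=yates)
                ref = sps.chi2_contingency(arr, correction=yates)
                assert stat == pytest.approx(ref.statistic, rel=1e-12)
                assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_yates_never_exceeds_uncorrected(self, rng):
        for _ in range(50):
            table = Contingency2x2(*map(int, rng.integers(1, 50, size=4)))
            stat, _ = chi_square_2x2(table)
            stat_y, _ = chi_square_2x2(table, yates=True)
            assert stat_y <= stat + 1e-12

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(Contingency2x2(0, 0, 5, 5))


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney_u(x, x)
        assert p == 1.0

    def test_fully_below_gives_zero_u(self):
        u, _ = mann_whitney_u([1.0, 2.0], [3.0, 4.0, 5.0])
        assert u == 0.0

    def test_u_matches_brute_force_pair_count(self, rng):
        for _ in range(40):
            x = rng.integers(0, 6, size=int(rng.integers(2, 9))).astype(float)
            y = rng.integers(0, 6, size=int(rng.integers(2, 9))).astype(float)
            u, _ = mann_whitney_u(x, y)
            brute = sum(
                1.0 if xi > yj else (0.5 if xi == yj else 0.0)
                for xi, yj in itertools.product(x, y)
            )
            assert u == pytest.approx(brute, abs=1e-9)

    def test_matches_scipy_asymptotic(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(0.5, 1.0, size=25)
            u, p = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            )
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestYoudenCutoffEstimator:
    def test_fit_predict_roundtrip(self, rng):
        marker = rng.normal(8.0, 4.0, size=500)
        outcome = ((marker < 6.0) & (rng.random(500) < 0.6)).astype(int)
        outcome |= (rng.random(500) < 0.05).astype(int)
        clf = YoudenCutoff().fit(marker, outcome)
        pred = clf.predict(marker)
        np.testing.assert_array_equal(pred, (marker < clf.cutoff_).astype(int))
        assert 0.0 <= clf.auc_ <= 1.0
        assert -1.0 <= clf.youden_j_ <= 1.0

    def test_fixed_cutoff_bypasses_selection(self, rng):
        marker = rng.normal(8.0, 4.0, size=200)
        outcome = (rng.random(200) < 0.2).astype(int)
        clf = YoudenCutoff(fixed_cutoff=6.0).fit(marker, outcome)
        assert clf.cutoff_ == 6.0
        res = confusion_at_cutoff(marker, outcome, 6.0)
        assert clf.sensitivity_ == res.sensitivity
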