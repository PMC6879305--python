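import numpy as np
import pandas as pd
import pytest

from tigs.evaluation import (
    CohortORRPoint,
    compare_biomarkers,
    fit_orr_model,
    km_logrank,
    median_split,
    predict_orr,
    roc_auc,
    slope_confidence_interval,
)
from tigs.io_formats import ClinicalTable

from .oracles import auc_pair_oracle, logrank_oracle


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert r.auc == 1.0

    def test_nine_pair_brute_force(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(8 / 9)
        assert r.auc == pytest.approx(auc_pair_oracle(scores, labels))

    def test_all_tied_gives_half(self):
        r = roc_auc([5.0] * 6, [1, 1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(0.5)

    def test_one_class_absent_names_it(self):
        with pytest.raises(ValueError, match="responder"):
            roc_auc([1, 2], [1, 1])

    def test_orientation_flag_flips(self):
        r = roc_auc([1, 2, 3, 4], [1, 1, 0, 0], higher_is_positive=False)
        assert r.auc == 1.0

    def test_missing_scores_dropped(self):
        r = roc_auc([np.nan, 1, 2, 3], [1, 0, 0, 1])
        assert r.n_positive == 1 and r.n_negative == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_complement_identity_tie_free(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=20)
        y = rng.integers(0, 2, size=20)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        y = (rng.random(30) < 0.4).astype(int)
        a = roc_auc(s, y).auc
        b = roc_auc(np.exp(2 * s) + 1, y).auc
        assert a == pytest.approx(b)


class TestMedianSplit:
    def test_odd_n(self):
        g = median_split(pd.Series([1, 2, 3, 4, 5], index=list("abcde")))
        assert list(g[g == "High"].index) == ["d", "e"]

    def test_ties_at_median_go_low(self):
        g = median_split(pd.Series([1, 1, 2, 2]))
        assert list(g) == ["Low", "Low", "High", "High"]

    def test_degenerate_all_identical(self):
        with pytest.warns(UserWarning, match="degenerate"):
            g = median_split(pd.Series([7.0, 7.0, 7.0]))
        assert (g == "Low").all()

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match=">= 2"):
            median_split(pd.Series([1.0]))


def _clinical(samples, times, events):
    return ClinicalTable(samples, [np.nan] * len(samples), times, events)


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        samples = [f"P{i}" for i in range(8)]
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 1, 0, 1, 1, 1, 0]
        groups = pd.Series(["High"] * 4 + ["Low"] * 4, index=samples)
        res = km_logrank(groups, _clinical(samples, times, events))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_step_function_identity(self):
        # A all die at t=1, B all at t=2, no censoring
        samples = [f"P{i}" for i in range(6)]
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=samples)
        res = km_logrank(groups, _clinical(samples, [1, 1, 1, 2, 2, 2], [1] * 6))
        assert res.survival_at("A", 1.5) == 0.0
        assert res.survival_at("B", 1.5) == 1.0

    def test_six_subject_hand_worked_statistic(self):
        samples = [f"P{i}" for i in range(6)]
        times = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        events = [1, 0, 1, 1, 1, 0]
        groups = pd.Series(["A", "A", "A", "B", "B", "B"], index=samples)
        res = km_logrank(groups, _clinical(samples, times, events))
        want = logrank_oracle(times[:3], events[:3], times[3:], events[3:])
        assert res.statistic == pytest.approx(want, rel=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        samples = [f"P{i}" for i in range(20)]
        times = rng.exponential(10, 20)
        events = rng.integers(0, 2, 20).astype(float)
        scores = pd.Series(rng.normal(size=20), index=samples)
        clin = _clinical(samples, times, events)
        res1 = km_logrank(median_split(scores), clin)
        perm = rng.permutation(20)
        clin2 = _clinical(
            [samples[i] for i in perm], times[perm], events[perm]
        )
        res2 = km_logrank(median_split(scores.iloc[perm]), clin2)
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_empty_group_rejected(self):
        samples = ["P0", "P1"]
        groups = pd.Series(["A", "B"], index=["P0", "ZZ"])
        with pytest.raises(ValueError):
            km_logrank(groups, _clinical(samples, [1.0, 2.0], [1, 1]))


class TestOrrModel:
    def test_noiseless_exact_recovery(self):
        tigs = np.linspace(0.2, 2.0, 10)
        pts = pd.DataFrame({"orr": 21.4 * tigs - 2.7, "median_tigs": tigs})
        m = fit_orr_model(pts)
        assert m.slope == pytest.approx(21.4, abs=1e-8)
        assert m.intercept == pytest.approx(-2.7, abs=1e-8)
        assert m.r == pytest.approx(1.0, abs=1e-8)

    def test_two_points_rejected(self):
        pts = pd.DataFrame({"orr": [1.0, 2.0], "median_tigs": [0.1, 0.2]})
        with pytest.raises(ValueError, match=">= 3"):
            fit_orr_model(pts)

    def test_zero_variance_predictor_rejected(self):
        pts = pd.DataFrame({"orr": [1.0, 2.0, 3.0], "median_tigs": [0.5] * 3})
        with pytest.raises(ValueError, match="variance"):
            fit_orr_model(pts)

    def test_cohort_point_inclusion_rule(self):
        with pytest.raises(ValueError, match="fewer than 10"):
            CohortORRPoint("X", orr=20.0, median_tigs=1.0, n_patients=5)
        with pytest.raises(ValueError, match="percentage"):
            CohortORRPoint("X", orr=120.0, median_tigs=1.0)

    def test_list_of_points_accepted(self):
        pts = [
            CohortORRPoint(f"T{i}", orr=float(5 + 10 * i), median_tigs=0.2 * i + 0.1)
            for i in range(5)
        ]
        m = fit_orr_model(pts)
        assert m.n == 5 and m.slope == pytest.approx(50.0)

    def test_predict_at_zero_is_intercept(self):
        from tigs.evaluation import ORRModel

        m = ORRModel.from_coefficients(21.4, -2.7)
        point, ci = predict_orr(m, 0.0)
        assert point == pytest.approx(-2.7) and ci is None

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (10, 40, 160):
            x = np.linspace(0.1, 2.0, n)
            y = 21.4 * x - 2.7 + rng.normal(0, 3, n)
            m = fit_orr_model(pd.DataFrame({"orr": np.clip(y, 0, 100), "median_tigs": x}))
            _, (lo, hi) = predict_orr(m, 1.0)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_slope_ci_contains_truth_for_clean_fit(self):
        x = np.linspace(0.1, 2.0, 25)
        rng = np.random.default_rng(1)
        y = np.clip(21.4 * x - 2.7 + rng.normal(0, 3, 25), 0, 100)
        m = fit_orr_model(pd.DataFrame({"orr": y, "median_tigs": x}))
        lo, hi = slope_confidence_interval(m)
        assert lo < 21.4 < hi


class TestCompareBiomarkers:
    def test_label_column_scores_one(self):
        idx = [f"P{i}" for i in range(10)]
        labels = pd.Series([1, 0] * 5, index=idx, dtype=float)
        result = pd.DataFrame({"tigs": labels, "tmb": 1 - labels})
        out = compare_biomarkers(result, labels).set_index("biomarker")
        assert out.loc["tigs", "auc"] == 1.0
        assert out.loc["tmb", "auc"] == 0.0

    def test_tide_orientation_negated(self):
        idx = [f"P{i}" for i in range(8)]
        labels = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=idx, dtype=float)
        # low TIDE = responsive: responders have the LOWEST tide scores
        result = pd.DataFrame(
            {"tide": [1, 2, 3, 4, 5, 6, 7, 8], "tigs": [0.0] * 8}, index=idx
        )
        out = compare_biomarkers(result, labels).set_index("biomarker")
        assert out.loc["tide", "auc"] == 1.0

    def test_per_biomarker_n_with_missing_values(self):
        idx = [f"P{i}" for i in range(10)]
        labels = pd.Series([1, 0] * 5, index=idx, dtype=float)
        tmb = pd.Series(np.r_[np.full(4, np.nan), np.arange(6)], index=idx)
        result = pd.DataFrame({"tigs": np.arange(10), "tmb": tmb}, index=idx)
        out = compare_biomarkers(result, labels).set_index("biomarker")
        assert out.loc["tigs", "n"] == 10
        assert out.loc["tmb", "n"] == 6

    def test_apsr_mean_row_appended(self):
        rng = np.random.default_rng(7)
        idx = [f"P{i}" for i in range(12)]
        labels = pd.Series(rng.integers(0, 2, 12), index=idx, dtype=float)
        if labels.min() == labels.max():
            labels.iloc[0] = 1 - labels.iloc[0]
        result = pd.DataFrame({"tigs": rng.normal(size=12)}, index=idx)
        apsr = pd.DataFrame(rng.normal(size=(5, 12)), columns=idx)
        out = compare_biomarkers(result, labels, apsr).set_index("biomarker")
        assert "apsr" in out.index
        per_repeat = [auc_pair_oracle(apsr.iloc[i], labels) for i in range(5)]
        assert out.loc["apsr", "auc"] == pytest.approx(np.mean(per_repeat))
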