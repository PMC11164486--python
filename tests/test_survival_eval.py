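"""Cutpoint, Kaplan-Meier, log-rank, time-dependent ROC, C-index, calibration."""

import numpy as np
import pandas as pd
import pytest

from mpps import (
    SurvivalData,
    calibration_curve,
    compare_groups,
    concordance_index,
    kaplan_meier,
    logrank_test,
    multivariable_prognostic_model,
    optimal_cutpoint,
    time_dependent_auc,
)
from conftest import cindex_oracle, mann_whitney_auc, random_survival


def surv_of(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalData.from_arrays(ids, times, events)


class TestOptimalCutpoint:
    def test_perfect_separation_between_plateaus(self):
        scores = pd.Series([1, 1, 1, 1, 10, 10, 10, 10], index=[f"s{i}" for i in range(8)], dtype=float)
        surv = surv_of([10, 11, 12, 13, 1, 2, 3, 4], [1] * 8)
        strat = optimal_cutpoint(scores, surv, minprop=0.2)
        assert strat.cutpoint == 1.0
        assert (strat.group[scores > 1] == "high").all() and (strat.group[scores <= 1] == "low").all()

    def test_equals_exhaustive_bruteforce(self, rng):
        """Oracle: lifelines log-rank at every admissible candidate, max |z|, smallest tie."""
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(8):
            n = 30
            scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            surv, _ = random_survival(rng, n, censor_frac=0.2)
            scores.index = surv.sample_ids
            minprop = 0.15
            min_group = int(np.ceil(minprop * n))
            best = (-np.inf, None)
            for c in np.unique(scores.to_numpy()):
                hi = scores.to_numpy() > c
                if hi.sum() < min_group or (~hi).sum() < min_group:
                    continue
                res = ll_logrank(surv.time[hi], surv.time[~hi], surv.event[hi], surv.event[~hi])
                z = np.sqrt(res.test_statistic)
                if z > best[0] + 1e-12:
                    best = (z, float(c))
            strat = optimal_cutpoint(scores, surv, minprop=minprop)
            assert strat.cutpoint == pytest.approx(best[1])
            assert abs(strat.zstat) == pytest.approx(best[0], abs=1e-8)

    def test_unsatisfiable_minprop_errors(self):
        scores = pd.Series([5.0] + [1.0] * 29, index=[f"s{i}" for i in range(30)])
        surv, _ = random_survival(np.random.default_rng(0), 30)
        scores.index = surv.sample_ids
        with pytest.raises(ValueError, match="cutpoint"):
            optimal_cutpoint(scores, surv, minprop=0.4)


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = kaplan_meier(surv_of([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(km.at_risk, [3, 2, 1])

    def test_censoring_handled_after_event(self):
        """(1,event),(2,censored),(3,event): S = 2/3 then (2/3)*(1 - 1/1) = 0."""
        km = kaplan_meier(surv_of([1, 2, 3], [1, 0, 1]))
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        km = kaplan_meier(surv_of([1, 2, 3], [0, 0, 0]))
        assert (km.survival == 1.0).all()

    def test_no_censoring_matches_empirical_fraction(self, rng):
        surv, _ = random_survival(rng, 40, censor_frac=0.0)
        km = kaplan_meier(surv)
        t_last = surv.time.max()
        assert km.survival_at(t_last) == pytest.approx(0.0)
        t_mid = np.median(surv.time)
        assert km.survival_at(t_mid) == pytest.approx((surv.time > t_mid).mean())


class TestLogrank:
    def test_identical_groups_give_zero(self):
        surv = surv_of([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1])
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=surv.sample_ids)
        chi2, p = logrank_test(surv, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        """A={1,2}, B={3,4}, all events: chi2 = (2 - 5/6)^2 / (17/36) = 49/17."""
        surv = surv_of([1, 2, 3, 4], [1, 1, 1, 1])
        labels = pd.Series(["A", "A", "B", "B"], index=surv.sample_ids)
        chi2, p = logrank_test(surv, labels)
        assert chi2 == pytest.approx(49 / 17, rel=1e-10)

    def test_label_swap_invariance(self, rng):
        surv, x = random_survival(rng, 50, log_hr=1.0)
        labels = pd.Series(np.where(x > 0, "hi", "lo"), index=surv.sample_ids)
        chi2a, _ = logrank_test(surv, labels)
        swapped = labels.map({"hi": "lo", "lo": "hi"})
        chi2b, _ = logrank_test(surv, swapped)
        assert chi2a == pytest.approx(chi2b)

    def test_single_group_errors(self):
        surv = surv_of([1, 2], [1, 1])
        with pytest.raises(ValueError, match="groups"):
            logrank_test(surv, pd.Series(["a", "a"], index=surv.sample_ids))


class TestTimeDependentAuc:
    def test_no_censoring_equals_mann_whitney(self, rng):
        surv, _ = random_survival(rng, 60, censor_frac=0.0)
        scores = pd.Series(rng.normal(size=60), index=surv.sample_ids)
        t = np.median(surv.time)
        auc, _ = time_dependent_auc(scores, surv, t)
        case = surv.time <= t
        expected = mann_whitney_auc(scores[case], scores[~case])
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_perfect_ordering_gives_one(self):
        times = np.arange(1.0, 11.0)
        surv = surv_of(times, [1] * 10)
        scores = pd.Series(-times, index=surv.sample_ids)  # earlier event = higher score
        auc, roc = time_dependent_auc(scores, surv, 5.5)
        assert auc == 1.0
        assert roc["tpr"].iloc[-1] == 1.0 and roc["fpr"].iloc[-1] == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(99)
        surv, _ = random_survival(rng, 2000, censor_frac=0.2)
        scores = pd.Series(rng.normal(size=2000), index=surv.sample_ids)
        auc, _ = time_dependent_auc(scores, surv, np.median(surv.time))
        assert 0.45 <= auc <= 0.55

    def test_matches_sksurv_ipcw_estimator(self, rng):
        """Independent cross-check against scikit-survival's cumulative/dynamic AUC."""
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        surv, _ = random_survival(rng, 200, censor_frac=0.3)
        scores = pd.Series(rng.normal(size=200), index=surv.sample_ids)
        t = float(np.quantile(surv.time, 0.4))
        auc, _ = time_dependent_auc(scores, surv, t)
        y = Surv.from_arrays(event=surv.event.astype(bool), time=surv.time)
        ref, _ = cumulative_dynamic_auc(y, y, scores.to_numpy(), [t])
        assert auc == pytest.approx(float(ref[0]), abs=1e-8)

    def test_no_cases_by_horizon_errors(self):
        surv = surv_of([5, 6, 7], [1, 1, 1])
        scores = pd.Series([1.0, 2.0, 3.0], index=surv.sample_ids)
        with pytest.raises(ValueError, match="t=1"):
            time_dependent_auc(scores, surv, 1.0)


class TestConcordance:
    def test_perfect_and_reversed_risk_ordering(self):
        surv = surv_of([1, 2, 3], [1, 1, 1])
        ids = surv.sample_ids
        assert concordance_index(pd.Series([3.0, 2.0, 1.0], index=ids), surv) == 1.0
        assert concordance_index(pd.Series([1.0, 2.0, 3.0], index=ids), surv) == 0.0

    def test_equals_bruteforce_enumeration(self, rng):
        for _ in range(10):
            surv, _ = random_survival(rng, 15, censor_frac=0.3)
            scores = pd.Series(rng.integers(0, 5, size=15).astype(float), index=surv.sample_ids)
            expected = cindex_oracle(scores.to_numpy(), surv.time, surv.event)
            assert concordance_index(scores, surv) == pytest.approx(expected, abs=1e-12)


class TestPrognosticModel:
    def _simulate(self, seed, n=500, b_age=0.37, b_stage=0.86):
        rng = np.random.default_rng(seed)
        age = rng.normal(0, 1, n)
        stage = (rng.random(n) < 0.4).astype(float)
        ortho = rng.normal(0, 1, n)  # unrelated to survival
        eta = b_age * age + b_stage * stage
        T = rng.exponential(1.0, n) / (0.3 * np.exp(eta))
        C = rng.exponential(1.0, n) / 0.075
        time = np.maximum(np.minimum(T, C), 1e-9)
        event = (T <= C).astype(int)
        ids = [f"s{i}" for i in range(n)]
        surv = SurvivalData.from_arrays(ids, time, event)
        cov = pd.DataFrame({"age": age, "stage": stage, "ortho": ortho}, index=ids)
        return surv, cov

    def test_recovers_known_log_hazards(self):
        """True effects lie inside the fitted 95% CIs in nearly all repetitions."""
        hits_age = hits_stage = covers_one = 0
        n_rep = 50
        for s in range(n_rep):
            surv, cov = self._simulate(4000 + s)
            res = multivariable_prognostic_model(surv, cov)
            sm = res.summary
            if sm.loc["age", "ci_lower"] <= np.exp(0.37) <= sm.loc["age", "ci_upper"]:
                hits_age += 1
            if sm.loc["stage", "ci_lower"] <= np.exp(0.86) <= sm.loc["stage", "ci_upper"]:
                hits_stage += 1
            if sm.loc["ortho", "ci_lower"] <= 1.0 <= sm.loc["ortho", "ci_upper"]:
                covers_one += 1
        assert hits_age >= 0.9 * n_rep and hits_stage >= 0.9 * n_rep
        assert 0.85 * n_rep <= covers_one  # ~95% nominal coverage

    def test_linear_predictor_additive(self):
        surv, cov = self._simulate(1)
        res = multivariable_prognostic_model(surv, cov)
        coefs = res.summary["coef"]
        manual = sum(cov[c] * coefs[c] for c in cov.columns)
        np.testing.assert_allclose(res.linear_predictor.to_numpy(), manual.to_numpy(), atol=1e-10)

    def test_categorical_expansion_against_reference(self):
        surv, cov = self._simulate(2, n=300)
        cov = cov.drop(columns="stage").assign(stage=np.where(cov["stage"] > 0, "II", "I"))
        res = multivariable_prognostic_model(surv, cov, reference={"stage": "I"})
        assert "stage[II]" in res.summary.index

    def test_constant_column_errors(self):
        surv, cov = self._simulate(3, n=100)
        cov["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            multivariable_prognostic_model(surv, cov)

    def test_predicted_survival_is_probability(self):
        surv, cov = self._simulate(4, n=200)
        res = multivariable_prognostic_model(surv, cov)
        pred = res.predict_survival([1.0, 3.0])
        assert ((pred >= 0) & (pred <= 1)).all().all()
        assert (pred[3.0] <= pred[1.0] + 1e-12).all()


class TestCalibration:
    def test_well_specified_predictions_calibrate(self):
        """Predicted survival from the true exponential model tracks the KM estimate."""
        rng = np.random.default_rng(5)
        n = 1000
        x = rng.normal(0, 1, n)
        rate = 0.3 * np.exp(0.8 * x)
        T = rng.exponential(1.0, n) / rate
        C = rng.exponential(1.0, n) / 0.08
        surv = SurvivalData.from_arrays(
            [f"s{i}" for i in range(n)], np.maximum(np.minimum(T, C), 1e-9), (T <= C).astype(int)
        )
        t = 2.0
        predicted = pd.Series(np.exp(-rate * t), index=surv.sample_ids)
        cal = calibration_curve(predicted, surv, t, bins=4)
        assert (cal["mean_predicted"] - cal["observed"]).abs().mean() <= 0.05

    def test_constant_predictions_single_bin_whole_cohort_km(self, rng):
        surv, _ = random_survival(rng, 50, censor_frac=0.2)
        predicted = pd.Series(0.7, index=surv.sample_ids)
        t = float(np.median(surv.time))
        cal = calibration_curve(predicted, surv, t, bins=3)
        assert len(cal) == 1
        assert cal["observed"].iloc[0] == pytest.approx(kaplan_meier(surv).survival_at(t))

    def test_two_bins_on_four_subjects(self):
        surv = surv_of([1, 2, 3, 4], [1, 1, 1, 1])
        predicted = pd.Series([0.1, 0.2, 0.8, 0.9], index=surv.sample_ids)
        cal = calibration_curve(predicted, surv, 2.5, bins=2)
        assert cal["n"].tolist() == [2, 2]

    def test_out_of_range_predictions_error(self, rng):
        surv, _ = random_survival(rng, 10)
        predicted = pd.Series(1.5, index=surv.sample_ids)
        with pytest.raises(ValueError, match="probabilit"):
            calibration_curve(predicted, surv, 1.0)


class TestCompareGroups:
    def test_bh_stepup_hand_case(self):
        """p = (0.01, 0.02, 0.03, 0.04), m=4 -> every adjusted p is 0.04 by step-up."""
        from mpps.survival_eval import adjust_bh

        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_complete_separation_exact_p(self):
        """5 vs 5 with one group uniformly larger: exact two-sided p = 2/252."""
        vals = pd.DataFrame({"v": [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]}, index=[f"s{i}" for i in range(10)], dtype=float)
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=vals.index)
        out = compare_groups(vals, labels, adjust="none")
        assert out.loc["v", "p"] == pytest.approx(2 / 252, rel=1e-9)

    def test_three_groups_dispatch_kruskal(self, rng):
        vals = pd.DataFrame({"v": rng.normal(size=30)}, index=[f"s{i}" for i in range(30)])
        labels = pd.Series(["a", "b", "c"] * 10, index=vals.index)
        out = compare_groups(vals, labels)
        assert np.isfinite(out.loc["v", "p"])

    def test_bh_adjusts_across_variables(self, rng):
        vals = pd.DataFrame(rng.normal(size=(40, 6)), index=[f"s{i}" for i in range(40)], columns=list("abcdef"))
        labels = pd.Series(["x"] * 20 + ["y"] * 20, index=vals.index)
        out = compare_groups(vals, labels, adjust="BH")
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_missing_label_errors(self, rng):
        vals = pd.DataFrame({"v": rng.normal(size=4)}, index=list("abcd"))
        labels = pd.Series({"a": "x", "b": "x", "c": "y"})
        with pytest.raises(ValueError, match="missing"):
            compare_groups(vals, labels)
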