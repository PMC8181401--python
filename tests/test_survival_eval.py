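import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pairrank as pr
from pairrank.errors import ValidationError
from pairrank.survival_eval import cox_models, km_curve, logrank_test, td_roc


def _surv(time, status, index=None, **covs):
    index = index or [f"s{i}" for i in range(len(time))]
    return pd.DataFrame({"time": time, "status": status, **covs}, index=index)


def manual_logrank(time, event, group):
    """Independent oracle: explicit O-E tally with hypergeometric variance."""
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, 1 - stats.chi2.cdf(chi2, df=1)


class TestTdRoc:
    def test_perfect_marker_has_auc_one(self):
        rng = np.random.default_rng(0)
        time = rng.uniform(1, 100, size=60)
        surv = _surv(time, np.ones(60, dtype=int))
        scores = pd.Series(-time, index=surv.index)  # shorter survival, higher score
        roc = td_roc(scores, surv, horizon=40.0)
        assert roc.auc == pytest.approx(1.0)

    def test_uncensored_reduces_to_binary_roc(self):
        from sklearn.metrics import roc_auc_score, roc_curve

        rng = np.random.default_rng(1)
        time = rng.uniform(1, 100, size=200)
        scores = pd.Series(-time + rng.normal(0, 20, size=200))
        surv = _surv(time, np.ones(200, dtype=int),
                     index=list(scores.index.astype(str)))
        scores.index = surv.index
        horizon = 50.0
        roc = td_roc(scores, surv, horizon)
        labels = (time <= horizon).astype(int)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)
        fpr, tpr, thr = roc_curve(labels, scores)
        # sensitivities at shared thresholds agree with sklearn's binary ROC
        for c, s in zip(roc.thresholds, roc.sensitivity):
            expected = (scores[labels == 1] > c).mean()
            assert s == pytest.approx(expected)

    def test_censored_auc_close_to_reference_estimator(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        spec = pr.CohortSpec(n_samples=400, n_genes=10, n_informative_pairs=3,
                             censoring_rate=0.3, seed=23)
        _, surv, truth = pr.simulate_cohort(spec)
        scores = truth["linear_predictor"]
        roc = td_roc(scores, surv, horizon=36.0)
        y = Surv.from_arrays(event=surv["status"].astype(bool), time=surv["time"])
        ref_auc, _ = cumulative_dynamic_auc(y, y, scores.to_numpy(), [36.0])
        assert roc.auc == pytest.approx(float(ref_auc[0]), abs=0.02)

    def test_null_scores_give_auc_half(self):
        rng = np.random.default_rng(3)
        spec = pr.CohortSpec(n_samples=1000, n_genes=10,
                             pair_coefficients=np.zeros(5), seed=3)
        _, surv, _ = pr.simulate_cohort(spec)
        scores = pd.Series(rng.normal(size=1000), index=surv.index)
        roc = td_roc(scores, surv, horizon=36.0)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_curve_monotone_and_youden_optimal(self):
        rng = np.random.default_rng(4)
        time = rng.uniform(1, 100, size=150)
        status = rng.integers(0, 2, size=150)
        status[:10] = 1
        surv = _surv(time, status)
        scores = pd.Series(-time + rng.normal(0, 30, 150), index=surv.index)
        roc = td_roc(scores, surv, horizon=50.0)
        assert (np.diff(roc.sensitivity) <= 1e-12).all()
        assert (np.diff(roc.specificity) >= -1e-12).all()
        youden = roc.sensitivity + roc.specificity - 1
        best = roc.optimal_sens + roc.optimal_spec - 1
        assert best == pytest.approx(youden.max())

    def test_no_events_before_horizon_rejected(self):
        surv = _surv([100.0, 120.0], [1, 1])
        scores = pd.Series([0.1, 0.2], index=surv.index)
        with pytest.raises(ValidationError, match="no events"):
            td_roc(scores, surv, horizon=50.0)


class TestKmCurve:
    def _sf(self, curve, t):
        eligible = curve[curve["time"] <= t]
        return eligible["survival"].iloc[-1]

    def test_three_deaths_no_censoring(self):
        surv = _surv([1.0, 2.0, 3.0], [1, 1, 1])
        curve = km_curve(surv, pd.Series("g", index=surv.index))["g"]
        assert self._sf(curve, 1) == pytest.approx(2 / 3)
        assert self._sf(curve, 2) == pytest.approx(1 / 3)
        assert self._sf(curve, 3) == pytest.approx(0.0)

    def test_censoring_reduces_risk_set_without_step(self):
        # times 1+ (censored), 2, 3: S(2) = 1/2, S(3) = 0
        surv = _surv([1.0, 2.0, 3.0], [0, 1, 1])
        curve = km_curve(surv, pd.Series("g", index=surv.index))["g"]
        assert self._sf(curve, 1) == pytest.approx(1.0)
        assert self._sf(curve, 2) == pytest.approx(0.5)
        assert self._sf(curve, 3) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        surv = _surv([1.0, 2.0, 3.0], [0, 0, 0])
        curve = km_curve(surv, pd.Series("g", index=surv.index))["g"]
        assert (curve["survival"] == 1.0).all()

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(8)
        time = rng.exponential(10, size=80)
        surv = _surv(time, np.ones(80, dtype=int))
        curve = km_curve(surv, pd.Series("g", index=surv.index))["g"]
        for t in np.quantile(time, [0.1, 0.5, 0.9]):
            assert self._sf(curve, t) == pytest.approx((time > t).mean())

    def test_empty_group_rejected(self):
        surv = _surv([1.0], [1])
        groups = pd.Series(["a"], index=surv.index)
        curves = km_curve(surv, groups)
        assert set(curves) == {"a"}


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        status = [1, 0, 1, 1, 0, 1]
        surv = _surv(time, status)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=surv.index)
        stat, p = logrank_test(surv, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_example_matches_manual_tally(self):
        time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        event = np.array([1, 0, 1, 1, 1, 0])
        group = np.array([0, 0, 0, 1, 1, 1])
        surv = _surv(time, event)
        stat, p = logrank_test(surv, pd.Series(group, index=surv.index))
        exp_stat, exp_p = manual_logrank(time, event, group)
        assert stat == pytest.approx(exp_stat)
        assert p == pytest.approx(exp_p)

    def test_matches_manual_tally_on_random_data(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            n = 40
            time = rng.exponential(10, size=n).round(1) + 0.1
            event = rng.integers(0, 2, size=n)
            if event.sum() == 0:
                event[0] = 1
            group = rng.integers(0, 2, size=n)
            if group.min() == group.max():
                group[0] = 1 - group[0]
            surv = _surv(time, event)
            stat, p = logrank_test(surv, pd.Series(group, index=surv.index))
            exp_stat, _ = manual_logrank(time, event, group)
            assert stat == pytest.approx(exp_stat, rel=1e-6)

    def test_strong_separation_detected(self):
        detections = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            n = 200
            group = np.repeat([0, 1], n // 2)
            hazard = np.where(group == 1, 4.0, 1.0)
            time = rng.exponential(1.0 / hazard * 30)
            censor = rng.exponential(60, size=n)
            surv = _surv(np.minimum(time, censor), (time <= censor).astype(int))
            _, p = logrank_test(surv, pd.Series(group, index=surv.index))
            detections += p < 0.001
        assert detections >= 10 * 0.95

    def test_single_group_rejected(self):
        surv = _surv([1.0, 2.0], [1, 1])
        with pytest.raises(ValidationError, match="2 groups"):
            logrank_test(surv, pd.Series(["a", "a"], index=surv.index))


class TestCoxModels:
    def test_true_hazard_ratio_recovered(self):
        hrs = []
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            n = 400
            group = rng.integers(0, 2, size=n)
            time = rng.exponential(30 / np.exp(np.log(4.0) * group))
            censor = rng.exponential(90, size=n)
            surv = _surv(np.minimum(time, censor), (time <= censor).astype(int),
                         exposure=group.astype(float))
            report = cox_models(surv, covariates=["exposure"])
            hrs.append(report.iloc[0]["hazard_ratio"])
        assert all(3.0 <= hr <= 5.3 for hr in hrs)

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            n = 150
            surv = _surv(rng.exponential(30, size=n),
                         np.ones(n, dtype=int),
                         noise=rng.normal(size=n))
            report = cox_models(surv, covariates=["noise"])
            row = report.iloc[0]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 18  # >= 90% nominal coverage

    def test_univariate_and_multivariate_rows(self, cohort):
        _, surv, truth = cohort
        frame = surv.copy()
        frame["score"] = truth["linear_predictor"]
        report = cox_models(frame, covariates=["age", "score"])
        assert set(report["model"]) == {"univariate", "multivariate"}
        multi = report[report["model"] == "multivariate"]
        score_row = multi[multi["term"] == "score"].iloc[0]
        assert score_row["ci_low"] <= score_row["hazard_ratio"] <= score_row["ci_high"]
        assert score_row["hazard_ratio"] > 1.5  # strong planted effect

    def test_exponential_closed_form(self):
        # no censoring, binary covariate: HR ~ ratio of rate estimates
        rng = np.random.default_rng(5)
        n = 4000
        group = np.repeat([0, 1], n // 2)
        time = rng.exponential(np.where(group == 1, 10.0, 30.0))
        surv = _surv(time, np.ones(n, dtype=int), exposure=group.astype(float))
        report = cox_models(surv, covariates=["exposure"])
        assert report.iloc[0]["hazard_ratio"] == pytest.approx(3.0, rel=0.15)
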