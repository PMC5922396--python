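"""Survival stack: transforms, KM/log-rank oracles, Cox correctness against
lifelines and classical equivalences, frailty behavior, stepwise selection,
Uno's C against brute-force pair counting, and the bootstrap comparison."""

import numpy as np
import pandas as pd
import pytest

from ctcev import survival as surv
from ctcev.simulate.cohort import CohortSimParams, generate_cohort
from .conftest import simulate_survival_frame


class TestTransforms:
    def test_printed_formulas(self):
        assert surv.count_log_transform(0) == pytest.approx(np.log(1e-4))
        assert surv.count_log_transform(1000) == pytest.approx(np.log(1.0001))
        assert surv.enzyme_log_transform(100) == pytest.approx(np.log(1.001))

    def test_applies_to_expected_columns_only(self):
        df = pd.DataFrame(
            {"ctc": [0, 10], "tdev": [100, 0], "ldh": [250.0, 100], "alp": [120.0, 80],
             "albumin": [4.0, 3.5], "age": [70, 60]}
        )
        out = surv.transform_covariates(df)
        assert out.tdev[1] == pytest.approx(np.log(1e-4))
        assert out.ldh[1] == pytest.approx(np.log(1.001))
        assert (out.albumin == df.albumin).all()
        assert set(out.attrs["transforms"]) == {"ctc", "tdev", "ldh", "alp"}

    def test_negative_rejected(self):
        with pytest.raises(surv.SurvivalError):
            surv.count_log_transform([-1])


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = surv.km_fit([1, 2, 3, 4, 5])
        lookup = dict(zip(km.times, km.survival))
        for t, s in [(1, 0.8), (2, 0.6), (3, 0.4), (4, 0.2), (5, 0.0)]:
            assert lookup[t] == pytest.approx(s)

    def test_all_censored_median_not_reached(self):
        km = surv.km_fit([1, 2, 3], [0, 0, 0])
        assert (km.survival == 1).all()
        assert np.isinf(km.median)

    def test_uncensored_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 200)
        km = surv.km_fit(t)
        empirical = 1 - np.searchsorted(np.sort(t), km.times, side="right") / t.size
        np.testing.assert_allclose(km.survival, empirical, atol=1e-12)

    def test_median_is_smallest_time_with_half_survival(self):
        km = surv.km_fit([1, 2, 3, 4, 5])
        assert km.median == 3

    def test_nonpositive_times_rejected(self):
        with pytest.raises(surv.SurvivalError):
            surv.km_fit([0.0, 1.0])


def hand_logrank_two_groups(t1, e1, t2, e2):
    """Standard observed-minus-expected log-rank over pooled event times."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 1, 0, 1])
        chi2, p = surv.logrank((t, e), (t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_table(self):
        t1 = np.array([1.0, 3, 5, 7, 9, 11.0])
        e1 = np.array([1, 1, 0, 1, 1, 0])
        t2 = np.array([2.0, 4, 6, 8, 10, 12.0])
        e2 = np.array([1, 0, 1, 1, 0, 1])
        chi2, _ = surv.logrank((t1, e1), (t2, e2))
        assert chi2 == pytest.approx(hand_logrank_two_groups(t1, e1, t2, e2), abs=1e-6)

    def test_zero_subject_group_rejected(self):
        with pytest.raises(surv.SurvivalError):
            surv.logrank(([1.0], [1]), ([], []))


class TestCox:
    def test_zero_variance_covariate_rejected(self):
        df = simulate_survival_frame(50, {"x": 0.5}, seed=1)
        df["flat"] = 1.0
        with pytest.raises(surv.SingularDesignError):
            surv.cox_fit(df, ["flat"])

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        df = simulate_survival_frame(150, {"a": 0.6, "b": -0.3}, seed=2)
        df["os_months"] = np.ceil(df["os_months"])  # force heavy ties
        ours = surv.cox_fit(df, ["a", "b"])
        cph = CoxPHFitter()
        cph.fit(df[["a", "b", "os_months", "event"]], "os_months", "event")
        np.testing.assert_allclose(ours.beta, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(
            ours.summary.se.values, cph.standard_errors_.values, atol=1e-5
        )

    def test_recovers_generative_hazard_ratio(self):
        df = simulate_survival_frame(800, {"x": np.log(2)}, seed=3)
        fit = surv.cox_fit(df, ["x"])
        row = fit.summary.loc["x"]
        assert abs(row.coef - np.log(2)) < 2 * row.se

    def test_score_test_equals_logrank_for_binary_covariate(self):
        rng = np.random.default_rng(4)
        n = 60
        g = rng.integers(0, 2, n)
        t = rng.exponential(10 * np.exp(-0.7 * g))
        e = np.ones(n, dtype=int)
        df = pd.DataFrame({"g": g, "os_months": t, "event": e})
        chi2_score, _ = surv.cox_score_test(df, "g")
        chi2_lr, _ = surv.logrank((t[g == 0], e[g == 0]), (t[g == 1], e[g == 1]))
        assert chi2_score == pytest.approx(chi2_lr, abs=1e-6)

    def test_partial_likelihood_never_decreases(self):
        df = simulate_survival_frame(300, {"a": 0.8, "b": 0.4, "c": -0.6}, seed=5)
        fit = surv.cox_fit(df, ["a", "b", "c"])
        assert (np.diff(fit.iteration_trace) >= -1e-12).all()

    def test_too_few_events_rejected(self):
        df = simulate_survival_frame(30, {"a": 0.1, "b": 0.1}, seed=6)
        df["event"] = 0
        df.loc[:1, "event"] = 1
        with pytest.raises(surv.SurvivalError):
            surv.cox_fit(df, ["a", "b"])


class TestFrailty:
    def test_zero_variance_generation_collapses_to_plain_fit(self):
        params = CohortSimParams(
            n_patients={"a": 200, "b": 200},
            coefficients={"tdev": 0.5},
            frailty_variance=0.0,
            censoring_rate=0.2,
            seed=7,
        )
        table = surv.transform_covariates(generate_cohort(params))
        plain = surv.cox_fit(table, ["tdev"])
        frail = surv.cox_fit(table, ["tdev"], frailty_col="dataset")
        assert np.abs(frail.beta - plain.beta).max() < 1e-2
        assert frail.frailty_variance <= 0.05

    def test_recovers_coefficient_under_strong_frailty(self):
        params = CohortSimParams(
            n_patients={lab: 80 for lab in "abcdef"},
            coefficients={"tdev": 0.5},
            frailty_variance=0.4,
            censoring_rate=0.2,
            seed=8,
        )
        table = surv.transform_covariates(generate_cohort(params))
        fit = surv.cox_fit(table, ["tdev"], frailty_col="dataset")
        row = fit.summary.loc["tdev"]
        assert abs(row.coef - 0.5) < 2.5 * row.se
        assert fit.frailty_variance > 0
        # estimated frailties track the generative ones
        truth = generate_cohort(params).attrs["frailty"]
        labs = sorted(truth)
        from scipy.stats import spearmanr

        rho, _ = spearmanr([truth[l] for l in labs], [fit.frailty[l] for l in labs])
        assert rho > 0.7


class TestStepwise:
    def test_single_strong_covariate_selected_among_noise(self):
        hits = 0
        for rep in range(25):
            df = simulate_survival_frame(
                300, {"signal": np.log(2), **{f"n{i}": 0.0 for i in range(5)}}, seed=100 + rep
            )
            fit, _ = surv.forward_stepwise(df, list(df.columns[:6]))
            hits += "signal" in fit.covariates
        assert hits >= 23

    def test_collinear_pair_admits_only_one(self):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        hits = 0
        for rep in range(25):
            df = simulate_survival_frame(300, {"a": np.log(2), "b": 0.0}, seed=200 + rep, corr=corr)
            fit, trace = surv.forward_stepwise(df, ["a", "b"])
            hits += len(fit.covariates) == 1
        assert hits >= 22

    def test_all_null_usually_empty_and_trace_logged(self):
        empty = 0
        for rep in range(30):
            df = simulate_survival_frame(150, {f"x{i}": 0.0 for i in range(4)}, seed=300 + rep)
            fit, trace = surv.forward_stepwise(df, [f"x{i}" for i in range(4)])
            empty += len(fit.covariates) == 0
            for step in trace:
                assert step["action"] in ("add", "drop")
        # (1 - 0.05)^4 ~ 0.81; allow broad Monte-Carlo slack
        assert empty >= 18


def brute_force_harrell_c(time, risk):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j]:
                den += 1
                num += (risk[i] > risk[j]) + 0.5 * (risk[i] == risk[j])
    return num / den


class TestUnoC:
    def test_perfect_concordance(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(10, 40)
        assert surv.uno_c(t, np.ones(40), -t, tau=1e6) == pytest.approx(1.0)

    def test_equals_brute_force_pairs_without_censoring(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            t = rng.exponential(10, 50)
            risk = rng.normal(size=50)
            assert surv.uno_c(t, np.ones(50), risk, tau=1e6) == pytest.approx(
                brute_force_harrell_c(t, risk), abs=1e-12
            )

    def test_null_risk_near_half(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10, 2000)
        c = rng.exponential(20, 2000)
        obs, e = np.minimum(t, c), (t <= c).astype(int)
        assert surv.uno_c(obs, e, rng.permutation(2000).astype(float), tau=24) == pytest.approx(
            0.5, abs=0.03
        )


class TestBootstrapDelta:
    def test_identical_models_give_zero_delta(self):
        df = simulate_survival_frame(150, {"x": 0.7}, seed=12)
        rep = surv.bootstrap_c_delta(df, ["x"], ["x"], reps=30, seed=1, tau=50)
        assert rep.delta == 0.0
        assert rep.ci_lower <= 0.0 <= rep.ci_upper
        assert rep.p_value == 1.0

    def test_strong_extra_covariate_detected(self):
        df = simulate_survival_frame(500, {"strong": 1.2, "weak": 0.3}, seed=13)
        rep = surv.bootstrap_c_delta(df, ["strong", "weak"], ["weak"], reps=100, seed=2, tau=50)
        assert rep.delta > 0
        assert rep.ci_lower > 0
        assert rep.p_value < 0.05

    def test_deterministic_for_fixed_seed(self):
        df = simulate_survival_frame(120, {"x": 0.7, "y": 0.0}, seed=14)
        a = surv.bootstrap_c_delta(df, ["x", "y"], ["x"], reps=25, seed=3, tau=50)
        b = surv.bootstrap_c_delta(df, ["x", "y"], ["x"], reps=25, seed=3, tau=50)
        assert a.delta == b.delta
        assert (a.ci_lower, a.ci_upper, a.p_value) == (b.ci_lower, b.ci_upper, b.p_value)
        assert a.reps_used == 25
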