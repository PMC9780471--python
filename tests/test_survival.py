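"""Survival validation: rates, Kaplan-Meier, Cox fits, concordance.

Each numerical routine is checked against an independent oracle: hand
product-limit arithmetic for Kaplan-Meier, a brute-force grid search of
the Breslow partial likelihood for Cox coefficients, and exhaustive
O(n^2) pair enumeration for Harrell's C.
"""

import numpy as np
import pandas as pd
import pytest

from frailtykit import (
    compare_concordance,
    concordance,
    fit_cox,
    kaplan_meier,
    person_time_rates,
    subgroup_table,
)


def _df(time, event, **cols):
    return pd.DataFrame({"follow_up_time": time, "event": event, **cols})


# ---------------------------------------------------------------- oracles


def breslow_log_partial_likelihood(beta, x, time, event):
    """Direct evaluation of the Breslow log partial likelihood."""
    lpl = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        lpl += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return lpl


def harrell_c_enumeration(time, event, risk):
    """All-pairs Harrell's C: comparable when the earlier time is an event."""
    conc = disc = tied = 0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = event[i] and (
                time[i] < time[j] or (time[i] == time[j] and not event[j])
            )
            if not comparable:
                continue
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] < risk[j]:
                disc += 1
            else:
                tied += 1
    return (conc + 0.5 * tied) / (conc + disc + tied), conc + disc + tied


# ------------------------------------------------------------------ rates


class TestPersonTimeRates:
    def test_exact_arithmetic(self):
        data = _df([70.0] * 10, [1] * 10, category=["g"] * 10)
        out = person_time_rates(data)
        assert out.loc["g", "rate"] == pytest.approx(10 / 700 * 1000)

    def test_no_deaths_rate_zero(self):
        data = _df([2.0, 3.0], [0, 0], category=["g", "g"])
        out = person_time_rates(data)
        assert out.loc["g", "rate"] == 0.0
        assert out.loc["g", "rate_ci_low"] == 0.0

    def test_zero_person_time_rejected(self):
        data = _df([0.0], [1], category=["g"])
        with pytest.raises(ValueError, match="person-time"):
            person_time_rates(data)


# --------------------------------------------------------------- KM curve


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self, rng):
        time = rng.exponential(2.0, size=60)
        data = _df(time, np.ones(60, dtype=int))
        km = kaplan_meier(data, group_col=None)["all"]
        for t in np.quantile(time, [0.1, 0.5, 0.9]):
            empirical = (time > t).mean()
            assert km.predict(t) == pytest.approx(empirical, abs=1e-12)

    def test_four_distinct_deaths_step_quarters(self):
        data = _df([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        km = kaplan_meier(data, group_col=None)["all"]
        assert [km.predict(t) for t in (1, 2, 3, 4)] == pytest.approx(
            [0.75, 0.5, 0.25, 0.0]
        )

    def test_all_censored_survival_stays_one(self):
        data = _df([1.0, 2.0, 3.0], [0, 0, 0])
        km = kaplan_meier(data, group_col=None)["all"]
        assert km.predict(3.0) == pytest.approx(1.0)

    def test_mixed_toy_matches_hand_product_limit(self):
        # deaths at 1, 2, 3, 5; censored at 2 and 4:
        # S(1)=5/6, S(2)=5/6*4/5=2/3, S(3)=2/3*2/3=4/9, S(5)=0
        data = _df([1.0, 2.0, 2.0, 3.0, 4.0, 5.0], [1, 0, 1, 1, 0, 1])
        km = kaplan_meier(data, group_col=None)["all"]
        assert km.predict(1.0) == pytest.approx(5 / 6)
        assert km.predict(2.0) == pytest.approx(2 / 3)
        assert km.predict(3.0) == pytest.approx(4 / 9)
        assert km.predict(5.0) == pytest.approx(0.0)

    def test_per_group_fit(self, rng):
        data = _df(
            rng.exponential(2, 40) + 0.01,
            rng.integers(0, 2, 40),
            category=rng.choice(["a", "b"], 40),
        )
        km = kaplan_meier(data)
        assert set(km) == {"a", "b"}


# --------------------------------------------------------------- Cox fits


class TestCox:
    def test_symmetric_toy_gives_zero_coefficient(self):
        # identical event-time patterns in both groups: score is zero at 0
        data = _df([1.0, 2.0, 1.0, 2.0], [1, 1, 1, 1], x=[0, 0, 1, 1])
        res = fit_cox(data, covariates=["x"], category_col=None)
        assert res.params["x"] == pytest.approx(0.0, abs=1e-6)

    def test_ten_subject_toy_matches_grid_search_oracle(self, rng):
        time = rng.exponential(1.0, size=10) + 0.05
        time += np.arange(10) * 1e-4  # guarantee distinct times
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
        x = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0], dtype=float)
        res = fit_cox(
            _df(time, event, x=x), covariates=["x"], category_col=None,
            tie_method="breslow",
        )
        grid = np.arange(-5.0, 5.0, 1e-3)
        lpl = [breslow_log_partial_likelihood(b, x, time, event) for b in grid]
        coarse = grid[int(np.argmax(lpl))]
        fine = np.arange(coarse - 2e-3, coarse + 2e-3, 1e-5)
        lpl = [breslow_log_partial_likelihood(b, x, time, event) for b in fine]
        best = fine[int(np.argmax(lpl))]
        assert res.params["x"] == pytest.approx(best, abs=1e-4)

    def test_score_at_zero_equals_logrank_numerator(self, rng):
        # numerical derivative of the partial likelihood at beta=0 equals
        # the observed-minus-expected log-rank numerator
        time = rng.exponential(1.0, size=30) + np.linspace(0, 1e-3, 30)
        event = rng.integers(0, 2, 30)
        event[:3] = 1
        x = rng.integers(0, 2, 30).astype(float)
        eps = 1e-6
        deriv = (
            breslow_log_partial_likelihood(eps, x, time, event)
            - breslow_log_partial_likelihood(-eps, x, time, event)
        ) / (2 * eps)
        o_minus_e = sum(
            x[i] - x[time >= time[i]].mean() for i in np.flatnonzero(event)
        )
        assert deriv == pytest.approx(o_minus_e, abs=1e-6)

    def test_agrees_with_lifelines_on_simulated_cohort(self, small_cohort):
        from lifelines import CoxPHFitter

        from frailtykit import CutpointSet, score_cohort, default_schema

        cuts = CutpointSet(
            boundaries=(0.10, 0.25, 0.45),
            labels=("fit", "pre-frail", "mildly-frail", "severely-frail"),
        )
        scored = score_cohort(small_cohort.cohort, default_schema(), cutpoints=cuts)
        res = fit_cox(scored, covariates=["age"], tie_method="efron")
        dummies = pd.get_dummies(scored["category"], dtype=float)
        df = pd.DataFrame(
            {
                "t": scored["follow_up_time"],
                "e": scored["event"],
                "age": scored["age"],
                "pre": dummies["pre-frail"],
                "mild": dummies["mildly-frail"],
                "severe": dummies["severely-frail"],
            }
        )
        cf = CoxPHFitter().fit(df, "t", "e")
        assert res.params["category[pre-frail]"] == pytest.approx(
            cf.params_["pre"], abs=1e-4
        )
        assert res.params["category[severely-frail]"] == pytest.approx(
            cf.params_["severe"], abs=1e-4
        )
        assert res.params["age"] == pytest.approx(cf.params_["age"], abs=1e-5)

    def test_constant_covariate_rejected(self):
        data = _df([1.0, 2.0, 3.0], [1, 1, 1], x=[1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            fit_cox(data, covariates=["x"], category_col=None)

    def test_too_few_event_times_rejected(self):
        data = _df([1.0, 1.0, 2.0], [1, 1, 0], x=[0, 1, 0])
        with pytest.raises(ValueError, match="event times"):
            fit_cox(data, covariates=["x"], category_col=None)

    def test_separation_is_flagged_not_silent(self):
        # all deaths in one group, all censoring in the other, with the
        # deaths strictly earlier: monotone likelihood
        data = _df(
            [1.0, 1.1, 1.2, 1.3, 9.0, 9.1, 9.2, 9.3],
            [1, 1, 1, 1, 0, 0, 0, 0],
            x=[1, 1, 1, 1, 0, 0, 0, 0],
        )
        res = fit_cox(data, covariates=["x"], category_col=None)
        assert not res.converged


class TestSubgroups:
    def test_single_level_identical_to_plain_fit(self, small_cohort):
        from frailtykit import CutpointSet, default_schema, score_cohort

        cuts = CutpointSet(
            boundaries=(0.10, 0.25, 0.45),
            labels=("fit", "pre-frail", "mildly-frail", "severely-frail"),
        )
        scored = score_cohort(small_cohort.cohort, default_schema(), cutpoints=cuts)
        scored["one"] = "all"
        tab = subgroup_table(scored, "one", covariates=["age"])
        direct = fit_cox(scored, covariates=["age"])
        assert tab["all"].params.equals(direct.params)

    def test_eventless_stratum_flagged_and_skipped(self):
        data = _df(
            [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],
            [1, 1, 1, 1, 0, 0, 0, 0],
            x=[0, 1, 0, 1, 0, 1, 0, 1],
            g=["a"] * 4 + ["b"] * 4,
        )
        with pytest.warns(UserWarning, match="skipped"):
            tab = subgroup_table(data, "g", covariates=["x"], category_col=None)
        assert tab["b"] is None
        assert tab["a"] is not None


# ------------------------------------------------------------ concordance


class TestConcordance:
    def test_perfect_ordering_no_censoring(self):
        time = np.array([4.0, 3.0, 2.0, 1.0])
        risk = np.array([1.0, 2.0, 3.0, 4.0])
        res = concordance(_df(time, [1, 1, 1, 1]), risk)
        assert res.c_index == 1.0
        assert res.n_comparable_pairs == 6

    def test_risk_independent_of_outcome_near_half(self, rng):
        n = 2000
        time = rng.exponential(1.0, n)
        risk = rng.normal(size=n)
        res = concordance(_df(time, np.ones(n, dtype=int)), risk)
        assert res.c_index == pytest.approx(0.5, abs=0.03)

    def test_eight_subject_censored_toy_equals_enumeration(self):
        time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        event = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        risk = np.array([0.9, 0.1, 0.8, 0.8, 0.3, 0.5, 0.2, 0.1])
        res = concordance(_df(time, event), risk)
        c_oracle, pairs_oracle = harrell_c_enumeration(time, event, risk)
        assert res.c_index == pytest.approx(c_oracle, abs=1e-12)
        assert res.n_comparable_pairs == pairs_oracle

    @pytest.mark.parametrize("n", [25, 100, 200])
    def test_matches_enumeration_up_to_n200(self, n, rng):
        time = rng.choice([1.0, 2.0, 3.0, 4.0, 5.0, 6.5], size=n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        risk = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=n)
        res = concordance(_df(time, event), risk)
        c_oracle, pairs_oracle = harrell_c_enumeration(time, event, risk)
        assert res.c_index == pytest.approx(c_oracle, abs=1e-12)
        assert res.n_comparable_pairs == pairs_oracle

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance(_df([1.0, 2.0], [0, 0]), [0.1, 0.2])


class TestCompareConcordance:
    def test_identical_scores_p_near_one(self, rng):
        time = rng.exponential(1.0, 150)
        event = rng.integers(0, 2, 150)
        event[0] = 1
        risk = rng.normal(size=150)
        out = compare_concordance(
            _df(time, event), risk, risk.copy(), n_boot=100, seed=3
        )
        assert out["delta"] == 0.0
        assert out["p_value"] == 1.0

    def test_informative_vs_noise_score_detected(self, rng):
        n = 400
        risk = rng.normal(size=n)
        time = rng.exponential(np.exp(-1.5 * risk))
        event = (time < 2.0).astype(int)
        time = np.minimum(time, 2.0)
        noise = rng.normal(size=n)
        out = compare_concordance(
            _df(time, event), risk, noise, n_boot=200, seed=4
        )
        assert out["c_a"] > out["c_b"]
        assert out["p_value"] < 0.01

    def test_deterministic_given_seed(self, rng):
        time = rng.exponential(1.0, 80)
        event = np.ones(80, dtype=int)
        a = rng.normal(size=80)
        b = rng.normal(size=80)
        data = _df(time, event)
        r1 = compare_concordance(data, a, b, n_boot=50, seed=9)
        r2 = compare_concordance(data, a, b, n_boot=50, seed=9)
        assert r1 == r2
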