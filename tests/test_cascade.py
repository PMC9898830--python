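"""Cascade economics: click totals, expected yields, costs, bands, rankings.

Expected values marked by hand arithmetic were computed independently
(mean-of-four clicks x duration; budget divided by expected yield) and
frozen here.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adcascade as ac
from adcascade.cascade import CascadeParams

D10 = dict(conversion_rate=0.11, duration=10.0)


def _row(stratum_id, reach, budgets, clicks, reaches=(1, 2, 3, 4)):
    return ac.AdEstimateRow(
        spec=ac.AdTargetSpec(stratum_id=stratum_id),
        potential_reach=reach,
        budget_low=budgets[0],
        budget_high=budgets[1],
        daily_reach_low_at_low_budget=reaches[0],
        daily_reach_high_at_low_budget=reaches[1],
        daily_reach_low_at_high_budget=reaches[2],
        daily_reach_high_at_high_budget=reaches[3],
        daily_clicks_low_at_low_budget=clicks[0],
        daily_clicks_high_at_low_budget=clicks[1],
        daily_clicks_low_at_high_budget=clicks[2],
        daily_clicks_high_at_high_budget=clicks[3],
    )


class TestCascadeSteps:
    @pytest.mark.parametrize(
        "quad,duration,expected",
        [
            ((288, 832, 718, 2100), 10, 9845),  # hand: mean 984.5 x 10
            ((51, 146, 128, 369), 10, 1735),  # hand: mean 173.5 x 10
            ((0, 0, 0, 0), 7, 0),
        ],
    )
    def test_total_clicks_is_duration_times_mean_of_four(self, quad, duration, expected):
        row = _row("X", 1000, (10, 20), quad)
        assert ac.total_clicks(row, duration) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "clicks,rate,expected", [(110, 0.11, 12.1), (0, 0.11, 0), (9845, 0.11, 1082.95)]
    )
    def test_expected_tests(self, clicks, rate, expected):
        assert ac.expected_tests(clicks, rate) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "tests,p,expected", [(12.1, 0.015, 0.1815), (7.3, 0.0, 0.0), (1082.95, 0.012, 12.9954)]
    )
    def test_expected_diagnoses(self, tests, p, expected):
        assert ac.expected_diagnoses(tests, p) == pytest.approx(expected)

    @given(
        clicks=st.integers(min_value=0, max_value=500),
        c=st.sampled_from([0.05, 0.11, 0.5, 1.0]),
        p=st.sampled_from([0.0, 0.012, 0.023, 1.0]),
    )
    def test_expected_diagnoses_matches_per_click_bernoulli_sum(self, clicks, c, p):
        # Independent oracle: each click independently converts to a test
        # w.p. c and that test is positive w.p. p, so the expectation is
        # the sum of the per-click Bernoulli(c)*Bernoulli(p) means.
        brute = sum(c * p for _ in range(clicks))
        tests = ac.expected_tests(clicks, c)
        assert ac.expected_diagnoses(tests, p) == pytest.approx(brute, abs=1e-9)


class TestCosts:
    @pytest.mark.parametrize(
        "budget,clicks,p,display",
        [
            (10, 110, 0.015, "55.10"),
            (7935, 9845, 0.012, "610.60"),
            (1255, 1735, 0.012, "547.99"),
        ],
    )
    def test_cost_per_diagnosis_reproduces_published_cents(self, budget, clicks, p, display):
        cost = ac.cost_per_diagnosis(budget, clicks, CascadeParams(positivity=p, **D10))
        assert ac.format_usd(cost) == display

    @pytest.mark.parametrize(
        "budget,clicks,display", [(10, 110, "0.83"), (10, 310, "0.29"), (0, 50, "0.00")]
    )
    def test_cost_per_test(self, budget, clicks, display):
        assert ac.format_usd(ac.cost_per_test(budget, clicks, 0.11)) == display

    @pytest.mark.parametrize(
        "budget,reach,display",
        [(61035, 3_300_000, "18.50"), (7935, 430_000, "18.45"), (0, 1000, "0.00")],
    )
    def test_cost_per_thousand_reach(self, budget, reach, display):
        assert ac.format_usd(ac.cost_per_thousand_reach(budget, reach)) == display

    def test_half_cent_displays_away_from_zero(self):
        # 61035 / 3300 = 18.495 exactly; displays as 18.50, not 18.49
        assert ac.display_cents(18.495) == 18.50

    @pytest.mark.parametrize(
        "daily_clicks,p,display",
        [(11, 0.015, "55.10"), (31, 0.021, "13.96"), (31.5, 0.023, "12.55")],
    )
    def test_fixed_price_cost_per_diagnosis(self, daily_clicks, p, display):
        cost = ac.fixed_price_cost_per_diagnosis(
            ac.StudyConstants(), daily_clicks, CascadeParams(positivity=p, **D10)
        )
        assert ac.format_usd(cost) == display

    def test_zero_yield_is_an_undefined_cost_not_infinity(self):
        with pytest.raises(ac.UndefinedCostError):
            ac.cost_per_diagnosis(100, 50, CascadeParams(positivity=0.0, **D10))
        with pytest.raises(ac.UndefinedCostError):
            ac.cost_per_test(100, 0, 0.11)
        with pytest.raises(ac.UndefinedCostError):
            ac.cost_per_thousand_reach(100, 0)

    @given(
        budget=st.floats(1, 1e6),
        clicks=st.floats(1, 1e5),
        c=st.floats(0.01, 1.0),
        p=st.floats(0.001, 1.0),
        factor=st.floats(1.01, 10.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_cost_strictly_decreases_in_each_yield_factor(self, budget, clicks, c, p, factor):
        base = ac.cost_per_diagnosis(budget, clicks, CascadeParams(c, p, 10))
        assert ac.cost_per_diagnosis(budget, clicks * factor, CascadeParams(c, p, 10)) < base
        if c * factor <= 1:
            assert ac.cost_per_diagnosis(budget, clicks, CascadeParams(c * factor, p, 10)) < base
        if p * factor <= 1:
            assert ac.cost_per_diagnosis(budget, clicks, CascadeParams(c, p * factor, 10)) < base

    @given(
        unit=st.floats(1, 1000),
        duration=st.floats(1, 30),
        daily=st.floats(0.1, 1000),
        c=st.floats(0.01, 1.0),
        p=st.floats(0.001, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_fixed_price_form_composes_with_general_form(self, unit, duration, daily, c, p):
        params = CascadeParams(c, p, duration)
        fixed = ac.fixed_price_cost_per_diagnosis(
            ac.StudyConstants(conversion_rate=c, duration=duration, unit_ad_budget=unit),
            daily,
            params,
        )
        general = ac.cost_per_diagnosis(unit, duration * daily, params)
        assert fixed == pytest.approx(general, rel=1e-12)


class TestEvaluate:
    def test_new_jersey_and_utah_published_costs(self):
        nj = _row("New Jersey", 88_000, (670, 2650), (69, 198, 166, 481))
        res = ac.evaluate_stratum(nj, CascadeParams(positivity=0.013, **D10))
        assert ac.format_usd(res.cost_per_diagnosis) == "508.03"
        ut = _row("Utah", 40_000, (260, 1290), (33, 97, 84, 242))
        res = ac.evaluate_stratum(ut, CascadeParams(positivity=0.012, **D10))
        assert ac.format_usd(res.cost_per_diagnosis) == "515.02"

    def test_degenerate_rates_collapse_costs_to_budget_per_click(self):
        row = _row("X", 1000, (100, 300), (10, 20, 30, 40))
        res = ac.evaluate_stratum(row, CascadeParams(1.0, 1.0, 10))
        assert res.cost_per_diagnosis == pytest.approx(res.cost_per_test)
        assert res.cost_per_diagnosis == pytest.approx(res.avg_budget / res.total_clicks)

    def test_conservation_budget_recovered_from_cost_times_diagnoses(self, state_results):
        by_state, _ = state_results
        for res in by_state.values():
            assert res.cost_per_diagnosis * res.expected_diagnoses == pytest.approx(
                res.avg_budget, rel=1e-9
            )
            assert res.expected_diagnoses <= res.expected_tests
            assert res.cost_per_diagnosis >= res.cost_per_test

    def test_table_summary_matches_published_column_totals(self, state_results):
        _, summary = state_results
        assert summary.n_strata == 50
        assert summary.total_potential_reach == 3_294_900
        assert summary.total_budget_low == 19_750
        assert summary.total_budget_high == 95_960

    def test_single_row_table_equals_evaluate_stratum(self, study, constants):
        rows, _, positivity, region_map = study
        ca = next(r for r in rows if r.stratum_id == "California")
        results, summary = ac.evaluate_table([ca], positivity, region_map, constants)
        expected = ac.evaluate_stratum(ca, CascadeParams(positivity=0.012, **D10))
        assert results == [expected]
        assert summary.n_strata == 1

    def test_unmapped_state_error_names_the_state(self, study, constants):
        rows, _, positivity, _ = study
        tiny_map = ac.RegionMap({"California": "West"})
        with pytest.raises(ac.UnknownStratumError, match="Texas"):
            ac.evaluate_table(
                [r for r in rows if r.stratum_id == "Texas"],
                positivity,
                tiny_map,
                constants,
            )

    def test_costs_scale_linearly_in_budget_at_fixed_clicks(self):
        params = CascadeParams(positivity=0.02, **D10)
        assert ac.cost_per_diagnosis(500, 100, params) == pytest.approx(
            5 * ac.cost_per_diagnosis(100, 100, params)
        )


class TestBandsAndRanking:
    @pytest.mark.parametrize(
        "value,width,label",
        [
            (243.02, 50, "200.00-249.99"),
            (0.0, 50, "0.00-49.99"),
            (250.00, 50, "250.00-299.99"),  # half-open: the boundary opens a new band
        ],
    )
    def test_assign_band_half_open_labels(self, value, width, label):
        assert ac.assign_band(value, width) == label

    def test_texas_falls_in_published_band(self, state_results):
        by_state, _ = state_results
        assert by_state["Texas"].band_label == "200.00-249.99"

    def test_reach_ranking_matches_published_order(self, state_results):
        by_state, _ = state_results
        ranked = ac.rank_strata(by_state.values(), "potential_reach", "desc")
        assert [r.stratum_id for r in ranked[:4]] == [
            "California",
            "Texas",
            "Florida",
            "New York",
        ]

    def test_california_has_highest_cost_per_diagnosis(self, state_results):
        by_state, _ = state_results
        ranked = ac.rank_strata(by_state.values(), "cost_per_diagnosis", "desc")
        assert ranked[0].stratum_id == "California"

    def test_ties_break_alphabetically_and_singleton_is_identity(self, state_results):
        by_state, _ = state_results
        one = [by_state["Texas"]]
        assert ac.rank_strata(one, "avg_budget") == one
        dup_a = by_state["Texas"]
        dup_b = by_state["Texas"]
        import dataclasses

        dup_b = dataclasses.replace(dup_b, stratum_id="Aaaa")
        assert ac.rank_strata([dup_a, dup_b], "avg_budget")[0].stratum_id == "Aaaa"

    def test_unknown_rank_key_raises_usage_error(self, state_results):
        by_state, _ = state_results
        with pytest.raises(ac.ValidationError, match="cannot rank"):
            ac.rank_strata(by_state.values(), "stratum_id")
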