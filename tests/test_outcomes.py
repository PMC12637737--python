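"""Outcome measures: person-years, rates, arm comparison, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmisim import (
    compare_arms,
    incidence_rate,
    person_years,
    pool_weighted,
    stratify,
    summarize_replicates,
)
from bmisim.disease import EventRecords
from bmisim.outcomes import replicate_measures, round_percent, round_ten, summarize_trial


def _events(dx, death, horizon=7):
    dx = np.asarray(dx)
    return EventRecords(
        agent_ids=np.arange(len(dx)),
        dx_year=dx,
        death_year=np.asarray(death),
        horizon=horizon,
    )


class TestPersonYears:
    def test_no_deaths_full_followup(self):
        ev = _events([0] * 10, [0] * 10)
        assert person_years(ev) == 70.0

    def test_death_contributes_half_year(self):
        assert person_years(_events([0], [1])) == 0.5
        assert person_years(_events([0], [4])) == 3.5

    def test_diagnosis_does_not_censor_by_default(self):
        ev = _events([2], [0])
        assert person_years(ev) == 7.0
        assert person_years(ev, censor_at_diagnosis=True) == 1.5

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 7), min_size=1, max_size=50))
    def test_matches_per_agent_loop(self, death):
        ev = _events([0] * len(death), death)
        expected = sum((k - 0.5) if k > 0 else 7.0 for k in death)
        assert person_years(ev) == pytest.approx(expected, abs=1e-9)


class TestRates:
    @pytest.mark.parametrize(
        "n_dx, py, expected",
        [(107, 10_000, 10.7), (0, 55.0, 0.0), (9_460, 884_112, 10.70)],
    )
    def test_rate_arithmetic(self, n_dx, py, expected):
        assert incidence_rate(n_dx, py) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_person_years_rejected(self):
        with pytest.raises(ValueError):
            incidence_rate(1, 0.0)


class TestCompareArms:
    def test_published_headline_values(self):
        row = compare_arms(10.7, 8.7, treated=125_700, averted=1_760)
        assert row.arr == pytest.approx(2.0)
        assert round_percent(100 * row.rrr) == 19
        assert round_percent(row.nnt_population) == 71
        assert row.nnt_rate == pytest.approx(0.5)

    def test_equal_arms_have_no_nnt(self):
        row = compare_arms(10.0, 10.0, treated=100, averted=0)
        assert row.arr == 0 and row.rrr == 0
        assert row.nnt_population is None and row.nnt_rate is None

    def test_zero_control_rate_has_undefined_rrr(self):
        assert compare_arms(0.0, 0.0, 10, 0).rrr is None

    def test_formatted_rounding(self):
        row = compare_arms(10.74, 8.71, treated=125_712, averted=1_757)
        fmt = row.formatted()
        assert fmt["control_rate"] == 10.7 and fmt["arr"] == 2.0
        assert fmt["rrr_percent"] == 19
        assert fmt["treated"] == 125_700 and fmt["averted"] == 1_760
        assert round_ten(1_764) == 1_760


class TestPooling:
    def test_equal_values_pool_to_value(self):
        assert pool_weighted([0.4, 0.4, 0.4], [1, 5, 2]) == pytest.approx(0.4)

    def test_simple_weighted_mean(self):
        assert pool_weighted([50, 100], [1, 1]) == pytest.approx(75)

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ValueError):
            pool_weighted([1.0], [0.0])
        with pytest.raises(ValueError):
            pool_weighted([1.0, 2.0], [1.0, -1.0])


class TestSummaries:
    def test_median_of_1_to_1000(self):
        s = summarize_replicates(np.arange(1, 1001))
        assert s.median == 500.5

    def test_constant_vector(self):
        s = summarize_replicates([3.0] * 8)
        assert (s.median, s.lower95, s.upper95) == (3.0, 3.0, 3.0)

    def test_normal_draws_recover_95_range(self):
        draws = np.random.default_rng(0).standard_normal(10_000)
        s = summarize_replicates(draws)
        assert s.lower95 == pytest.approx(-1.96, abs=0.1)
        assert s.upper95 == pytest.approx(1.96, abs=0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates([])


class TestStratify:
    def test_band_totals_conserve_overall(self, endtoend_results):
        """Diagnoses, person-years and averted partition exactly across
        strata within every replicate (per-replicate conservation)."""
        from bmisim.outcomes import _stratum_column

        for rep in endtoend_results[:5]:
            a = rep.agents
            py = np.where(a["death_year"] > 0, a["death_year"] - 0.5, 7.0)
            m = replicate_measures(rep)
            for by in ("subgroup", "age_band", "bmi_band"):
                groups = a.groupby(_stratum_column(a, by), observed=True).groups
                dx_sum = sum(
                    int((a.loc[idx, "dx_year_control"] > 0).sum())
                    for idx in groups.values()
                )
                py_sum = sum(float(py[idx].sum()) for idx in groups.values())
                averted_sum = sum(
                    int((a.loc[idx, "dx_year_control"] > 0).sum())
                    - int((a.loc[idx, "dx_year_intervention"] > 0).sum())
                    for idx in groups.values()
                )
                assert dx_sum == m["diagnoses_control"]
                assert py_sum == pytest.approx(m["person_years"], abs=1e-9)
                assert averted_sum == m["averted"]

    def test_single_stratum_equals_overall(self, endtoend_results):
        rep = endtoend_results[0]
        table = stratify([rep], by="subgroup")
        m = replicate_measures(rep)
        assert table["diagnoses_control_median"].sum() == m["diagnoses_control"]
        assert table["person_years_median"].sum() == pytest.approx(m["person_years"])
        assert table["averted_median"].sum() == m["averted"]

    def test_rrr_rises_with_baseline_bmi(self, endtoend_results):
        """Relative reduction scales with baseline BMI from band 18.5-19 up
        to 25-26 (a positive trend, as in the stratified findings)."""
        table = stratify(endtoend_results, by="bmi_band")
        bands = ["18.5-19", "19-20", "20-21", "21-22", "22-23", "23-24",
                 "24-25", "25-26"]
        rrr = table.loc[bands, "rrr_median"].to_numpy()
        x = np.arange(len(bands))
        slope = np.polyfit(x, rrr, 1)[0]
        assert slope > 0
        assert rrr[-1] > rrr[0]

    def test_unknown_stratum_rejected(self, endtoend_results):
        with pytest.raises(ValueError):
            stratify(endtoend_results[:1], by="zodiac_sign")


def test_summarize_trial_shape(endtoend_results):
    table = summarize_trial(endtoend_results[:5])
    assert {"measure", "median", "lower95", "upper95"} <= set(table.columns)
    assert "control_rate" in set(table["measure"])
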