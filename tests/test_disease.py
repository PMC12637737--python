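"""Annual diabetes/mortality cycle and the hazard-intercept calibration."""

import numpy as np
import pytest
from scipy.special import logit

from bmisim import (
    SubgroupKey,
    annual_diabetes_prob,
    calibrate_hazard,
    sample_bmi_deltas,
    simulate_agent,
    simulate_cohort,
)
from bmisim.bmi import BmiOutcome
from bmisim.cohort import CRN_LENGTH, Agent, generate_eligible_cohort
from bmisim.disease import CalibrationError
from bmisim.subgroups import SUBGROUPS


def _flat_hazard(params, p_annual, mortality=0.0):
    """All covariate effects off, identical annual probability everywhere."""
    hz = params.diabetes_hazard
    hz.beta_age = [0.0] * 7
    hz.beta_bmi = {c: 0.0 for c in hz.beta_bmi}
    hz.beta_delta_bmi = 0.0
    for g in SUBGROUPS:
        hz.intercept[g] = float(logit(p_annual))
        params.mortality[g] = [mortality] * 7
    return params


class TestAnnualProbability:
    def test_all_zero_coefficients_give_half(self, default_params):
        _flat_hazard(default_params, 0.5)
        state = dict(subgroup="black_msm", age=35, bmi_current=26.0, delta_bmi_to_date=0.0)
        assert annual_diabetes_prob(state, default_params) == pytest.approx(0.5)

    def test_zero_gain_coefficient_nulls_delta(self, default_params):
        default_params.diabetes_hazard.beta_delta_bmi = 0.0
        base = dict(subgroup="white_wwid", age=45, bmi_current=24.0, delta_bmi_to_date=0.0)
        gained = dict(base, delta_bmi_to_date=2.0)
        assert annual_diabetes_prob(base, default_params) == annual_diabetes_prob(
            gained, default_params
        )

    def test_gain_odds_ratio_closed_form(self, default_params):
        """+2 kg/m2 of gain multiplies the odds by exp(2 * beta_delta_bmi)."""
        beta = default_params.diabetes_hazard.beta_delta_bmi
        base = dict(subgroup="black_msm", age=40, bmi_current=26.0, delta_bmi_to_date=0.0)
        gained = dict(base, delta_bmi_to_date=2.0)
        p0 = annual_diabetes_prob(base, default_params)
        p1 = annual_diabetes_prob(gained, default_params)
        odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds_ratio == pytest.approx(np.exp(2 * beta), rel=1e-9)

    def test_only_positive_gain_enters(self, default_params):
        base = dict(subgroup="black_msm", age=40, bmi_current=26.0, delta_bmi_to_date=0.0)
        lost = dict(base, delta_bmi_to_date=-2.0)
        assert annual_diabetes_prob(lost, default_params) == annual_diabetes_prob(
            base, default_params
        )

    def test_monotone_in_bmi_category(self, default_params):
        probs = [
            annual_diabetes_prob(
                dict(subgroup="black_msm", age=40, bmi_current=b, delta_bmi_to_date=0.0),
                default_params,
            )
            for b in (20.0, 27.0, 33.0)
        ]
        assert probs[0] < probs[1] < probs[2]

    def test_unknown_subgroup_rejected(self, default_params):
        with pytest.raises(ValueError):
            annual_diabetes_prob(
                dict(subgroup="martian_msm", age=40, bmi_current=26, delta_bmi_to_date=0),
                default_params,
            )


def _single_agent(crn_diab=0.99, crn_mort=0.99, prevalent=False):
    crn = np.full(CRN_LENGTH, 0.5)
    crn[5:12] = crn_diab
    crn[12:19] = crn_mort
    return Agent(
        id=0, subgroup=SubgroupKey.BLACK_MSM, entry_year=2013, age0=40.0,
        bmi0=26.0, prevalent_diabetes=prevalent, crn=crn,
    )


class TestSimulation:
    def test_prevalent_diabetes_never_diagnosed(self, default_params):
        _flat_hazard(default_params, 0.999)
        agent = _single_agent(crn_diab=0.001, prevalent=True)
        events = simulate_agent(agent, BmiOutcome(bmi0=26.0, delta24=0.0), default_params)
        assert events.dx_year[0] == 0

    def test_survivor_with_high_draws_reaches_horizon(self, default_params):
        _flat_hazard(default_params, 0.1, mortality=0.0)
        agent = _single_agent(crn_diab=0.99, crn_mort=0.99)
        events = simulate_agent(agent, BmiOutcome(bmi0=26.0, delta24=0.0), default_params)
        assert events.dx_year[0] == 0
        assert events.death_year[0] == 0
        assert events.followup_end[0] == 7

    def test_death_censors_diagnosis_same_year(self, default_params):
        _flat_hazard(default_params, 0.999, mortality=0.999)
        agent = _single_agent(crn_diab=0.001, crn_mort=0.001)
        events = simulate_agent(agent, BmiOutcome(bmi0=26.0, delta24=0.0), default_params)
        assert events.death_year[0] == 1 and events.dx_year[0] == 0

    def test_cumulative_incidence_closed_form(self, default_params):
        """Constant p = 0.01, no mortality: 7-year risk is 1 - 0.99^7."""
        p = 0.01
        _flat_hazard(default_params, p, mortality=0.0)
        n = 10_000
        cohort = generate_eligible_cohort(default_params, SubgroupKey.BLACK_MSM, n, rng=5)
        path = BmiOutcome(bmi0=cohort.bmi0, delta24=np.zeros(n))
        events = simulate_cohort(cohort, path, default_params)
        expected = 1 - (1 - p) ** 7
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(events.n_diagnoses / n - expected) < 3 * se


class TestCalibration:
    def test_fixed_point_leaves_intercept(self, default_params):
        """Recalibrating to the rate a subgroup already produces is a no-op."""
        key = SubgroupKey.WHITE_MSM
        cohort = generate_eligible_cohort(
            default_params, key, 20_000, rng=np.random.default_rng([0, SUBGROUPS.index(key)])
        )
        path = sample_bmi_deltas(cohort, default_params)
        from bmisim.disease import _control_rate

        current = _control_rate(cohort, path, default_params)
        calibrated, report = calibrate_hazard(
            default_params, {key: current}, n_cal=20_000, seed=0
        )
        assert report.loc[0, "achieved_rate"] == pytest.approx(current, rel=0.02)
        assert calibrated.diabetes_hazard.intercept[key] == pytest.approx(
            default_params.diabetes_hazard.intercept[key], abs=0.1
        )

    def test_doubled_target_raises_intercept(self, default_params):
        key = SubgroupKey.BLACK_MSM
        lo, _ = calibrate_hazard(default_params, {key: 10.0}, n_cal=8_000, seed=1)
        hi, _ = calibrate_hazard(default_params, {key: 20.0}, n_cal=8_000, seed=1)
        assert (
            hi.diabetes_hazard.intercept[key] > lo.diabetes_hazard.intercept[key]
        )

    def test_parameter_recovery(self, default_params):
        """Simulate with known intercepts, re-calibrate to the realized rates,
        and recover the truth — the module's core correctness check."""
        keys = [SubgroupKey.BLACK_MSM, SubgroupKey.WHITE_WWID, SubgroupKey.HISPANIC_HET_MEN]
        truth = {k: default_params.diabetes_hazard.intercept[k] for k in keys}
        from bmisim.disease import _control_rate

        rates = {}
        for k in keys:
            gi = SUBGROUPS.index(k)
            cohort = generate_eligible_cohort(
                default_params, k, 40_000, rng=np.random.default_rng([77, gi])
            )
            path = sample_bmi_deltas(cohort, default_params)
            rates[k] = _control_rate(cohort, path, default_params)

        shifted = default_params.model_copy(deep=True)
        for k in keys:
            shifted.diabetes_hazard.intercept[k] = truth[k] - 1.0
        recovered, _ = calibrate_hazard(shifted, rates, n_cal=40_000, seed=202)
        for k in keys:
            assert recovered.diabetes_hazard.intercept[k] == pytest.approx(
                truth[k], abs=0.05
            )

    def test_unreachable_target_fails_loudly(self, default_params):
        with pytest.raises(CalibrationError):
            calibrate_hazard(
                default_params,
                {SubgroupKey.WHITE_MSM: 900.0},
                n_cal=2_000,
                seed=0,
                bracket=(-14.0, -6.0),
            )

    def test_nonpositive_target_rejected(self, default_params):
        with pytest.raises(ValueError):
            calibrate_hazard(default_params, {SubgroupKey.WHITE_MSM: 0.0}, n_cal=1_000)

    def test_gain_coefficient_widens_arm_gap(self, default_params):
        """Raising beta_delta_bmi raises the control rate and the arm gap."""
        from bmisim import TrialConfig, run_replicate
        from bmisim.outcomes import replicate_measures

        config = TrialConfig(replicates=1, scale=0.05, base_seed=3)
        base = replicate_measures(run_replicate(default_params, config, 3))
        default_params.diabetes_hazard.beta_delta_bmi *= 3
        boosted = replicate_measures(run_replicate(default_params, config, 3))
        assert boosted["control_rate"] > base["control_rate"]
        assert boosted["arr"] > base["arr"]
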