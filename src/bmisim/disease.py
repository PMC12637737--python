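"""Annual-cycle simulation of incident diabetes and death over seven years.

Each follow-up year, in order: the mortality draw is evaluated first (death
censors the agent mid-year); among survivors still at risk — no prevalent
diabetes and no prior incident diagnosis — the diabetes draw is compared
with the annual diagnosis probability from a logistic hazard evaluated at
the year-start state (age, current BMI category, cumulative BMI gain).
Agents continue after a diagnosis until death or the horizon, because
person-time is censored at death only.

The module also provides the calibration routine that fixes the
per-subgroup hazard intercepts by monotone root-finding against target
control-arm rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .bmi import BmiOutcome, bmi_category_index, sample_bmi_deltas
from .cohort import CRN_DIABETES, CRN_MORTALITY, Agent, AgentCohort, generate_eligible_cohort
from .params import ParameterSet
from .subgroups import BMI_CATEGORIES, SUBGROUPS, SubgroupKey, age_band_index

__all__ = [
    "HORIZON_YEARS",
    "EventRecords",
    "annual_diabetes_prob",
    "simulate_cohort",
    "simulate_agent",
    "CalibrationError",
    "calibrate_hazard",
]

HORIZON_YEARS = 7


@dataclass
class EventRecords:
    """Per-agent event times over the follow-up horizon.

    ``dx_year`` / ``death_year`` are 1-based follow-up year indices, 0 when
    the event did not occur.  ``followup_end`` is min(horizon, death year).
    """

    agent_ids: np.ndarray
    dx_year: np.ndarray
    death_year: np.ndarray
    horizon: int = HORIZON_YEARS

    def __len__(self) -> int:
        return self.agent_ids.shape[0]

    @property
    def followup_end(self) -> np.ndarray:
        return np.where(self.death_year > 0, self.death_year, self.horizon)

    @property
    def n_diagnoses(self) -> int:
        return int(np.count_nonzero(self.dx_year))

    @property
    def n_deaths(self) -> int:
        return int(np.count_nonzero(self.death_year))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent_id": self.agent_ids,
                "dx_year": self.dx_year,
                "death_year": self.death_year,
                "followup_end": self.followup_end,
            }
        )


def _hazard_arrays(params: ParameterSet):
    hz = params.diabetes_hazard
    intercepts = np.array([hz.intercept[g] for g in SUBGROUPS])
    beta_age = np.asarray(hz.beta_age, dtype=float)
    beta_bmi = np.array([hz.beta_bmi[c] for c in BMI_CATEGORIES])
    return intercepts, beta_age, beta_bmi, hz.beta_delta_bmi


def annual_diabetes_prob(agent_state: dict, params: ParameterSet) -> float:
    """Annual probability of incident diabetes diagnosis for one agent-state.

    ``agent_state`` carries ``subgroup`` (:class:`SubgroupKey`), ``age``
    (years), ``bmi_current`` (kg/m^2) and ``delta_bmi_to_date`` (signed
    kg/m^2; only positive gain enters the hazard).
    """
    hz = params.diabetes_hazard
    key = SubgroupKey(agent_state["subgroup"])
    if key not in hz.intercept:
        raise ValueError(f"no hazard intercept for subgroup {key!r}")
    lin = (
        hz.intercept[key]
        + hz.beta_age[age_band_index(agent_state["age"])]
        + hz.beta_bmi[BMI_CATEGORIES[bmi_category_index(agent_state["bmi_current"])]]
        + hz.beta_delta_bmi * max(float(agent_state["delta_bmi_to_date"]), 0.0)
    )
    p = float(expit(lin)) * params.hazard_prob_scale
    return float(np.clip(p, 0.0, 1.0 - 1e-12))


def simulate_cohort(
    cohort: AgentCohort,
    bmi_path: BmiOutcome,
    params: ParameterSet,
    horizon: int = HORIZON_YEARS,
) -> EventRecords:
    """Vectorized annual-cycle simulation; consumes only the cohort's CRN."""
    n = len(cohort)
    intercepts, beta_age, beta_bmi, beta_delta = _hazard_arrays(params)
    mort_table = np.array([params.mortality[g] for g in SUBGROUPS])

    crn_diab = cohort.crn[:, CRN_DIABETES]
    crn_mort = cohort.crn[:, CRN_MORTALITY]

    dx_year = np.zeros(n, dtype=np.int64)
    death_year = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    gi = cohort.subgroup_idx

    for t in range(1, horizon + 1):
        band = age_band_index(cohort.age0 + (t - 1))
        q_mort = mort_table[gi, band]
        dies = alive & (crn_mort[:, t - 1] < q_mort)
        death_year[dies] = t
        alive &= ~dies

        at_risk = alive & ~cohort.prevalent_diabetes & (dx_year == 0)
        if not np.any(at_risk):
            continue
        bmi_t = bmi_path.bmi_at_year_start(t)
        gain_t = bmi_path.gain_to_year_start(t)
        lin = (
            intercepts[gi]
            + beta_age[band]
            + beta_bmi[bmi_category_index(bmi_t)]
            + beta_delta * gain_t
        )
        p = np.clip(expit(lin) * params.hazard_prob_scale, 0.0, 1.0 - 1e-12)
        dx = at_risk & (crn_diab[:, t - 1] < p)
        dx_year[dx] = t

    return EventRecords(
        agent_ids=cohort.ids.copy(), dx_year=dx_year, death_year=death_year,
        horizon=horizon,
    )


def simulate_agent(
    agent: Agent,
    bmi_path: BmiOutcome,
    params: ParameterSet,
    horizon: int = HORIZON_YEARS,
):
    """Single-agent wrapper around :func:`simulate_cohort`."""
    cohort = AgentCohort(
        ids=np.array([agent.id]),
        subgroup_idx=np.array([SUBGROUPS.index(agent.subgroup)]),
        entry_year=np.array([agent.entry_year]),
        age0=np.array([agent.age0]),
        bmi0=np.array([agent.bmi0]),
        prevalent_diabetes=np.array([agent.prevalent_diabetes]),
        crn=agent.crn.reshape(1, -1),
    )
    path = BmiOutcome(
        bmi0=np.atleast_1d(np.asarray(bmi_path.bmi0, dtype=float)),
        delta24=np.atleast_1d(np.asarray(bmi_path.delta24, dtype=float)),
    )
    return simulate_cohort(cohort, path, params, horizon=horizon)


# ---------------------------------------------------------------------------
# Calibration


class CalibrationError(RuntimeError):
    """Raised when the intercept search interval does not bracket the target."""


def _control_rate(cohort: AgentCohort, path: BmiOutcome, params: ParameterSet) -> float:
    events = simulate_cohort(cohort, path, params)
    py = np.where(events.death_year > 0, events.death_year - 0.5, events.horizon).sum()
    return 1000.0 * events.n_diagnoses / py


def calibrate_hazard(
    params: ParameterSet,
    targets: dict[SubgroupKey, float],
    n_cal: int = 20_000,
    seed: int = 0,
    tol: float = 0.02,
    bracket: tuple[float, float] = (-14.0, 0.0),
) -> tuple[ParameterSet, pd.DataFrame]:
    """Fix each subgroup's hazard intercept to hit a target control-arm rate.

    For each subgroup, a fixed cohort of ``n_cal`` eligible agents is
    simulated under the control arm; the intercept is found by monotone
    root-finding (Brent's method on the simulated rate minus the target, a
    step function of the intercept that is non-decreasing because every
    agent's draws are held fixed).  Age/BMI/gain coefficients are taken as
    given.  Returns the updated set and a calibration report with the
    achieved rates.

    ``targets`` are rates per 1,000 person-years; relative agreement within
    ``tol`` is required, else :class:`CalibrationError`.
    """
    out = params.model_copy(deep=True)
    rows = []
    for gi, key in enumerate(SUBGROUPS):
        if key not in targets:
            continue
        target = float(targets[key])
        if target <= 0:
            raise ValueError(f"target rate for {key.value} must be positive")
        rng = np.random.default_rng([seed, gi])
        cohort = generate_eligible_cohort(out, key, n_cal, rng)
        path = sample_bmi_deltas(cohort, out)

        def objective(b0: float) -> float:
            out.diabetes_hazard.intercept[key] = b0
            return _control_rate(cohort, path, out) - target

        lo, hi = bracket
        f_lo, f_hi = objective(lo), objective(hi)
        if f_lo > 0 or f_hi < 0:
            raise CalibrationError(
                f"{key.value}: interval {bracket} does not bracket target "
                f"{target} (rate range [{f_lo + target:.3f}, {f_hi + target:.3f}])"
            )
        b0 = brentq(objective, lo, hi, xtol=1e-6)
        out.diabetes_hazard.intercept[key] = float(b0)
        achieved = _control_rate(cohort, path, out)
        if abs(achieved - target) > tol * target:
            raise CalibrationError(
                f"{key.value}: achieved rate {achieved:.3f} misses target "
                f"{target:.3f} beyond {tol:.0%} relative tolerance"
            )
        rows.append(
            {
                "subgroup": key.value,
                "target_rate": target,
                "achieved_rate": achieved,
                "intercept": float(b0),
                "n_cal": n_cal,
            }
        )
    report = pd.DataFrame(rows)
    return out, report
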