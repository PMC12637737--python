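"""24-month BMI trajectories and the maintenance intervention transform.

BMI is modelled as a two-point trajectory: the value at ART initiation and
the value 24 months later.  For hazard evaluation the trajectory is linearly
interpolated within the first two years and held constant afterwards.  The
maintenance intervention caps the 24-month change at zero — BMI may decrease
naturally but any increase is prevented — for agents who are enrolled and
adherent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .cohort import (
    CRN_GAIN_INDICATOR,
    CRN_GAIN_MAGNITUDE,
    CRN_LOSS_MAGNITUDE,
    Agent,
    AgentCohort,
)
from .params import ParameterSet
from .subgroups import BMI_CATEGORIES, BMI_CUTS, SUBGROUPS

__all__ = [
    "BmiOutcome",
    "bmi_category",
    "bmi_category_index",
    "sample_bmi_delta",
    "sample_bmi_deltas",
    "apply_maintenance",
]


def bmi_category_index(bmi):
    """0=underweight, 1=normal, 2=overweight, 3=obese (cut points 18.5/25/30)."""
    bmi_arr = np.asarray(bmi, dtype=float)
    if np.any(bmi_arr <= 0):
        raise ValueError("BMI must be positive")
    idx = np.searchsorted(np.asarray(BMI_CUTS), bmi_arr, side="right")
    return idx if idx.ndim else int(idx)


def bmi_category(bmi):
    """BMI category label(s) for scalar or array input."""
    idx = bmi_category_index(bmi)
    if np.ndim(idx) == 0:
        return BMI_CATEGORIES[int(idx)]
    return np.asarray(BMI_CATEGORIES, dtype=object)[idx]


@dataclass
class BmiOutcome:
    """Signed 24-month BMI change and the implied endpoint state.

    Fields are scalars for a single agent or aligned arrays for a cohort;
    ``bmi24 = bmi0 + delta24`` always holds.
    """

    bmi0: np.ndarray | float
    delta24: np.ndarray | float

    @property
    def bmi24(self):
        return self.bmi0 + self.delta24

    @property
    def category0(self):
        return bmi_category(self.bmi0)

    @property
    def category24(self):
        return bmi_category(self.bmi24)

    def bmi_at_year_start(self, t: int):
        """Interpolated BMI at the start of follow-up year t (1-based).

        Year 1 starts at month 0, year 2 at month 12 (half the 24-month
        change accrued), years 3+ at the month-24 value, held constant.
        """
        frac = min(max(t - 1, 0), 2) / 2.0
        return self.bmi0 + frac * self.delta24

    def gain_to_year_start(self, t: int):
        """Cumulative positive BMI gain at the start of year t (>= 0)."""
        frac = min(max(t - 1, 0), 2) / 2.0
        return frac * np.maximum(self.delta24, 0.0)


def sample_bmi_deltas(cohort: AgentCohort, params: ParameterSet) -> BmiOutcome:
    """Sample every agent's 24-month BMI change from its reserved CRN draws.

    With probability ``p_gain`` (gain-indicator draw) the change is a
    positive log-normal magnitude; otherwise a non-positive half-normal
    loss.  Purely a deterministic function of the cohort's CRN — calling
    twice gives identical outcomes.
    """
    n = len(cohort)
    p_gain = np.empty(n)
    gain_mu = np.empty(n)
    gain_sigma = np.empty(n)
    loss_scale = np.empty(n)
    for gi, key in enumerate(SUBGROUPS):
        mask = cohort.subgroup_idx == gi
        if not np.any(mask):
            continue
        m = params.bmi_change_model[key]
        p_gain[mask] = m.p_gain
        gain_mu[mask] = m.gain_mu
        gain_sigma[mask] = m.gain_sigma
        loss_scale[mask] = m.loss_scale

    gains = np.exp(gain_mu + gain_sigma * ndtri(cohort.crn[:, CRN_GAIN_MAGNITUDE]))
    losses = -loss_scale * np.abs(
        ndtri(0.5 + 0.5 * cohort.crn[:, CRN_LOSS_MAGNITUDE])
    )
    is_gain = cohort.crn[:, CRN_GAIN_INDICATOR] < p_gain
    delta = np.where(is_gain, gains, losses) * params.bmi_change_scale
    return BmiOutcome(bmi0=cohort.bmi0.copy(), delta24=delta)


def sample_bmi_delta(agent: Agent, params: ParameterSet) -> BmiOutcome:
    """Single-agent convenience wrapper around :func:`sample_bmi_deltas`."""
    m = params.bmi_change_model[agent.subgroup]
    if agent.crn[CRN_GAIN_INDICATOR] < m.p_gain:
        delta = float(np.exp(m.gain_mu + m.gain_sigma * ndtri(agent.crn[CRN_GAIN_MAGNITUDE])))
    else:
        delta = float(-m.loss_scale * abs(ndtri(0.5 + 0.5 * agent.crn[CRN_LOSS_MAGNITUDE])))
    return BmiOutcome(bmi0=agent.bmi0, delta24=delta * params.bmi_change_scale)


def apply_maintenance(outcome: BmiOutcome, enrolled, adherent) -> BmiOutcome:
    """Cap the 24-month change at zero for enrolled-and-adherent agents.

    BMI decreases pass through unchanged; increases are removed.  Idempotent
    and never increases ``bmi24``.  ``enrolled``/``adherent`` may be scalars
    or aligned boolean arrays.
    """
    active = np.logical_and(enrolled, adherent)
    delta = np.where(active, np.minimum(outcome.delta24, 0.0), outcome.delta24)
    if np.ndim(outcome.delta24) == 0:
        delta = float(delta)
    return BmiOutcome(bmi0=outcome.bmi0, delta24=delta)
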