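"""Simulated ART-initiator cohorts.

Agents enter the simulation at ART initiation (calendar years 2013-2017)
with a baseline age, BMI and prevalent-diabetes state drawn from the
subgroup-specific distributions in a :class:`~bmisim.params.ParameterSet`.
Each agent also receives a fixed-length vector of uniform(0, 1) draws — the
common random numbers (CRN) — at generation time.  Every downstream
stochastic decision (BMI gain indicator and magnitudes, enrollment,
adherence, the seven annual diabetes draws and seven annual mortality
draws) consumes these pre-drawn numbers, never fresh randomness, so the
control and intervention arms are a paired counterfactual on the same
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .params import ENTRY_YEARS, AGE_RANGE, ParameterSet
from .subgroups import SUBGROUPS, SubgroupKey

__all__ = [
    "CRN_GAIN_INDICATOR",
    "CRN_GAIN_MAGNITUDE",
    "CRN_LOSS_MAGNITUDE",
    "CRN_ENROLLMENT",
    "CRN_ADHERENCE",
    "CRN_DIABETES",
    "CRN_MORTALITY",
    "CRN_LENGTH",
    "Agent",
    "AgentCohort",
    "generate_cohort",
    "generate_eligible_cohort",
    "eligible",
    "eligible_mask",
]

# Fixed CRN layout (columns of the per-agent draw matrix).  The order is
# part of the reproducibility contract: changing it changes every simulation.
CRN_GAIN_INDICATOR = 0
CRN_GAIN_MAGNITUDE = 1
CRN_LOSS_MAGNITUDE = 2
CRN_ENROLLMENT = 3
CRN_ADHERENCE = 4
CRN_DIABETES = slice(5, 12)    # 7 annual diabetes draws
CRN_MORTALITY = slice(12, 19)  # 7 annual mortality draws
CRN_LENGTH = 19

_ELIGIBLE_BMI = (18.5, 30.0)


class Agent(NamedTuple):
    """Single-agent view into an :class:`AgentCohort` (scalar fields)."""

    id: int
    subgroup: SubgroupKey
    entry_year: int
    age0: float
    bmi0: float
    prevalent_diabetes: bool
    crn: np.ndarray  # length CRN_LENGTH


@dataclass
class AgentCohort:
    """Column-array container for a simulated cohort of ART initiators."""

    ids: np.ndarray
    subgroup_idx: np.ndarray      # index into subgroups.SUBGROUPS
    entry_year: np.ndarray
    age0: np.ndarray
    bmi0: np.ndarray
    prevalent_diabetes: np.ndarray
    crn: np.ndarray               # shape (n, CRN_LENGTH)
    scale: float = 1.0
    seed: int | None = None

    def __len__(self) -> int:
        return self.ids.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    def agent(self, i: int) -> Agent:
        return Agent(
            id=int(self.ids[i]),
            subgroup=SUBGROUPS[int(self.subgroup_idx[i])],
            entry_year=int(self.entry_year[i]),
            age0=float(self.age0[i]),
            bmi0=float(self.bmi0[i]),
            prevalent_diabetes=bool(self.prevalent_diabetes[i]),
            crn=self.crn[i],
        )

    def subset(self, mask: np.ndarray) -> "AgentCohort":
        return AgentCohort(
            ids=self.ids[mask],
            subgroup_idx=self.subgroup_idx[mask],
            entry_year=self.entry_year[mask],
            age0=self.age0[mask],
            bmi0=self.bmi0[mask],
            prevalent_diabetes=self.prevalent_diabetes[mask],
            crn=self.crn[mask],
            scale=self.scale,
            seed=self.seed,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Baseline-state table (CRN draws deliberately omitted)."""
        return pd.DataFrame(
            {
                "id": self.ids,
                "subgroup": [SUBGROUPS[i].value for i in self.subgroup_idx],
                "entry_year": self.entry_year,
                "age0": self.age0,
                "bmi0": self.bmi0,
                "prevalent_diabetes": self.prevalent_diabetes,
            }
        )


def eligible(agent: Agent) -> bool:
    """Intervention eligibility: normal/overweight BMI and no prior diabetes.

    The BMI band is closed at 18.5 (underweight is BMI < 18.5) and open at
    30 (obesity is BMI >= 30).
    """
    return (
        _ELIGIBLE_BMI[0] <= agent.bmi0 < _ELIGIBLE_BMI[1]
        and not agent.prevalent_diabetes
    )


def eligible_mask(cohort: AgentCohort) -> np.ndarray:
    return (
        (cohort.bmi0 >= _ELIGIBLE_BMI[0])
        & (cohort.bmi0 < _ELIGIBLE_BMI[1])
        & ~cohort.prevalent_diabetes
    )


# ---------------------------------------------------------------------------
# Sampling


def _sample_ages(dist, n: int, rng: np.random.Generator) -> np.ndarray:
    """Split-normal around the median, folded halves, truncated by clipping."""
    left = rng.random(n) < 0.5
    z = np.abs(rng.standard_normal(n))
    ages = np.where(
        left,
        dist.median_age - dist.sigma_lower * z,
        dist.median_age + dist.sigma_upper * z,
    )
    return np.clip(ages, AGE_RANGE[0], AGE_RANGE[1])


def _sample_bmi(dist, n: int, rng: np.random.Generator,
                eligible_only: bool = False) -> np.ndarray:
    """Baseline BMI: category draw then within-category shape.

    Underweight uniform [16, 18.5); normal uniform [18.5, 25); overweight
    triangular on [25, 30) with mode 30; obese uniform [30, 40).
    """
    if eligible_only:
        p = np.array([0.0, 1.0, 0.0])
    else:
        p = np.array([dist.p_underweight, dist.p_normal_overweight, dist.p_obese])
        p = p / p.sum()
    cat = rng.choice(3, size=n, p=p)
    u = rng.random(n)
    v = rng.random(n)  # normal-vs-overweight split within the eligible band
    bmi = np.empty(n)

    uw = cat == 0
    bmi[uw] = 16.0 + 2.5 * u[uw]

    mid = cat == 1
    ow = mid & (v < dist.overweight_share)
    nm = mid & ~ow
    bmi[nm] = 18.5 + 6.5 * u[nm]
    bmi[ow] = 25.0 + 5.0 * np.sqrt(u[ow])  # density rising linearly toward 30

    ob = cat == 2
    bmi[ob] = 30.0 + 10.0 * u[ob]
    return bmi


def _sample_baseline(
    params: ParameterSet,
    key: SubgroupKey,
    n: int,
    rng: np.random.Generator,
    eligible_only: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (age0, bmi0, prevalent_diabetes) for n agents of one subgroup."""
    ages = _sample_ages(params.age_dist[key], n, rng)
    bmi = _sample_bmi(params.baseline_bmi_dist[key], n, rng, eligible_only)
    bmi = bmi * params.baseline_bmi_scale
    if eligible_only:
        prevalent = np.zeros(n, dtype=bool)
    else:
        prevalent = rng.random(n) < params.prevalent_diabetes_prob[key]
    return ages, bmi, prevalent


def _draw_crn(n: int, rng: np.random.Generator) -> np.ndarray:
    crn = rng.random((n, CRN_LENGTH))
    # keep draws strictly inside (0, 1)
    return np.clip(crn, 1e-12, 1.0 - 1e-12)


def generate_cohort(
    params: ParameterSet,
    years=ENTRY_YEARS,
    scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
    exact_counts: bool = False,
) -> AgentCohort:
    """Generate the simulated ART-initiator population.

    Per subgroup and entry year the agent count is Poisson with mean
    ``scale * initiators_per_year`` (or the rounded mean with
    ``exact_counts=True``, useful in tests).  Baseline state and the full
    CRN vector are drawn here once; nothing downstream draws fresh
    randomness.  Deterministic given the generator state.
    """
    years = tuple(int(y) for y in years)
    if not years:
        raise ValueError("year range must be non-empty")
    bad = set(years) - set(ENTRY_YEARS)
    if bad:
        raise ValueError(f"years outside the simulated range {ENTRY_YEARS}: {sorted(bad)}")
    if not (0.0 < scale <= 1.0):
        raise ValueError(f"scale must be in (0, 1], got {scale!r}")

    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    cols: dict[str, list[np.ndarray]] = {k: [] for k in (
        "subgroup_idx", "entry_year", "age0", "bmi0", "prevalent", "crn")}
    for gi, key in enumerate(SUBGROUPS):
        per_year = params.initiators_per_year[key]
        for year in years:
            mean = scale * float(per_year.get(year, 0.0))
            n = int(round(mean)) if exact_counts else int(rng.poisson(mean))
            if n == 0:
                continue
            ages, bmi, prevalent = _sample_baseline(params, key, n, rng)
            cols["subgroup_idx"].append(np.full(n, gi, dtype=np.int64))
            cols["entry_year"].append(np.full(n, year, dtype=np.int64))
            cols["age0"].append(ages)
            cols["bmi0"].append(bmi)
            cols["prevalent"].append(prevalent)
            cols["crn"].append(_draw_crn(n, rng))

    def cat(name, dtype=None, width=None):
        parts = cols[name]
        if not parts:
            shape = (0, width) if width else (0,)
            return np.empty(shape, dtype=dtype or float)
        return np.concatenate(parts)

    subgroup_idx = cat("subgroup_idx", np.int64)
    total = subgroup_idx.shape[0]
    return AgentCohort(
        ids=np.arange(total, dtype=np.int64),
        subgroup_idx=subgroup_idx,
        entry_year=cat("entry_year", np.int64),
        age0=cat("age0"),
        bmi0=cat("bmi0"),
        prevalent_diabetes=cat("prevalent", bool),
        crn=cat("crn", float, width=CRN_LENGTH),
        scale=scale,
        seed=seed,
    )


def generate_eligible_cohort(
    params: ParameterSet,
    key: SubgroupKey,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> AgentCohort:
    """Fixed-size cohort of eligible agents from one subgroup.

    Samples BMI directly from the eligible band [18.5, 30) with no prevalent
    diabetes; used by hazard calibration, where only the control-arm rate of
    eligible participants matters.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    gi = SUBGROUPS.index(key)
    ages, bmi, prevalent = _sample_baseline(params, key, n, rng, eligible_only=True)
    return AgentCohort(
        ids=np.arange(n, dtype=np.int64),
        subgroup_idx=np.full(n, gi, dtype=np.int64),
        entry_year=np.full(n, ENTRY_YEARS[0], dtype=np.int64),
        age0=ages,
        bmi0=bmi,
        prevalent_diabetes=prevalent,
        crn=_draw_crn(n, rng),
        scale=1.0,
    )
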