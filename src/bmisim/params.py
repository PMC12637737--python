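"""Parameter data model for the simulation.

A :class:`ParameterSet` carries everything that drives the microsimulation:
per-subgroup ART-initiator counts, baseline age and BMI distributions,
prevalent-diabetes probabilities, 24-month BMI-change models, the
incident-diabetes logistic hazard, and background mortality.  The shipped
default set (:func:`default_parameter_set`) is synthetic, constructed by
calibration against published marginal characteristics of 2013-2017 US ART
initiators (see :mod:`bmisim.targets`); its provenance is recorded inside
the parameter file itself.

Numeric *range* invariants are deliberately checked by
:func:`validate_parameters` rather than at construction time, so that tests
and sensitivity machinery can build and inspect out-of-range sets.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .subgroups import SUBGROUPS, N_AGE_BANDS, SubgroupKey

__all__ = [
    "AgeDistribution",
    "BaselineBmiDistribution",
    "BmiChangeModel",
    "DiabetesHazard",
    "ParameterSet",
    "PerturbationRecord",
    "PERTURBATION_BLOCKS",
    "default_parameter_set",
    "load_parameters",
    "save_parameters",
    "validate_parameters",
    "perturb_parameters",
]

SCHEMA_VERSION = "1.0"

#: Calendar entry years simulated.
ENTRY_YEARS = (2013, 2014, 2015, 2016, 2017)

#: Age support for the baseline age distribution (years).
AGE_RANGE = (18.0, 85.0)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class AgeDistribution(_Model):
    """Two-piece (split-normal) age-at-initiation distribution.

    Parameterized by the median and the 2.5th/97.5th percentiles; each half
    is a folded normal around the median with scale chosen so the stated
    percentile is reproduced.  Samples are truncated to ``AGE_RANGE``.
    """

    median_age: float
    lower95: float
    upper95: float

    @property
    def sigma_lower(self) -> float:
        return (self.median_age - self.lower95) / 1.959963984540054

    @property
    def sigma_upper(self) -> float:
        return (self.upper95 - self.median_age) / 1.959963984540054


class BaselineBmiDistribution(_Model):
    """Baseline BMI category shares and within-category shapes.

    ``p_underweight + p_normal_overweight + p_obese`` must sum to 1.  Within
    the eligible band [18.5, 30), a fraction ``overweight_share`` falls in
    [25, 30) with density rising linearly toward 30 (triangular, mode 30)
    and the rest is uniform on [18.5, 25).  Underweight is uniform on
    [16, 18.5), obese uniform on [30, 40).  Only the category shares are
    published; the within-category shapes are this package's explicit
    modelling choice (see docs/methods.md).
    """

    p_underweight: float
    p_normal_overweight: float
    p_obese: float
    overweight_share: float = 0.45


class BmiChangeModel(_Model):
    """24-month BMI change: Bernoulli gain indicator + magnitude draws.

    With probability ``p_gain`` the change is a positive log-normal draw
    (``exp(gain_mu + gain_sigma * z)``); otherwise a non-positive half-normal
    draw (``-loss_scale * |z|``).  Units: kg/m^2.
    """

    p_gain: float
    gain_mu: float
    gain_sigma: float
    loss_scale: float


class DiabetesHazard(_Model):
    """Logistic model for the annual probability of incident diabetes diagnosis.

    log-odds = intercept[subgroup] + beta_age[age band] + beta_bmi[category]
               + beta_delta_bmi * max(cumulative BMI gain, 0)

    ``beta_age`` is indexed by the decadal bands <20 ... 70+; ``beta_bmi``
    by category with normal as the reference (0 by convention).
    """

    intercept: dict[SubgroupKey, float]
    beta_age: list[float] = Field(min_length=N_AGE_BANDS, max_length=N_AGE_BANDS)
    beta_bmi: dict[str, float]  # keys: underweight, normal, overweight, obese
    beta_delta_bmi: float


class ParameterSet(_Model):
    schema_version: str = SCHEMA_VERSION
    provenance: str = ""
    initiators_per_year: dict[SubgroupKey, dict[int, float]]
    age_dist: dict[SubgroupKey, AgeDistribution]
    prevalent_diabetes_prob: dict[SubgroupKey, float]
    baseline_bmi_dist: dict[SubgroupKey, BaselineBmiDistribution]
    bmi_change_model: dict[SubgroupKey, BmiChangeModel]
    diabetes_hazard: DiabetesHazard
    #: annual death probability per subgroup, indexed by decadal age band
    mortality: dict[SubgroupKey, list[float]]
    # Multiplicative sensitivity-analysis dials (1.0 = baseline).
    baseline_bmi_scale: float = 1.0
    bmi_change_scale: float = 1.0
    hazard_prob_scale: float = 1.0

    # -- convenience accessors -------------------------------------------
    def total_initiators(self) -> float:
        """Expected number of ART initiators over all subgroups and years."""
        return float(sum(sum(v.values()) for v in self.initiators_per_year.values()))

    def subgroup_initiators(self, key: SubgroupKey) -> float:
        return float(sum(self.initiators_per_year[key].values()))

    def to_json(self) -> str:
        """Stable serialization: sorted keys, 2-space indent, trailing newline."""
        payload = self.model_dump(mode="json")
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"


class PerturbationRecord(_Model):
    """One probabilistic-sensitivity-analysis draw: the multiplicative factors
    applied to each parameter block, all within [1-magnitude, 1+magnitude]."""

    draw_id: int = 0
    magnitude: float
    factors: dict[str, float]
    seed: int | None = None


#: The perturbed parameter blocks.  The two published prevalent-diabetes
#: blocks (initial ART users vs. ART initiators) collapse to one here because
#: only 2013-2017 initiators are simulated.
PERTURBATION_BLOCKS = (
    "initiators",
    "baseline_bmi",
    "bmi_change",
    "prevalent_diabetes",
    "diabetes_hazard",
)


# ---------------------------------------------------------------------------
# I/O


def load_parameters(path: str | Path) -> ParameterSet:
    with open(path, "r", encoding="utf-8") as fh:
        return ParameterSet.model_validate(json.load(fh))


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(params.to_json(), encoding="utf-8")


_DEFAULT_CACHE: ParameterSet | None = None


def default_parameter_set() -> ParameterSet:
    """The shipped default parameter set, calibrated to published marginals.

    Deterministic: repeated calls return equal (deep-copied) sets.
    """
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        text = resources.files("bmisim.data").joinpath("default_params.json").read_text()
        _DEFAULT_CACHE = ParameterSet.model_validate(json.loads(text))
    return _DEFAULT_CACHE.model_copy(deep=True)


# ---------------------------------------------------------------------------
# Validation


def _check_prob(violations: list[str], value: float, field: str, sub: str) -> None:
    if not (0.0 <= value <= 1.0):
        violations.append(f"{field}[{sub}]: probability {value!r} outside [0, 1]")


def validate_parameters(params: ParameterSet) -> list[str]:
    """Report every violated range/shape invariant; empty list means valid."""
    v: list[str] = []
    for g in SUBGROUPS:
        for table, name in (
            (params.initiators_per_year, "initiators_per_year"),
            (params.age_dist, "age_dist"),
            (params.prevalent_diabetes_prob, "prevalent_diabetes_prob"),
            (params.baseline_bmi_dist, "baseline_bmi_dist"),
            (params.bmi_change_model, "bmi_change_model"),
            (params.mortality, "mortality"),
        ):
            if g not in table:
                v.append(f"{name}: missing subgroup {g.value}")
        if g not in params.diabetes_hazard.intercept:
            v.append(f"diabetes_hazard.intercept: missing subgroup {g.value}")

    for g, counts in params.initiators_per_year.items():
        for year, n in counts.items():
            if n < 0:
                v.append(f"initiators_per_year[{g.value}][{year}]: negative count {n!r}")

    for g, dist in params.age_dist.items():
        if not (AGE_RANGE[0] <= dist.lower95 <= dist.median_age <= dist.upper95 <= AGE_RANGE[1]):
            v.append(f"age_dist[{g.value}]: quantiles not ordered within {AGE_RANGE}")

    for g, p in params.prevalent_diabetes_prob.items():
        _check_prob(v, p, "prevalent_diabetes_prob", g.value)

    for g, d in params.baseline_bmi_dist.items():
        for field in ("p_underweight", "p_normal_overweight", "p_obese", "overweight_share"):
            _check_prob(v, getattr(d, field), f"baseline_bmi_dist.{field}", g.value)
        total = d.p_underweight + d.p_normal_overweight + d.p_obese
        if abs(total - 1.0) > 1e-9:
            v.append(
                f"baseline_bmi_dist[{g.value}]: category probabilities sum to {total!r}, not 1"
            )

    for g, m in params.bmi_change_model.items():
        _check_prob(v, m.p_gain, "bmi_change_model.p_gain", g.value)
        if m.gain_sigma <= 0:
            v.append(f"bmi_change_model[{g.value}]: gain_sigma must be > 0")
        if m.loss_scale < 0:
            v.append(f"bmi_change_model[{g.value}]: loss_scale must be >= 0")

    hz = params.diabetes_hazard
    if hz.beta_delta_bmi < 0:
        v.append("diabetes_hazard.beta_delta_bmi: must be >= 0 (gain must not reduce hazard)")
    missing = set(("underweight", "normal", "overweight", "obese")) - set(hz.beta_bmi)
    if missing:
        v.append(f"diabetes_hazard.beta_bmi: missing categories {sorted(missing)}")

    for g, qs in params.mortality.items():
        if len(qs) != N_AGE_BANDS:
            v.append(f"mortality[{g.value}]: expected {N_AGE_BANDS} age-band probabilities")
        for q in qs:
            _check_prob(v, q, "mortality", g.value)

    for field in ("baseline_bmi_scale", "bmi_change_scale", "hazard_prob_scale"):
        if getattr(params, field) <= 0:
            v.append(f"{field}: must be > 0")
    return v


# ---------------------------------------------------------------------------
# Perturbation (probabilistic sensitivity analysis)


def perturb_parameters(
    params: ParameterSet,
    magnitude: float,
    rng: np.random.Generator,
    draw_id: int = 0,
    seed: int | None = None,
) -> tuple[ParameterSet, PerturbationRecord]:
    """Scale each parameter block by an independent uniform factor.

    Each of the perturbed blocks (``PERTURBATION_BLOCKS``) receives one
    factor drawn uniformly from [1 - magnitude, 1 + magnitude]; probabilities
    are clamped to [0, 1] after scaling.  Returns the perturbed set and a
    record of all factors.
    """
    if not (0.0 < magnitude < 1.0):
        raise ValueError(f"magnitude must be in (0, 1), got {magnitude!r}")

    factors = {
        block: float(rng.uniform(1.0 - magnitude, 1.0 + magnitude))
        for block in PERTURBATION_BLOCKS
    }
    out = params.model_copy(deep=True)

    f = factors["initiators"]
    for g in out.initiators_per_year:
        out.initiators_per_year[g] = {
            yr: n * f for yr, n in out.initiators_per_year[g].items()
        }

    out.baseline_bmi_scale = params.baseline_bmi_scale * factors["baseline_bmi"]
    out.bmi_change_scale = params.bmi_change_scale * factors["bmi_change"]

    f = factors["prevalent_diabetes"]
    for g in out.prevalent_diabetes_prob:
        out.prevalent_diabetes_prob[g] = float(
            np.clip(out.prevalent_diabetes_prob[g] * f, 0.0, 1.0)
        )

    out.hazard_prob_scale = params.hazard_prob_scale * factors["diabetes_hazard"]

    record = PerturbationRecord(
        draw_id=draw_id, magnitude=magnitude, factors=factors, seed=seed
    )
    return out, record
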