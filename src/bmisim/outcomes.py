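"""Outcome measures and replicate aggregation.

Incidence is diagnoses per 1,000 person-years at risk, with person-time
censored at death only (a death in follow-up year t contributes t - 0.5
years, the mid-year convention); diagnosed agents keep accruing person-time
until death or the horizon.  Arm comparisons report the absolute rate
reduction (ARR), relative reduction (RRR = ARR / control rate), diagnoses
averted, and two number-needed-to-treat variants: the primary
persons-treated-per-case-averted (treated / averted) and the reciprocal-rate
variant 1 / ARR.  Replicate distributions are summarized as the median and
the 2.5th/97.5th percentiles (the 95% uncertainty range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .disease import EventRecords
from .subgroups import AGE_BAND_LABELS, age_band_index

__all__ = [
    "person_years",
    "incidence_rate",
    "ComparisonRow",
    "compare_arms",
    "pool_weighted",
    "Summary",
    "summarize_replicates",
    "replicate_measures",
    "summarize_trial",
    "stratify",
    "round_rate",
    "round_percent",
    "round_ten",
    "round_hundred",
]


# -- rounding conventions used for report output (raw values always kept) ---

def round_rate(x: float) -> float:
    """Rates per 1,000 person-years print with one decimal."""
    return round(float(x), 1)


def round_percent(x: float) -> int:
    """Percentages print with zero decimals."""
    return int(round(float(x)))


def round_ten(x: float) -> int:
    """Small counts (diagnoses averted, NNT denominators) print to the nearest ten."""
    return int(round(float(x) / 10.0) * 10)


def round_hundred(x: float) -> int:
    """Population sizes print to the nearest hundred."""
    return int(round(float(x) / 100.0) * 100)


def person_years(
    events: EventRecords,
    horizon: int | None = None,
    censor_at_diagnosis: bool = False,
) -> float:
    """Total person-years at risk over the horizon.

    Death in year t contributes t - 0.5 years.  By default diagnosis does
    not censor (the convention behind the headline rates);
    ``censor_at_diagnosis=True`` gives the conventional at-risk alternative
    where follow-up additionally stops mid-year at diagnosis.
    """
    horizon = events.horizon if horizon is None else horizon
    end = np.where(events.death_year > 0, events.death_year - 0.5, float(horizon))
    if censor_at_diagnosis:
        dx_end = np.where(events.dx_year > 0, events.dx_year - 0.5, np.inf)
        end = np.minimum(end, dx_end)
    return float(end.sum())


def incidence_rate(n_dx: float, py: float) -> float:
    """Diagnoses per 1,000 person-years."""
    if py <= 0:
        raise ValueError(f"person-years must be positive, got {py!r}")
    return 1000.0 * n_dx / py


@dataclass
class ComparisonRow:
    """Arm-vs-arm outcome measures for one stratum (or the pooled population)."""

    control_rate: float
    intervention_rate: float
    arr: float                     # per 1,000 person-years
    rrr: float | None              # fraction; None when control rate is 0
    treated: float
    averted: float
    nnt_population: float | None   # treated / averted (primary definition)
    nnt_rate: float | None         # 1 / ARR, in 1,000-person-year units

    def formatted(self) -> dict:
        """Values rounded per the reporting conventions."""
        return {
            "control_rate": round_rate(self.control_rate),
            "intervention_rate": round_rate(self.intervention_rate),
            "arr": round_rate(self.arr),
            "rrr_percent": None if self.rrr is None else round_percent(100 * self.rrr),
            "treated": round_hundred(self.treated),
            "averted": round_ten(self.averted),
            "nnt": None if self.nnt_population is None else round_percent(self.nnt_population),
        }


def compare_arms(
    control_rate: float,
    intervention_rate: float,
    treated: float,
    averted: float,
) -> ComparisonRow:
    """Derive ARR, RRR and both NNT variants from arm-level summaries."""
    if control_rate < 0:
        raise ValueError("control rate must be non-negative")
    arr = control_rate - intervention_rate
    rrr = arr / control_rate if control_rate > 0 else None
    nnt_pop = treated / averted if averted > 0 else None
    nnt_rate = 1.0 / arr if arr > 0 else None
    return ComparisonRow(
        control_rate=control_rate,
        intervention_rate=intervention_rate,
        arr=arr,
        rrr=rrr,
        treated=treated,
        averted=averted,
        nnt_population=nnt_pop,
        nnt_rate=nnt_rate,
    )


def pool_weighted(values, weights) -> float:
    """Weighted mean of per-stratum values (e.g. percentages by stratum size)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    return float((values * weights).sum() / total)


@dataclass
class Summary:
    """Median and 95% uncertainty range (2.5th/97.5th percentiles)."""

    median: float
    lower95: float
    upper95: float


def summarize_replicates(values) -> Summary:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate value")
    med, lo, hi = np.percentile(values, [50.0, 2.5, 97.5])
    return Summary(median=float(med), lower95=float(lo), upper95=float(hi))


# ---------------------------------------------------------------------------
# Replicate-level aggregation


def _measures_from_counts(
    dx_c: float, dx_i: float, py: float, treated: float
) -> dict:
    rate_c = incidence_rate(dx_c, py) if py > 0 else math.nan
    rate_i = incidence_rate(dx_i, py) if py > 0 else math.nan
    averted = dx_c - dx_i
    row = compare_arms(rate_c, rate_i, treated, averted) if py > 0 else None
    return {
        "diagnoses_control": dx_c,
        "diagnoses_intervention": dx_i,
        "person_years": py,
        "treated": treated,
        "control_rate": rate_c,
        "intervention_rate": rate_i,
        "arr": rate_c - rate_i,
        "rrr": row.rrr if row else math.nan,
        "averted": averted,
        "nnt": (row.nnt_population if row and row.nnt_population is not None else math.nan),
    }


def replicate_measures(rep) -> dict:
    """Pooled outcome measures for one :class:`~bmisim.trial.ReplicateResult`."""
    c = rep.counts
    ctrl = c[c["arm"] == "control"]
    itv = c[c["arm"] == "intervention"]
    return _measures_from_counts(
        dx_c=float(ctrl["diagnoses"].sum()),
        dx_i=float(itv["diagnoses"].sum()),
        py=float(ctrl["person_years"].sum()),
        treated=float(ctrl["treated_n"].sum()),
    )


def summarize_trial(results) -> pd.DataFrame:
    """Median [95% UR] of every pooled measure across replicates (tidy form)."""
    per_rep = pd.DataFrame([replicate_measures(r) for r in results])
    rows = []
    for measure in per_rep.columns:
        vals = per_rep[measure].dropna().to_numpy()
        if vals.size == 0:
            continue
        s = summarize_replicates(vals)
        rows.append(
            {
                "measure": measure,
                "median": s.median,
                "lower95": s.lower95,
                "upper95": s.upper95,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stratified reporting


_BMI_BAND_EDGES = np.array([18.5, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30])


def _bmi_band_label(bmi: np.ndarray) -> np.ndarray:
    idx = np.clip(
        np.searchsorted(_BMI_BAND_EDGES, bmi, side="right") - 1,
        0,
        len(_BMI_BAND_EDGES) - 2,
    )
    labels = np.array(
        [f"{lo:g}-{hi:g}" for lo, hi in zip(_BMI_BAND_EDGES[:-1], _BMI_BAND_EDGES[1:])],
        dtype=object,
    )
    return labels[idx]


def _stratum_column(agents: pd.DataFrame, by: str) -> pd.Series:
    if by == "subgroup":
        return agents["subgroup"].astype(str)
    if by == "age_band":
        return pd.Series(
            np.asarray(AGE_BAND_LABELS, dtype=object)[age_band_index(agents["age0"].to_numpy())],
            index=agents.index,
        )
    if by == "bmi_band":
        return pd.Series(_bmi_band_label(agents["bmi0"].to_numpy()), index=agents.index)
    raise ValueError("by must be one of {'subgroup', 'age_band', 'bmi_band'}")


def stratify(results, by: str = "subgroup") -> pd.DataFrame:
    """Per-stratum comparison table with replicate-level uncertainty ranges.

    Strata: the 15 subgroups, decadal age bands, or unit-width baseline-BMI
    bands 18.5-19 ... 29-30.  Each stratum row carries the median [95% UR]
    across replicates of the control/intervention rates, ARR, RRR, averted
    count, treated count and NNT.
    """
    per_rep: dict[str, list[dict]] = {}
    for rep in results:
        a = rep.agents
        strata = _stratum_column(a, by)
        py = pd.Series(
            np.where(a["death_year"] > 0, a["death_year"] - 0.5, 7.0), index=a.index
        )
        for stratum, idx in a.groupby(strata, observed=True).groups.items():
            sub = a.loc[idx]
            m = _measures_from_counts(
                dx_c=float((sub["dx_year_control"] > 0).sum()),
                dx_i=float((sub["dx_year_intervention"] > 0).sum()),
                py=float(py.loc[idx].sum()),
                treated=float(sub["treated"].sum()),
            )
            per_rep.setdefault(str(stratum), []).append(m)

    measures = (
        "control_rate", "intervention_rate", "arr", "rrr",
        "averted", "treated", "nnt", "diagnoses_control", "person_years",
    )
    rows = []
    for stratum, recs in per_rep.items():
        df = pd.DataFrame(recs)
        row: dict = {"stratum": stratum, "n_replicates": len(recs)}
        for measure in measures:
            vals = df[measure].dropna().to_numpy()
            if vals.size:
                s = summarize_replicates(vals)
                row[f"{measure}_median"] = s.median
                row[f"{measure}_lower95"] = s.lower95
                row[f"{measure}_upper95"] = s.upper95
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum").sort_index()
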