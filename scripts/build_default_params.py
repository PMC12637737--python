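"""Construct and calibrate the shipped default parameter set.

This is a development-time tool: it builds the synthetic ParameterSet from
the published marginal targets (bmisim.targets), calibrates the free pieces
(per-subgroup BMI-gain scales to the obesity-conversion shares; a common
overweight share to the pooled gain median; hazard intercepts to the
control-arm rate targets; the BMI-gain coefficient to the pooled
relative-risk-reduction band) and writes src/bmisim/data/default_params.json.

Run from the repository root after an editable install:

    python scripts/build_default_params.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from bmisim import targets as T
from bmisim.disease import calibrate_hazard
from bmisim.outcomes import replicate_measures
from bmisim.params import (
    ENTRY_YEARS,
    AgeDistribution,
    BaselineBmiDistribution,
    BmiChangeModel,
    DiabetesHazard,
    ParameterSet,
    save_parameters,
)
from bmisim.subgroups import SUBGROUPS
from bmisim.trial import TrialConfig, run_replicates

OUT = Path(__file__).resolve().parents[1] / "src" / "bmisim" / "data" / "default_params.json"

GAIN_SIGMA = 0.46          # common log-scale SD of positive 24-month gains
LOSS_SCALE = 0.75          # half-normal scale of 24-month losses (kg/m^2)
MORTALITY = [0.0015, 0.0015, 0.002, 0.004, 0.006, 0.010, 0.020]
BETA_AGE = [-0.3, 0.0, 0.6, 1.0, 1.3, 1.5, 1.6]
BETA_BMI = {"underweight": -0.3, "normal": 0.0, "overweight": 0.5, "obese": 1.0}
RRR_TARGET = 0.185         # centre of the published 16-21% band
CAL_N = 20_000
CAL_SEED = 12345


def obesity_share(mu: float, p_gain: float, r_ow: float) -> float:
    """P(BMI24 >= 30 | eligible) under the within-band shapes (quadrature)."""
    def survival(x):
        return norm.sf((np.log(np.maximum(x, 1e-12)) - mu) / GAIN_SIGMA)

    # normal band: uniform on [18.5, 25)
    b = np.linspace(18.5, 25.0, 257)[:-1] + (25.0 - 18.5) / 512
    p_norm = survival(30.0 - b).mean()
    # overweight band: density rising linearly toward 30 on [25, 30)
    b = np.linspace(25.0, 30.0, 257)[:-1] + 5.0 / 512
    w = (b - 25.0)
    p_ow = (survival(30.0 - b) * w).sum() / w.sum()
    return p_gain * ((1 - r_ow) * p_norm + r_ow * p_ow)


def tune_gain_mus(r_ow: float) -> dict:
    mus = {}
    for key in SUBGROUPS:
        m = T.MARGINALS[key]
        f = lambda mu: obesity_share(mu, m.p_gain, r_ow) - m.p_become_obese
        lo, hi = np.log(0.1), np.log(8.0)
        if f(lo) > 0:
            mus[key] = lo
        elif f(hi) < 0:
            mus[key] = hi
        else:
            mus[key] = brentq(f, lo, hi, xtol=1e-8)
    return mus


def pooled_gain_median(mus: dict) -> float:
    w = np.array([T.MARGINALS[k].initiators_2013_2017
                  * T.MARGINALS[k].p_normal_overweight
                  * (1 - T.MARGINALS[k].p_prevalent_diabetes)
                  * T.MARGINALS[k].p_gain for k in SUBGROUPS])
    w = w / w.sum()
    mu = np.array([mus[k] for k in SUBGROUPS])

    def cdf(x):
        return float((w * norm.cdf((np.log(x) - mu) / GAIN_SIGMA)).sum())

    return brentq(lambda x: cdf(x) - 0.5, 0.05, 10.0, xtol=1e-8)


def build_base() -> ParameterSet:
    # Outer calibration: common overweight share so the pooled median of
    # positive gains matches the published 1.01 kg/m^2, with per-subgroup
    # gain scales re-tuned to the obesity-conversion shares at each step.
    def median_err(r):
        return pooled_gain_median(tune_gain_mus(r)) - T.POOLED_GAIN_MEDIAN

    r_ow = brentq(median_err, 0.15, 0.85, xtol=1e-4)
    mus = tune_gain_mus(r_ow)
    print(f"overweight share within eligible band: {r_ow:.4f}")
    print(f"pooled gain median: {pooled_gain_median(mus):.4f}")

    return ParameterSet(
        provenance=(
            "Synthetic parameter set calibrated to published marginal "
            "characteristics of US ART initiators 2013-2017 (subgroup sizes, "
            "age quantiles, prevalent-diabetes and BMI-category shares, "
            "24-month BMI-gain and obesity-conversion shares) and to "
            "published control-arm 7-year incident-diabetes rates. Hazard "
            "intercepts and the BMI-gain coefficient are calibration "
            "products, not published estimates; within-category BMI shapes, "
            "loss magnitudes and mortality are documented modelling choices "
            "(docs/methods.md)."
        ),
        initiators_per_year={
            k: {y: T.MARGINALS[k].initiators_2013_2017 / len(ENTRY_YEARS) for y in ENTRY_YEARS}
            for k in SUBGROUPS
        },
        age_dist={
            k: AgeDistribution(
                median_age=T.MARGINALS[k].median_age,
                lower95=T.MARGINALS[k].age_lower95,
                upper95=T.MARGINALS[k].age_upper95,
            )
            for k in SUBGROUPS
        },
        prevalent_diabetes_prob={k: T.MARGINALS[k].p_prevalent_diabetes for k in SUBGROUPS},
        baseline_bmi_dist={
            # The published category shares are rounded and sum to <1 in most
            # subgroups.  The underweight and normal/overweight shares are the
            # ones the published eligibility products rest on, so they are
            # kept verbatim and the obese share absorbs the rounding residual.
            k: BaselineBmiDistribution(
                p_underweight=T.MARGINALS[k].p_underweight,
                p_normal_overweight=T.MARGINALS[k].p_normal_overweight,
                p_obese=1.0 - T.MARGINALS[k].p_underweight - T.MARGINALS[k].p_normal_overweight,
                overweight_share=round(r_ow, 4),
            )
            for k in SUBGROUPS
        },
        bmi_change_model={
            k: BmiChangeModel(
                p_gain=T.MARGINALS[k].p_gain,
                gain_mu=round(mus[k], 6),
                gain_sigma=GAIN_SIGMA,
                loss_scale=LOSS_SCALE,
            )
            for k in SUBGROUPS
        },
        diabetes_hazard=DiabetesHazard(
            intercept={k: -6.0 for k in SUBGROUPS},  # placeholder, calibrated below
            beta_age=BETA_AGE,
            beta_bmi=BETA_BMI,
            beta_delta_bmi=0.10,                     # placeholder, calibrated below
        ),
        mortality={k: MORTALITY for k in SUBGROUPS},
    )


def measure_rrr(params: ParameterSet) -> float:
    config = TrialConfig(replicates=30, scale=0.1, base_seed=2025)
    results = run_replicates(params, config)
    per_rep = pd.DataFrame([replicate_measures(r) for r in results])
    return float(per_rep["rrr"].median())


def main() -> None:
    params = build_base()
    rate_targets = {k: t.rate for k, t in T.CONTROL_RATE_TARGETS.items()}

    # Joint calibration: the intercepts absorb part of any BMI-gain effect,
    # so recalibrate them at every beta_delta_bmi trial value (bisection on
    # the pooled relative risk reduction).
    lo, hi = 0.0, 0.5
    calibrated = None
    for it in range(14):
        mid = 0.5 * (lo + hi)
        params.diabetes_hazard.beta_delta_bmi = mid
        calibrated, report = calibrate_hazard(
            params, rate_targets, n_cal=CAL_N, seed=CAL_SEED
        )
        rrr = measure_rrr(calibrated)
        print(f"iter {it}: beta_delta_bmi={mid:.4f} pooled RRR={rrr:.4f}")
        if abs(rrr - RRR_TARGET) < 0.004:
            break
        if rrr < RRR_TARGET:
            lo = mid
        else:
            hi = mid
    assert calibrated is not None
    calibrated.diabetes_hazard.beta_delta_bmi = round(
        calibrated.diabetes_hazard.beta_delta_bmi, 4
    )
    calibrated, report = calibrate_hazard(
        calibrated, rate_targets, n_cal=CAL_N, seed=CAL_SEED
    )
    print(report.to_string(index=False))

    for key in SUBGROUPS:
        calibrated.diabetes_hazard.intercept[key] = round(
            calibrated.diabetes_hazard.intercept[key], 6
        )
    OUT.parent.mkdir(parents=True, exist_ok=True)
    save_parameters(calibrated, OUT)
    print(f"wrote {OUT}")

    # end-to-end sanity check at the acceptance problem size
    config = TrialConfig(replicates=100, scale=0.1, base_seed=42)
    results = run_replicates(calibrated, config)
    per_rep = pd.DataFrame([replicate_measures(r) for r in results])
    print("pooled control rate median:", per_rep["control_rate"].median())
    print("control diagnoses median x10:", per_rep["diagnoses_control"].median() * 10)
    print("pooled RRR median:", per_rep["rrr"].median())
    print("averted median x10:", per_rep["averted"].median() * 10)
    print("NNT median:", per_rep["nnt"].median())


if __name__ == "__main__":
    sys.exit(main())
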