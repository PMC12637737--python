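"""Calibration targets for the shipped default parameter set.

The default :class:`~bmisim.params.ParameterSet` is synthetic: the
patient-level cohort data behind the published US ART-initiator forecasts is
not public, so the parameter set is constructed by calibrating to the
published *marginal* characteristics of 2013-2017 ART initiators (subgroup
sizes, median age with 95% range, prevalent-diabetes share, baseline BMI
category shares, 24-month BMI-gain and obesity-conversion shares) and to the
published control-arm 7-year incident-diabetes rates.

Everything in this module is a calibration target, not an output of this
package.  Control-arm rate targets carry an ``authoritative`` flag: published
values (or values back-derived from published diagnosis counts) are
authoritative; the remaining subgroups' rates were not published numerically
and are interpolated so that the person-year-weighted pooled rate reproduces
the published 10.7 per 1,000 person-years.
"""

from __future__ import annotations

from dataclasses import dataclass

from .subgroups import SubgroupKey as K

__all__ = [
    "SubgroupMarginals",
    "MARGINALS",
    "RateTarget",
    "CONTROL_RATE_TARGETS",
    "POOLED_CONTROL_RATE",
    "POOLED_GAIN_MEDIAN",
    "POOLED_GAIN_Q025",
    "POOLED_GAIN_Q975",
    "POOLED_RRR_BAND",
]


@dataclass(frozen=True)
class SubgroupMarginals:
    """Published per-subgroup characteristics of 2013-2017 ART initiators."""

    initiators_2013_2017: float  # persons over the five entry years
    median_age: float            # years at ART initiation
    age_lower95: float
    age_upper95: float
    p_prevalent_diabetes: float
    p_underweight: float         # BMI < 18.5 at initiation
    p_normal_overweight: float   # 18.5 <= BMI < 30
    p_obese: float               # BMI >= 30
    p_gain: float                # eligible agents gaining BMI by month 24
    p_become_obese: float        # eligible agents with BMI >= 30 at month 24


MARGINALS: dict[K, SubgroupMarginals] = {
    K.BLACK_HET_WOMEN:    SubgroupMarginals(19_400, 41, 24, 59, 0.10, 0.02, 0.56, 0.41, 0.71, 0.24),
    K.WHITE_HET_WOMEN:    SubgroupMarginals(4_400, 41, 25, 62, 0.10, 0.04, 0.64, 0.30, 0.63, 0.16),
    K.HISPANIC_HET_WOMEN: SubgroupMarginals(5_100, 38, 25, 65, 0.10, 0.01, 0.62, 0.35, 0.67, 0.18),
    K.BLACK_HET_MEN:      SubgroupMarginals(9_400, 43, 24, 61, 0.09, 0.03, 0.74, 0.21, 0.68, 0.14),
    K.WHITE_HET_MEN:      SubgroupMarginals(2_100, 46, 26, 66, 0.09, 0.02, 0.80, 0.16, 0.75, 0.15),
    K.HISPANIC_HET_MEN:   SubgroupMarginals(2_900, 43, 26, 67, 0.09, 0.02, 0.80, 0.16, 0.79, 0.20),
    K.BLACK_WWID:         SubgroupMarginals(2_000, 48, 27, 65, 0.10, 0.02, 0.63, 0.33, 0.60, 0.17),
    K.WHITE_WWID:         SubgroupMarginals(2_100, 41, 26, 60, 0.10, 0.03, 0.76, 0.20, 0.76, 0.24),
    K.HISPANIC_WWID:      SubgroupMarginals(863, 47, 31, 62, 0.10, 0.03, 0.77, 0.18, 0.73, 0.20),
    K.BLACK_MWID:         SubgroupMarginals(3_900, 45, 22, 63, 0.13, 0.02, 0.79, 0.17, 0.58, 0.08),
    K.WHITE_MWID:         SubgroupMarginals(5_600, 43, 24, 62, 0.06, 0.02, 0.88, 0.08, 0.63, 0.08),
    K.HISPANIC_MWID:      SubgroupMarginals(3_500, 42, 24, 59, 0.06, 0.015, 0.705, 0.28, 0.57, 0.11),
    K.BLACK_MSM:          SubgroupMarginals(43_400, 29, 21, 54, 0.04, 0.04, 0.80, 0.15, 0.67, 0.11),
    K.WHITE_MSM:          SubgroupMarginals(33_200, 40, 23, 60, 0.03, 0.02, 0.84, 0.12, 0.66, 0.09),
    K.HISPANIC_MSM:       SubgroupMarginals(33_300, 32, 22, 52, 0.03, 0.02, 0.85, 0.12, 0.65, 0.08),
}


@dataclass(frozen=True)
class RateTarget:
    """Control-arm 7-year incident-diabetes rate target, per 1,000 person-years."""

    rate: float
    authoritative: bool  # False = interpolated, not a published number


# Published directly: White MSM 4.5, Hispanic MSM 3.4; WWID span 26.4-29.9;
# HET-women span 21.4-24.2.  Back-derived from published diagnosis counts:
# Black MSM (2,860 dx / ~33,400 eligible over ~6.9 y -> 12.3) and Black HET
# women (1,650 dx -> 24.2, the top of the published HET-women span).  The
# rest are interpolated (see module docstring).
CONTROL_RATE_TARGETS: dict[K, RateTarget] = {
    K.WHITE_MSM:          RateTarget(4.5, True),
    K.HISPANIC_MSM:       RateTarget(3.4, True),
    K.BLACK_MSM:          RateTarget(12.3, True),
    K.BLACK_WWID:         RateTarget(26.4, True),
    K.WHITE_WWID:         RateTarget(29.9, True),
    K.HISPANIC_WWID:      RateTarget(28.8, False),
    K.BLACK_HET_WOMEN:    RateTarget(24.2, True),
    K.WHITE_HET_WOMEN:    RateTarget(21.4, True),
    K.HISPANIC_HET_WOMEN: RateTarget(23.4, False),
    K.BLACK_HET_MEN:      RateTarget(16.2, False),
    K.WHITE_HET_MEN:      RateTarget(13.2, False),
    K.HISPANIC_HET_MEN:   RateTarget(14.9, False),
    K.BLACK_MWID:         RateTarget(17.2, False),
    K.WHITE_MWID:         RateTarget(12.7, False),
    K.HISPANIC_MWID:      RateTarget(14.7, False),
}

#: Published pooled control-arm rate (per 1,000 person-years) and its 95%
#: uncertainty range; the interpolated subgroup targets above are chosen so
#: the weighted pooled rate reproduces this.
POOLED_CONTROL_RATE = (10.7, 10.6, 10.9)

#: Published 24-month BMI-gain quantiles among eligible gainers (kg/m^2).
POOLED_GAIN_MEDIAN = 1.01
POOLED_GAIN_Q025 = 0.39
POOLED_GAIN_Q975 = 2.38

#: Published pooled relative risk reduction band used to tune the BMI-gain
#: hazard coefficient (fraction).
POOLED_RRR_BAND = (0.16, 0.21)
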