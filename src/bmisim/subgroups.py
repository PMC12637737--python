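"""Population strata and banding conventions.

The simulated population of US ART initiators is partitioned into 15
subgroups: the cross of five HIV-acquisition/sex groups (men who have sex
with men, men/women who inject drugs, heterosexual men/women) with three
race-ethnicity groups (non-Hispanic Black, non-Hispanic White, Hispanic).
All parameter tables in :mod:`bmisim.params` index these 15 keys.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "SubgroupKey",
    "SUBGROUPS",
    "AGE_BAND_LABELS",
    "N_AGE_BANDS",
    "age_band_index",
    "BMI_CUTS",
    "BMI_CATEGORIES",
]


class SubgroupKey(str, enum.Enum):
    """One of the 15 population strata (acquisition/sex group x race-ethnicity)."""

    BLACK_MSM = "black_msm"
    WHITE_MSM = "white_msm"
    HISPANIC_MSM = "hispanic_msm"
    BLACK_MWID = "black_mwid"
    WHITE_MWID = "white_mwid"
    HISPANIC_MWID = "hispanic_mwid"
    BLACK_WWID = "black_wwid"
    WHITE_WWID = "white_wwid"
    HISPANIC_WWID = "hispanic_wwid"
    BLACK_HET_MEN = "black_het_men"
    WHITE_HET_MEN = "white_het_men"
    HISPANIC_HET_MEN = "hispanic_het_men"
    BLACK_HET_WOMEN = "black_het_women"
    WHITE_HET_WOMEN = "white_het_women"
    HISPANIC_HET_WOMEN = "hispanic_het_women"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used for array-backed per-subgroup storage.
SUBGROUPS: tuple[SubgroupKey, ...] = tuple(SubgroupKey)

#: Decadal age bands used for the diabetes-hazard age effect, mortality, and
#: age-stratified outcome reporting.
AGE_BAND_LABELS: tuple[str, ...] = (
    "<20", "20-29", "30-39", "40-49", "50-59", "60-69", "70+",
)
N_AGE_BANDS = len(AGE_BAND_LABELS)


def age_band_index(age):
    """Map age in years to the decadal band index 0..6 (<20 ... 70+)."""
    age = np.asarray(age)
    idx = np.clip(np.floor(age / 10.0).astype(int) - 1, 0, N_AGE_BANDS - 1)
    return idx if idx.ndim else int(idx)


#: BMI category cutpoints (kg/m^2): underweight <18.5, normal 18.5-<25,
#: overweight 25-<30, obese >=30.
BMI_CUTS = (18.5, 25.0, 30.0)
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
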