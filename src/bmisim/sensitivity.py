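"""Probabilistic sensitivity analysis and coverage/effectiveness scenarios.

The PSA perturbs the primary parameter blocks (initiator counts, baseline
BMI, 24-month BMI change, prevalent diabetes, incident-diabetes hazard) by
independent multiplicative factors within ±magnitude, reruns a
reduced-replicate trial per draw, and reads sensitivity off a
decile contrast: for one block at a time, the outcome medians among the
draws whose factor for that block sits in its top versus bottom decile.

The scenario grid reruns the trial over coverage x effectiveness levels.
Under all-or-nothing adherence the expected impact multiplier is exactly
coverage x effectiveness, which serves as the analytic oracle for the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outcomes import replicate_measures, summarize_replicates
from .params import PERTURBATION_BLOCKS, ParameterSet, perturb_parameters
from .trial import TrialConfig, run_replicates

__all__ = ["PSAResult", "run_psa", "scenario_grid", "expected_impact_multiplier"]

PSA_OUTCOMES = ("rrr", "averted", "nnt", "control_rate")


def expected_impact_multiplier(coverage: float, effectiveness: float) -> float:
    """Expected fraction of full-scenario impact retained at partial
    coverage/effectiveness (all-or-nothing adherence makes this the product)."""
    if not (0.0 <= coverage <= 1.0 and 0.0 <= effectiveness <= 1.0):
        raise ValueError("coverage and effectiveness must be in [0, 1]")
    return coverage * effectiveness


@dataclass
class PSAResult:
    """Per-draw factors + headline outcomes, and the decile-contrast table."""

    draws: pd.DataFrame     # one row per draw: factor_<block>..., outcome columns
    magnitude: float

    def decile_contrast(self, block: str, outcome: str = "rrr") -> dict:
        """Outcome medians in the top vs bottom decile of one block's factor."""
        if block not in PERTURBATION_BLOCKS:
            raise ValueError(f"unknown block {block!r}")
        n = len(self.draws)
        k = n // 10
        if k < 1:
            raise ValueError("too few draws for decile contrast")
        order = self.draws.sort_values(f"factor_{block}")
        bottom = order.head(k)[outcome].median()
        top = order.tail(k)[outcome].median()
        return {
            "block": block,
            "outcome": outcome,
            "bottom_decile_median": float(bottom),
            "top_decile_median": float(top),
            "difference": float(top - bottom),
        }

    def contrast_table(self, outcome: str = "rrr") -> pd.DataFrame:
        return pd.DataFrame(
            [self.decile_contrast(block, outcome) for block in PERTURBATION_BLOCKS]
        )


def run_psa(
    params: ParameterSet,
    config: TrialConfig,
    n_draws: int = 500,
    base_seed: int = 0,
    magnitude: float = 0.2,
) -> PSAResult:
    """Run the probabilistic sensitivity analysis.

    Every draw perturbs all blocks independently and reruns the trial with
    the *same* trial seeds (``config.base_seed``), so outcome differences
    between draws reflect the parameter factors alone; with all factors
    forced to 1 each draw reproduces the baseline run exactly.
    Deterministic given ``base_seed``.
    """
    if n_draws < 20:
        raise ValueError("n_draws must be >= 20 for a meaningful decile readout")
    rows = []
    for d in range(n_draws):
        rng = np.random.default_rng([base_seed, d])
        perturbed, record = perturb_parameters(
            params, magnitude, rng, draw_id=d, seed=base_seed
        )
        results = run_replicates(perturbed, config)
        per_rep = pd.DataFrame([replicate_measures(r) for r in results])
        row = {f"factor_{b}": record.factors[b] for b in PERTURBATION_BLOCKS}
        row["draw_id"] = d
        for outcome in PSA_OUTCOMES:
            row[outcome] = float(per_rep[outcome].median())
        rows.append(row)
    return PSAResult(draws=pd.DataFrame(rows), magnitude=magnitude)


def scenario_grid(
    params: ParameterSet,
    config: TrialConfig,
    coverage_levels=(1.0, 0.75),
    effectiveness_levels=(1.0, 0.75),
) -> pd.DataFrame:
    """Trial outcomes over a coverage x effectiveness grid.

    Reports the median averted count and NNT per cell plus the averted-count
    multiplier relative to the (1, 1) cell (computed even when (1, 1) is not
    in the requested grid).
    """
    levels = sorted({(c, e) for c in coverage_levels for e in effectiveness_levels} | {(1.0, 1.0)})
    cells = {}
    for cov, eff in levels:
        cfg = config.model_copy(update={"coverage": cov, "effectiveness": eff})
        results = run_replicates(params, cfg)
        per_rep = pd.DataFrame([replicate_measures(r) for r in results])
        cells[(cov, eff)] = per_rep

    base_averted = float(cells[(1.0, 1.0)]["averted"].median())
    rows = []
    for (cov, eff), per_rep in cells.items():
        if (cov, eff) not in {(c, e) for c in coverage_levels for e in effectiveness_levels}:
            continue
        averted = summarize_replicates(per_rep["averted"])
        nnt_vals = per_rep["nnt"].dropna()
        rows.append(
            {
                "coverage": cov,
                "effectiveness": eff,
                "averted_median": averted.median,
                "averted_lower95": averted.lower95,
                "averted_upper95": averted.upper95,
                "nnt_median": float(nnt_vals.median()) if len(nnt_vals) else float("nan"),
                "impact_multiplier": (
                    averted.median / base_averted if base_averted > 0 else float("nan")
                ),
                "expected_multiplier": expected_impact_multiplier(cov, eff),
            }
        )
    return pd.DataFrame(rows)
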