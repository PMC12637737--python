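"""Configuration loading, result serialization and the run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from . import __version__
from .outcomes import replicate_measures, stratify, summarize_trial
from .params import ParameterSet
from .trial import TrialConfig

__all__ = ["RunManifest", "load_config", "save_config", "write_report", "parameter_hash"]

import pandas as pd


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")

    software_version: str
    parameter_hash: str
    config: dict
    base_seed: int
    files: list[str]
    wall_time_seconds: dict[str, float]


def load_config(path: str | Path) -> TrialConfig:
    """Parse a trial-configuration JSON file.

    Missing keys take the primary-analysis defaults (full coverage and
    effectiveness, 7-year horizon, 1,000 replicates); unknown keys are a
    hard error so typos cannot silently revert a setting to its default.
    """
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return TrialConfig.model_validate(payload)


def save_config(config: TrialConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(config.model_dump(mode="json"), sort_keys=True, indent=2) + "\n",
        encoding="utf-8",
    )


def parameter_hash(params: ParameterSet) -> str:
    return hashlib.sha256(params.to_json().encode("utf-8")).hexdigest()


def write_report(
    results,
    out_dir: str | Path,
    params: ParameterSet,
    config: TrialConfig,
    timings: dict[str, float] | None = None,
) -> RunManifest:
    """Write the summary JSON, tidy CSVs and the run manifest.

    Deterministic: identical inputs reproduce byte-identical CSV content.
    """
    if not results:
        raise ValueError("results must be non-empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    files: list[str] = []

    def _write_csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index, float_format="%.10g", lineterminator="\n")
        files.append(name)

    summary = summarize_trial(results)
    _write_csv(summary, "summary.csv")

    per_rep = pd.DataFrame(
        [{"replicate": r.index, "seed": r.seed, **replicate_measures(r)} for r in results]
    )
    _write_csv(per_rep, "replicates.csv")

    _write_csv(stratify(results, by="subgroup").reset_index(), "subgroups.csv")

    summary_json = {
        row["measure"]: {
            "median": row["median"],
            "lower95": row["lower95"],
            "upper95": row["upper95"],
        }
        for _, row in summary.iterrows()
    }
    (out / "summary.json").write_text(
        json.dumps(summary_json, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    files.append("summary.json")

    timings = dict(timings or {})
    timings["write_report"] = time.perf_counter() - t0
    manifest = RunManifest(
        software_version=__version__,
        parameter_hash=parameter_hash(params),
        config=config.model_dump(mode="json"),
        base_seed=config.base_seed,
        files=sorted(files + ["manifest.json"]),
        wall_time_seconds=timings,
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.model_dump(mode="json"), sort_keys=True, indent=2) + "\n",
        encoding="utf-8",
    )
    return manifest
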