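"""File formats: profiles CSV, scenarios YAML, and tabular/JSON exports.

Profiles travel as CSV with header ``drug_id,indication,<criterion_id...>,
annual_cost_eur`` (scores as integers, missing cost as an empty field).
Scenarios are YAML/JSON lists of ``{name, weights: {criterion_id: value}}``
where values may be fractions or percentages; the string ``builtin:table2``
loads the packaged scenarios. All tabular exports start with ``#``-prefixed
provenance comment lines (tool version, config hash, seed) so reruns can be
audited; readers here skip them.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import InputError
from .framework import ScoringFramework, _is_existing_path, default_framework
from .scoring import DrugProfile, ScoreResult, WeightScenario, builtin_scenarios

BUILTIN_SCENARIOS_TOKEN = "builtin:table2"


def provenance_comment(config_hash: str = "", seed: int | None = None) -> str:
    parts = [f"tool=orphanmcda/{__version__}"]
    if config_hash:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts) + "\n"


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serialisable config object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def read_profiles(path, framework: ScoringFramework | None = None) -> list[DrugProfile]:
    """Read drug profiles from CSV; raises on an empty or malformed table."""
    framework = framework or default_framework()
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise InputError(f"profiles file {path} is empty")
    if df.empty:
        raise InputError(f"profiles file {path} contains no drugs")
    required = {"drug_id"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"profiles file {path} lacks required columns: {sorted(missing)}")
    cost_col = "annual_cost_eur" if "annual_cost_eur" in df.columns else None
    score_cols = [c for c in df.columns if c in set(framework.criterion_ids)]
    profiles = []
    for _, row in df.iterrows():
        scores = {}
        for cid in score_cols:
            val = row[cid]
            if pd.isna(val):
                continue
            scores[cid] = int(val)
        cost = None
        if cost_col is not None and not pd.isna(row[cost_col]):
            cost = float(row[cost_col])
        profiles.append(
            DrugProfile(
                drug_id=str(row["drug_id"]),
                indication=str(row.get("indication", "") or ""),
                scores=scores,
                annual_cost=cost,
            )
        )
    return profiles


def write_profiles(
    profiles: Sequence[DrugProfile],
    path,
    framework: ScoringFramework | None = None,
    header_comment: str = "",
) -> None:
    """Write profiles to CSV in the canonical column order."""
    framework = framework or default_framework()
    cols = ["drug_id", "indication", *framework.criterion_ids, "annual_cost_eur"]
    rows = []
    for p in profiles:
        row = {"drug_id": p.drug_id, "indication": p.indication}
        for cid in framework.criterion_ids:
            row[cid] = p.scores.get(cid, "")
        row["annual_cost_eur"] = "" if p.annual_cost is None else repr(p.annual_cost)
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(header_comment)
        df.to_csv(fh, index=False)


def load_scenarios(source) -> list[WeightScenario]:
    """Load weight scenarios from YAML/JSON, or the packaged set.

    ``source`` may be the token ``builtin:table2``, a path, or a file
    object. Each scenario's weights are normalised on construction.
    """
    if isinstance(source, str) and source.strip().lower() == BUILTIN_SCENARIOS_TOKEN:
        return builtin_scenarios()
    if _is_existing_path(source):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, list):
        raise InputError("scenarios document must be a list of {name, weights}")
    scenarios = []
    for entry in doc:
        if "name" not in entry or "weights" not in entry:
            raise InputError(f"scenario entry missing 'name' or 'weights': {entry!r}")
        weights = {str(k): float(v) for k, v in entry["weights"].items()}
        scenarios.append(WeightScenario(name=str(entry["name"]), weights=weights))
    return scenarios


def score_results_frame(results: Iterable[ScoreResult]) -> pd.DataFrame:
    """Long table of score results (one row per drug x scenario)."""
    return pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "scenario": r.scenario,
                "weighted_score": r.weighted_score,
                "raw_sum": r.raw_sum,
                "percent_of_max": r.percent_of_max,
            }
            for r in results
        ]
    )


def write_tsv(df: pd.DataFrame, path, header_comment: str = "") -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(header_comment)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_csv(df: pd.DataFrame, path, header_comment: str = "", index: bool = False) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(header_comment)
        df.to_csv(fh, index=index, float_format="%.10g")


def write_json(obj: dict, path, provenance: dict | None = None) -> None:
    doc = dict(obj)
    if provenance:
        doc["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(_jsonable(doc), fh, indent=2, sort_keys=False)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):  # numpy scalars
        return _jsonable(obj.item())
    return obj
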