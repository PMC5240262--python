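"""Weighted-sum aggregation of ordinal criterion scores under weight scenarios.

The aggregate for a drug with criterion scores ``s_i`` under a scenario with
weights ``w_i`` (w_i >= 0, sum w_i = 1) is the weighted sum

    S_w = sum_i w_i * s_i

which lives on the same [1, 3] scale as the individual scores when every
criterion is scored. The raw sum ``sum_i s_i`` (range [9, 27] for the
nine-criterion framework) and the percent-of-maximum ``100 * S_w / 3`` are
reported alongside, since published analyses do not always state which scale
a "total drug score" refers to. A zero weight excludes a criterion: its
score cannot move the aggregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .framework import ScoringFramework, default_framework

__all__ = [
    "DrugProfile",
    "WeightScenario",
    "ScoreResult",
    "Ranking",
    "builtin_scenarios",
    "aggregate_score",
    "contribution_matrix",
    "rank_drugs",
]


@dataclass(frozen=True)
class DrugProfile:
    """One drug's criterion scores and (optionally) its annual cost.

    ``annual_cost`` is money per patient-year, tagged with ``currency``;
    it is optional because scoring does not require it.
    """

    drug_id: str
    indication: str = ""
    scores: dict[str, int] = field(default_factory=dict)
    annual_cost: float | None = None
    currency: str = "EUR"

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise InputError("drug_id must be non-empty")
        if self.annual_cost is not None and not self.annual_cost > 0:
            raise InputError(f"annual_cost must be > 0, got {self.annual_cost!r}")


@dataclass(frozen=True)
class WeightScenario:
    """A named assignment of non-negative weights to criterion ids.

    Weights may be supplied as fractions or percentages; they are normalised
    to sum exactly to one (weights already summing to 1.0 are left
    untouched, preserving exact hand-constructed values such as ninths).
    A weight of zero encodes exclusion of that criterion.
    """

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise InputError(f"scenario {self.name!r} has no weights")
        for cid, w in self.weights.items():
            if not math.isfinite(w) or w < 0:
                raise InputError(f"scenario {self.name!r}: weight for {cid!r} must be >= 0, got {w!r}")
        total = math.fsum(self.weights.values())
        if total <= 0:
            raise InputError(f"scenario {self.name!r}: weights must not all be zero")
        if total != 1.0:
            object.__setattr__(
                self, "weights", {cid: w / total for cid, w in self.weights.items()}
            )

    @property
    def excluded(self) -> frozenset[str]:
        """Criterion ids carrying zero weight."""
        return frozenset(cid for cid, w in self.weights.items() if w == 0)


@dataclass(frozen=True)
class ScoreResult:
    """Aggregation outcome for one drug under one scenario."""

    drug_id: str
    scenario: str
    weighted_score: float
    raw_sum: int
    percent_of_max: float
    contributions: dict[str, float]


@dataclass(frozen=True)
class Ranking:
    """Competition-style ranking of drugs by descending weighted score.

    Tied drugs share the better rank and the next rank skips; the display
    order breaks ties lexicographically by drug id.
    """

    scenario: str
    entries: tuple[tuple[int, str, float], ...]
    tie_groups: tuple[frozenset[str], ...] = ()

    def rank_of(self, drug_id: str) -> int:
        for rank, did, _ in self.entries:
            if did == drug_id:
                return rank
        raise KeyError(drug_id)

    @property
    def drug_ids(self) -> frozenset[str]:
        return frozenset(did for _, did, _ in self.entries)


def builtin_scenarios() -> list[WeightScenario]:
    """The three packaged weight scenarios.

    Scenario 1 (Base Case) weights all nine criteria equally at exactly one
    ninth each. Scenario 2 drops the four criteria an HTA body is unlikely
    to consider (research level, effectiveness uncertainty, manufacturing
    complexity, unique indication) and concentrates weight on disease
    severity and treatment impact (30% each). Scenario 3 re-admits research
    level and effectiveness uncertainty, excluding only manufacturing
    complexity and unique indication.
    """
    ninth = 1.0 / 9.0
    ids = default_framework().criterion_ids
    return [
        WeightScenario("Scenario 1 (Base Case)", {cid: ninth for cid in ids}),
        WeightScenario(
            "Scenario 2",
            {
                "rarity": 0.14,
                "research_level": 0.0,
                "effectiveness_uncertainty": 0.0,
                "manufacturing_complexity": 0.0,
                "follow_up_measures": 0.06,
                "disease_severity": 0.30,
                "available_alternatives": 0.20,
                "treatment_impact": 0.30,
                "unique_indication": 0.0,
            },
        ),
        WeightScenario(
            "Scenario 3",
            {
                "rarity": 0.10,
                "research_level": 0.20,
                "effectiveness_uncertainty": 0.10,
                "manufacturing_complexity": 0.0,
                "follow_up_measures": 0.15,
                "disease_severity": 0.15,
                "available_alternatives": 0.10,
                "treatment_impact": 0.20,
                "unique_indication": 0.0,
            },
        ),
    ]


def _check_criteria_match(profile: DrugProfile, scenario: WeightScenario) -> None:
    missing = set(scenario.weights) - set(profile.scores)
    extra = set(profile.scores) - set(scenario.weights)
    if missing or extra:
        raise InputError(
            f"criterion mismatch between profile {profile.drug_id!r} and scenario "
            f"{scenario.name!r}: missing from profile {sorted(missing)}, "
            f"not in scenario {sorted(extra)}"
        )


def aggregate_score(profile: DrugProfile, scenario: WeightScenario) -> ScoreResult:
    """Compute the weighted aggregate S_w = sum_i w_i * s_i for one drug.

    The profile's score keys and the scenario's weight keys must cover the
    same criterion ids. Returns the weighted score, the raw (unweighted)
    sum, the percent of the maximum attainable weighted score (3), and the
    per-criterion contributions ``w_i * s_i`` whose sum is S_w.
    """
    _check_criteria_match(profile, scenario)
    for cid, s in profile.scores.items():
        if s not in (1, 2, 3):
            raise InputError(f"profile {profile.drug_id!r}: score for {cid!r} must be in {{1,2,3}}, got {s!r}")
    contributions = {cid: scenario.weights[cid] * profile.scores[cid] for cid in scenario.weights}
    weighted = math.fsum(contributions.values())
    return ScoreResult(
        drug_id=profile.drug_id,
        scenario=scenario.name,
        weighted_score=weighted,
        raw_sum=sum(profile.scores.values()),
        percent_of_max=100.0 * weighted / 3.0,
        contributions=contributions,
    )


def contribution_matrix(
    profiles: list[DrugProfile],
    scenario: WeightScenario,
    framework: ScoringFramework | None = None,
) -> pd.DataFrame:
    """Drug-by-criterion matrix of contributions ``w_i * s_i``.

    Rows are drugs (in input order), columns follow the framework's
    criterion order; each row sums to the drug's weighted score. This is
    the stacked-bar decomposition of the overall drug scores.
    """
    framework = framework or default_framework()
    order = [cid for cid in framework.criterion_ids if cid in scenario.weights]
    order += [cid for cid in scenario.weights if cid not in order]
    rows = {}
    for p in profiles:
        result = aggregate_score(p, scenario)
        rows[p.drug_id] = [result.contributions[cid] for cid in order]
    return pd.DataFrame.from_dict(rows, orient="index", columns=order)


def rank_drugs(results: list[ScoreResult]) -> Ranking:
    """Competition-rank drugs by descending weighted score.

    All results must come from the same scenario and carry distinct drug
    ids. Tied drugs share the better rank (1, 1, 3, ...); display order
    within a tie is lexicographic by drug id.
    """
    if not results:
        raise InputError("cannot rank an empty result list")
    scenarios = {r.scenario for r in results}
    if len(scenarios) > 1:
        raise InputError(f"results span multiple scenarios: {sorted(scenarios)}")
    ids = [r.drug_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({d for d in ids if ids.count(d) > 1})
        raise InputError(f"duplicate drug ids in ranking input: {dupes}")

    ordered = sorted(results, key=lambda r: (-r.weighted_score, r.drug_id))
    entries: list[tuple[int, str, float]] = []
    tie_groups: list[frozenset[str]] = []
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j].weighted_score == ordered[i].weighted_score:
            j += 1
        rank = i + 1  # competition rank: position of the first tied item
        group = [r.drug_id for r in ordered[i:j]]
        for r in ordered[i:j]:
            entries.append((rank, r.drug_id, r.weighted_score))
        if len(group) > 1:
            tie_groups.append(frozenset(group))
        i = j
    return Ranking(
        scenario=next(iter(scenarios)),
        entries=tuple(entries),
        tie_groups=tuple(tie_groups),
    )
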