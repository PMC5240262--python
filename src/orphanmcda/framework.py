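"""The nine-criterion ordinal scoring framework for orphan drugs.

The framework (Hughes-Wilson et al., Orphanet J Rare Dis 2012) scores a drug
on nine criteria — rarity, level of research undertaken, uncertainty of
effectiveness, manufacturing complexity, follow-up measures, disease
severity, available alternatives/unmet need, treatment impact on disease,
and uniqueness of indication — each on an ordinal 1..3 scale where 1 is the
lowest level of attribution. Only the rarity criterion is mechanically
scorable from raw evidence (published prevalence); all other criterion
scores are asserted by the analyst.

This module holds the typed framework definition, YAML (de)serialisation,
the prevalence-to-score mapping, and non-throwing profile validation.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import yaml

from .errors import DomainError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import DrugProfile

VALID_SCORES = (1, 2, 3)

#: Prevalence-denominator bin edges for the rarity criterion: a disease seen
#: in 1 per N persons scores 1 for N in [2,000, 20,000), 2 for
#: [20,000, 200,000) and 3 for N >= 200,000. Shared printed endpoints are
#: assigned to the rarer (higher-score) bin.
RARITY_EDGES = (2_000.0, 20_000.0, 200_000.0)


@dataclass(frozen=True)
class CriterionLevel:
    """One ordinal level of a criterion."""

    score: int
    label: str
    definition: str = ""

    def __post_init__(self) -> None:
        if self.score not in VALID_SCORES:
            raise InputError(f"level score must be one of {VALID_SCORES}, got {self.score!r}")


@dataclass(frozen=True)
class Criterion:
    """A scoring criterion with exactly one level per score 1, 2, 3."""

    id: str
    name: str
    levels: tuple[CriterionLevel, ...]

    def __post_init__(self) -> None:
        scores = sorted(lv.score for lv in self.levels)
        if scores != list(VALID_SCORES):
            raise InputError(
                f"criterion {self.id!r} must have exactly one level per score "
                f"{VALID_SCORES}, got scores {scores}"
            )
        labels = {lv.label for lv in self.levels}
        if len(labels) != len(self.levels):
            raise InputError(f"criterion {self.id!r} has duplicate level labels")

    def level(self, score: int) -> CriterionLevel:
        for lv in self.levels:
            if lv.score == score:
                return lv
        raise InputError(f"criterion {self.id!r} has no level with score {score}")


@dataclass(frozen=True)
class ScoringFramework:
    """An ordered collection of criteria with pairwise-distinct ids."""

    criteria: tuple[Criterion, ...]
    version_tag: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.criteria]
        if len(set(ids)) != len(ids):
            raise InputError("criterion ids must be pairwise distinct")

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    def __getitem__(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(criterion_id)


@dataclass(frozen=True)
class ValidationReport:
    """Exhaustive, non-throwing validation outcome for one drug profile.

    ``violations`` is a list of ``(drug_id, criterion_id, message)`` tuples;
    the profile is valid iff the list is empty.
    """

    violations: tuple[tuple[str, str, str], ...] = field(default=())

    @property
    def is_valid(self) -> bool:
        return not self.violations


@functools.lru_cache(maxsize=1)
def default_framework() -> ScoringFramework:
    """Return the packaged nine-criterion framework in its canonical order."""
    with resources.files("orphanmcda.data").joinpath("framework_default.yaml").open() as fh:
        return load_framework(fh)


def _is_existing_path(source) -> bool:
    if not isinstance(source, (str, Path)):
        return False
    try:
        return Path(source).exists()
    except OSError:  # e.g. a YAML document passed as a very long string
        return False


def load_framework(source) -> ScoringFramework:
    """Load a framework from a YAML/JSON mapping (path, str or file object).

    Schema: ``{version_tag, criteria: [{id, name, levels: [{score, label,
    definition}]}]}``.
    """
    if _is_existing_path(source):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, dict) or "criteria" not in doc:
        raise InputError("framework document must be a mapping with a 'criteria' list")
    criteria = tuple(
        Criterion(
            id=str(c["id"]),
            name=str(c["name"]),
            levels=tuple(
                CriterionLevel(
                    score=int(lv["score"]),
                    label=str(lv["label"]),
                    definition=str(lv.get("definition", "")),
                )
                for lv in c["levels"]
            ),
        )
        for c in doc["criteria"]
    )
    return ScoringFramework(criteria=criteria, version_tag=str(doc.get("version_tag", "")))


def dump_framework(framework: ScoringFramework) -> str:
    """Serialise a framework to YAML; inverse of :func:`load_framework`."""
    doc = {
        "version_tag": framework.version_tag,
        "criteria": [
            {
                "id": c.id,
                "name": c.name,
                "levels": [
                    {"score": lv.score, "label": lv.label, "definition": lv.definition}
                    for lv in c.levels
                ],
            }
            for c in framework.criteria
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def rarity_score(prevalence_denominator: float) -> int:
    """Map a prevalence of 1 case per ``prevalence_denominator`` population
    to the ordinal rarity score.

    The framework covers only orphan-range prevalence (at most 1 in 2,000).
    Bins are half-open with shared endpoints assigned to the rarer bin:
    [2,000, 20,000) -> 1, [20,000, 200,000) -> 2, [200,000, inf) -> 3.
    """
    n = prevalence_denominator
    if not isinstance(n, (int, float)) or isinstance(n, bool):
        raise InputError(f"prevalence denominator must be a number, got {type(n).__name__}")
    if not math.isfinite(n) or n <= 0:
        raise InputError(f"prevalence denominator must be positive and finite, got {n!r}")
    if n < RARITY_EDGES[0]:
        raise DomainError(
            f"prevalence 1:{n:g} is above the orphan range (more common than 1:2,000)"
        )
    if n < RARITY_EDGES[1]:
        return 1
    if n < RARITY_EDGES[2]:
        return 2
    return 3


def validate_profile(framework: ScoringFramework, profile: "DrugProfile") -> ValidationReport:
    """Check a drug profile against a framework, reporting every violation.

    Problems reported (never raised): a framework criterion with no score, a
    score for an unknown criterion id, and a score outside {1, 2, 3}.
    """
    violations: list[tuple[str, str, str]] = []
    known = set(framework.criterion_ids)
    for cid in framework.criterion_ids:
        if cid not in profile.scores:
            violations.append((profile.drug_id, cid, "missing score for criterion"))
    for cid, score in profile.scores.items():
        if cid not in known:
            violations.append((profile.drug_id, cid, "unknown criterion id"))
        elif score not in VALID_SCORES:
            violations.append(
                (profile.drug_id, cid, f"score out of range: {score!r} not in {{1,2,3}}")
            )
    if profile.annual_cost is not None and not profile.annual_cost > 0:
        violations.append((profile.drug_id, "", f"annual cost must be > 0, got {profile.annual_cost!r}"))
    return ValidationReport(violations=tuple(violations))


def validate_profiles(
    framework: ScoringFramework, profiles: Iterable["DrugProfile"]
) -> ValidationReport:
    """Validate many profiles, concatenating all violations."""
    violations: list[tuple[str, str, str]] = []
    for p in profiles:
        violations.extend(validate_profile(framework, p).violations)
    return ValidationReport(violations=tuple(violations))
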