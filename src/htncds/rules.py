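"""Declarative six-domain rule base for lifestyle recommendations.

The knowledge base covers six intervention domains — physical activity,
stress management, nutrition, sleep, therapeutic adherence, and general
health behaviors — each with a fixed taxonomy of intervention levels
ordered by clinical urgency.  Rules are pure conjunctions of atomic
predicates over schema variables; alternation is expressed as multiple
rules, which keeps the fired-rule traces legible.  All numeric thresholds
live in the rule file (the shipped defaults encode common guideline
anchors such as the <130/80 mmHg blood-pressure control target and are
meant to be re-parameterized for local calibration), never in code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .cohort import VariableSchema

__all__ = [
    "DOMAIN_TAXONOMIES",
    "URGENCY_RANKS",
    "InterventionLevel",
    "Rule",
    "KnowledgeBase",
    "KBValidationReport",
    "RuleValidationError",
    "load_rules",
    "default_kb",
    "validate_kb",
]

#: Fixed per-domain level taxonomies.
DOMAIN_TAXONOMIES: dict[str, tuple[str, ...]] = {
    "physical_activity": ("initiate", "increase", "maintain"),
    "stress": ("urgent", "reduce", "maintain"),
    "nutrition": ("reduce", "maintain", "increase"),
    "sleep": ("urgent", "general"),
    "adherence": ("urgent", "general", "maintain"),
    "general_behaviors": ("urgent", "reduce"),
}

DOMAINS = tuple(DOMAIN_TAXONOMIES)

#: Higher rank = more urgent; strictly ordered within each domain.
URGENCY_RANKS: dict[str, dict[str, int]] = {
    "physical_activity": {"initiate": 2, "increase": 1, "maintain": 0},
    "stress": {"urgent": 2, "reduce": 1, "maintain": 0},
    "nutrition": {"reduce": 2, "increase": 1, "maintain": 0},
    "sleep": {"urgent": 1, "general": 0},
    "adherence": {"urgent": 2, "general": 1, "maintain": 0},
    "general_behaviors": {"urgent": 1, "reduce": 0},
}

COMPARATORS = ("<", "<=", ">", ">=", "==", "in", "contains")


class RuleValidationError(ValueError):
    pass


@dataclass(frozen=True)
class InterventionLevel:
    domain: str
    level: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_TAXONOMIES:
            raise RuleValidationError(f"unknown domain {self.domain!r}")
        if self.level not in DOMAIN_TAXONOMIES[self.domain]:
            raise RuleValidationError(
                f"level {self.level!r} not in the {self.domain} taxonomy "
                f"{DOMAIN_TAXONOMIES[self.domain]}"
            )

    @property
    def urgency_rank(self) -> int:
        return URGENCY_RANKS[self.domain][self.level]


@dataclass(frozen=True)
class Condition:
    variable: str
    comparator: str
    value: Any

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise RuleValidationError(f"unknown comparator {self.comparator!r}")

    def holds(self, values: Mapping[str, Any]) -> bool:
        if self.variable not in values:
            raise KeyError(f"patient values missing variable {self.variable!r}")
        v = values[self.variable]
        op = self.comparator
        if op == "<":
            return v < self.value
        if op == "<=":
            return v <= self.value
        if op == ">":
            return v > self.value
        if op == ">=":
            return v >= self.value
        if op == "==":
            return v == self.value
        if op == "in":
            return v in self.value
        # multihot containment
        return self.value in v


@dataclass(frozen=True)
class Rule:
    id: str
    domain: str
    conditions: tuple[Condition, ...]
    target_level: InterventionLevel
    weight: float = 1.0
    note: str = ""

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise RuleValidationError(f"rule {self.id}: weight must be positive")
        if self.target_level.domain != self.domain:
            raise RuleValidationError(
                f"rule {self.id}: target level belongs to {self.target_level.domain}"
            )

    def fires(self, values: Mapping[str, Any]) -> bool:
        return all(c.holds(values) for c in self.conditions)


@dataclass
class KnowledgeBase:
    rules: dict[str, list[Rule]]             # domain -> rules
    fallbacks: dict[str, InterventionLevel]  # domain -> level when nothing fires
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [d for d in DOMAINS if d not in self.fallbacks]
        if missing:
            raise RuleValidationError(f"domains without a fallback level: {missing}")
        ids = [r.id for rs in self.rules.values() for r in rs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RuleValidationError(f"duplicate rule ids: {dupes}")

    def domain_rules(self, domain: str) -> list[Rule]:
        return self.rules.get(domain, [])

    def referenced_variables(self) -> set[str]:
        return {
            c.variable for rs in self.rules.values() for r in rs for c in r.conditions
        }


def _parse_rule(entry: Mapping[str, Any]) -> Rule:
    try:
        domain = entry["domain"]
        conditions = tuple(
            Condition(variable=c[0], comparator=c[1], value=c[2])
            for c in entry.get("when", [])
        )
        return Rule(
            id=str(entry["id"]),
            domain=domain,
            conditions=conditions,
            target_level=InterventionLevel(domain, entry["then"]),
            weight=float(entry.get("weight", 1.0)),
            note=str(entry.get("note", "")),
        )
    except (KeyError, IndexError, TypeError) as exc:
        raise RuleValidationError(f"malformed rule entry {entry!r}: {exc}") from exc


def load_rules(path: str | Path) -> KnowledgeBase:
    """Load and validate a YAML rule file.

    Format::

        fallbacks: {physical_activity: maintain, ...}
        rules:
          - {id: pa-initiate, domain: physical_activity,
             when: [[activity_days_week, <, 1]], then: initiate, weight: 1}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _build_kb(raw)


def _build_kb(raw: Mapping[str, Any]) -> KnowledgeBase:
    fallbacks = {
        domain: InterventionLevel(domain, level)
        for domain, level in raw.get("fallbacks", {}).items()
    }
    rules: dict[str, list[Rule]] = {d: [] for d in DOMAINS}
    provenance: dict[str, str] = {}
    for entry in raw.get("rules", []):
        rule = _parse_rule(entry)
        rules.setdefault(rule.domain, []).append(rule)
        if rule.note:
            provenance[rule.id] = rule.note
    return KnowledgeBase(rules=rules, fallbacks=fallbacks, provenance=provenance)


def default_kb() -> KnowledgeBase:
    """The shipped six-domain rule base with documented default thresholds."""
    ref = importlib.resources.files("htncds").joinpath("data/default_rules.yaml")
    with ref.open() as fh:
        raw = yaml.safe_load(fh)
    return _build_kb(raw)


@dataclass
class KBValidationReport:
    violations: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_kb(
    kb: KnowledgeBase, schema: Sequence[VariableSchema] | None = None
) -> KBValidationReport:
    """Report structural problems; no violations means the base is sound.

    Checks: every domain has a fallback (guaranteeing a decision for any
    input), referenced variables exist in the schema, and taxonomy
    conformance (already enforced at construction).  Domains without rules
    remain valid via the fallback, but a coverage note is emitted.
    """
    report = KBValidationReport()
    if schema is not None:
        known = {v.name for v in schema}
        for rs in kb.rules.values():
            for r in rs:
                for c in r.conditions:
                    if c.variable not in known:
                        report.violations.append(
                            f"rule {r.id}: variable {c.variable!r} not in schema"
                        )
    for domain in DOMAINS:
        if not kb.domain_rules(domain):
            report.notes.append(
                f"domain {domain!r} has no rules; fallback "
                f"{kb.fallbacks[domain].level!r} always applies"
            )
    return report
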