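"""Hybrid rule inference with dual individual/cluster weighting.

For each of the six intervention domains the engine evaluates the rule base
twice: once on the patient's own values and once on a *virtual patient*
assembled from the patient's cluster profile (centroid means for numeric
variables, modal categories otherwise).  The two normalized per-level score
vectors are combined convexly,

    combined = alpha * individual + beta * cluster,      alpha + beta = 1,

with defaults alpha = 0.85 and beta = 0.15, so recommendations stay
personalized while inheriting group-level context.  The chosen level is the
argmax of the combined scores; ties break toward the clinically more urgent
level.  Every recommendation carries its fired-rule trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .rules import DOMAIN_TAXONOMIES, DOMAINS, URGENCY_RANKS, KnowledgeBase
from .stratify import ClusterProfileSet

__all__ = [
    "WeightConfig",
    "DomainScores",
    "RecommendationSet",
    "CohortRecommendationMatrix",
    "bp_controlled",
    "evaluate_individual",
    "cluster_context",
    "combine",
    "recommend_patient",
    "recommend_cohort",
    "beta_sweep",
]


def bp_controlled(values: Mapping[str, Any],
                  sbp_target: float = 130, dbp_target: float = 80) -> bool:
    """Blood pressure at the control target (<130/80 mmHg by default)."""
    return values["systolic_bp"] < sbp_target and values["diastolic_bp"] < dbp_target


@dataclass(frozen=True)
class WeightConfig:
    alpha: float = 0.85
    beta: float = 0.15

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")


@dataclass
class DomainScores:
    """Per-level scores for one domain; sums to 1 when any rule fired,
    otherwise the fallback level holds score 1 and ``fallback`` is set."""

    domain: str
    scores: dict[str, float]
    fired: list[str] = field(default_factory=list)
    fallback: bool = False

    def top_level(self) -> str:
        ranks = URGENCY_RANKS[self.domain]
        best = max(self.scores.values())
        tied = [lvl for lvl, sc in self.scores.items() if abs(sc - best) <= 1e-12]
        # clinically conservative tie-break: higher urgency, then alphabetical
        tied.sort(key=lambda lvl: (-ranks[lvl], lvl))
        return tied[0]


def _evaluate(values: Mapping[str, Any], kb: KnowledgeBase,
              normalize: bool = True) -> dict[str, DomainScores]:
    out: dict[str, DomainScores] = {}
    for domain in DOMAINS:
        levels = DOMAIN_TAXONOMIES[domain]
        scores = {lvl: 0.0 for lvl in levels}
        fired: list[str] = []
        for rule in kb.domain_rules(domain):
            if rule.fires(values):
                scores[rule.target_level.level] += rule.weight
                fired.append(rule.id)
        if fired:
            if normalize:
                total = sum(scores.values())
                scores = {lvl: sc / total for lvl, sc in scores.items()}
            out[domain] = DomainScores(domain=domain, scores=scores, fired=fired)
        else:
            scores[kb.fallbacks[domain].level] = 1.0
            out[domain] = DomainScores(domain=domain, scores=scores, fallback=True)
    return out


def evaluate_individual(values: Mapping[str, Any], kb: KnowledgeBase,
                        normalize: bool = True) -> dict[str, DomainScores]:
    """Score each domain on the patient's own values.

    Each satisfied rule adds its weight to its target level; per-domain
    scores are normalized to sum to 1 (configurable); with no rule fired the
    fallback level receives score 1.
    """
    return _evaluate(values, kb, normalize=normalize)


def virtual_patient(profiles: ClusterProfileSet, cluster_id: int) -> dict[str, Any]:
    """Centroid means for numeric variables, modal categories otherwise."""
    values: dict[str, Any] = dict(profiles.centroid(cluster_id))
    for var, freqs in profiles.categorical_freqs[cluster_id].items():
        values[var] = max(freqs, key=lambda c: (freqs[c], c))
    return values


def cluster_context(profiles: ClusterProfileSet, cluster_id: int,
                    kb: KnowledgeBase, normalize: bool = True) -> dict[str, DomainScores]:
    """Evaluate the rule base on the cluster's virtual patient."""
    return _evaluate(virtual_patient(profiles, cluster_id), kb, normalize=normalize)


def combine(individual: DomainScores, cluster: DomainScores,
            weights: WeightConfig = WeightConfig()) -> DomainScores:
    """Convex combination of the two score vectors, level by level."""
    if individual.domain != cluster.domain:
        raise ValueError(
            f"domain mismatch: {individual.domain} vs {cluster.domain}"
        )
    if set(individual.scores) != set(cluster.scores):
        raise ValueError("taxonomy mismatch between score vectors")
    scores = {
        lvl: weights.alpha * individual.scores[lvl] + weights.beta * cluster.scores[lvl]
        for lvl in individual.scores
    }
    return DomainScores(
        domain=individual.domain,
        scores=scores,
        fired=list(individual.fired),
        fallback=individual.fallback and cluster.fallback,
    )


@dataclass
class DomainRecommendation:
    level: str
    combined: dict[str, float]
    individual: dict[str, float]
    cluster: dict[str, float]
    fired_rules: list[str]
    fallback: bool


@dataclass
class RecommendationSet:
    patient_id: Any
    cluster_id: int
    domains: dict[str, DomainRecommendation]

    def levels(self) -> dict[str, str]:
        return {d: r.level for d, r in self.domains.items()}


def recommend_patient(
    values: Mapping[str, Any],
    patient_id: Any,
    cluster_id: int,
    profiles: ClusterProfileSet,
    kb: KnowledgeBase,
    weights: WeightConfig = WeightConfig(),
    context: dict[str, DomainScores] | None = None,
) -> RecommendationSet:
    """Full dual-weighted recommendation for one patient.

    ``context`` allows the per-cluster scores to be computed once and shared
    across a cohort run.
    """
    if cluster_id not in profiles.sizes:
        raise ValueError(f"unknown cluster id {cluster_id}")
    ind = evaluate_individual(values, kb)
    ctx = context if context is not None else cluster_context(profiles, cluster_id, kb)
    domains = {}
    for domain in DOMAINS:
        comb = combine(ind[domain], ctx[domain], weights)
        domains[domain] = DomainRecommendation(
            level=comb.top_level(),
            combined=comb.scores,
            individual=ind[domain].scores,
            cluster=ctx[domain].scores,
            fired_rules=ind[domain].fired,
            fallback=ind[domain].fallback,
        )
    return RecommendationSet(patient_id=patient_id, cluster_id=cluster_id, domains=domains)


@dataclass
class CohortRecommendationMatrix:
    """Percent of patients per (domain, level), overall and per cluster."""

    overall: pd.DataFrame                 # index (domain, level), column 'pct'
    per_cluster: pd.DataFrame             # columns cluster_<id>
    recommendations: list[RecommendationSet]

    def to_frame(self) -> pd.DataFrame:
        out = self.overall.join(self.per_cluster)
        return out.reset_index().rename(columns={"level_0": "domain", "level_1": "level"})


def _matrix_from_levels(levels: pd.DataFrame, clusters: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    idx = pd.MultiIndex.from_tuples(
        [(d, lvl) for d in DOMAINS for lvl in DOMAIN_TAXONOMIES[d]],
        names=["domain", "level"],
    )
    overall = pd.DataFrame(0.0, index=idx, columns=["pct"])
    cluster_ids = sorted(np.unique(clusters))
    per_cluster = pd.DataFrame(0.0, index=idx, columns=[f"cluster_{c}" for c in cluster_ids])
    n = len(levels)
    for d in DOMAINS:
        counts = levels[d].value_counts()
        for lvl in DOMAIN_TAXONOMIES[d]:
            overall.loc[(d, lvl), "pct"] = 100.0 * counts.get(lvl, 0) / n
        for c in cluster_ids:
            sub = levels.loc[clusters == c, d].value_counts()
            size = int((clusters == c).sum())
            for lvl in DOMAIN_TAXONOMIES[d]:
                per_cluster.loc[(d, lvl), f"cluster_{c}"] = 100.0 * sub.get(lvl, 0) / size
    return overall, per_cluster


def recommend_cohort(
    cohort: CohortTable,
    labels: np.ndarray,
    profiles: ClusterProfileSet,
    kb: KnowledgeBase,
    weights: WeightConfig = WeightConfig(),
) -> CohortRecommendationMatrix:
    """Run the engine over a cohort; per-domain percentages sum to 100."""
    labels = np.asarray(labels)
    if len(labels) != cohort.n_rows:
        raise ValueError("labels must align with cohort rows")
    contexts = {
        c: cluster_context(profiles, c, kb) for c in sorted(profiles.sizes)
    }
    recs = []
    records = cohort.data.to_dict("records")
    for i, row in enumerate(records):
        recs.append(
            recommend_patient(
                row, row[cohort.id_variable], int(labels[i]), profiles, kb,
                weights, context=contexts[int(labels[i])],
            )
        )
    level_frame = pd.DataFrame([r.levels() for r in recs])
    overall, per_cluster = _matrix_from_levels(level_frame, labels)
    return CohortRecommendationMatrix(
        overall=overall, per_cluster=per_cluster, recommendations=recs
    )


@dataclass
class BetaSweepReport:
    betas: list[float]
    matrices: dict[float, CohortRecommendationMatrix]
    flip_counts: dict[tuple[float, float], int]
    flip_fractions: dict[tuple[float, float], float]
    total_decisions: int


def beta_sweep(
    cohort: CohortTable,
    labels: np.ndarray,
    profiles: ClusterProfileSet,
    kb: KnowledgeBase,
    betas: list[float],
) -> BetaSweepReport:
    """Recommendation matrices per beta plus decision flips between
    consecutive beta values (robustness of the weighting scheme)."""
    if any(not 0 <= b <= 1 for b in betas):
        raise ValueError("betas must lie in [0, 1]")
    matrices: dict[float, CohortRecommendationMatrix] = {}
    for b in betas:
        matrices[b] = recommend_cohort(
            cohort, labels, profiles, kb, WeightConfig(alpha=1 - b, beta=b)
        )
    total = cohort.n_rows * len(DOMAINS)
    flips: dict[tuple[float, float], int] = {}
    fracs: dict[tuple[float, float], float] = {}
    for b0, b1 in zip(betas, betas[1:]):
        lv0 = [r.levels() for r in matrices[b0].recommendations]
        lv1 = [r.levels() for r in matrices[b1].recommendations]
        count = sum(
            a[d] != b[d] for a, b in zip(lv0, lv1) for d in DOMAINS
        )
        flips[(b0, b1)] = count
        fracs[(b0, b1)] = count / total
    return BetaSweepReport(
        betas=list(betas), matrices=matrices, flip_counts=flips,
        flip_fractions=fracs, total_decisions=total,
    )
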