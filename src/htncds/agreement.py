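"""Expert-agreement evaluation: sampling, consensus, kappa, chi-square.

The validation design compares the engine's recommendation (one rater) with
the majority consensus of a panel of human raters (the other rater), per
domain: cases are drawn by stratified sampling proportional to cluster
sizes, panel labels are collapsed by simple majority (>= 3 of 5), and
agreement is summarized as percent agreement, Cohen's kappa with an
asymptotic 95 % confidence interval, and a Pearson chi-square homogeneity
test on the two level distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

from .rules import DOMAIN_TAXONOMIES, URGENCY_RANKS

__all__ = [
    "RatingsPanel",
    "ConsensusLabels",
    "AgreementReport",
    "stratified_sample",
    "simulate_rater_panel",
    "majority_consensus",
    "percent_agreement",
    "cohens_kappa",
    "chi_square_homogeneity",
    "agreement_report",
]


def stratified_sample(
    labels: np.ndarray, n: int, seed: int = 0
) -> np.ndarray:
    """Sample case indices proportionally to cluster sizes.

    Allocation uses largest-remainder rounding so the per-stratum counts sum
    to ``n`` exactly; a stratum smaller than its allocation is capped with
    the remainder redistributed (warning emitted).  Within-stratum selection
    is uniform without replacement.
    """
    labels = np.asarray(labels)
    total = len(labels)
    if n > total:
        raise ValueError(f"cannot sample {n} of {total} cases")
    strata = sorted(np.unique(labels))
    sizes = {s: int((labels == s).sum()) for s in strata}
    quotas = {s: n * sizes[s] / total for s in strata}
    alloc = {s: int(np.floor(q)) for s, q in quotas.items()}
    leftover = n - sum(alloc.values())
    by_remainder = sorted(strata, key=lambda s: (-(quotas[s] - alloc[s]), s))
    for s in by_remainder[:leftover]:
        alloc[s] += 1
    # cap allocations at stratum sizes and redistribute
    overflow = 0
    for s in strata:
        if alloc[s] > sizes[s]:
            overflow += alloc[s] - sizes[s]
            alloc[s] = sizes[s]
    if overflow:
        warnings.warn("stratum smaller than its allocation; redistributing")
        for s in sorted(strata, key=lambda s: sizes[s] - alloc[s], reverse=True):
            room = sizes[s] - alloc[s]
            take = min(room, overflow)
            alloc[s] += take
            overflow -= take
            if overflow == 0:
                break
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for s in strata:
        idx = np.flatnonzero(labels == s)
        chosen.extend(rng.choice(idx, size=alloc[s], replace=False).tolist())
    return np.array(sorted(chosen))


@dataclass
class RatingsPanel:
    """Complete rater x case categorical labels, one grid per domain."""

    cases: list
    raters: list
    ratings: dict[str, pd.DataFrame]   # domain -> (raters x cases) labels

    def __post_init__(self) -> None:
        for domain, grid in self.ratings.items():
            levels = set(DOMAIN_TAXONOMIES[domain])
            bad = set(np.unique(grid.to_numpy())) - levels
            if bad:
                raise ValueError(f"{domain}: labels outside taxonomy: {sorted(bad)}")
            if grid.isna().any().any():
                raise ValueError(f"{domain}: panel has missing ratings")


def simulate_rater_panel(
    truth: Mapping[str, Sequence[str]],
    echo_probability: float,
    raters: int = 5,
    seed: int = 0,
) -> RatingsPanel:
    """Synthetic panel: each rater echoes the truth label with probability
    ``echo_probability``, otherwise emits a uniformly chosen *other* level."""
    if not 0 <= echo_probability <= 1:
        raise ValueError("echo probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    domains = list(truth)
    n_cases = len(truth[domains[0]])
    cases = list(range(n_cases))
    rater_ids = [f"rater_{i}" for i in range(raters)]
    ratings = {}
    for domain in domains:
        levels = DOMAIN_TAXONOMIES[domain]
        grid = np.empty((raters, n_cases), dtype=object)
        for c, true_level in enumerate(truth[domain]):
            others = [lvl for lvl in levels if lvl != true_level]
            for r in range(raters):
                if rng.random() < echo_probability or not others:
                    grid[r, c] = true_level
                else:
                    grid[r, c] = others[rng.integers(len(others))]
        ratings[domain] = pd.DataFrame(grid, index=rater_ids, columns=cases)
    return RatingsPanel(cases=cases, raters=rater_ids, ratings=ratings)


@dataclass
class ConsensusLabels:
    labels: dict[str, list[str | None]]
    strengths: dict[str, list[int]]
    no_consensus: dict[str, list[bool]]
    tie_flagged: dict[str, list[bool]]


def majority_consensus(panel: RatingsPanel) -> ConsensusLabels:
    """Collapse each case to the simple-majority level (>= 3 of 5 raters).

    When no level reaches the majority count the plurality wins; a full
    plurality tie breaks toward the more urgent level and flags the case.
    """
    labels: dict[str, list] = {}
    strengths: dict[str, list[int]] = {}
    no_cons: dict[str, list[bool]] = {}
    ties: dict[str, list[bool]] = {}
    for domain, grid in panel.ratings.items():
        majority = len(panel.raters) // 2 + 1
        ranks = URGENCY_RANKS[domain]
        lv, st, nc, tf = [], [], [], []
        for case in grid.columns:
            counts = grid[case].value_counts()
            top = int(counts.max())
            tied = sorted(
                [l for l, c in counts.items() if c == top],
                key=lambda l: (-ranks[l], l),
            )
            lv.append(tied[0])
            st.append(top)
            nc.append(top < majority)
            tf.append(len(tied) > 1)
        labels[domain] = lv
        strengths[domain] = st
        no_cons[domain] = nc
        ties[domain] = tf
    return ConsensusLabels(labels=labels, strengths=strengths,
                           no_consensus=no_cons, tie_flagged=ties)


def percent_agreement(
    system: Sequence[str], consensus: Sequence[str]
) -> tuple[float, pd.DataFrame]:
    """Overall match fraction plus a per-level breakdown.

    Per-level agreement divides the matches among cases where the *system*
    chose that level by the system's count for the level.
    """
    if len(system) != len(consensus):
        raise ValueError("label vectors must have equal length")
    sys_arr = np.asarray(system, dtype=object)
    con_arr = np.asarray(consensus, dtype=object)
    match = sys_arr == con_arr
    rows = []
    for level in sorted(set(sys_arr) | set(con_arr)):
        sys_n = int((sys_arr == level).sum())
        con_n = int((con_arr == level).sum())
        hits = int(match[sys_arr == level].sum())
        rows.append(
            {
                "level": level,
                "system_n": sys_n,
                "consensus_n": con_n,
                "matches": hits,
                "agreement_pct": 100.0 * hits / sys_n if sys_n else np.nan,
            }
        )
    return float(match.mean()), pd.DataFrame(rows)


@dataclass
class KappaResult:
    kappa: float
    p_o: float
    p_e: float
    ci_low: float
    ci_high: float
    se: float
    undefined: bool = False


def confusion_table(system: Sequence[str], consensus: Sequence[str],
                    levels: Sequence[str]) -> pd.DataFrame:
    sys_arr = np.asarray(system, dtype=object)
    con_arr = np.asarray(consensus, dtype=object)
    table = pd.DataFrame(0, index=list(levels), columns=list(levels))
    for s, c in zip(sys_arr, con_arr):
        table.loc[s, c] += 1
    return table


def cohens_kappa(table: pd.DataFrame | np.ndarray) -> KappaResult:
    """Unweighted Cohen's kappa with the asymptotic 95 % interval.

    kappa = (p_o - p_e)/(1 - p_e) with p_o the diagonal fraction and p_e the
    chance agreement from the marginals.  Both-raters-constant-and-equal
    (p_e = 1) is undefined and returned flagged rather than raised.
    """
    arr = np.asarray(table, dtype=float)
    total = arr.sum()
    if total < 1:
        raise ValueError("confusion table is empty")
    p_o = np.trace(arr) / total
    row = arr.sum(axis=1) / total
    col = arr.sum(axis=0) / total
    p_e = float(row @ col)
    if p_e >= 1 - 1e-15:
        return KappaResult(kappa=np.nan, p_o=p_o, p_e=p_e,
                           ci_low=np.nan, ci_high=np.nan, se=np.nan, undefined=True)
    res = _sm_kappa(arr, return_results=True)
    kappa = float(res.kappa)
    se = float(np.sqrt(res.var_kappa))
    return KappaResult(
        kappa=kappa, p_o=float(p_o), p_e=p_e,
        ci_low=kappa - 1.96 * se, ci_high=kappa + 1.96 * se, se=se,
    )


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_homogeneity(
    system_counts: Mapping[str, int], consensus_counts: Mapping[str, int]
) -> ChiSquareResult:
    """Pearson chi-square on the 2 x L (source x level) table, df = L - 1,
    no continuity correction."""
    levels = sorted(set(system_counts) | set(consensus_counts))
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")
    a = np.array([system_counts.get(l, 0) for l in levels], dtype=float)
    b = np.array([consensus_counts.get(l, 0) for l in levels], dtype=float)
    if a.sum() != b.sum():
        raise ValueError("totals must be equal for the homogeneity test")
    table = np.vstack([a, b])
    expected_zero = [l for l, c in zip(levels, table.sum(axis=0)) if c == 0]
    if expected_zero:
        raise ValueError(f"expected count of zero for levels: {expected_zero}")
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


@dataclass
class AgreementReport:
    per_domain: pd.DataFrame      # one row per domain
    per_level: pd.DataFrame       # one row per (domain, level)
    overall_agreement: float
    overall_kappa: KappaResult
    excluded_no_consensus: dict[str, int] = field(default_factory=dict)


def agreement_report(
    system_levels: Mapping[str, Sequence[str]],
    panel: RatingsPanel,
) -> AgreementReport:
    """Assemble per-domain and pooled agreement statistics.

    ``system_levels`` maps each domain to the engine's chosen level per
    case, aligned with the panel's cases.  Cases without panel consensus
    are excluded from the statistics and counted.
    """
    consensus = majority_consensus(panel)
    domain_rows, level_rows = [], []
    pooled_match = 0
    pooled_total = 0
    pooled_table = None
    excluded: dict[str, int] = {}
    for domain in system_levels:
        sys_all = list(system_levels[domain])
        con_all = consensus.labels[domain]
        keep = [i for i, nc in enumerate(consensus.no_consensus[domain]) if not nc]
        excluded[domain] = len(sys_all) - len(keep)
        sys_lab = [sys_all[i] for i in keep]
        con_lab = [con_all[i] for i in keep]
        overall, per_level = percent_agreement(sys_lab, con_lab)
        levels = DOMAIN_TAXONOMIES[domain]
        table = confusion_table(sys_lab, con_lab, levels)
        kap = cohens_kappa(table)
        sys_counts = {l: int((np.asarray(sys_lab, dtype=object) == l).sum())
                      for l in levels}
        con_counts = {l: int((np.asarray(con_lab, dtype=object) == l).sum())
                      for l in levels}
        present = [l for l in levels if sys_counts[l] + con_counts[l] > 0]
        if len(present) >= 2:
            chi = chi_square_homogeneity(
                {l: sys_counts[l] for l in present},
                {l: con_counts[l] for l in present},
            )
        else:  # a single observed level carries no distributional contrast
            chi = ChiSquareResult(statistic=0.0, df=0, p_value=1.0)
        domain_rows.append(
            {
                "domain": domain,
                "n_cases": len(sys_lab),
                "agreement_pct": 100.0 * overall,
                "kappa": kap.kappa,
                "kappa_ci_low": kap.ci_low,
                "kappa_ci_high": kap.ci_high,
                "chi2": chi.statistic,
                "df": chi.df,
                "p_value": chi.p_value,
            }
        )
        per_level.insert(0, "domain", domain)
        level_rows.append(per_level)
        pooled_match += int(
            (np.asarray(sys_lab, dtype=object) == np.asarray(con_lab, dtype=object)).sum()
        )
        pooled_total += len(sys_lab)
        # pooled kappa over (domain, level) pairs treated as distinct categories
        wide = confusion_table(
            [f"{domain}:{l}" for l in sys_lab],
            [f"{domain}:{l}" for l in con_lab],
            [f"{domain}:{l}" for l in levels],
        )
        pooled_table = wide if pooled_table is None else _block_diag(pooled_table, wide)
    overall_kappa = cohens_kappa(pooled_table)
    return AgreementReport(
        per_domain=pd.DataFrame(domain_rows),
        per_level=pd.concat(level_rows, ignore_index=True),
        overall_agreement=pooled_match / pooled_total if pooled_total else np.nan,
        overall_kappa=overall_kappa,
        excluded_no_consensus=excluded,
    )


def _block_diag(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(
        0, index=list(a.index) + list(b.index), columns=list(a.columns) + list(b.columns)
    )
    out.loc[a.index, a.columns] = a.to_numpy()
    out.loc[b.index, b.columns] = b.to_numpy()
    return out
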