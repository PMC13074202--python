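"""End-to-end pipeline orchestration with reproducible artifacts.

``run_pipeline`` wires the stages in their fixed order — cohort input (or
synthesis), preprocessing, standardization of the clustering features, PCA,
model selection over the algorithm x k grid, cluster profiling, dual-weighted
recommendation, and (optionally) simulated-panel agreement validation — and
writes every result as a JSON/CSV artifact tagged with the configuration
hash and seed.  A single global seed deterministically derives every stage
seed, so reruns with the same configuration reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import inference as inf
from .cohort import CohortTable, load_schema, read_cohort, write_cohort
from .preprocess import PreprocessConfig, run_preprocessing, zscore_standardize
from .rules import default_kb, load_rules
from .stratify import assess_stability, fit_pca, profile_clusters, select_model
from .synthetic import default_study_config, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    cohort_path: str | None = None
    schema_path: str | None = None
    rules_path: str | None = None
    output_dir: str = "artifacts"
    max_missing_fraction: float = 0.5
    knn_k: int | str = "sqrt"
    pca_tau: float = 0.90
    algorithms: tuple[str, ...] = ("kmeans", "hac", "gmm")
    k_min: int = 3
    k_max: int = 6
    alpha: float = 0.85
    beta: float = 0.15
    validation_cases: int = 120
    validation_raters: int = 5
    validation_echo: float | None = None
    stability_seeds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    cohort: CohortTable
    preprocess_report: Any
    pca_model: Any
    selection: Any
    profiles: Any
    matrix: Any
    stability: Any
    agreement: Any | None
    artifacts: dict[str, str] = field(default_factory=dict)


def _dump_json(obj: Any, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the artifact bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": dataclasses.asdict(config), "config_hash": config.config_hash(),
            "seed": config.seed}
    artifacts: dict[str, str] = {}

    # --- input ---------------------------------------------------------------
    if config.cohort_path:
        if not config.schema_path:
            raise ValueError("a cohort_path requires a schema_path")
        schema = load_schema(config.schema_path)
        cohort = read_cohort(config.cohort_path, schema)
        truth = None
    else:
        gen = default_study_config(seed=stage_seed(config.seed, "generate"))
        cohort, truth = generate_cohort(gen)
        write_cohort(cohort, out / "synthetic_cohort.csv")
        artifacts["synthetic_cohort"] = str(out / "synthetic_cohort.csv")

    # --- preprocessing -------------------------------------------------------
    pcfg = PreprocessConfig(
        max_missing_fraction=config.max_missing_fraction, knn_k=config.knn_k
    )
    clean, report = run_preprocessing(cohort, pcfg)
    _dump_json(report, out / "preprocess_report.json")
    artifacts["preprocess_report"] = str(out / "preprocess_report.json")

    # --- stratification ------------------------------------------------------
    clus_vars = clean.variables(clustering=True)
    matrix = zscore_standardize(clean, clus_vars)
    pca = fit_pca(matrix, tau=config.pca_tau)
    scores = pca.transform(matrix.values)
    _dump_json(
        {
            "retained_m": pca.retained_m,
            "threshold_tau": pca.threshold_tau,
            "explained_variance_ratios": pca.explained_variance_ratios,
            "columns": pca.columns,
        },
        out / "pca_model.json",
    )
    artifacts["pca_model"] = str(out / "pca_model.json")

    selection = select_model(
        scores,
        algorithms=config.algorithms,
        k_range=range(config.k_min, config.k_max + 1),
        seed=stage_seed(config.seed, "cluster"),
        original_features=clean.data[clus_vars].astype(float),
    )
    selection.to_frame().to_csv(out / "selection_grid.csv", index=False)
    _dump_json(
        {"chosen": list(selection.chosen), "rationale": selection.rationale,
         "grid": {f"{a}:{k}": vi.as_dict() for (a, k), vi in selection.grid.items()}},
        out / "selection_report.json",
    )
    artifacts["selection_report"] = str(out / "selection_report.json")
    model = selection.chosen_model

    stability = assess_stability(
        scores, model.algorithm, model.k,
        seeds=[stage_seed(config.seed, f"stab{i}") for i in range(config.stability_seeds)],
    )
    _dump_json(stability, out / "stability_report.json")
    artifacts["stability_report"] = str(out / "stability_report.json")

    profiles = profile_clusters(clean, model.labels)
    _dump_json(
        {
            "names": profiles.names,
            "sizes": profiles.sizes,
            "variable_importance": profiles.variable_importance,
            "centroids": {g: profiles.centroid(g) for g in profiles.sizes},
        },
        out / "cluster_profiles.json",
    )
    artifacts["cluster_profiles"] = str(out / "cluster_profiles.json")

    # --- inference -----------------------------------------------------------
    kb = load_rules(config.rules_path) if config.rules_path else default_kb()
    weights = inf.WeightConfig(alpha=config.alpha, beta=config.beta)
    rec_matrix = inf.recommend_cohort(clean, model.labels, profiles, kb, weights)
    rec_matrix.to_frame().to_csv(out / "recommendation_matrix.csv", index=False)
    artifacts["recommendation_matrix"] = str(out / "recommendation_matrix.csv")
    with open(out / "recommendations.jsonl", "w") as fh:
        for rec in rec_matrix.recommendations:
            fh.write(json.dumps(dataclasses.asdict(rec), default=str) + "\n")
    artifacts["recommendations"] = str(out / "recommendations.jsonl")

    # --- validation (simulated panel, optional) ------------------------------
    agreement = None
    if config.validation_echo is not None:
        sample = agr.stratified_sample(
            model.labels, config.validation_cases,
            seed=stage_seed(config.seed, "sample"),
        )
        system_levels = {
            d: [rec_matrix.recommendations[i].domains[d].level for i in sample]
            for d in kb.fallbacks
        }
        panel = agr.simulate_rater_panel(
            system_levels, config.validation_echo, raters=config.validation_raters,
            seed=stage_seed(config.seed, "panel"),
        )
        agreement = agr.agreement_report(system_levels, panel)
        _dump_json(
            {
                "overall_agreement": agreement.overall_agreement,
                "overall_kappa": agreement.overall_kappa,
                "per_domain": agreement.per_domain.to_dict("records"),
                "excluded_no_consensus": agreement.excluded_no_consensus,
            },
            out / "agreement_report.json",
        )
        artifacts["agreement_report"] = str(out / "agreement_report.json")

    _dump_json({**meta, "artifacts": artifacts}, out / "run_meta.json")
    return PipelineResult(
        cohort=clean,
        preprocess_report=report,
        pca_model=pca,
        selection=selection,
        profiles=profiles,
        matrix=rec_matrix,
        stability=stability,
        agreement=agreement,
        artifacts=artifacts,
    )
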