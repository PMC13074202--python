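"""Reference experiments: phenotype-recovery on the default synthetic cohort.

The recovery experiment is the package's main end-to-end check: generate
the calibrated cohort, run the cleaning pipeline, standardize the 15
clustering features, reduce with PCA at 90 % retained variance, fit the
algorithm x k grid and keep the validity-selected model, then compare the
recovered partition against the planted profiles — matching recovered
clusters to profiles by minimal standardized centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .preprocess import PreprocessConfig, run_preprocessing, zscore_standardize
from .stratify import select_model
from .stratify import fit_pca
from .synthetic import default_study_config, generate_cohort

__all__ = ["RecoveryResult", "phenotype_recovery", "match_clusters_to_profiles"]


@dataclass
class RecoveryResult:
    seed: int
    chosen: tuple[str, int]
    sizes: dict[int, int]                  # recovered cluster -> member count
    matched: dict[int, int]                # planted profile -> recovered cluster
    centroids: dict[int, dict[str, float]]  # recovered cluster -> original-unit means
    ari: float
    n_rows: int

    @property
    def size_largest(self) -> int:
        return max(self.sizes.values())

    @property
    def size_second(self) -> int:
        return sorted(self.sizes.values(), reverse=True)[1]

    def matched_centroid(self, profile: int) -> dict[str, float]:
        return self.centroids[self.matched[profile]]


def match_clusters_to_profiles(
    cluster_centroids: np.ndarray,
    profile_means: np.ndarray,
    scale: np.ndarray,
) -> dict[int, int]:
    """One-to-one match of planted profiles to recovered clusters by minimal
    Euclidean distance on ``scale``-standardized centroid coordinates."""
    C = cluster_centroids / scale
    P = profile_means / scale
    cost = np.linalg.norm(P[:, None, :] - C[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return {int(p): int(c) for p, c in zip(rows, cols)}


def phenotype_recovery(seed: int, tau: float = 0.90) -> RecoveryResult:
    """Run the full stratification pipeline on the default cohort at ``seed``
    and report the recovered sizes and matched centroids."""
    config = default_study_config(seed=seed)
    cohort, truth = generate_cohort(config)
    clean, report = run_preprocessing(cohort, PreprocessConfig())
    kept_ids = set(clean.data[clean.id_variable])
    keep = cohort.data[cohort.id_variable].isin(kept_ids).to_numpy()

    clus_vars = clean.variables(clustering=True)
    matrix = zscore_standardize(clean, clus_vars)
    pca = fit_pca(matrix, tau=tau)
    scores = pca.transform(matrix.values)
    selection = select_model(
        scores, seed=seed, original_features=clean.data[clus_vars].astype(float)
    )
    model = selection.chosen_model
    labels = model.labels

    sizes = {int(g): int(n) for g, n in zip(*np.unique(labels, return_counts=True))}
    centroids = {
        g: {
            var: float(clean.data.loc[labels == g, var].astype(float).mean())
            for var in clus_vars
        }
        for g in sizes
    }
    profile_means = np.array(
        [[p.numeric_means[v] for v in clus_vars] for p in config.profiles]
    )
    cluster_cents = np.array(
        [[centroids[g][v] for v in clus_vars] for g in sorted(sizes)]
    )
    scale = np.where(matrix.sds == 0, 1.0, matrix.sds)
    matched_idx = match_clusters_to_profiles(cluster_cents, profile_means, scale)
    order = sorted(sizes)
    matched = {p: order[c] for p, c in matched_idx.items()}

    return RecoveryResult(
        seed=seed,
        chosen=selection.chosen,
        sizes=sizes,
        matched=matched,
        centroids=centroids,
        ari=float(adjusted_rand_score(truth.labels[keep], labels)),
        n_rows=clean.n_rows,
    )
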