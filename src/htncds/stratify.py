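"""Patient stratification: PCA, clustering, internal validity, profiling.

The stratification stage reduces the standardized clinical matrix with PCA
(components retained up to a cumulative explained-variance threshold, 0.90
by default), fits candidate partitions over an algorithm x k grid
(k-means, Ward hierarchical agglomeration, Gaussian mixtures), and scores
every cell with three internal validity indices:

* mean silhouette  s(i) = (b(i) - a(i)) / max{a(i), b(i)}  — cohesion vs
  separation per point, averaged;
* Davies-Bouldin  DB = (1/c) sum_i max_{j!=i} (d(X_i)+d(X_j))/d(c_i,c_j)
  — worst-case dispersion-to-separation ratio, lower is better;
* Calinski-Harabasz  CH = [tr(S_B)/(k-1)] / [tr(S_W)/(n-k)]  — between- to
  within-scatter ratio with the standard degree-of-freedom normalization.

Model selection is lexicographic — maximize silhouette, break ties by CH,
then by DB — because a deterministic total order is needed even though the
three indices are conceptually weighed jointly.

The index implementations here are deliberately first-party (they define
the selection semantics, including the singleton and zero-distance
conventions); library versions serve as independent cross-checks in the
test-suite only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import f_oneway
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .cohort import CohortTable
from .preprocess import StandardizedMatrix

__all__ = [
    "PCAModel",
    "ClusterModel",
    "ValidityIndices",
    "SelectionReport",
    "ClusterProfileSet",
    "StabilityReport",
    "fit_pca",
    "silhouette_index",
    "davies_bouldin_index",
    "calinski_harabasz_index",
    "run_clustering",
    "select_model",
    "assess_stability",
    "profile_clusters",
    "DEFAULT_PROFILE_SIGNATURES",
]

ALGORITHMS = ("kmeans", "hac", "gmm")


class UndefinedIndexError(ValueError):
    """An internal validity index is undefined for the given partition."""


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: np.ndarray              # variables x components
    eigenvalues: np.ndarray
    explained_variance_ratios: np.ndarray
    retained_m: int
    threshold_tau: float
    columns: list[str]
    means: np.ndarray

    def transform(self, values: np.ndarray, full: bool = False) -> np.ndarray:
        scores = (values - self.means) @ self.loadings
        return scores if full else scores[:, : self.retained_m]


def fit_pca(matrix: StandardizedMatrix | np.ndarray, tau: float = 0.90,
            columns: list[str] | None = None) -> PCAModel:
    """Full-rank PCA with components retained up to cumulative ratio >= tau.

    The retention boundary is inclusive: ratios (0.9, 0.1) at tau = 0.90
    retain a single component.  Sign convention: the largest-magnitude
    loading of each component is positive, making the decomposition
    deterministic.  Rank-deficient input is fine (zero eigenvalues allowed).
    """
    if isinstance(matrix, StandardizedMatrix):
        X = matrix.values
        columns = list(matrix.columns)
    else:
        X = np.asarray(matrix, dtype=float)
        columns = columns or [f"x{i}" for i in range(X.shape[1])]
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.T.copy()          # variables x components
    for j in range(loadings.shape[1]):
        peak = np.argmax(np.abs(loadings[:, j]))
        if loadings[peak, j] < 0:
            loadings[:, j] = -loadings[:, j]
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    retained = int(np.searchsorted(cum, tau - 1e-12) + 1)
    retained = min(retained, len(ratios))
    return PCAModel(
        loadings=loadings,
        eigenvalues=pca.explained_variance_.copy(),
        explained_variance_ratios=ratios.copy(),
        retained_m=retained,
        threshold_tau=tau,
        columns=columns,
        means=pca.mean_.copy(),
    )


# ---------------------------------------------------------------------------
# Internal validity indices
# ---------------------------------------------------------------------------


@dataclass
class ValidityIndices:
    silhouette_mean: float
    davies_bouldin: float
    calinski_harabasz: float
    silhouette_per_point: np.ndarray | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "silhouette_mean": self.silhouette_mean,
            "davies_bouldin": self.davies_bouldin,
            "calinski_harabasz": self.calinski_harabasz,
        }


def _check_partition(points: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    labels = np.asarray(labels)
    if len(labels) != len(points):
        raise ValueError("labels must align with points")
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    if len(groups) < 2:
        raise UndefinedIndexError("validity indices need at least 2 clusters")
    return groups


def silhouette_index(points: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean silhouette and per-point values.

    Conventions: a(i) averages over same-cluster points excluding i;
    singletons get s(i) = 0; a(i) = 0 with b(i) > 0 gives s(i) = 1; the
    degenerate a = b = 0 case is 0.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    groups = _check_partition(points, labels)
    D = cdist(points, points)
    n = len(points)
    s = np.zeros(n)
    sums = {g: D[:, idx].sum(axis=1) for g, idx in enumerate(groups)}
    sizes = [len(idx) for idx in groups]
    member_of = np.empty(n, dtype=int)
    for g, idx in enumerate(groups):
        member_of[idx] = g
    for i in range(n):
        g = member_of[i]
        if sizes[g] == 1:
            s[i] = 0.0
            continue
        a = sums[g][i] / (sizes[g] - 1)
        b = min(sums[h][i] / sizes[h] for h in range(len(groups)) if h != g)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean()), s


def davies_bouldin_index(points: np.ndarray, labels: np.ndarray) -> float:
    """DB index; coincident centroids propagate +inf with a warning."""
    points = np.asarray(points, dtype=float)
    groups = _check_partition(points, labels)
    centroids = np.array([points[idx].mean(axis=0) for idx in groups])
    dispersions = np.array(
        [np.linalg.norm(points[idx] - c, axis=1).mean()
         for idx, c in zip(groups, centroids)]
    )
    c = len(groups)
    total = 0.0
    for i in range(c):
        worst = -np.inf
        for j in range(c):
            if i == j:
                continue
            sep = np.linalg.norm(centroids[i] - centroids[j])
            if sep == 0:
                warnings.warn("coincident centroids: Davies-Bouldin is infinite")
                ratio = np.inf
            else:
                ratio = (dispersions[i] + dispersions[j]) / sep
            worst = max(worst, ratio)
        total += worst
    return float(total / c)


def calinski_harabasz_index(points: np.ndarray, labels: np.ndarray) -> float:
    """CH index with (k-1, n-k) normalization; zero within-scatter gives +inf."""
    points = np.asarray(points, dtype=float)
    groups = _check_partition(points, labels)
    n, k = len(points), len(groups)
    if n <= k:
        raise UndefinedIndexError("Calinski-Harabasz needs more points than clusters")
    grand = points.mean(axis=0)
    sb = sum(len(idx) * np.sum((points[idx].mean(axis=0) - grand) ** 2) for idx in groups)
    sw = sum(np.sum((points[idx] - points[idx].mean(axis=0)) ** 2) for idx in groups)
    if sw == 0:
        warnings.warn("zero within-cluster scatter: Calinski-Harabasz is infinite")
        return float(np.inf)
    return float((sb / (k - 1)) / (sw / (n - k)))


def compute_indices(points: np.ndarray, labels: np.ndarray) -> ValidityIndices:
    sil, per_point = silhouette_index(points, labels)
    return ValidityIndices(
        silhouette_mean=sil,
        davies_bouldin=davies_bouldin_index(points, labels),
        calinski_harabasz=calinski_harabasz_index(points, labels),
        silhouette_per_point=per_point,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    algorithm: str
    k: int
    labels: np.ndarray
    centroids_reduced: np.ndarray
    seed: int
    centroids_original: np.ndarray | None = None
    original_columns: list[str] | None = None

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster must be non-empty")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _fit_labels(points: np.ndarray, algorithm: str, k: int, seed: int) -> np.ndarray:
    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        return km.fit_predict(points)
    if algorithm == "hac":
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(points)
    if algorithm == "gmm":
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=5, random_state=seed
        )
        return gm.fit_predict(points)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def run_clustering(
    points: np.ndarray,
    algorithm: str,
    k: int,
    seed: int = 0,
    original_features: pd.DataFrame | None = None,
) -> ClusterModel:
    """Fit one (algorithm, k) cell and package labels plus centroids.

    k-means uses k-means++ with 10 restarts keeping the best inertia; HAC is
    Ward linkage on Euclidean distances (deterministic, seed ignored); GMM
    uses full covariances with labels by maximum responsibility.  A fit that
    leaves an empty cluster is retried once with a derived seed.
    """
    points = np.asarray(points, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    labels = _fit_labels(points, algorithm, k, seed)
    if len(np.unique(labels)) < k:
        labels = _fit_labels(points, algorithm, k, seed + 10007)
        if len(np.unique(labels)) < k:
            raise RuntimeError(f"{algorithm} left an empty cluster after retry")
    centroids = np.array([points[labels == g].mean(axis=0) for g in range(k)])
    model = ClusterModel(
        algorithm=algorithm, k=k, labels=labels,
        centroids_reduced=centroids, seed=seed,
    )
    if original_features is not None:
        model.centroids_original = np.array(
            [original_features.to_numpy(dtype=float)[labels == g].mean(axis=0)
             for g in range(k)]
        )
        model.original_columns = list(original_features.columns)
    return model


# ---------------------------------------------------------------------------
# Model selection & stability
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    grid: dict[tuple[str, int], ValidityIndices]
    chosen: tuple[str, int]
    rationale: list[str]
    models: dict[tuple[str, int], ClusterModel] = field(default_factory=dict)

    @property
    def chosen_model(self) -> ClusterModel:
        return self.models[self.chosen]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"algorithm": alg, "k": k, **vi.as_dict(),
             "chosen": (alg, k) == self.chosen}
            for (alg, k), vi in self.grid.items()
        ]
        return pd.DataFrame(rows)


_TIE_TOL = 1e-12


def select_model(
    points: np.ndarray,
    algorithms: tuple[str, ...] = ALGORITHMS,
    k_range: range | tuple[int, ...] = range(3, 7),
    seed: int = 0,
    original_features: pd.DataFrame | None = None,
) -> SelectionReport:
    """Score every grid cell and choose lexicographically:
    max silhouette, then max Calinski-Harabasz, then min Davies-Bouldin."""
    grid: dict[tuple[str, int], ValidityIndices] = {}
    models: dict[tuple[str, int], ClusterModel] = {}
    for alg in algorithms:
        for k in k_range:
            model = run_clustering(points, alg, k, seed=seed,
                                   original_features=original_features)
            grid[(alg, k)] = compute_indices(points, model.labels)
            models[(alg, k)] = model
    if not grid:
        raise ValueError("empty model grid")

    def better(a: ValidityIndices, b: ValidityIndices) -> bool:
        if abs(a.silhouette_mean - b.silhouette_mean) > _TIE_TOL:
            return a.silhouette_mean > b.silhouette_mean
        if abs(a.calinski_harabasz - b.calinski_harabasz) > _TIE_TOL:
            return a.calinski_harabasz > b.calinski_harabasz
        return a.davies_bouldin < b.davies_bouldin

    chosen = next(iter(grid))
    for cell, vi in grid.items():
        if cell != chosen and better(vi, grid[chosen]):
            chosen = cell
    rationale = [
        "lexicographic rule: max silhouette, tie-break max Calinski-Harabasz, "
        "tie-break min Davies-Bouldin",
        f"chosen {chosen[0]} k={chosen[1]} with silhouette "
        f"{grid[chosen].silhouette_mean:.4f}",
    ]
    return SelectionReport(grid=grid, chosen=chosen, rationale=rationale, models=models)


@dataclass
class StabilityReport:
    seeds: list[int]
    pairwise_ari: list[float]
    mean_ari: float


def assess_stability(
    points: np.ndarray, algorithm: str, k: int, seeds: list[int]
) -> StabilityReport:
    """Adjusted Rand index between re-runs under different seeds."""
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds")
    runs = [run_clustering(points, algorithm, k, seed=s).labels for s in seeds]
    pairs = [
        float(adjusted_rand_score(runs[i], runs[j]))
        for i in range(len(runs))
        for j in range(i + 1, len(runs))
    ]
    return StabilityReport(seeds=list(seeds), pairwise_ari=pairs,
                           mean_ari=float(np.mean(pairs)))


# ---------------------------------------------------------------------------
# Profiling and naming
# ---------------------------------------------------------------------------


#: Dominant-deviation signatures mapping cluster phenotypes to their
#: standard names: glycemic alteration, high cholesterol with low
#: hemoglobin, and distinctive anthropometrics respectively.
DEFAULT_PROFILE_SIGNATURES: dict[str, dict[str, float]] = {
    "metabolic-hypertensive": {"glucose": 1.0},
    "dyslipidemic-anemic": {"cholesterol_total": 1.0, "hemoglobin": -1.0},
    "constitutional-atypical": {"height_cm": 1.0},
}


@dataclass
class ClusterProfileSet:
    numeric_stats: dict[int, pd.DataFrame]       # per cluster: mean/sd per variable
    categorical_freqs: dict[int, dict[str, dict[str, float]]]
    variable_importance: pd.Series               # F statistic per clustering variable
    names: dict[int, str]
    sizes: dict[int, int]

    def centroid(self, cluster: int) -> pd.Series:
        return self.numeric_stats[cluster]["mean"]


def profile_clusters(
    cohort: CohortTable,
    labels: np.ndarray,
    signatures: dict[str, dict[str, float]] | None = None,
) -> ClusterProfileSet:
    """Describe each cluster and rank discriminating variables.

    Importance is the one-way ANOVA F statistic of each clustering feature
    across clusters.  Names are assigned by matching per-cluster z-deviation
    patterns against ``signatures`` (one-to-one, best total match); with a
    cluster count different from the signature count, clusters get generic
    names.
    """
    labels = np.asarray(labels)
    if len(labels) != cohort.n_rows:
        raise ValueError("labels must align with cohort rows")
    clusters = [int(g) for g in np.unique(labels)]
    num_vars = cohort.variables(kind="numeric")
    clus_vars = cohort.variables(clustering=True)
    X = cohort.data[num_vars].astype(float)

    numeric_stats, cat_freqs, sizes = {}, {}, {}
    for g in clusters:
        sub = X[labels == g]
        numeric_stats[g] = pd.DataFrame(
            {"mean": sub.mean(), "sd": sub.std(ddof=0)}
        )
        sizes[g] = int((labels == g).sum())
        freqs: dict[str, dict[str, float]] = {}
        for var in cohort.schema:
            if var.kind != "categorical" or var.identifier:
                continue
            counts = cohort.data.loc[labels == g, var.name].value_counts(normalize=True)
            freqs[var.name] = {c: float(counts.get(c, 0.0)) for c in var.categories}
        cat_freqs[g] = freqs

    fstats = {}
    for var in clus_vars:
        samples = [X.loc[labels == g, var].to_numpy() for g in clusters]
        if any(len(s) < 2 for s in samples) or np.ptp(np.concatenate(samples)) == 0:
            fstats[var] = 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, _ = f_oneway(*samples)
        fstats[var] = float(f) if np.isfinite(f) else 0.0
    importance = pd.Series(fstats).sort_values(ascending=False)

    signatures = signatures if signatures is not None else DEFAULT_PROFILE_SIGNATURES
    names = {g: f"cluster_{g}" for g in clusters}
    if len(signatures) == len(clusters):
        grand_mean = X.mean()
        grand_sd = X.std(ddof=0).replace(0, 1.0)
        zdev = {g: (numeric_stats[g]["mean"] - grand_mean) / grand_sd for g in clusters}
        sig_names = list(signatures)
        score = np.zeros((len(clusters), len(sig_names)))
        for i, g in enumerate(clusters):
            for j, sig in enumerate(sig_names):
                score[i, j] = sum(
                    direction * zdev[g].get(var, 0.0)
                    for var, direction in signatures[sig].items()
                )
        rows, cols = linear_sum_assignment(-score)
        for i, j in zip(rows, cols):
            names[clusters[i]] = sig_names[j]

    return ClusterProfileSet(
        numeric_stats=numeric_stats,
        categorical_freqs=cat_freqs,
        variable_importance=importance,
        names=names,
        sizes=sizes,
    )
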