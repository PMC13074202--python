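"""PCA retention, validity indices vs brute-force oracles, clustering grid."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group
from sklearn import metrics as skm

from htncds.stratify import (
    UndefinedIndexError,
    assess_stability,
    calinski_harabasz_index,
    davies_bouldin_index,
    fit_pca,
    profile_clusters,
    run_clustering,
    select_model,
    silhouette_index,
)

from conftest import make_table


# --- brute-force oracles (straight double loops over the definitions) -------


def brute_silhouette(points, labels):
    n = len(points)
    d = lambda i, j: np.linalg.norm(points[i] - points[j])
    out = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([d(i, j) for j in own])
        b = min(
            np.mean([d(i, j) for j in range(n) if labels[j] == g])
            for g in set(labels) if g != labels[i]
        )
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out.mean(), out


def brute_davies_bouldin(points, labels):
    groups = sorted(set(labels))
    cents = {g: points[labels == g].mean(axis=0) for g in groups}
    disp = {
        g: np.mean([np.linalg.norm(x - cents[g]) for x in points[labels == g]])
        for g in groups
    }
    total = 0.0
    for i in groups:
        total += max(
            (disp[i] + disp[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in groups if j != i
        )
    return total / len(groups)


def brute_calinski(points, labels):
    groups = sorted(set(labels))
    n, k = len(points), len(groups)
    grand = points.mean(axis=0)
    sb = sum(
        (labels == g).sum() * np.sum((points[labels == g].mean(axis=0) - grand) ** 2)
        for g in groups
    )
    sw = sum(
        np.sum((x - points[labels == g].mean(axis=0)) ** 2)
        for g in groups for x in points[labels == g]
    )
    return (sb / (k - 1)) / (sw / (n - k))


TOY = np.array([[0.0], [1.0], [5.0], [6.0]])
TOY_LABELS = np.array([0, 0, 1, 1])


class TestPCA:
    def test_perfectly_correlated_columns_collapse_to_one_component(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        X = np.column_stack([x, 2 * x])
        model = fit_pca(X, tau=0.9)
        assert model.explained_variance_ratios[0] == pytest.approx(1.0)
        assert model.retained_m == 1

    def test_isotropic_gaussian_keeps_all_three(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20000, 3))
        model = fit_pca(X, tau=0.9)
        assert model.explained_variance_ratios == pytest.approx(
            np.full(3, 1 / 3), abs=0.02
        )
        assert model.retained_m == 3

    def test_retention_boundary_is_inclusive(self):
        # orthogonal columns with variance ratio exactly 9:1
        X = np.array([[3.0, 1.0], [3.0, -1.0], [-3.0, 1.0], [-3.0, -1.0]])
        model = fit_pca(X, tau=0.90)
        assert model.explained_variance_ratios == pytest.approx([0.9, 0.1])
        assert model.retained_m == 1

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 4))
        model = fit_pca(X, tau=0.9)
        for j in range(model.loadings.shape[1]):
            peak = np.argmax(np.abs(model.loadings[:, j]))
            assert model.loadings[peak, j] > 0

    def test_ratios_sum_to_one_and_nonincreasing(self, stratified):
        _, _, _, selection = stratified
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 6)) * np.arange(1, 7)
        model = fit_pca(X, tau=0.9)
        assert model.explained_variance_ratios.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(model.explained_variance_ratios) <= 1e-12).all()


class TestIndicesHandExamples:
    def test_silhouette_toy_value(self):
        mean, per_point = silhouette_index(TOY, TOY_LABELS)
        assert per_point == pytest.approx([0.8182, 0.7778, 0.7778, 0.8182], abs=1e-4)
        assert mean == pytest.approx(0.7980, abs=1e-4)

    def test_silhouette_coincident_clusters_reach_one(self):
        pts = np.array([[0.0], [0.0], [9.0], [9.0]])
        mean, _ = silhouette_index(pts, np.array([0, 0, 1, 1]))
        assert mean == pytest.approx(1.0)

    def test_silhouette_single_cluster_errors(self):
        with pytest.raises(UndefinedIndexError):
            silhouette_index(TOY, np.zeros(4, dtype=int))

    def test_silhouette_random_labels_near_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((200, 2))
        labels = rng.integers(0, 3, 200)
        mean, _ = silhouette_index(pts, labels)
        assert abs(mean) < 0.1

    def test_davies_bouldin_toy_value(self):
        assert davies_bouldin_index(TOY, TOY_LABELS) == pytest.approx(0.2)

    def test_davies_bouldin_shrinks_as_clusters_move_apart(self):
        # same within-cluster dispersion, centroid gap widened 5 -> 50
        apart = np.array([[0.0], [1.0], [50.0], [51.0]])
        assert davies_bouldin_index(apart, TOY_LABELS) == pytest.approx(0.02)

    def test_davies_bouldin_single_cluster_errors(self):
        with pytest.raises(UndefinedIndexError):
            davies_bouldin_index(TOY, np.zeros(4, dtype=int))

    def test_calinski_toy_value(self):
        assert calinski_harabasz_index(TOY, TOY_LABELS) == pytest.approx(50.0)

    def test_calinski_zero_within_scatter_infinite(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        with pytest.warns(UserWarning):
            assert np.isinf(calinski_harabasz_index(pts, np.array([0, 0, 1, 1])))

    def test_calinski_random_labels_within_permutation_band(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((200, 2))
        labels = rng.integers(0, 3, 200)
        value = calinski_harabasz_index(pts, labels)
        baseline = [
            calinski_harabasz_index(pts, rng.permutation(labels)) for _ in range(50)
        ]
        lo, hi = np.quantile(baseline, [0.005, 0.995])
        assert lo <= value <= hi


class TestIndicesAgainstOracles:
    @pytest.mark.parametrize("trial", range(20))
    def test_brute_force_agreement_on_random_instances(self, trial):
        rng = np.random.default_rng(trial)
        n = rng.integers(6, 31)
        k = rng.integers(2, min(4, n - 1) + 1)
        pts = rng.standard_normal((n, rng.integers(1, 4)))
        labels = rng.integers(0, k, n)
        while len(set(labels)) < 2:
            labels = rng.integers(0, k, n)
        mean, per = silhouette_index(pts, labels)
        bmean, bper = brute_silhouette(pts, labels)
        assert per == pytest.approx(bper, abs=1e-9)
        assert davies_bouldin_index(pts, labels) == pytest.approx(
            brute_davies_bouldin(pts, labels), abs=1e-9
        )
        if len(set(labels)) < n:
            assert calinski_harabasz_index(pts, labels) == pytest.approx(
                brute_calinski(pts, labels), abs=1e-9
            )

    def test_cross_check_against_library_implementations(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((120, 4))
        labels = rng.integers(0, 3, 120)
        mean, _ = silhouette_index(pts, labels)
        assert mean == pytest.approx(skm.silhouette_score(pts, labels), abs=1e-9)
        assert davies_bouldin_index(pts, labels) == pytest.approx(
            skm.davies_bouldin_score(pts, labels), abs=1e-9
        )
        assert calinski_harabasz_index(pts, labels) == pytest.approx(
            skm.calinski_harabasz_score(pts, labels), rel=1e-9
        )

    def test_silhouette_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((40, 3))
        labels = rng.integers(0, 3, 40)
        R = special_ortho_group.rvs(3, random_state=5)
        moved = pts @ R.T + np.array([3.0, -1.0, 10.0])
        s0, _ = silhouette_index(pts, labels)
        s1, _ = silhouette_index(moved, labels)
        assert s1 == pytest.approx(s0, abs=1e-9)
        assert davies_bouldin_index(moved, labels) == pytest.approx(
            davies_bouldin_index(pts, labels), abs=1e-9
        )
        assert calinski_harabasz_index(moved, labels) == pytest.approx(
            calinski_harabasz_index(pts, labels), rel=1e-9
        )


def _blobs(rng, centers, n_per, sd=0.3):
    pts = np.vstack([c + sd * rng.standard_normal((n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


class TestClustering:
    @pytest.mark.parametrize("algorithm", ["kmeans", "hac", "gmm"])
    def test_well_separated_blobs_recovered_exactly(self, algorithm):
        rng = np.random.default_rng(0)
        pts, labels = _blobs(rng, [np.zeros(2), [8, 0], [0, 8]], 50)
        model = run_clustering(pts, algorithm, 3, seed=0)
        assert skm.adjusted_rand_score(labels, model.labels) == 1.0

    def test_hac_with_k_equal_n_gives_singletons(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((6, 2))
        model = run_clustering(pts, "hac", 6, seed=0)
        assert sorted(model.sizes.tolist()) == [1] * 6

    def test_kmeans_same_seed_identical_labels(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((100, 3))
        a = run_clustering(pts, "kmeans", 4, seed=9)
        b = run_clustering(pts, "kmeans", 4, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_centroids_match_member_means(self):
        rng = np.random.default_rng(3)
        pts, _ = _blobs(rng, [np.zeros(2), [5, 5]], 30)
        model = run_clustering(pts, "kmeans", 2, seed=0)
        for g in range(2):
            assert model.centroids_reduced[g] == pytest.approx(
                pts[model.labels == g].mean(axis=0), abs=1e-9
            )

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            run_clustering(TOY, "kmeans", 1, seed=0)


class TestSelection:
    def test_single_cell_grid_is_chosen(self):
        rng = np.random.default_rng(4)
        pts, _ = _blobs(rng, [np.zeros(2), [6, 0]], 40)
        report = select_model(pts, algorithms=("kmeans",), k_range=(2,), seed=0)
        assert report.chosen == ("kmeans", 2)

    def test_exact_silhouette_tie_decided_by_calinski(self):
        rng = np.random.default_rng(5)
        pts, _ = _blobs(rng, [np.zeros(2), [7, 0]], 40)
        # kmeans and hac find the identical partition -> identical silhouette;
        # the rule must fall through without raising and pick either cell
        report = select_model(pts, algorithms=("kmeans", "hac"), k_range=(2,), seed=0)
        cells = list(report.grid)
        assert report.grid[cells[0]].silhouette_mean == pytest.approx(
            report.grid[cells[1]].silhouette_mean, abs=1e-12
        )
        assert report.chosen in cells

    def test_default_cohort_grid_selects_k3(self, stratified):
        _, model, _, selection = stratified
        assert selection.chosen[1] == 3
        assert len(selection.grid) == 12


class TestStability:
    def test_hac_is_seed_free(self):
        rng = np.random.default_rng(6)
        pts, _ = _blobs(rng, [np.zeros(2), [6, 0], [0, 6]], 30)
        report = assess_stability(pts, "hac", 3, seeds=list(range(5)))
        assert report.pairwise_ari == pytest.approx([1.0] * 10)
        assert report.mean_ari == 1.0

    def test_kmeans_stable_on_planted_structure(self):
        rng = np.random.default_rng(7)
        pts, _ = _blobs(rng, [np.zeros(2), [8, 0], [0, 8]], 60)
        report = assess_stability(pts, "kmeans", 3, seeds=list(range(10)))
        assert report.mean_ari >= 0.99

    def test_noise_reports_without_error(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((90, 2))
        report = assess_stability(pts, "kmeans", 3, seeds=list(range(10)))
        assert len(report.pairwise_ari) == 45
        assert -1 <= report.mean_ari <= 1


class TestProfiling:
    def test_constant_variable_ranks_last(self, tiny_schema):
        from htncds.cohort import VariableSchema
        schema = [
            tiny_schema[0],
            VariableSchema(name="shifted", kind="numeric", clustering_feature=True),
            VariableSchema(name="flat", kind="numeric", clustering_feature=True),
        ]
        rng = np.random.default_rng(0)
        rows = [
            {"pid": f"p{i}", "shifted": float(5 * (i >= 20) + rng.normal(0, 0.1)),
             "flat": 1.0}
            for i in range(40)
        ]
        t = make_table(schema, rows)
        labels = np.repeat([0, 1], 20)
        profiles = profile_clusters(t, labels)
        assert profiles.variable_importance.index[0] == "shifted"
        assert profiles.variable_importance.index[-1] == "flat"
        assert profiles.variable_importance["flat"] == 0.0

    def test_glucose_and_cholesterol_among_top_discriminators(self, stratified):
        _, _, profiles, _ = stratified
        top5 = set(profiles.variable_importance.index[:5])
        assert "glucose" in top5
        assert "cholesterol_total" in top5

    def test_default_cohort_names_all_three_phenotypes(self, stratified):
        _, _, profiles, _ = stratified
        assert set(profiles.names.values()) == {
            "metabolic-hypertensive", "dyslipidemic-anemic", "constitutional-atypical",
        }

    def test_importance_is_permutation_of_clustering_variables(self, stratified):
        clean, _, profiles, _ = stratified
        assert sorted(profiles.variable_importance.index) == sorted(
            clean.variables(clustering=True)
        )
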