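"""Record filtering, unit repair, imputation, standardization, encoding."""

import numpy as np
import pytest

from htncds.cohort import VariableSchema
from htncds.preprocess import (
    PreprocessConfig,
    UnimputableError,
    correct_height_units,
    filter_incomplete_records,
    flag_implausible,
    impute_categorical_mode,
    impute_numeric_knn,
    impute_numeric_median,
    multihot_fill_zero,
    one_hot_encode,
    pearson_correlations,
    run_preprocessing,
    zscore_standardize,
)

from conftest import make_table


def _mask_cells(cohort, row, variables):
    for var in variables:
        cohort.mask.loc[row, var] = True
        col = cohort.data.columns.get_loc(var)
        kind = next(v.kind for v in cohort.schema if v.name == var)
        cohort.data.iloc[row, col] = np.nan if kind == "numeric" else None


class TestRecordFilter:
    def test_strict_majority_boundary(self, study_cohort):
        cohort, _ = study_cohort
        cohort = cohort.copy()
        non_id = [v.name for v in cohort.schema if not v.identifier]
        # row 0: 27/52 missing (0.519) -> dropped; row 1: 26/52 (0.5) -> kept
        cohort.mask.loc[0, :] = False
        cohort.mask.loc[1, :] = False
        _mask_cells(cohort, 0, non_id[:27])
        _mask_cells(cohort, 1, non_id[:26])
        kept, report = filter_incomplete_records(cohort)
        assert "P0000" in report.dropped_identifiers
        assert "P0001" in kept.data[kept.id_variable].values

    def test_eight_overmissing_rows_leave_615(self, study_config):
        from htncds.synthetic import generate_cohort

        cfg = study_config
        cohort, _ = generate_cohort(cfg)
        cohort = cohort.copy()
        non_id = [v.name for v in cohort.schema if not v.identifier]
        for row in range(8):
            cohort.mask.loc[row, :] = False
            _mask_cells(cohort, row, non_id[:30])
        for row in range(8, cohort.n_rows):  # everyone else safely under 50 %
            keep_masked = cohort.mask.loc[row]
            if keep_masked.mean() > 0.5:
                cohort.mask.loc[row, :] = False
        kept, report = filter_incomplete_records(cohort)
        assert report.rows_dropped == 8
        assert kept.n_rows == 615


class TestHeightRepair:
    def test_meters_scaled_centimeters_untouched(self, tiny_schema):
        schema = tiny_schema + [
            VariableSchema(name="height_cm", kind="numeric", units="cm",
                           plausible_range=(120, 220))
        ]
        t = make_table(
            schema,
            [
                {"pid": "a", "glucose": 1, "gender": "F",
                 "avoided_foods": frozenset(), "height_cm": 1.65},
                {"pid": "b", "glucose": 1, "gender": "F",
                 "avoided_foods": frozenset(), "height_cm": 170.0},
            ],
        )
        fixed, report = correct_height_units(t)
        assert fixed.data["height_cm"].tolist() == [165.0, 170.0]
        assert report.unit_corrections == 1
        assert report.unit_correction_rows == ["a"]

    def test_all_314_planted_meter_entries_corrected(self, study_cohort):
        cohort, _ = study_cohort
        fixed, report = correct_height_units(cohort)
        assert report.unit_corrections == 314
        h = fixed.data["height_cm"]
        assert not ((h < 3.0) & h.notna()).any()


class TestPlausibility:
    def test_planted_out_of_range_cells_flagged_with_addresses(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": p, "glucose": g, "gender": "F", "avoided_foods": frozenset()}
             for p, g in [("a", 5000.0), ("b", 90.0), ("c", 10.0), ("d", 700.0)]],
        )
        report = flag_implausible(t)
        assert len(report.out_of_range_flags) == 3
        flagged = {(f["identifier"], f["variable"]) for f in report.out_of_range_flags}
        assert flagged == {("a", "glucose"), ("c", "glucose"), ("d", "glucose")}

    def test_all_in_range_gives_empty_report(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": "a", "glucose": 90.0, "gender": "F", "avoided_foods": frozenset()}],
        )
        assert flag_implausible(t).out_of_range_flags == []


class TestKNNImputation:
    def test_nearest_neighbor_hand_example(self, tiny_schema):
        schema = tiny_schema + [
            VariableSchema(name="y", kind="numeric")
        ]
        t = make_table(
            schema,
            [
                {"pid": "a", "glucose": 1.0, "gender": "F",
                 "avoided_foods": frozenset(), "y": 2.0},
                {"pid": "b", "glucose": 1.0, "gender": "F",
                 "avoided_foods": frozenset(), "y": np.nan},
                {"pid": "c", "glucose": 10.0, "gender": "F",
                 "avoided_foods": frozenset(), "y": 20.0},
            ],
            masked=[(1, "y")],
        )
        out, report = impute_numeric_knn(t, PreprocessConfig(knn_k=1))
        assert out.data.loc[1, "y"] == pytest.approx(2.0)
        assert report.numeric_cells_imputed == 1

    def test_no_missing_cells_is_identity(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": "a", "glucose": 5.0, "gender": "F", "avoided_foods": frozenset()}],
        )
        out, report = impute_numeric_knn(t, PreprocessConfig(knn_k=1))
        assert report.numeric_cells_imputed == 0
        assert out.data["glucose"].equals(t.data["glucose"])

    def test_sqrt_sentinel_gives_25_neighbors_at_615(self):
        assert PreprocessConfig(knn_k="sqrt").resolve_k(615) == 25

    def test_observed_cells_never_altered(self, study_cohort):
        cohort, _ = study_cohort
        fixed, _ = correct_height_units(cohort)
        out, _ = impute_numeric_knn(fixed)
        num = [v.name for v in cohort.schema if v.kind == "numeric"]
        before = fixed.data[num].to_numpy()
        after = out.data[num].to_numpy()
        observed = ~fixed.mask[num].to_numpy()
        assert np.array_equal(before[observed], after[observed])
        assert not out.mask[num].to_numpy().any()

    def test_fully_missing_variable_raises(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": "a", "glucose": np.nan, "gender": "F",
              "avoided_foods": frozenset()}],
            masked=[(0, "glucose")],
        )
        with pytest.raises(UnimputableError, match="glucose"):
            impute_numeric_knn(t, PreprocessConfig(knn_k=1))


class TestCategoricalImputation:
    def test_modal_category_fills_missing(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": p, "glucose": 1.0, "gender": g, "avoided_foods": frozenset()}
             for p, g in [("a", "F"), ("b", "F"), ("c", "M"), ("d", None)]],
            masked=[(3, "gender")],
        )
        out, report = impute_categorical_mode(t)
        assert out.data.loc[3, "gender"] == "F"
        assert report.categorical_cells_imputed == {"gender": 1}
        assert report.categorical_imputed_value == {"gender": "F"}

    def test_tie_breaks_by_schema_category_order_and_logs(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": p, "glucose": 1.0, "gender": g, "avoided_foods": frozenset()}
             for p, g in [("a", "F"), ("b", "M"), ("c", None)]],
            masked=[(2, "gender")],
        )
        out, report = impute_categorical_mode(t)
        assert out.data.loc[2, "gender"] == "F"  # schema order: F before M
        assert any("tie" in note for note in report.notes)

    def test_female_majority_cohort_imputes_female(self, study_cohort):
        cohort, _ = study_cohort
        out, report = impute_categorical_mode(cohort)
        assert report.categorical_imputed_value["gender"] == "female"


class TestMultihotFill:
    def test_blank_entries_become_empty_selection(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [
                {"pid": "a", "glucose": 1.0, "gender": "F",
                 "avoided_foods": frozenset({"salt"})},
                {"pid": "b", "glucose": 1.0, "gender": "F", "avoided_foods": None},
            ],
            masked=[(1, "avoided_foods")],
        )
        before = int(t.mask["avoided_foods"].sum())
        out, report = multihot_fill_zero(t)
        assert report.multihot_cells_zeroed == before == 1
        assert out.data.loc[1, "avoided_foods"] == frozenset()
        assert out.data.loc[0, "avoided_foods"] == frozenset({"salt"})
        assert not out.mask["avoided_foods"].any()


class TestStandardization:
    def test_population_sd_hand_example(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": p, "glucose": g, "gender": "F", "avoided_foods": frozenset()}
             for p, g in [("a", 1.0), ("b", 2.0), ("c", 3.0)]],
        )
        m = zscore_standardize(t, ["glucose"])
        assert m.values[:, 0] == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_idempotent_on_standardized_input(self, tiny_schema):
        vals = np.array([-1.2247448, 0.0, 1.2247448])
        t = make_table(
            tiny_schema,
            [{"pid": p, "glucose": v, "gender": "F", "avoided_foods": frozenset()}
             for p, v in zip("abc", vals)],
        )
        m = zscore_standardize(t, ["glucose"])
        assert np.allclose(m.values[:, 0], vals, atol=1e-9)

    def test_constant_column_becomes_zeros_with_warning(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": p, "glucose": 5.0, "gender": "F", "avoided_foods": frozenset()}
             for p in "abc"],
        )
        with pytest.warns(UserWarning, match="constant"):
            m = zscore_standardize(t, ["glucose"])
        assert (m.values[:, 0] == 0).all()

    def test_non_numeric_request_raises(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": "a", "glucose": 1.0, "gender": "F", "avoided_foods": frozenset()}],
        )
        with pytest.raises(TypeError):
            zscore_standardize(t, ["gender"])


class TestOneHot:
    def test_categorical_rows_sum_to_one_across_indicators(self, tiny_schema):
        t = make_table(
            tiny_schema,
            [{"pid": p, "glucose": 1.0, "gender": g,
              "avoided_foods": frozenset({"salt"})}
             for p, g in [("a", "F"), ("b", "M"), ("c", "F"), ("d", "F")]],
        )
        enc, registry = one_hot_encode(t)
        gender_cols = [c for c in registry if c.startswith("gender=")]
        assert len(gender_cols) == 2
        assert (enc[gender_cols].sum(axis=1) == 1).all()
        food_cols = [c for c in registry if c.startswith("avoided_foods=")]
        assert len(food_cols) == 3
        assert set(np.unique(enc[food_cols].to_numpy())) <= {0.0, 1.0}

    def test_column_count_matches_schema_tally(self, clean_cohort):
        clean, _ = clean_cohort
        enc, registry = one_hot_encode(clean)
        expected = sum(
            1 if v.kind == "numeric" else len(v.categories)
            for v in clean.schema
            if not v.identifier
        )
        assert len(registry) == expected
        assert enc.shape[1] == expected


class TestCorrelations:
    def test_self_and_anticorrelation(self, tiny_schema):
        schema = tiny_schema + [VariableSchema(name="negg", kind="numeric")]
        rows = [
            {"pid": p, "glucose": g, "gender": "F",
             "avoided_foods": frozenset(), "negg": -g}
            for p, g in [("a", 1.0), ("b", 2.0), ("c", 5.0)]
        ]
        m = zscore_standardize(make_table(schema, rows), ["glucose", "negg"])
        corr = pearson_correlations(m)
        assert corr.loc["glucose", "glucose"] == 1.0
        assert corr.loc["glucose", "negg"] == pytest.approx(-1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)

    def test_recovers_simulated_correlation(self, tiny_schema):
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.standard_normal(n)
        y = 0.4 * x + np.sqrt(1 - 0.16) * rng.standard_normal(n)
        schema = tiny_schema + [VariableSchema(name="y", kind="numeric")]
        rows = [
            {"pid": f"p{i}", "glucose": float(x[i]), "gender": "F",
             "avoided_foods": frozenset(), "y": float(y[i])}
            for i in range(n)
        ]
        m = zscore_standardize(make_table(schema, rows), ["glucose", "y"])
        corr = pearson_correlations(m)
        assert corr.loc["glucose", "y"] == pytest.approx(0.4, abs=0.05)


class TestPipelineOrderAndSensitivity:
    def test_post_pipeline_table_has_zero_masked_cells(self, clean_cohort):
        clean, _ = clean_cohort
        assert not clean.mask.to_numpy().any()

    def test_report_counts_consistent(self, clean_cohort, study_cohort):
        clean, report = clean_cohort
        cohort, _ = study_cohort
        assert report.unit_corrections == 314
        assert clean.n_rows == cohort.n_rows - report.rows_dropped
        num = [v.name for v in cohort.schema if v.kind == "numeric"]
        assert report.numeric_cells_imputed <= int(cohort.mask[num].to_numpy().sum())

    def test_median_imputation_changes_few_downstream_labels(self, study_cohort):
        """Swapping KNN for median imputation relabels < 10 % of records."""
        from htncds.stratify import fit_pca, run_clustering
        cohort, _ = study_cohort
        labelings = {}
        for imputer in ("knn", "median"):
            clean, _ = run_preprocessing(cohort.copy(), numeric_imputer=imputer)
            m = zscore_standardize(clean, clean.variables(clustering=True))
            S = fit_pca(m, 0.90).transform(m.values)
            labelings[imputer] = run_clustering(S, "hac", 3, seed=0).labels
        a, b = labelings["knn"], labelings["median"]
        # align label ids by majority overlap, then count disagreements
        remap = {}
        for g in np.unique(b):
            vals, counts = np.unique(a[b == g], return_counts=True)
            remap[g] = vals[np.argmax(counts)]
        changed = np.mean([remap[x] != y for x, y in zip(b, a)])
        assert changed < 0.10
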