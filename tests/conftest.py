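import numpy as np
import pytest

from htncds.cohort import CohortTable, VariableSchema
from htncds.preprocess import run_preprocessing, zscore_standardize
from htncds.rules import default_kb
from htncds.stratify import fit_pca, profile_clusters, select_model
from htncds.synthetic import default_study_config, generate_cohort


@pytest.fixture(scope="session")
def study_config():
    return default_study_config(seed=0)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    """Default synthetic cohort (623 patients) plus planted ground truth."""
    return generate_cohort(study_config)


@pytest.fixture(scope="session")
def clean_cohort(study_cohort):
    cohort, _ = study_cohort
    clean, report = run_preprocessing(cohort)
    return clean, report


@pytest.fixture(scope="session")
def stratified(clean_cohort):
    """Selected cluster model + profiles on the default cohort."""
    clean, _ = clean_cohort
    clus_vars = clean.variables(clustering=True)
    matrix = zscore_standardize(clean, clus_vars)
    pca = fit_pca(matrix, tau=0.90)
    selection = select_model(
        pca.transform(matrix.values), seed=0,
        original_features=clean.data[clus_vars].astype(float),
    )
    model = selection.chosen_model
    profiles = profile_clusters(clean, model.labels)
    return clean, model, profiles, selection


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture
def tiny_schema():
    return [
        VariableSchema(name="pid", kind="categorical", categories=("id",), identifier=True),
        VariableSchema(name="glucose", kind="numeric", units="mg/dL",
                       plausible_range=(40, 600), clustering_feature=True),
        VariableSchema(name="gender", kind="categorical", categories=("F", "M")),
        VariableSchema(name="avoided_foods", kind="multihot",
                       categories=("salt", "sugar", "fat")),
    ]


def make_table(schema, rows, masked=()):
    """Build a CohortTable from row dicts; ``masked`` lists (row, var) cells."""
    import pandas as pd

    names = [v.name for v in schema]
    data = pd.DataFrame(rows, columns=names)
    mask = pd.DataFrame(False, index=data.index, columns=names)
    for r, var in masked:
        mask.loc[r, var] = True
        col = data.columns.get_loc(var)
        kind = next(v.kind for v in schema if v.name == var)
        data.iloc[r, col] = np.nan if kind == "numeric" else None
    for v in schema:
        if v.kind == "numeric":
            data[v.name] = data[v.name].astype(float)
    return CohortTable(schema=list(schema), data=data, mask=mask)
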