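"""Shared fixtures: small synthetic cohorts generated once per session."""

from __future__ import annotations

import pytest

from gexmap import (
    DiseasePanel,
    FixtureConfig,
    GeneCategoryFilter,
    QuerySpec,
    chronic_disease_study_config,
    generate_cohort,
    import_annotations,
    load_cohort,
)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """4 samples x 60 genes with two planted panels (asthma fully expressed,
    arthritis half expressed).  Returns (paths, annotation_csv, truth)."""
    config = FixtureConfig(
        n_samples=4,
        n_genes=60,
        diseases=[
            DiseasePanel("asthma", 6, 1.0),
            DiseasePanel("arthritis", 8, 0.5),
        ],
        seed=7,
    )
    directory = tmp_path_factory.mktemp("small_cohort")
    paths, annotation_csv, truth = generate_cohort(config, directory)
    return paths, annotation_csv, truth


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    paths, _ann, _truth = small_cohort
    return load_cohort(paths)


@pytest.fixture(scope="session")
def small_annotations(small_cohort):
    _paths, ann, _truth = small_cohort
    return import_annotations(ann)


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    """The full default study design (31 samples, 9 panels), one seed."""
    directory = tmp_path_factory.mktemp("study_cohort")
    return generate_cohort(chronic_disease_study_config(seed=11), directory)


@pytest.fixture()
def cutoff_query(small_dataset, small_cohort):
    _paths, _ann, truth = small_cohort
    return QuerySpec(
        samples=list(small_dataset.samples),
        min_value=truth.cutoff,
        category=GeneCategoryFilter.BOTH,
    )
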