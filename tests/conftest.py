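"""Shared fixtures: catalogs, designs, cohorts, and one small fitted model.

Everything is generated programmatically and seeded; the heavier objects are
session-scoped so the suite pays for them once.
"""

import numpy as np
import pytest

import incentdce as dce
from incentdce.pipeline import expand_seed, make_fixture


@pytest.fixture(scope="session")
def catalog():
    return dce.default_catalog()


@pytest.fixture(scope="session")
def binary_catalog():
    """One effects-coded binary attribute, no money column."""
    return dce.AttributeCatalog(
        attributes=(
            dce.AttributeSpec(
                name="x", levels=("lo", "hi"), coding="effects", omitted_level="lo",
                preference_direction=("lo", "hi"),
            ),
        )
    )


@pytest.fixture(scope="session")
def two_binary_catalog():
    return dce.AttributeCatalog(
        attributes=(
            dce.AttributeSpec(name="x", levels=("x0", "x1"), omitted_level="x0"),
            dce.AttributeSpec(name="y", levels=("y0", "y1"), omitted_level="y0"),
        )
    )


@pytest.fixture(scope="session")
def study_design(catalog):
    from incentdce.pipeline import _fixture_design

    return _fixture_design(expand_seed(202008)[0])


@pytest.fixture(scope="session")
def study_cohort():
    data, manifest = make_fixture("study-cohort")
    return data, manifest


@pytest.fixture(scope="session")
def cleaned_study_cohort(study_cohort):
    data, _ = study_cohort
    return dce.clean_study(data)


@pytest.fixture(scope="session")
def study_encoded(cleaned_study_cohort, study_design, catalog):
    cleaned, _ = cleaned_study_cohort
    return dce.to_long_format(cleaned, study_design, catalog)


@pytest.fixture(scope="session")
def study_fit(study_encoded):
    """Mixed logit fitted to the 430-respondent cohort with 100 Halton draws."""
    spec = dce.ModelSpec(
        random_terms=list(study_encoded.attribute_columns),
        fixed_terms=list(study_encoded.fixed_columns),
        n_draws=100,
        seed=1,
    )
    return dce.MixedLogit(study_encoded, spec).fit()


@pytest.fixture(scope="session")
def table_truth():
    """The generating preference parameters used by the default cohorts."""
    prefs = dce.table_preferences()
    truth = dict(prefs.means)
    truth["amount_rescaled"] = prefs.amount_coef
    truth["asc_no_program"] = prefs.asc_optout
    for g, v in prefs.amount_by_income.items():
        truth[f"amount_rescaled:{g}"] = v
    for g, v in prefs.asc_by_income.items():
        truth[f"asc_no_program:{g}"] = v
    return truth, prefs
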