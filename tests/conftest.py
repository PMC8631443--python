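"""Shared fixtures: one default synthetic study, fitted once per session."""

import numpy as np
import pytest

from nkdeconv import (
    build_signature_matrix,
    fit_hierarchy_posteriors,
    gen_foreign_profiles,
    gen_reference_compendium,
    gen_survival_pool,
    gen_taxonomy,
    select_markers,
)


@pytest.fixture(scope="session")
def taxonomy():
    return gen_taxonomy()


@pytest.fixture(scope="session")
def compendium(taxonomy):
    """Default fixture: 1,000 genes, 10 replicates per leaf."""
    return gen_reference_compendium(taxonomy, seed=11)


@pytest.fixture(scope="session")
def posteriors(compendium, taxonomy):
    return fit_hierarchy_posteriors(compendium, taxonomy)


@pytest.fixture(scope="session")
def markers(posteriors, taxonomy):
    return select_markers(posteriors, taxonomy)


@pytest.fixture(scope="session")
def signature(posteriors, markers, taxonomy):
    return build_signature_matrix(posteriors, markers, taxonomy)


@pytest.fixture(scope="session")
def survival_pool():
    return gen_survival_pool(2000, seed=12)


@pytest.fixture(scope="session")
def foreign(compendium):
    return gen_foreign_profiles(
        compendium.gene_index, reps=4, seed=13, leaf_means=compendium.truth.mean
    )
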