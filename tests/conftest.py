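import pytest

from edss_patterns.binarize import binarize_table
from edss_patterns.catalog import default_catalog
from edss_patterns.cluster_engine import ClusterParams, EmbedParams, \
    fit_embed_cluster
from edss_patterns.ingest import adjust_pt_labels
from edss_patterns.synthetic_data import default_expandlike_config, \
    generate_cohort, planted_config


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def cohort(catalog):
    """Scaled-down study-like cohort: 150 patients, ~1200 assessments."""
    return generate_cohort(default_expandlike_config(n_patients=150, seed=11),
                           catalog)


@pytest.fixture(scope="session")
def adjusted(cohort, catalog):
    return adjust_pt_labels(cohort, catalog)


@pytest.fixture(scope="session")
def planted(catalog):
    """Single-stratum cohort with the four archetypes at 30/25/25/20%."""
    table = generate_cohort(planted_config(600, seed=0), catalog)
    return table, binarize_table(table)


@pytest.fixture(scope="session")
def planted_model(planted):
    _, features = planted
    return fit_embed_cluster(features, EmbedParams(n_neighbors=30, seed=0),
                             ClusterParams(min_cluster_size=30))
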