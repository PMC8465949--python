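"""Shared fixtures: schema, calibrated cohort and preprocessed design.

Session-scoped so the (moderately expensive) generation and preprocessing
run once for the whole suite.
"""

import numpy as np
import pytest

from crsml import (
    default_classifier_specs,
    default_config,
    default_schema,
    generate_cohort,
    mc_splits,
    preprocess_cohort,
)

COHORT_SEED = 1


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def cohort90(config, schema):
    """Default calibrated paired cohort, n = 90."""
    return generate_cohort(config, seed=COHORT_SEED, schema=schema)


@pytest.fixture(scope="session")
def design_and_labels(cohort90, schema):
    """Preprocessed numeric design matrix and occasion labels."""
    design, _ = preprocess_cohort(cohort90, schema, seed=COHORT_SEED)
    labels = design["occasion"].to_numpy()
    x = design.drop(columns=["patient_id", "occasion"])
    return x, labels


@pytest.fixture(scope="session")
def small_specs():
    """Classifier panel with a compact forest for fast suites."""
    return default_classifier_specs(forest_trees=32)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
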