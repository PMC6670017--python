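import numpy as np
import pytest

from bonemet import (
    SynthConfig,
    center_probes,
    fit_oplsda,
    generate_cohort,
    select_markers,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the generator's default study conditions."""
    return generate_cohort(seed=11)


@pytest.fixture(scope="session")
def centered_matrix(default_cohort):
    """Per-cohort probe-centered expression of the default cohort."""
    return center_probes(default_cohort.expression)


@pytest.fixture(scope="session")
def marker_panel(centered_matrix, default_cohort):
    return select_markers(centered_matrix, default_cohort.truth_labels)


@pytest.fixture(scope="session")
def fitted_model(centered_matrix, default_cohort, marker_panel):
    X = centered_matrix.values.loc[marker_panel.union].T
    return fit_oplsda(X, default_cohort.truth_labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
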