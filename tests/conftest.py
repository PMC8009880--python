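import numpy as np
import pytest

import neostrat as ns


@pytest.fixture(scope="session")
def small_cohort():
    """400-infant missingness-free cohort with planted truth."""
    spec = ns.CohortSpec(n_infants=400, seed=1)
    episodes, daily, truth = ns.generate_cohort(spec)
    return spec, episodes, daily, truth


@pytest.fixture(scope="session")
def small_curated(small_cohort):
    _, episodes, daily, _ = small_cohort
    return ns.curate(episodes, daily)


@pytest.fixture(scope="session")
def study_cohort():
    """The default study conditions: 3000 infants, three planted archetypes."""
    spec = ns.CohortSpec(n_infants=3000, seed=2)
    episodes, daily, truth = ns.generate_cohort(spec)
    cohort = ns.curate(episodes, daily)
    labels_true = truth.labels.loc[cohort.nutrition.index].to_numpy()
    return cohort, labels_true, truth


@pytest.fixture(scope="session")
def study_model(study_cohort):
    cohort, _, _ = study_cohort
    return ns.DirichletProcessGMM(truncation=20, random_state=0).fit(cohort.matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
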