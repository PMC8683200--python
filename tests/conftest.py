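import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

from snvnet.filters import filter_pipeline
from snvnet.simulate import SyntheticCohortSpec, generate_cohort, study_mirror_fixture


@pytest.fixture(scope="session")
def mirror():
    """The deterministic study-mirror cohort (seed fixed for the session)."""
    return study_mirror_fixture(seed=1)


@pytest.fixture(scope="session")
def mirror_design(mirror):
    """Filtered design + report from the mirror cohort."""
    G, pheno = mirror
    return filter_pipeline(G, pheno)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick synthetic cohort for plumbing tests (60 samples, 40 SNVs)."""
    spec = SyntheticCohortSpec(
        n_samples=60,
        n_snvs=40,
        n_low_variation=5,
        n_high_missing=8,
        n_duplicate=3,
        n_incomplete_pheno=6,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
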