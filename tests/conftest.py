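import numpy as np
import pytest

from neuromark import CohortSpec, RunConfig, featurize_cohort, generate_cohort
from neuromark.cohort import high_effect_spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_effect_cohort():
    """A compact planted-effect cohort shared by several feature-level tests."""
    spec = high_effect_spec(
        n_controls=15, n_patients=15, n_regions=14, voxels_per_region=8, seed=7
    )
    return generate_cohort(spec), spec


@pytest.fixture(scope="session")
def small_featurized(small_effect_cohort):
    cohort, spec = small_effect_cohort
    return featurize_cohort(cohort, RunConfig(cohort=spec))


@pytest.fixture(scope="session")
def tiny_null_cohort():
    spec = CohortSpec(
        n_controls=8, n_patients=8, n_regions=6, voxels_per_region=8, seed=3
    )
    return generate_cohort(spec), spec
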