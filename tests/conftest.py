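import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def geometry():
    from cohermetrics.stimuli import DisplayGeometry
    return DisplayGeometry()


@pytest.fixture
def dots():
    from cohermetrics.stimuli import ElementSpec
    return ElementSpec.dots()


@pytest.fixture
def bars():
    from cohermetrics.stimuli import ElementSpec
    return ElementSpec.bars()


@pytest.fixture
def default_spec():
    from cohermetrics.cohort import default_cohort_spec
    return default_cohort_spec()


@pytest.fixture
def cohort_106(default_spec):
    """One default synthetic cohort with composite and group columns."""
    from cohermetrics.cohort import assign_groups, generate_cohort
    from cohermetrics.composite import pca_composite
    cohort = generate_cohort(default_spec, seed=2024)
    comp = pca_composite(cohort[["nart_raw", "towre_swe_std", "towre_pd_std"]])
    return assign_groups(cohort.assign(reading_composite=comp.scores))


def spawn_rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
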