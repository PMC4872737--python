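import pytest

from mitodyn import (
    CohortSpec,
    FilterConfig,
    MtReference,
    load_cohort_counts,
    simulate_cohort,
    synthetic_reference,
)


@pytest.fixture(scope="session")
def mt_ref():
    """Full-size synthetic circular mt-like reference (16,569 bp)."""
    return synthetic_reference(seed=1)


@pytest.fixture
def tiny_ref():
    return MtReference("m", "ACGT")


@pytest.fixture(scope="session")
def cohort_counts():
    """Bundled per-patient counts of the published relapse cohort."""
    return load_cohort_counts()


@pytest.fixture(scope="session")
def small_cohort(mt_ref):
    """Six simulated patients at default rates, fixed seed."""
    return simulate_cohort(CohortSpec(n_patients=6, seed=42), mt_ref)


@pytest.fixture
def fcfg():
    return FilterConfig()
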