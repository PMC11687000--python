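import pytest

from targetsv.synthetic import (
    CallerProfile,
    VariantSpec,
    generate_cohort,
)

SMALL = dict(n_samples=3, n_regions=3, variant_spec=VariantSpec.small())


@pytest.fixture(scope="session")
def small_bundle():
    """3-sample / 3-region cohort, default (noisy) caller profiles, no reads."""
    return generate_cohort(11, simulate_reads=False, **SMALL)


@pytest.fixture(scope="session")
def small_clean_bundle():
    """Same shape but in the no-noise limit (exact recall expected)."""
    return generate_cohort(11, simulate_reads=False,
                           caller_profiles=CallerProfile.noise_free(), **SMALL)


@pytest.fixture(scope="session")
def full_clean_bundle():
    """Default 10-sample / 8-region study-shaped cohort, no-noise limit."""
    return generate_cohort(7, simulate_reads=False,
                           caller_profiles=CallerProfile.noise_free())


@pytest.fixture(scope="session")
def full_noisy_bundle():
    """Default 10-sample / 8-region study-shaped cohort, default noise."""
    return generate_cohort(7, simulate_reads=False)
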