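import pytest

from hetscreen import CohortSpec, simulate_cohort_pair


@pytest.fixture(scope="session")
def small_cohort_pair():
    """A desk-scale two-cohort simulation with planted lethals."""
    spec = CohortSpec(
        n_individuals=1000,
        n_variants=400,
        lethal_fraction=0.1,
        cross_cohort_noise=0.02,
        seed=20240917,
    )
    return simulate_cohort_pair(spec)
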