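import pytest
from hypothesis import settings, HealthCheck

from timehom import SimConfig, simulate_cohort, quantify_cohort

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_bundle():
    """Four tumors x five regions, trimmed filler genes: fast but enough
    within-tumor degrees of freedom (16) for the 9-feature covariance."""
    cfg = SimConfig(n_tumors=4, n_filler_genes=40, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_samples(small_bundle):
    return quantify_cohort(small_bundle.ihc_fields, small_bundle.tls)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study design: 10 tumors, T1-T5, 20% heterogeneous."""
    return simulate_cohort(SimConfig(seed=7))
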