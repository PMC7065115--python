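import numpy as np
import pytest

import nipsim as ns


@pytest.fixture(scope="session")
def genome():
    return ns.GenomeModel()


@pytest.fixture(scope="session")
def cohort_enriched():
    """20k-patient cohort with trisomy prevalence boosted to 2% each so the
    percentile-shift fits have a few hundred records per trisomy."""
    cfg = ns.CohortConfig(
        n_patients=20_000,
        seed=42,
        trisomy_prevalence={"T13": 0.02, "T18": 0.02, "T21": 0.02},
    )
    return ns.generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_model(cohort_enriched):
    return ns.ConditionalFFModel.fit(cohort_enriched)


@pytest.fixture(scope="session")
def zref_mean(genome):
    """Mean-statistic reference with a large panel (tight moments, so the
    normal-approximation oracle is not blurred by panel noise)."""
    return ns.build_z_reference(genome, 1e7, n_reference=40_000, statistic="mean", seed=7)


@pytest.fixture(scope="session")
def zref_median(genome):
    return ns.build_z_reference(genome, 1e7, n_reference=10_000, statistic="median", seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
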