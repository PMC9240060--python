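import numpy as np
import pytest

from somarvas import syndata


@pytest.fixture(scope="session")
def tracks():
    return syndata.generate_genome_tracks(7, genome_length=3_000_000)


@pytest.fixture(scope="session")
def catalogs():
    return syndata.synthetic_catalogs(7)


@pytest.fixture(scope="session")
def small_cohort():
    """200-sample germline cohort with planted carriers, LOH and QC structure."""
    spec = syndata.SyntheticCohortSpec(n_samples=200, seed=11)
    germ = syndata.generate_germline_cohort(
        spec, rng=np.random.default_rng(11))
    return spec, germ


@pytest.fixture(scope="session")
def event_catalog(tracks, catalogs):
    spec = syndata.SyntheticCohortSpec(n_samples=6, seed=5)
    return syndata.generate_event_catalog(
        spec, tracks, catalogs, n_snv_per_sample=600,
        rng=np.random.default_rng(5))
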