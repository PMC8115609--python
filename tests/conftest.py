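import pytest

import dyadshare as ds


@pytest.fixture(scope="session")
def cohort():
    """A small three-study cohort under the default generative conditions."""
    return ds.generate_cohort(ds.default_config(seed=11, dyads_per_study=12))


@pytest.fixture(scope="session")
def pairing(cohort):
    return ds.pair_dyads(cohort.metadata)


@pytest.fixture(scope="session")
def sharing_records(cohort, pairing):
    return ds.compute_sharing(cohort.species_table, pairing)
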