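import pytest

from neoseek.config import CohortConfig
from neoseek.synthetic import generate_cohort, generate_reference


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(seed=1, n_patients=3, n_transcripts=20, n_rna_only=150,
                        n_somatic_dna=20, normal_cohort_size=2000)


@pytest.fixture(scope="session")
def reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def cohort(small_config):
    return generate_cohort(small_config)
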