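import numpy as np
import pytest

from mmtfs import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """25+25 subjects, 20 imaging features, 60 SNPs, clear planted signal."""
    spec = CohortSpec(
        n_per_class=25, d_imaging=20, d_snp=60,
        k_informative_imaging=3, k_informative_snp=3,
        effect_size=1.5, snp_effect=0.3, seed=3,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
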