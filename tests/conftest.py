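import numpy as np
import pytest

from omicsim.distributions import LogNormal, PointMass, Uniform
from omicsim.fixtures import (generate_methylation_profile, generate_reference_panel,
                              generate_rnaseq_profile)
from omicsim.genomics import RecombinationMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_panel():
    """200 haplotypes x 12 variants, MAFs in (0.1, 0.4), unlinked."""
    return generate_reference_panel(200, 12, Uniform(0.1, 0.4),
                                    ld_block_length=1, seed=7)


@pytest.fixture(scope="session")
def zero_rmap(small_panel):
    return RecombinationMap.zero(small_panel.n_variants)


@pytest.fixture(scope="session")
def meth_profile():
    return generate_methylation_profile(40, status_mix=(0.25, 0.5, 0.25),
                                        depth_mean=30, seed=11)


@pytest.fixture(scope="session")
def rna_profile():
    return generate_rnaseq_profile(30, 25, LogNormal(5.0, 0.8),
                                   PointMass(0.1), LogNormal(0.0, 0.1), seed=13)
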