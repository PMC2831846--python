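import numpy as np
import pytest

from oryzaloss import mapping as mp
from oryzaloss import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    """Shared 600 kb genome with the default composition (39% repeats)."""
    return sd.build_ancestral_genome(sd.GenomeSpec(length=600_000, n_genes=60), seed=101)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return mp.ReferenceIndex.build(small_genome, k=13)


@pytest.fixture(scope="session")
def study_genome():
    """Full-scale synthetic genome (2 Mbp, ~39% repeats), shared by the
    masking-target and self-mapping checks."""
    return sd.build_ancestral_genome(
        sd.GenomeSpec(length=2_000_000, target_repeat_fraction=0.39), seed=17
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
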