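import numpy as np
import pytest

from rloopkit.io import Condition, FragmentSet, Gene, GenomeModel
from rloopkit.simulate import SimConfig, simulate_cohort


@pytest.fixture
def tiny_genome() -> GenomeModel:
    genes = [
        Gene("g1", "chr1", "+", 10_000, 20_000, "protein_coding", 10.0),
        Gene("g2", "chr1", "-", 40_000, 55_000, "protein_coding", 3.0),
        Gene("g3", "chr2", "+", 5_000, 8_000, "pseudogene", 0.0),
    ]
    return GenomeModel({"chr1": 100_000, "chr2": 50_000}, genes)


def frags(records, sample_id="s", condition=Condition.DRIP) -> FragmentSet:
    return FragmentSet.from_records(sample_id, condition, records)


@pytest.fixture
def make_frags():
    return frags


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale cohort: 1.2 Mb genome, 10+10 loops, 2e5-equivalent depth."""
    return SimConfig(genome=[("chr1", 1_200_000)], n_genes=60,
                     n_stranded=10, n_unstranded=10, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
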