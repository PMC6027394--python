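import numpy as np
import pytest

from regulonkit.config import PipelineConfig
from regulonkit.core_io import Gene, GenomeRecord, Operon
from regulonkit.synthetic import SyntheticScenario, generate


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def toy_genome():
    return GenomeRecord("toy", "AAACCCGGGTTT")


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


def make_operon(operon_id, strand, *coords):
    genes = tuple(
        Gene(f"{operon_id}_g{i}", s, e, strand) for i, (s, e) in enumerate(coords)
    )
    return Operon(operon_id, genes, strand)


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-scenario dataset shared across tests (seed fixed)."""
    return generate(SyntheticScenario(rng_seed=1))


@pytest.fixture(scope="session")
def synthetic_small():
    """A down-scaled scenario for fast end-to-end plumbing tests."""
    return generate(SyntheticScenario(
        rng_seed=7, genome_length=80_000, n_regulons=3,
        operons_per_regulon=15, background_operons=20, n_decoy_motifs=3,
    ))
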