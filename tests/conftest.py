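import numpy as np
import pytest

from aposeq import synthetic_data as sd
from aposeq.core_io import AnalysisConfig


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic genome shared by read-only tests.

    Two 100-kb contigs, 40 genes (5 scenario-1 and 3 scenario-2 deletions,
    5 siRNA targets, 4 miRNA hairpin loci), fixed seed.
    """
    contigs, genes, truth = sd.simulate_genome(
        n_contigs=2,
        contig_length=100_000,
        n_genes=40,
        gene_len_range=(500, 1200),
        n_scenario1=5,
        n_scenario2=3,
        n_sirna_targets=5,
        n_mirna_loci=4,
        seed=11,
    )
    return contigs, genes, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
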