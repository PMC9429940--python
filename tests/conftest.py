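import numpy as np
import pytest

from amplikit import synthetic as syn


@pytest.fixture(scope="session")
def panel():
    """Six-gene reference panel, mirroring a six-marker study design."""
    return syn.make_reference_panel(6, 150, seed=11)


@pytest.fixture(scope="session")
def gene(panel):
    return panel[0]


@pytest.fixture(scope="session")
def small_community(gene):
    """Ten taxa, two groups x three replicates, light error model."""
    taxa = syn.derive_taxa(gene, 10, 0.92, seed=21)
    design = syn.assign_abundances(taxa, 2, 3, 4.0, 0.3, 1.0, seed=22)
    reads, truth = syn.simulate_amplicons(
        design, 600, syn.ErrorModel(0.0005, 0.0001, 0.01, seed=23))
    return design, reads, truth


@pytest.fixture(scope="session")
def community_seqs(small_community):
    _, reads, _ = small_community
    return {s: [r.seq for r in rs] for s, rs in reads.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
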