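import numpy as np
import pytest

from agbt.algebraic_graph import AGConfig, DEFAULT_KERNELS, build_subgraph
from agbt.chem_io import dataset_sigma
from agbt.fixtures import make_smiles_corpus, make_toy_molecules
from agbt.smiles_lm import EncoderConfig, MaskingPolicy, pretrain


@pytest.fixture(scope="session")
def toy_molecules():
    return make_toy_molecules(60, seed=7)


@pytest.fixture(scope="session")
def toy_sigma(toy_molecules):
    return dataset_sigma(toy_molecules)


@pytest.fixture(scope="session")
def random_subgraphs(toy_molecules, toy_sigma):
    """>=100 non-empty element-pair subgraphs drawn from the toy molecules."""
    config = AGConfig()
    graphs = []
    for mol in toy_molecules:
        for pair in config.pairs:
            for kernel in DEFAULT_KERNELS[:2]:
                g = build_subgraph(mol, pair, kernel, toy_sigma)
                if g.edges:
                    graphs.append(g)
    assert len(graphs) >= 100
    return graphs[:400]


@pytest.fixture(scope="session")
def tiny_corpus():
    return make_smiles_corpus(300, seed=11)


@pytest.fixture(scope="session")
def heldout_corpus():
    return make_smiles_corpus(120, seed=999)


@pytest.fixture(scope="session")
def pretrained_state(tiny_corpus):
    """One shared test-scale pre-training run (deterministic, seed 0)."""
    return pretrain(tiny_corpus, EncoderConfig.test_scale(seed=0), epochs=15, batch=32)


@pytest.fixture(scope="session")
def untrained_state(tiny_corpus):
    """Same architecture and vocabulary, zero training epochs."""
    return pretrain(tiny_corpus, EncoderConfig.test_scale(seed=0), epochs=0)
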