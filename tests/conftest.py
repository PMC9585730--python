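"""Shared fixtures: a drug-like SMILES panel and small trained artifacts.

Everything is generated programmatically at test time; nothing is read from
disk except files the tests themselves write into tmp dirs.
"""

from __future__ import annotations

import numpy as np
import pytest

from molsent import (
    EncoderConfig,
    GeneratorSpec,
    PretrainSettings,
    Vocabulary,
    build_corpus,
    build_vocab,
    gen_molecules,
    pretrain,
)

# A small panel of real drug-like molecules (common drugs and fragments),
# complemented below with fragment-grammar molecules to reach 50.
DRUG_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",  # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",  # paracetamol
    "Clc1ccccc1",  # chlorobenzene
    "c1ccc2ccccc2c1",  # naphthalene
    "OCC1OC(O)C(O)C(O)C1O",  # glucose (pyranose)
    "CCN(CC)CC",  # triethylamine
    "CCCN(=O)=O",  # 1-nitropropane (as drawn)
    "O=C(O)c1ccccc1O",  # salicylic acid
]


@pytest.fixture(scope="session")
def fixture_smiles() -> list[str]:
    """Fifty drug-like molecules: 10 named compounds + 40 generated."""
    generated = gen_molecules(GeneratorSpec(n_molecules=40, seed=123))
    return DRUG_SMILES + generated


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory, fixture_smiles):
    """Corpus + vocabulary over 200 generated molecules."""
    tmp = tmp_path_factory.mktemp("corpus")
    mols = gen_molecules(GeneratorSpec(n_molecules=200, seed=11))
    path = tmp / "tiny.corpus"
    build_corpus(mols, path)
    return path


@pytest.fixture(scope="session")
def tiny_vocab(tiny_corpus) -> Vocabulary:
    return build_vocab(tiny_corpus)


@pytest.fixture(scope="session")
def tiny_encoder_config() -> EncoderConfig:
    return EncoderConfig(hidden_size=32, n_layers=2, n_heads=2, max_positions=64)


@pytest.fixture(scope="session")
def tiny_encoder(tiny_corpus, tiny_vocab, tiny_encoder_config):
    """A briefly pre-trained small encoder shared across tests."""
    model, log = pretrain(
        tiny_corpus,
        tiny_vocab,
        tiny_encoder_config,
        PretrainSettings(max_epochs=3, learning_rate=1e-3),
        seed=7,
    )
    return model, log


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
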