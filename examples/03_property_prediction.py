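"""Train a frozen-encoder property head on a planted classification task.

The generator plants a structure-property rule (here: presence of a pyridine
ring, with 5% label noise); the convolutional head reads the encoder's
per-token states and must rediscover it.  Held-out ROC-AUC near 1 means the
planted substructure signal was recovered.
"""

import tempfile
from pathlib import Path

import numpy as np

from molsent import (
    EncoderConfig,
    GeneratorSpec,
    PlantedTask,
    PredictorConfig,
    PretrainSettings,
    auc,
    build_corpus,
    build_vocab,
    gen_molecules,
    plant_property,
    pretrain,
    random_split,
    train_predictor,
)

workdir = Path(tempfile.mkdtemp())
corpus = workdir / "pool.corpus"
build_corpus(gen_molecules(GeneratorSpec(n_molecules=800, seed=0)), corpus)
vocab = build_vocab(corpus)
encoder, _ = pretrain(
    corpus,
    vocab,
    EncoderConfig(hidden_size=64, n_layers=2, n_heads=4, max_positions=64),
    PretrainSettings(max_epochs=4, learning_rate=1e-3),
    seed=1,
)

molecules = gen_molecules(GeneratorSpec(n_molecules=800, seed=99))
rows = plant_property(
    molecules, PlantedTask(task="classification", noise=0.05), seed=2
)
labels = np.array([label for _, label in rows])
split = random_split(len(molecules), seed=3)  # 8:1:1

model, log = train_predictor(
    ([molecules[i] for i in split.train], labels[split.train]),
    ([molecules[i] for i in split.validation], labels[split.validation]),
    encoder,
    vocab,
    PredictorConfig(task="classification", n_kernels=128, fc_units=64, max_epochs=30),
    seed=4,
)
test_smiles = [molecules[i] for i in split.test]
predictions = model.predict_smiles(test_smiles)
print(f"trained {len(log)} epochs; best val AUC {max(r['val_metric'] for r in log):.3f}")
print(f"held-out test AUC: {auc(predictions, labels[split.test]):.3f}")
# AUC ~0.9 at this small demo scale: the head found the planted pyridine
# signal despite the 5% label flips; 0.5 would mean no signal recovered.
# The desk-scale benchmark (scripts/acceptance.py) uses 5,000 pre-training
# and 2,000 task molecules and scores higher.
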