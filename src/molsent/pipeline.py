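"""Desk-scale end-to-end workflow: generate, pre-train, train, evaluate.

This is the package's reference experiment at laptop scale: a fragment-
grammar corpus stands in for a large unlabeled compound library, a small
encoder (hidden size 64, 2 layers) is pre-trained with the masked-
substructure objective, and frozen-encoder heads are trained on planted
classification and regression tasks.  Problem sizes (5,000 pre-training
molecules, 2,000 labeled molecules, 8:1:1 split, flip rate 0.05,
noise sd 0.1) are the package's standard desk-scale study conditions.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

import numpy as np

from .encoder import EncoderConfig, PretrainSettings, TransformerEncoder, pretrain
from .evalkit import auc, positive_ratio, random_split, rmse
from .predictor import PredictorConfig, train_predictor
from .synth import GeneratorSpec, PlantedTask, gen_molecules, plant_property
from .vocab import Vocabulary, build_corpus, build_vocab

DESK_ENCODER = dict(hidden_size=64, n_layers=2, n_heads=4, max_positions=64)
DESK_PRETRAIN = dict(max_epochs=6, patience=3, learning_rate=1e-3, batch_size=32)
DESK_CLS_HEAD = dict(n_kernels=256, fc_units=128, max_epochs=100, patience=15)
DESK_REG_HEAD = dict(n_kernels=512, fc_units=128, max_epochs=120, patience=20)

N_PRETRAIN = 5000
N_TASK = 2000
FLIP_RATE = 0.05
NOISE_SD = 0.1


@dataclass
class BenchmarkResult:
    classification_auc: float
    regression_rmse: float
    regression_noise_sd: float
    pretrain_val_accuracy: float
    vocab_size: int
    positive_ratio: float
    n_task: int
    n_pretrain: int


def pretrain_desk_encoder(
    seed: int,
    n_molecules: int = N_PRETRAIN,
    workdir: str | None = None,
) -> tuple[TransformerEncoder, Vocabulary, list[dict]]:
    """Generate a corpus and pre-train the desk-scale encoder."""
    own_tmp = workdir is None
    workdir = workdir or tempfile.mkdtemp(prefix="molsent-")
    corpus_path = os.path.join(workdir, "pretrain.corpus")
    mols = gen_molecules(GeneratorSpec(n_molecules=n_molecules, seed=seed))
    build_corpus(mols, corpus_path)
    vocab = build_vocab(corpus_path)
    model, log = pretrain(
        corpus_path,
        vocab,
        EncoderConfig(**DESK_ENCODER),
        PretrainSettings(**DESK_PRETRAIN),
        seed=seed + 1,
    )
    if own_tmp:
        os.remove(corpus_path)
        os.rmdir(workdir)
    return model, vocab, log


def planted_task_data(task: PlantedTask, seed: int, n: int = N_TASK):
    """Labeled planted-task dataset with an 8:1:1 random split."""
    mols = gen_molecules(GeneratorSpec(n_molecules=n, seed=seed))
    rows = plant_property(mols, task, seed=seed + 1)
    y = np.asarray([label for _, label in rows])
    split = random_split(n, seed=seed + 2)
    subsets = {
        name: ([mols[i] for i in idx], y[idx])
        for name, idx in (
            ("train", split.train),
            ("validation", split.validation),
            ("test", split.test),
        )
    }
    return subsets


def run_planted_benchmark(seed: int) -> BenchmarkResult:
    """The full desk-scale study: pre-train once, then train and evaluate the
    classification and regression heads on held-out test sets."""
    encoder, vocab, log = pretrain_desk_encoder(seed)

    cls = planted_task_data(
        PlantedTask(task="classification", noise=FLIP_RATE), seed=seed + 100
    )
    cls_model, _ = train_predictor(
        cls["train"],
        cls["validation"],
        encoder,
        vocab,
        PredictorConfig(task="classification", **DESK_CLS_HEAD),
        seed=seed + 3,
    )
    cls_pred = cls_model.predict_smiles(cls["test"][0])
    cls_auc = auc(cls_pred, cls["test"][1])

    reg = planted_task_data(
        PlantedTask(task="regression", effect_size=1.0, noise=NOISE_SD),
        seed=seed + 200,
    )
    reg_model, _ = train_predictor(
        reg["train"],
        reg["validation"],
        encoder,
        vocab,
        PredictorConfig(task="regression", **DESK_REG_HEAD),
        seed=seed + 4,
    )
    reg_pred = reg_model.predict_smiles(reg["test"][0])
    reg_rmse = rmse(reg_pred, reg["test"][1])

    return BenchmarkResult(
        classification_auc=float(cls_auc),
        regression_rmse=float(reg_rmse),
        regression_noise_sd=NOISE_SD,
        pretrain_val_accuracy=float(max(r["val_accuracy"] for r in log)),
        vocab_size=len(vocab),
        positive_ratio=float(positive_ratio(cls["train"][1])),
        n_task=N_TASK,
        n_pretrain=N_PRETRAIN,
    )
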