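"""Bidirectional transformer encoder pre-trained with masked-substructure
prediction.

A molecular sentence enters as ``[CLS] a_1 ... a_n [SEP]`` token indices; the
sum of token, learned-position and segment embeddings passes through a stack
of self-attention blocks, yielding one contextual state vector ``T_i`` of
dimension ``hidden_size`` per token.  Pre-training corrupts a fixed fraction
of the substructure tokens per sentence (mask / random / keep at 0.8/0.1/0.1)
and minimises cross-entropy of the original identifiers at the corrupted
positions only.

The selection rule is a hard bound, not a Bernoulli draw: exactly
``max(1, floor(mask_rate * n_sub))`` substructure positions are corrupted, so
no sentence ever exceeds the configured masking fraction (for sentences long
enough that the floor is attainable).
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO
from pathlib import Path

import numpy as np

from .nn import Adam, Dropout, Embedding, Linear, Module, Tensor, TransformerBlock
from .nn.autograd import softmax_cross_entropy
from .vocab import (
    CLS_ID,
    PAD_ID,
    SEP_ID,
    TokenSequence,
    Vocabulary,
    encode_tokens,
    iter_corpus,
)


@dataclass
class EncoderConfig:
    hidden_size: int = 256
    n_layers: int = 6
    n_heads: int = 4
    feedforward_size: int | None = None  # defaults to 4 * hidden_size
    max_positions: int = 256
    dropout_rate: float = 0.1
    mask_rate: float = 0.15
    mask_action_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self):
        if self.feedforward_size is None:
            self.feedforward_size = 4 * self.hidden_size
        if self.hidden_size % self.n_heads:
            raise ValueError("n_heads must divide hidden_size")
        if not 0.0 < self.mask_rate < 1.0:
            raise ValueError("mask_rate must be in (0, 1)")
        if abs(sum(self.mask_action_probs) - 1.0) > 1e-9:
            raise ValueError("mask_action_probs must sum to 1")


@dataclass
class PretrainSettings:
    """Optimisation settings for masked-substructure pre-training."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 40
    patience: int = 5
    validation_fraction: float = 0.05


@dataclass
class MaskingPlan:
    selected_positions: list[int]
    actions: list[str]  # "mask" | "random" | "keep"
    original_ids: list[int]


@dataclass
class EncodedMolecule:
    """Per-token state vectors T = [T_1 ... T_n] with a substructure-row mask."""

    states: np.ndarray  # (seq_len, hidden_size)
    valid_mask: np.ndarray  # bool, True on substructure-token rows


def mask_sequence(
    seq: TokenSequence,
    rng: np.random.Generator,
    config: EncoderConfig,
    vocab_size: int,
) -> tuple[TokenSequence, MaskingPlan]:
    """Corrupt a token sequence for masked-substructure pre-training.

    Exactly ``max(1, floor(mask_rate * n_sub))`` substructure positions are
    selected (never [CLS]/[SEP]/[PAD]); each independently receives the
    mask / random / keep action.  "random" draws uniformly from the
    non-special vocabulary entries.
    """
    from .vocab import MASK_ID

    candidates = seq.substructure_positions()
    if not candidates:
        raise ValueError("sequence contains no substructure tokens to mask")
    n_select = max(1, int(np.floor(config.mask_rate * len(candidates))))
    selected = sorted(rng.choice(len(candidates), size=n_select, replace=False))
    selected = [candidates[i] for i in selected]

    n_specials = 5
    if vocab_size <= n_specials:
        raise ValueError("vocabulary has no substructure entries")
    new_ids = list(seq.ids)
    actions, originals = [], []
    action_names = ("mask", "random", "keep")
    probs = config.mask_action_probs
    for pos in selected:
        originals.append(seq.ids[pos])
        action = action_names[rng.choice(3, p=probs)]
        actions.append(action)
        if action == "mask":
            new_ids[pos] = MASK_ID
        elif action == "random":
            new_ids[pos] = int(rng.integers(n_specials, vocab_size))
    corrupted = TokenSequence(
        ids=new_ids,
        attention_mask=list(seq.attention_mask),
        segment_ids=list(seq.segment_ids),
    )
    return corrupted, MaskingPlan(selected, actions, originals)


class TransformerEncoder(Module):
    """Token/position/segment embeddings + transformer stack + MLM head."""

    def __init__(self, config: EncoderConfig, vocab_size: int, seed: int = 0):
        super().__init__()
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        H = config.hidden_size
        self.token_embedding = Embedding(vocab_size, H, rng)
        self.position_embedding = Embedding(config.max_positions, H, rng)
        self.segment_embedding = Embedding(1, H, rng)
        self.blocks = _BlockList(
            [
                TransformerBlock(
                    H, config.n_heads, config.feedforward_size, config.dropout_rate, rng
                )
                for _ in range(config.n_layers)
            ]
        )
        self.embed_dropout = Dropout(config.dropout_rate)
        self.mlm_head = Linear(H, vocab_size, rng)

    def forward(
        self,
        ids: np.ndarray,
        attention_mask: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """(B, L) token ids -> (B, L, H) state vectors."""
        ids = np.atleast_2d(np.asarray(ids))
        attention_mask = np.atleast_2d(np.asarray(attention_mask))
        length = ids.shape[1]
        if length > self.config.max_positions:
            raise ValueError(
                f"sequence length {length} exceeds max_positions "
                f"{self.config.max_positions}"
            )
        if rng is None:
            rng = np.random.default_rng(0)
        positions = np.broadcast_to(np.arange(length), ids.shape)
        segments = np.zeros_like(ids)
        x = (
            self.token_embedding(ids)
            + self.position_embedding(positions)
            + self.segment_embedding(segments)
        )
        x = self.embed_dropout(x, rng)
        for block in self.blocks.items:
            x = block(x, attention_mask, rng)
        return x


class _BlockList(Module):
    def __init__(self, items):
        super().__init__()
        self.items = items
        for i, item in enumerate(items):
            setattr(self, f"block{i}", item)


def encode(model: TransformerEncoder, seq: TokenSequence) -> EncodedMolecule:
    """Run the encoder in eval mode on one sequence, returning all per-token
    states and a mask selecting the substructure rows."""
    was_training = model.training
    model.eval()
    try:
        states = model.forward(
            np.asarray([seq.ids]), np.asarray([seq.attention_mask])
        ).data[0]
    finally:
        if was_training:
            model.train()
    valid = np.zeros(len(seq.ids), dtype=bool)
    valid[seq.substructure_positions()] = True
    return EncodedMolecule(states=states, valid_mask=valid)


def encode_batch(model: TransformerEncoder, seqs: list[TokenSequence]) -> list[EncodedMolecule]:
    """Batched :func:`encode` (identical results, one forward pass)."""
    if not seqs:
        return []
    was_training = model.training
    model.eval()
    try:
        ids, mask = _pad_batch(seqs)
        states = model.forward(ids, mask).data
    finally:
        if was_training:
            model.train()
    out = []
    for i, seq in enumerate(seqs):
        n = len(seq.ids)
        valid = np.zeros(n, dtype=bool)
        valid[seq.substructure_positions()] = True
        out.append(EncodedMolecule(states=states[i, :n], valid_mask=valid))
    return out


def mlm_loss(logits: Tensor, plans: list[MaskingPlan] | MaskingPlan) -> Tensor:
    """Mean cross-entropy over the selected positions of a (batch of)
    masking plan(s).  ``logits`` is (B, L, V)."""
    if isinstance(plans, MaskingPlan):
        plans = [plans]
    rows, cols, targets = [], [], []
    for b, plan in enumerate(plans):
        for pos, orig in zip(plan.selected_positions, plan.original_ids):
            rows.append(b)
            cols.append(pos)
            targets.append(orig)
    if not targets:
        raise ValueError("empty masking plan")
    batch, length, vsize = logits.shape
    flat = logits.reshape(batch * length, vsize)
    idx = np.asarray(rows) * length + np.asarray(cols)
    selected = _gather_rows(flat, idx)
    return softmax_cross_entropy(selected, np.asarray(targets))


def _gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    out_data = x.data[idx]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, idx, g)
            x._accum(full)

    return Tensor._from_op(out_data, (x,), backward)


def _load_sequences(corpus_path, vocab: Vocabulary, max_positions: int):
    seqs = []
    for tokens in iter_corpus(corpus_path):
        max_len = min(len(tokens) + 2, max_positions)
        seqs.append(encode_tokens(tokens, vocab, max_len=max_len))
    return seqs


def _pad_batch(seqs: list[TokenSequence]) -> tuple[np.ndarray, np.ndarray]:
    length = max(len(s.ids) for s in seqs)
    ids = np.full((len(seqs), length), PAD_ID, dtype=np.int64)
    mask = np.zeros((len(seqs), length), dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, : len(s.ids)] = s.ids
        mask[i, : len(s.ids)] = s.attention_mask
    return ids, mask


def pretrain(
    corpus_path,
    vocab: Vocabulary,
    config: EncoderConfig | None = None,
    settings: PretrainSettings | None = None,
    seed: int = 0,
    log_path=None,
) -> tuple[TransformerEncoder, list[dict]]:
    """Pre-train an encoder on a corpus file with the masked-substructure
    objective.

    Training stops at ``max_epochs`` or once validation masked-token accuracy
    has not improved for ``patience`` consecutive epochs; the returned model
    carries the parameters of the best validation epoch.  The log is a list of
    ``{"epoch", "train_loss", "val_accuracy"}`` records (also written as CSV
    to ``log_path`` if given).
    """
    config = config or EncoderConfig()
    settings = settings or PretrainSettings()
    rng = np.random.default_rng(seed)
    seqs = _load_sequences(corpus_path, vocab, config.max_positions)
    seqs = [s for s in seqs if s.n_substructure_tokens >= 1]
    if not seqs:
        raise ValueError("corpus contains no usable sentences")

    order = rng.permutation(len(seqs))
    n_val = max(1, int(round(settings.validation_fraction * len(seqs))))
    val_seqs = [seqs[i] for i in order[:n_val]]
    train_seqs = [seqs[i] for i in order[n_val:]] or val_seqs

    model = TransformerEncoder(config, len(vocab), seed=int(rng.integers(2**31)))
    optimizer = Adam(model.parameters(), lr=settings.learning_rate)

    log: list[dict] = []
    best_acc = -np.inf
    best_state = model.state_dict()
    epochs_since_best = 0
    for epoch in range(1, settings.max_epochs + 1):
        model.train()
        perm = rng.permutation(len(train_seqs))
        losses = []
        for start in range(0, len(perm), settings.batch_size):
            batch = [train_seqs[i] for i in perm[start : start + settings.batch_size]]
            corrupted, plans = [], []
            for s in batch:
                c, p = mask_sequence(s, rng, config, len(vocab))
                corrupted.append(c)
                plans.append(p)
            ids, mask = _pad_batch(corrupted)
            states = model.forward(ids, mask, rng)
            logits = model.mlm_head(states)
            loss = mlm_loss(logits, plans)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"masked-LM loss diverged (epoch {epoch}): {loss.data}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_acc = _masked_accuracy(model, val_seqs, config, len(vocab), seed)
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_accuracy": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= settings.patience:
                break
    model.load_state_dict(best_state)
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("epoch,train_loss,val_accuracy\n")
            for rec in log:
                fh.write(
                    f"{rec['epoch']},{rec['train_loss']:.6f},{rec['val_accuracy']:.6f}\n"
                )
    return model, log


def _masked_accuracy(
    model: TransformerEncoder,
    seqs: list[TokenSequence],
    config: EncoderConfig,
    vocab_size: int,
    seed: int,
) -> float:
    """Top-1 masked-token prediction accuracy with a fixed masking draw."""
    rng = np.random.default_rng(seed + 10_000)
    model.eval()
    n_correct = n_total = 0
    for start in range(0, len(seqs), 64):
        batch = seqs[start : start + 64]
        corrupted, plans = [], []
        for s in batch:
            c, p = mask_sequence(s, rng, config, vocab_size)
            corrupted.append(c)
            plans.append(p)
        ids, mask = _pad_batch(corrupted)
        logits = model.mlm_head(model.forward(ids, mask)).data
        for b, plan in enumerate(plans):
            for pos, orig in zip(plan.selected_positions, plan.original_ids):
                n_correct += int(logits[b, pos].argmax() == orig)
                n_total += 1
    model.train()
    return n_correct / max(n_total, 1)


def save_checkpoint(path, model: TransformerEncoder, vocab: Vocabulary) -> None:
    """Write a single-archive checkpoint: config JSON, vocabulary, tensors."""
    buf = BytesIO()
    np.savez(buf, **model.state_dict())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr(
            "config.json",
            json.dumps({"config": asdict(model.config), "vocab_size": model.vocab_size}),
        )
        zf.writestr("vocab.txt", "\n".join(vocab.tokens) + "\n")
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[TransformerEncoder, Vocabulary]:
    """Reload a checkpoint; reproduces :func:`encode` outputs bitwise."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        vocab = Vocabulary(tokens=zf.read("vocab.txt").decode().splitlines())
        with zf.open("weights.npz") as fh:
            weights = dict(np.load(BytesIO(fh.read())))
    cfg = meta["config"]
    cfg["mask_action_probs"] = tuple(cfg["mask_action_probs"])
    model = TransformerEncoder(EncoderConfig(**cfg), meta["vocab_size"])
    model.load_state_dict(weights)
    return model, vocab
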