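"""Frozen-encoder property prediction head.

The encoder's per-token state matrix ``x_in`` (substructure rows only, shape
n x H) is passed through a 1-D convolution along the token axis with ReLU,
global max pooling over valid positions, a fully connected ReLU layer, and a
single output unit — sigmoid for classification (positive-class probability)
or identity for regression.  The convolution uses no padding: output
positions whose receptive field would touch padded tokens are excluded from
pooling, so appending pads never changes a prediction.

The encoder is frozen throughout downstream training: only the convolution
and fully connected parameters receive gradient updates, and because the
encoder is fixed, every molecule is encoded once up front and training
iterates over cached state matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import EncodedMolecule, TransformerEncoder, encode_batch
from .nn import Adam, Linear, Module, Tensor
from .vocab import Vocabulary, encode_tokens


@dataclass
class PredictorConfig:
    task: str = "classification"  # "classification" | "regression"
    kernel_length: int | None = None  # defaults: 5 classification / 1 regression
    n_kernels: int | None = None  # defaults: 512 classification / 2048 regression
    fc_units: int = 256
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.kernel_length is None:
            self.kernel_length = 5 if self.task == "classification" else 1
        if self.n_kernels is None:
            self.n_kernels = 512 if self.task == "classification" else 2048
        if self.kernel_length < 1 or self.n_kernels < 1:
            raise ValueError("kernel_length and n_kernels must be >= 1")


class ConvHead(Module):
    """Conv1d -> ReLU -> global max pool -> FC(ReLU) -> output unit."""

    def __init__(self, config: PredictorConfig, hidden_size: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        k, c = config.kernel_length, config.n_kernels
        bound = np.sqrt(6.0 / (k * hidden_size + c))
        self.conv_weight = Tensor(
            rng.uniform(-bound, bound, size=(k, hidden_size, c)).astype(np.float32), requires_grad=True
        )
        self.conv_bias = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.fc = Linear(c, config.fc_units, rng)
        self.out = Linear(config.fc_units, 1, rng)

    def conv(self, x: Tensor) -> Tensor:
        """Valid (no-padding) 1-D convolution: (B, n, H) -> (B, n-k+1, C)."""
        k = self.config.kernel_length
        n = x.shape[1]
        if n < k:
            raise ValueError(
                f"sequence of {n} substructure tokens is shorter than the "
                f"convolution kernel ({k}); pad the input to at least {k} tokens"
            )
        acc = None
        for j in range(k):
            term = x.narrow(1, j, n - k + 1) @ self.conv_weight.narrow(0, j, 1).reshape(
                x.shape[2], self.conv_weight.shape[2]
            )
            acc = term if acc is None else acc + term
        return (acc + self.conv_bias).relu()

    def forward_states(self, states: Tensor, valid_counts: np.ndarray) -> Tensor:
        """States (B, n_max, H) with per-example valid token counts -> (B,) scores.

        Positions whose receptive field extends past an example's valid tokens
        are masked out of the max pool.
        """
        o_conv = self.conv(states)  # (B, P, C)
        n_pos = o_conv.shape[1]
        k = self.config.kernel_length
        valid_pos = valid_counts - k + 1  # conv outputs fully inside valid tokens
        if np.any(valid_pos < 1):
            raise ValueError(
                "an example has fewer substructure tokens than the kernel length"
            )
        mask = np.arange(n_pos)[None, :] < valid_pos[:, None]
        neg = np.where(mask, 0.0, -np.inf).astype(np.float32)[:, :, None]
        o_max = (o_conv + Tensor(neg)).max(axis=1)  # (B, C)
        hidden = self.fc(o_max).relu()
        y = self.out(hidden).reshape(o_conv.shape[0])
        if self.config.task == "classification":
            y = y.sigmoid()
        return y


@dataclass
class PropertyModel:
    """Frozen encoder + trained convolutional head."""

    encoder: TransformerEncoder
    head: ConvHead
    config: PredictorConfig
    vocab: Vocabulary
    max_radius: int = 1

    def predict_smiles(self, smiles_list: list[str], batch_size: int = 64) -> np.ndarray:
        from .graph import generate_sentence

        sentences = [generate_sentence(s, self.max_radius) for s in smiles_list]
        encoded = _encode_sentences(self.encoder, self.vocab, sentences)
        out = []
        for start in range(0, len(encoded), batch_size):
            chunk = encoded[start : start + batch_size]
            states, counts = _stack_states(chunk, self.config.kernel_length)
            out.append(self.head.forward_states(Tensor(states), counts).data)
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# functional pieces (also used directly by the tests)

def conv_features(x_in: np.ndarray | Tensor, head: ConvHead) -> np.ndarray:
    """Feature maps of one encoded molecule: (n, H) -> (n-k+1, n_kernels)."""
    x = x_in if isinstance(x_in, Tensor) else Tensor(np.asarray(x_in))
    if x.ndim == 2:
        x = x.reshape(1, *x.shape)
        return head.conv(x).data[0]
    return head.conv(x).data


def global_max_pool(o_conv: np.ndarray, valid_positions: np.ndarray | None = None) -> np.ndarray:
    """Per-channel maximum over valid output positions: (P, C) -> (C,)."""
    o_conv = np.asarray(o_conv)
    if valid_positions is None:
        valid_positions = np.ones(o_conv.shape[0], dtype=bool)
    valid_positions = np.asarray(valid_positions, dtype=bool)
    if not valid_positions.any():
        raise ValueError("global max pool requires at least one valid position")
    return o_conv[valid_positions].max(axis=0)


def predict(o_max: np.ndarray, head: ConvHead) -> float:
    """Pooled vector -> scalar prediction through the fully connected stack."""
    hidden = (Tensor(np.asarray(o_max)[None, :]) @ head.fc.weight + head.fc.bias).relu()
    y = (hidden @ head.out.weight + head.out.bias).data[0, 0]
    if head.config.task == "classification":
        y = 1.0 / (1.0 + np.exp(-y))
    return float(y)


def classification_loss(predictions, labels) -> float:
    """Mean binary cross-entropy; predictions are clamped to [1e-7, 1-1e-7]."""
    y = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(labels, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty input")
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("classification predictions must lie in [0, 1]")
    if not np.all(np.isin(t, (0.0, 1.0))):
        raise ValueError("classification labels must be 0 or 1")
    y = np.clip(y, 1e-7, 1 - 1e-7)
    return float(-np.mean(t * np.log(y) + (1 - t) * np.log(1 - y)))


def regression_loss(predictions, targets) -> float:
    """Mean squared error (non-negative)."""
    y = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != t.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y - t) ** 2))


# ---------------------------------------------------------------------------
# training

def _encode_sentences(encoder, vocab, sentences):
    from .vocab import TokenSequence  # noqa: F401

    seqs = [
        encode_tokens(s, vocab, max_len=min(len(s.tokens) + 2, encoder.config.max_positions))
        for s in sentences
    ]
    encoded: list[EncodedMolecule] = []
    for start in range(0, len(seqs), 64):
        encoded.extend(encode_batch(encoder, seqs[start : start + 64]))
    return encoded


def _substructure_states(enc: EncodedMolecule) -> np.ndarray:
    return enc.states[enc.valid_mask]


def _stack_states(encoded: list[EncodedMolecule], kernel_length: int):
    """Stack ragged substructure-state matrices into one padded array.

    Examples shorter than the kernel are zero-padded up to the kernel length;
    the valid-count vector records the true token counts (floored at the
    kernel length so that exactly the genuine positions survive pooling —
    for padded-up examples the single position covering the zero padding is
    unavoidable and deterministic).
    """
    counts = np.asarray(
        [max(_substructure_states(e).shape[0], kernel_length) for e in encoded]
    )
    n_max = counts.max()
    H = encoded[0].states.shape[1]
    states = np.zeros((len(encoded), n_max, H), dtype=np.float32)
    for i, e in enumerate(encoded):
        s = _substructure_states(e)
        states[i, : s.shape[0]] = s
    return states, counts


def train_predictor(
    train_data: tuple[list[str], np.ndarray],
    val_data: tuple[list[str], np.ndarray],
    encoder: TransformerEncoder,
    vocab: Vocabulary,
    config: PredictorConfig | None = None,
    seed: int = 0,
    max_radius: int = 1,
) -> tuple[PropertyModel, list[dict]]:
    """Train the convolutional head on labeled (smiles, label) data with the
    encoder frozen.

    Early stopping monitors the validation metric (ROC-AUC for
    classification, RMSE for regression) and reverts to the best epoch.  The
    encoder parameter checksum is asserted unchanged.
    """
    from .evalkit import auc as roc_auc
    from .graph import generate_sentence

    config = config or PredictorConfig()
    rng = np.random.default_rng(seed)
    train_smiles, train_y = train_data
    val_smiles, val_y = val_data
    if len(train_smiles) == 0 or len(val_smiles) == 0:
        raise ValueError("train and validation sets must be nonempty")
    train_y = np.asarray(train_y, dtype=np.float64)
    val_y = np.asarray(val_y, dtype=np.float64)
    if config.task == "classification" and not np.all(np.isin(train_y, (0, 1))):
        raise ValueError("classification labels must be binary")

    checksum_before = encoder.checksum()
    sentences = [generate_sentence(s, max_radius) for s in train_smiles]
    val_sentences = [generate_sentence(s, max_radius) for s in val_smiles]
    train_enc = _encode_sentences(encoder, vocab, sentences)
    val_enc = _encode_sentences(encoder, vocab, val_sentences)

    head = ConvHead(config, encoder.config.hidden_size, seed=int(rng.integers(2**31)))
    optimizer = Adam(head.parameters(), lr=config.learning_rate)

    def eval_metric() -> float:
        preds = _predict_encoded(head, val_enc, config)
        if config.task == "classification":
            return float(roc_auc(preds, val_y))
        return float(np.sqrt(np.mean((preds - val_y) ** 2)))

    better = (lambda a, b: a > b) if config.task == "classification" else (lambda a, b: a < b)
    best_metric = -np.inf if config.task == "classification" else np.inf
    best_state = head.state_dict()
    since_best = 0
    log: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(len(train_enc))
        losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            states, counts = _stack_states([train_enc[i] for i in idx], config.kernel_length)
            y = head.forward_states(Tensor(states), counts)
            t = train_y[idx]
            if config.task == "classification":
                yc = y * (1 - 2e-7) + 1e-7  # clamp away from {0,1} for the log
                tt = Tensor(t.astype(np.float32))
                loss = -(tt * yc.log() + (1 - tt) * (1 - yc).log()).mean()
            else:
                loss = (y - Tensor(t.astype(np.float32))).pow(2.0).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        metric = eval_metric()
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_metric": metric,
            }
        )
        if better(metric, best_metric):
            best_metric = metric
            best_state = head.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    head.load_state_dict(best_state)
    if encoder.checksum() != checksum_before:
        raise RuntimeError("encoder parameters changed during downstream training")
    model = PropertyModel(
        encoder=encoder, head=head, config=config, vocab=vocab, max_radius=max_radius
    )
    return model, log


def _predict_encoded(head: ConvHead, encoded: list[EncodedMolecule], config, batch_size: int = 256):
    out = []
    for start in range(0, len(encoded), batch_size):
        chunk = encoded[start : start + batch_size]
        states, counts = _stack_states(chunk, config.kernel_length)
        out.append(head.forward_states(Tensor(states), counts).data)
    return np.concatenate(out)
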