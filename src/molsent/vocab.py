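"""Corpus construction, vocabulary, and token-sequence encoding.

The corpus dialect is one molecule per line, sentence tokens written as
space-separated unsigned decimal integers.  The vocabulary maps each distinct
substructure identifier (rendered as its decimal string) to an index, after
five reserved special tokens at fixed indices 0-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .graph import EmptyMoleculeError, MolecularSentence, SmilesParseError, generate_sentence

logger = logging.getLogger(__name__)

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK)
PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(5)


@dataclass
class Vocabulary:
    """Bijection between tokens and indices; specials occupy indices 0-4."""

    tokens: list[str] = field(default_factory=lambda: list(SPECIAL_TOKENS))

    def __post_init__(self) -> None:
        if tuple(self.tokens[:5]) != SPECIAL_TOKENS:
            raise ValueError(f"first five tokens must be {SPECIAL_TOKENS}")
        self._index = {tok: i for i, tok in enumerate(self.tokens)}
        if len(self._index) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_specials(self) -> int:
        return len(SPECIAL_TOKENS)

    def add(self, token: str) -> int:
        if token not in self._index:
            self._index[token] = len(self.tokens)
            self.tokens.append(token)
        return self._index[token]

    def index(self, token: str) -> int:
        """Index of ``token``; unknown tokens map to [UNK]."""
        return self._index.get(token, UNK_ID)

    def token(self, index: int) -> str:
        return self.tokens[index]

    def save(self, path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        tokens = Path(path).read_text().splitlines()
        return cls(tokens=tokens)


@dataclass
class TokenSequence:
    """Fixed-length encoded sentence: [CLS] tokens... [SEP] [PAD]*."""

    ids: list[int]
    attention_mask: list[int]
    segment_ids: list[int]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_substructure_tokens(self) -> int:
        """Count of real (non-special, non-pad) token positions."""
        return sum(self.attention_mask) - 2

    def substructure_positions(self) -> list[int]:
        """Positions holding substructure tokens (excludes CLS/SEP/PAD)."""
        return list(range(1, 1 + self.n_substructure_tokens))


def build_corpus(smiles_source, out_path, max_radius: int = 1) -> int:
    """Convert a SMILES iterable to a corpus file; returns the skip count.

    Unparseable records are skipped (and logged); input order is preserved.
    """
    skipped = 0
    with open(out_path, "w") as fh:
        for smi in smiles_source:
            try:
                sentence = generate_sentence(smi, max_radius=max_radius)
            except (SmilesParseError, EmptyMoleculeError) as exc:
                skipped += 1
                logger.warning("skipping record: %s", exc)
                continue
            fh.write(sentence.as_text() + "\n")
    if skipped:
        logger.info("build_corpus skipped %d unparseable records", skipped)
    return skipped


def iter_corpus(path):
    """Yield token lists (as decimal strings) from a corpus file."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield line.split()


def build_vocab(corpus_path) -> Vocabulary:
    """Vocabulary over a corpus: 5 specials + identifiers in first-appearance order."""
    vocab = Vocabulary()
    n_lines = 0
    for tokens in iter_corpus(corpus_path):
        n_lines += 1
        for tok in tokens:
            vocab.add(tok)
    if n_lines == 0:
        raise ValueError(f"corpus is empty: {corpus_path}")
    return vocab


def encode_tokens(
    sentence: MolecularSentence | list[int] | list[str],
    vocab: Vocabulary,
    max_len: int = 256,
) -> TokenSequence:
    """Encode a sentence as ``[CLS] t1 ... tn [SEP]`` padded to ``max_len``.

    Sentences longer than ``max_len - 2`` are truncated from the tail;
    identifiers absent from the vocabulary map to [UNK].
    """
    if max_len < 3:
        raise ValueError("max_len must be >= 3")
    raw = sentence.tokens if isinstance(sentence, MolecularSentence) else sentence
    toks = [str(t) for t in raw][: max_len - 2]
    ids = [CLS_ID] + [vocab.index(t) for t in toks] + [SEP_ID]
    n_real = len(ids)
    ids += [PAD_ID] * (max_len - n_real)
    mask = [1] * n_real + [0] * (max_len - n_real)
    return TokenSequence(ids=ids, attention_mask=mask, segment_ids=[0] * max_len)


def decode_tokens(seq: TokenSequence, vocab: Vocabulary) -> list[str]:
    """Inverse of :func:`encode_tokens` for in-vocabulary tokens."""
    out = []
    for pos in seq.substructure_positions():
        out.append(vocab.token(seq.ids[pos]))
    return out
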