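"""Protein-sequence channel: subword tokenization plus a Transformer encoder.

Amino-acid sequences are decomposed into moderate-sized substrings with a
frequency-derived subword vocabulary (byte-pair-style merges, as in
explainable substructure partition fingerprints).  Token and position
embeddings are summed (``E = E_seq + E_pos``), passed through one Transformer
encoder block (masked multi-head self-attention and a position-wise
feed-forward network, each with dropout, a residual connection and layer
normalization), and mean-pooled over real tokens into a fixed-size target
embedding.

The vocabulary can be learned from a training corpus
(:func:`learn_subword_vocab`) or loaded from an external merge-operations
file in the ``left<SPACE>right`` one-merge-per-line dialect.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (Dropout, Embedding, Linear, LayerNorm, Module,
                 MultiHeadSelfAttention, Tensor)

__all__ = [
    "SubwordVocab", "TokenizedSequence", "TransformerConfig",
    "learn_subword_vocab", "tokenize", "TargetTransformer",
]

PAD_INDEX = 0
UNK_INDEX = 1
AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY") + list("XUBZ")


@dataclass
class SubwordVocab:
    """Ordered subword inventory plus the merge operations that built it."""

    tokens: list[str]                       # index 0 = PAD, 1 = UNK
    merges: list[tuple[str, str]]
    token_to_idx: dict[str, int] = field(init=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.token_to_idx = {t: i for i, t in enumerate(self.tokens)}

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return PAD_INDEX

    @property
    def unk_index(self) -> int:
        return UNK_INDEX

    def save(self, codes_path, tokens_path) -> None:
        with open(codes_path, "w") as fh:
            for a, b in self.merges:
                fh.write(f"{a} {b}\n")
        with open(tokens_path, "w") as fh:
            for i, t in enumerate(self.tokens):
                fh.write(f"{t}\t{i}\n")

    @classmethod
    def load(cls, codes_path, tokens_path) -> "SubwordVocab":
        merges = []
        for line in Path(codes_path).read_text().splitlines():
            if line.strip():
                a, b = line.split(" ")
                merges.append((a, b))
        tokens = [""] * 0
        rows = [ln.split("\t") for ln in Path(tokens_path).read_text().splitlines()
                if ln.strip()]
        tokens = [""] * len(rows)
        for tok, idx in rows:
            tokens[int(idx)] = tok
        return cls(tokens, merges)


def _apply_merges(symbols: list[str], merges: list[tuple[str, str]]) -> list[str]:
    """Apply merge operations in priority order, left to right."""
    for a, b in merges:
        merged, i = [], 0
        while i < len(symbols):
            if i + 1 < len(symbols) and symbols[i] == a and symbols[i + 1] == b:
                merged.append(a + b)
                i += 2
            else:
                merged.append(symbols[i])
                i += 1
        symbols = merged
    return symbols


def learn_subword_vocab(corpus: list[str], n_merges: int = 200) -> SubwordVocab:
    """Learn a deterministic byte-pair subword vocabulary from sequences.

    The most frequent adjacent symbol pair is merged at each step; frequency
    ties break lexicographically so that the result is reproducible.  Every
    single residue letter is always present, so no sequence is untokenizable.
    """
    seqs = [list(s) for s in corpus]
    merges: list[tuple[str, str]] = []
    for _ in range(n_merges):
        counts: Counter = Counter()
        for s in seqs:
            for i in range(len(s) - 1):
                counts[(s[i], s[i + 1])] += 1
        if not counts:
            break
        top = max(counts.values())
        best = min(p for p in counts if counts[p] == top)
        if top < 2:
            break
        merges.append(best)
        seqs = [_apply_merges(s, [best]) for s in seqs]
    subwords = sorted({tok for s in seqs for tok in s} | set(AMINO_ACIDS))
    tokens = ["<pad>", "<unk>"] + subwords
    return SubwordVocab(tokens, merges)


@dataclass
class TokenizedSequence:
    """Subword indices Z with 1-based positions P, padded/truncated to m."""

    Z: np.ndarray            # (m,) int token indices, PAD-filled
    P: np.ndarray            # (m,) int positions, 1-based, 0 on padding
    mask: np.ndarray         # (m,) binary
    true_length: int         # number of stored (non-pad) tokens, <= m
    tokens: list[str] = field(default_factory=list)  # untruncated subwords


def tokenize(sequence: str, vocab: SubwordVocab, m: int = 545) -> TokenizedSequence:
    """Decompose a sequence into subwords, then truncate to m and pad.

    Joining the (untruncated) tokens reconstructs the input exactly; residues
    absent from the vocabulary map to the UNK index rather than failing.
    """
    if not sequence:
        raise ValueError("cannot tokenize an empty sequence")
    toks = _apply_merges(list(sequence), vocab.merges)
    assert "".join(toks) == sequence
    stored = toks[:m]
    l = len(stored)
    Z = np.full(m, PAD_INDEX, dtype=np.intp)
    P = np.zeros(m, dtype=np.intp)
    mask = np.zeros(m, dtype=np.intp)
    for i, t in enumerate(stored):
        Z[i] = vocab.token_to_idx.get(t, UNK_INDEX)
        P[i] = i + 1
        mask[i] = 1
    return TokenizedSequence(Z, P, mask, l, tokens=toks)


@dataclass
class TransformerConfig:
    d: int = 64                 # embedding width
    m: int = 545                # maximum token length
    n_heads: int = 8
    ffn_dim: int = 256
    dropout: float = 0.1
    seed: int = 0
    pooling: str = "mean"       # masked mean over real tokens

    def __post_init__(self):
        if self.d % self.n_heads:
            raise ValueError("d must be divisible by n_heads")


class TargetTransformer(Module):
    """Single-block Transformer encoder producing one vector per sequence."""

    def __init__(self, vocab_size: int, config: TransformerConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.tok_emb = Embedding(vocab_size, config.d, rng, padding_idx=PAD_INDEX)
        self.pos_emb = Embedding(config.m + 1, config.d, rng, padding_idx=0)
        self.attn = MultiHeadSelfAttention(config.d, config.n_heads, rng)
        self.ln1 = LayerNorm(config.d)
        self.ffn1 = Linear(config.d, config.ffn_dim, rng)
        self.ffn2 = Linear(config.ffn_dim, config.d, rng)
        self.ln2 = LayerNorm(config.d)
        self.drop = Dropout(config.dropout, rng)

    # --- stages ------------------------------------------------------------
    def embed(self, Z: np.ndarray, P: np.ndarray) -> Tensor:
        """E = E_seq + E_pos; shape (..., m, d)."""
        return self.tok_emb(Z) + self.pos_emb(P)

    def transformer_block(self, E: Tensor, mask: np.ndarray) -> Tensor:
        """Post-norm encoder block; padded positions are never attended to."""
        a = self.drop(self.attn(E, mask))
        x = self.ln1(E + a)
        f = self.drop(self.ffn2(self.ffn1(x).relu()))
        return self.ln2(x + f)

    def encode_batch(self, toks: list[TokenizedSequence]) -> Tensor:
        Z = np.stack([t.Z for t in toks])
        P = np.stack([t.P for t in toks])
        mask = np.stack([t.mask for t in toks])
        out = self.transformer_block(self.embed(Z, P), mask)
        m = Tensor(mask[:, :, None].astype(float))
        pooled = (out * m).sum(axis=1) / Tensor(
            mask.sum(axis=1, keepdims=True).astype(float))
        return pooled

    def encode(self, tok: TokenizedSequence) -> Tensor:
        """Masked-mean pooled embedding of one sequence; shape (d,)."""
        return self.encode_batch([tok]).reshape(self.config.d)


def encode_target(sequence: str, vocab: SubwordVocab,
                  model: TargetTransformer) -> np.ndarray:
    """Convenience wrapper: tokenize + encode in eval mode."""
    was_training = model.training
    model.eval()
    vec = model.encode(tokenize(sequence, vocab, model.config.m)).data
    model.train(was_training)
    return vec
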