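"""Continuous bag-of-words (CBOW) word vectors.

Implements the classic word2vec CBOW objective with negative sampling:
the mean of the context-word input vectors predicts the centre word
against ``negative`` noise words drawn from the unigram^0.75
distribution.  Training is mini-batch SGD with a linearly decaying
learning rate and is deterministic given the seed (single worker, fixed
iteration order).  Tokens occurring fewer than ``min_count`` times are
dropped from the vocabulary before training.

Vectors round-trip through the standard word2vec text format (header
``"vocab_size dim"``, then one ``token v1 ... vdim`` row per word).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class EmbeddingConfig:
    """CBOW hyperparameters.

    ``dim``, ``window`` and ``min_count`` default to the reference
    settings (100 / 5 / 5); ``epochs``, ``negative``, ``learning_rate``
    and ``batch_size`` govern the optimizer.
    """

    dim: int = 100
    window: int = 5
    min_count: int = 5
    seed: int = 0
    epochs: int = 5
    negative: int = 5
    learning_rate: float = 0.025
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.min_count < 1:
            raise ValueError("dim, window and min_count must all be >= 1")


class WordEmbedding:
    """A vocabulary with one dense vector per token."""

    def __init__(self, tokens: Sequence[str], vectors: np.ndarray):
        if len(tokens) != vectors.shape[0]:
            raise ValueError("one vector per token required")
        self.tokens = list(tokens)
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self._index = {t: i for i, t in enumerate(self.tokens)}
        if len(self._index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self._index)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self._index[token]]

    def __len__(self) -> int:
        return len(self.tokens)

    def save(self, path: str | Path) -> None:
        """Write word2vec text format."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.tokens)} {self.dim}\n")
            for t, v in zip(self.tokens, self.vectors):
                fh.write(t + " " + " ".join(format(x, ".8g") for x in v) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "WordEmbedding":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            tokens, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                tokens.append(parts[0])
                rows.append([float(x) for x in parts[1 : dim + 1]])
        if len(tokens) != n:
            raise ValueError(f"header promised {n} rows, found {len(tokens)}")
        return cls(tokens, np.asarray(rows))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_embeddings(
    corpus: Iterable[Sequence[str]], config: EmbeddingConfig = EmbeddingConfig()
) -> WordEmbedding:
    """Train CBOW vectors on an iterable of token sequences.

    Raises ``ValueError`` on an empty corpus or when no token reaches
    ``min_count``.  Deterministic given ``config.seed``.
    """
    sentences = [list(s) for s in corpus]
    if not any(sentences):
        raise ValueError("empty corpus")
    counts = Counter(t for s in sentences for t in s)
    vocab = sorted(
        (t for t, c in counts.items() if c >= config.min_count),
        key=lambda t: (-counts[t], t),
    )
    if not vocab:
        raise ValueError(
            f"no token occurs at least min_count={config.min_count} times"
        )
    index = {t: i for i, t in enumerate(vocab)}
    V, dim = len(vocab), config.dim

    # (centre, padded context) training pairs
    centers: list[int] = []
    contexts: list[list[int]] = []
    w = config.window
    for sent in sentences:
        ids = [index[t] for t in sent if t in index]
        for pos, c in enumerate(ids):
            ctx = ids[max(0, pos - w) : pos] + ids[pos + 1 : pos + 1 + w]
            if ctx:
                centers.append(c)
                contexts.append(ctx)
    if not centers:
        raise ValueError("corpus has no context windows after vocabulary pruning")
    n_pairs = len(centers)
    width = 2 * w
    ctx_mat = np.zeros((n_pairs, width), dtype=np.int64)
    ctx_mask = np.zeros((n_pairs, width), dtype=np.float64)
    for i, ctx in enumerate(contexts):
        ctx_mat[i, : len(ctx)] = ctx
        ctx_mask[i, : len(ctx)] = 1.0
    ctx_count = ctx_mask.sum(axis=1, keepdims=True)
    centers_arr = np.asarray(centers, dtype=np.int64)

    noise = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(config.seed)
    Wi = (rng.random((V, dim)) - 0.5) / dim  # input (context) vectors
    Wo = np.zeros((V, dim))  # output (centre) vectors

    B = config.batch_size
    n_batches = (n_pairs + B - 1) // B
    total_steps = config.epochs * n_batches
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n_pairs)
        for b in range(n_batches):
            sel = order[b * B : (b + 1) * B]
            lr = config.learning_rate * max(
                1.0 - step / total_steps, 1e-4
            )
            step += 1
            ctx = ctx_mat[sel]
            mask = ctx_mask[sel][..., None]
            h = (Wi[ctx] * mask).sum(axis=1) / ctx_count[sel]
            neg = rng.choice(V, size=(len(sel), config.negative), p=noise)
            tgt = np.concatenate([centers_arr[sel][:, None], neg], axis=1)
            y = np.zeros_like(tgt, dtype=np.float64)
            y[:, 0] = 1.0
            out = Wo[tgt]  # (B, 1+k, dim)
            scores = np.einsum("bd,bkd->bk", h, out)
            g = (y - _sigmoid(scores)) * lr
            dh = np.einsum("bk,bkd->bd", g, out)
            np.add.at(
                Wo,
                tgt.ravel(),
                (g[..., None] * h[:, None, :]).reshape(-1, dim),
            )
            upd = (dh / ctx_count[sel])[:, None, :] * mask
            np.add.at(Wi, ctx.ravel(), upd.reshape(-1, dim))
    return WordEmbedding(vocab, Wi)
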