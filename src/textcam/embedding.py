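"""Skip-gram word embeddings with hierarchical softmax, trained in-process.

Each token maps to a fixed-dimension vector; the pad symbol and any
out-of-vocabulary token map to the all-zeros vector. Applying the table to a
token grid yields a channels-first array (D x H x W) in which channel m holds
element m of every cell's word vector — the "image" the classifier consumes.

The trainer is a faithful reimplementation of the classic skip-gram /
hierarchical-softmax procedure (Huffman-coded output tree, reduced-window
sampling, linearly decaying learning rate) so that no external embedding
library is required.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from textcam.preprocess import DEFAULT_PAD_SYMBOL, TokenGrid

_MIN_LR_FACTOR = 1e-4  # floor = initial_lr * factor, as in the reference implementation


@dataclass(frozen=True)
class EmbedConfig:
    vector_size: int = 100
    window: int = 100
    min_count: int = 1
    epochs: int = 5
    initial_lr: float = 0.025
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.vector_size < 1:
            raise ValueError(f"vector_size must be >= 1, got {self.vector_size}")
        if self.min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {self.min_count}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")


@dataclass
class EmbeddingModel:
    """Token -> vector table with an explicit pad/OOV zero-vector rule."""

    vocabulary: dict[str, int]
    vectors: np.ndarray  # (|V|, D) float32
    zero_tokens: frozenset[str] = frozenset({DEFAULT_PAD_SYMBOL})

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def lookup(self, token: str) -> np.ndarray:
        """Vector for ``token``; zeros for the pad symbol and OOV tokens."""
        if token in self.zero_tokens:
            return np.zeros(self.dim, dtype=np.float32)
        idx = self.vocabulary.get(token)
        if idx is None:
            return np.zeros(self.dim, dtype=np.float32)
        return self.vectors[idx]

    def save_word2vec_text(self, path: str | Path) -> None:
        """Persist as the word2vec text format: header '|V| D', then one
        token and D floats per line."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocabulary)} {self.dim}\n")
            inv = sorted(self.vocabulary.items(), key=lambda kv: kv[1])
            for token, idx in inv:
                vec = " ".join(repr(float(v)) for v in self.vectors[idx])
                fh.write(f"{token} {vec}\n")

    @classmethod
    def load_word2vec_text(
        cls, path: str | Path, zero_tokens: frozenset[str] = frozenset({DEFAULT_PAD_SYMBOL})
    ) -> "EmbeddingModel":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed word2vec text header")
            n_words, dim = int(header[0]), int(header[1])
            vocab: dict[str, int] = {}
            vectors = np.zeros((n_words, dim), dtype=np.float32)
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"{path}: line {i + 2} has wrong field count")
                vocab[parts[0]] = i
                vectors[i] = np.asarray(parts[1:], dtype=np.float32)
        if len(vocab) != n_words:
            raise ValueError(f"{path}: header declares {n_words} words, found {len(vocab)}")
        return cls(vocabulary=vocab, vectors=vectors, zero_tokens=zero_tokens)


def _build_huffman(counts: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Huffman-code the vocabulary by frequency.

    Returns per-word (codes, points): ``points[i]`` are internal-node row
    indices from the root downward and ``codes[i]`` the branch (0/1) taken at
    each of those nodes.
    """
    n = len(counts)
    if n == 1:
        return [np.zeros(0, dtype=np.int64)], [np.zeros(0, dtype=np.int64)]
    count = np.empty(2 * n - 1, dtype=np.int64)
    count[:n] = counts
    count[n:] = np.iinfo(np.int64).max
    parent = np.zeros(2 * n - 1, dtype=np.int64)
    binary = np.zeros(2 * n - 1, dtype=np.int64)
    pos1, pos2 = n - 1, n
    for a in range(n - 1):
        # two smallest remaining nodes; counts[:n] must be sorted descending
        if pos1 >= 0 and count[pos1] < count[pos2]:
            min1, pos1 = pos1, pos1 - 1
        else:
            min1, pos2 = pos2, pos2 + 1
        if pos1 >= 0 and count[pos1] < count[pos2]:
            min2, pos1 = pos1, pos1 - 1
        else:
            min2, pos2 = pos2, pos2 + 1
        count[n + a] = count[min1] + count[min2]
        parent[min1] = n + a
        parent[min2] = n + a
        binary[min2] = 1
    root = 2 * n - 2
    codes, points = [], []
    for a in range(n):
        code, node_path = [], []
        b = a
        while b != root:
            code.append(binary[b])
            node_path.append(parent[b] - n)
            b = parent[b]
        codes.append(np.array(code[::-1], dtype=np.int64))
        points.append(np.array(node_path[::-1], dtype=np.int64))
    return codes, points


def train_embedding(corpus: Sequence[Sequence[str]], cfg: EmbedConfig) -> EmbeddingModel:
    """Train skip-gram/hierarchical-softmax embeddings on token sequences.

    The corpus is the raw tokenized training split (never padded/formatted);
    with ``min_count=1`` every training token enters the vocabulary. A fixed
    seed makes training fully deterministic (single worker).
    """
    cfg.validate()
    counter: Counter[str] = Counter()
    for sent in corpus:
        counter.update(sent)
    if not counter:
        raise ValueError("cannot train an embedding on an empty corpus")
    kept = [(tok, c) for tok, c in counter.items() if c >= cfg.min_count]
    if not kept:
        raise ValueError(f"no token reaches min_count={cfg.min_count}")
    # frequency-descending order (ties broken lexically) for Huffman coding
    kept.sort(key=lambda kv: (-kv[1], kv[0]))
    vocab = {tok: i for i, (tok, _) in enumerate(kept)}
    counts = np.array([c for _, c in kept], dtype=np.int64)
    n_vocab, dim = len(vocab), cfg.vector_size

    codes, points = _build_huffman(counts)

    rng = np.random.default_rng(cfg.seed)
    syn0 = ((rng.random((n_vocab, dim)) - 0.5) / dim).astype(np.float32)
    syn1 = np.zeros((n_vocab - 1 if n_vocab > 1 else 1, dim), dtype=np.float32)

    sentences = [
        np.array([vocab[t] for t in sent if t in vocab], dtype=np.int64) for sent in corpus
    ]
    sentences = [s for s in sentences if len(s) > 0]
    total_words = sum(len(s) for s in sentences) * cfg.epochs
    lr0 = cfg.initial_lr
    lr_min = lr0 * _MIN_LR_FACTOR
    processed = 0

    for _epoch in range(cfg.epochs):
        for sent in sentences:
            n = len(sent)
            reduced = rng.integers(0, cfg.window, size=n)
            for i in range(n):
                center = sent[i]
                code, point = codes[center], points[center]
                if len(code) == 0:
                    processed += 1
                    continue
                lr = max(lr_min, lr0 * (1.0 - processed / max(1, total_words)))
                w = cfg.window - int(reduced[i])
                lo, hi = max(0, i - w), min(n, i + w + 1)
                theta = syn1[point]  # (L, D) view-copy via fancy indexing
                for j in range(lo, hi):
                    if j == i:
                        continue
                    v = syn0[sent[j]]
                    f = 1.0 / (1.0 + np.exp(-np.clip(theta @ v, -6.0, 6.0)))
                    g = ((1.0 - code - f) * lr).astype(np.float32)
                    dv = g @ theta
                    theta += np.outer(g, v)
                    v += dv
                syn1[point] = theta
                processed += 1

    return EmbeddingModel(vocabulary=vocab, vectors=syn0)


def lookup(model: EmbeddingModel, token: str) -> np.ndarray:
    return model.lookup(token)


@dataclass
class EmbeddedGrid:
    """Channels-first numeric view of a token grid: values[m, j, k] is
    element m of the vector of the token at row j, column k."""

    values: np.ndarray  # (D, H, W) float32
    source: Optional[TokenGrid] = None


def embed_grid(grid: TokenGrid, model: EmbeddingModel) -> EmbeddedGrid:
    """Cell-wise embedding lookup; pad cells become all-zero columns."""
    h, w = grid.height, grid.width
    flat = grid.tokens.reshape(-1)
    out = np.zeros((h * w, model.dim), dtype=np.float32)
    cache: dict[str, np.ndarray] = {}
    for idx, tok in enumerate(flat):
        tok = str(tok)
        vec = cache.get(tok)
        if vec is None:
            vec = model.lookup(tok)
            cache[tok] = vec
        out[idx] = vec
    values = out.reshape(h, w, model.dim).transpose(2, 0, 1).copy()
    return EmbeddedGrid(values=values, source=grid)
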