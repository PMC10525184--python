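"""Shared fixtures. The expensive end-to-end synthetic experiment is
session-scoped so the acceptance and explanation tests share one training
run."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from textcam import model as mdl
from textcam.embedding import EmbedConfig, embed_grid, train_embedding
from textcam.preprocess import Document, TokenGrid, format_grid, tokenize
from textcam.synthdata import SyntheticSpec, generate_corpus


@dataclass
class EndToEndRun:
    spec: SyntheticSpec
    embedder: object
    model: object
    history: mdl.TrainHistory
    x_val: np.ndarray
    y_val: np.ndarray
    val_docs: list[Document]
    val_grids: list[TokenGrid]
    truth: dict[str, list[int]]


def corpus_to_arrays(docs, embedder):
    grids = [format_grid(tokenize(d.text)) for d in docs]
    x = np.stack([embed_grid(g, embedder).values for g in grids])
    y = np.array([d.label for d in docs], dtype=np.int64)
    return x, y, grids


@pytest.fixture(scope="session")
def e2e_run() -> EndToEndRun:
    """Scaled-down five-class experiment: 1,000 keyword-planted documents,
    16 embedding channels, 5 training epochs on CPU."""
    spec = SyntheticSpec(
        n_classes=5,
        docs_per_class=200,
        keyword_rate=0.4,
        noise_vocab_size=300,
        doc_length=(30, 60),
        seed=7,
    )
    docs, truth = generate_corpus(spec)
    train_docs, val_docs = mdl.split_dataset(docs, 0.2, seed=7)
    embedder = train_embedding(
        [tokenize(d.text) for d in train_docs],
        EmbedConfig(vector_size=16, window=5, min_count=1, epochs=2, seed=7),
    )
    x_train, y_train, _ = corpus_to_arrays(train_docs, embedder)
    x_val, y_val, val_grids = corpus_to_arrays(val_docs, embedder)
    model = mdl.build_model(mdl.ModelConfig(in_channels=16, n_classes=5), seed=7)
    model, history = mdl.train(
        model,
        (x_train, y_train),
        (x_val, y_val),
        mdl.TrainConfig(learning_rate=0.1, epochs=5, batch_size=128, seed=7),
    )
    return EndToEndRun(
        spec=spec,
        embedder=embedder,
        model=model,
        history=history,
        x_val=x_val,
        y_val=y_val,
        val_docs=val_docs,
        val_grids=val_grids,
        truth=truth,
    )


@pytest.fixture(scope="session")
def tiny_embedder():
    """A small but non-degenerate embedding model for unit tests."""
    spec = SyntheticSpec(
        n_classes=3, docs_per_class=20, keyword_rate=0.5,
        noise_vocab_size=40, doc_length=(10, 25), seed=13,
    )
    docs, _ = generate_corpus(spec)
    return train_embedding(
        [tokenize(d.text) for d in docs],
        EmbedConfig(vector_size=8, window=4, min_count=1, epochs=2, seed=13),
    )
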