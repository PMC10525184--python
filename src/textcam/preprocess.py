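"""Document tokenization and fixed-size 2D token-grid formatting.

A document is laid out as an H x W grid of tokens ("text image") filled in
row-major reading order; unused trailing cells carry a pad symbol that later
embeds to the zero vector.
"""

from __future__ import annotations

import csv
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_GRID_HEIGHT = 25
DEFAULT_GRID_WIDTH = 25
DEFAULT_PAD_SYMBOL = "#"


@dataclass(frozen=True)
class Document:
    """A single labeled (or unlabeled, for inference) text record."""

    id: str
    text: str
    label: Optional[int] = None


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenization rules. Defaults: lowercase, whitespace split, strip
    punctuation at token edges, drop empties."""

    lowercase: bool = True
    strip_punctuation: bool = True
    punctuation: str = string.punctuation


def tokenize(text: str, rules: TokenizerConfig = TokenizerConfig()) -> list[str]:
    """Split raw text into an ordered token sequence.

    Deterministic; an empty string yields an empty list.
    """
    if rules.lowercase:
        text = text.lower()
    tokens = []
    for raw in text.split():
        tok = raw.strip(rules.punctuation) if rules.strip_punctuation else raw
        if tok:
            tokens.append(tok)
    return tokens


@dataclass
class TokenGrid:
    """A document as a fixed H x W arrangement of tokens plus a pad mask.

    Invariants: exactly H*W cells; pad cells hold ``pad_symbol``; non-pad
    tokens appear in original order under row-major traversal, and no non-pad
    cell follows a pad cell in that order.
    """

    tokens: np.ndarray  # (H, W) array of str objects
    pad_mask: np.ndarray  # (H, W) bool, True = pad cell
    pad_symbol: str = DEFAULT_PAD_SYMBOL

    @property
    def height(self) -> int:
        return int(self.tokens.shape[0])

    @property
    def width(self) -> int:
        return int(self.tokens.shape[1])

    def nonpad_tokens(self) -> list[str]:
        """Non-pad tokens in row-major (reading) order."""
        flat_tok = self.tokens.reshape(-1)
        flat_pad = self.pad_mask.reshape(-1)
        return [str(t) for t, p in zip(flat_tok, flat_pad) if not p]


def format_grid(
    tokens: Sequence[str],
    height: int = DEFAULT_GRID_HEIGHT,
    width: int = DEFAULT_GRID_WIDTH,
    pad_symbol: str = DEFAULT_PAD_SYMBOL,
) -> TokenGrid:
    """Arrange a token sequence in a row-major H x W grid, padding the tail.

    Sequences longer than H*W are truncated (with a warning); the cell count
    is always exactly H*W.
    """
    if height < 1 or width < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {height}x{width}")
    n_cells = height * width
    if len(tokens) > n_cells:
        logger.warning(
            "document has %d tokens; truncating to grid capacity %d",
            len(tokens),
            n_cells,
        )
        tokens = tokens[:n_cells]
    flat = list(tokens) + [pad_symbol] * (n_cells - len(tokens))
    grid = np.array(flat, dtype=object).reshape(height, width)
    mask = np.zeros(n_cells, dtype=bool)
    mask[len(tokens):] = True
    return TokenGrid(tokens=grid, pad_mask=mask.reshape(height, width), pad_symbol=pad_symbol)


def read_corpus_csv(path: str | Path, delimiter: str = ",") -> list[Document]:
    """Read a (id, label, text) CSV/TSV corpus. Header row required."""
    docs: list[Document] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or not {"id", "label", "text"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns id,label,text; got {reader.fieldnames}")
        for row in reader:
            label = row["label"]
            docs.append(
                Document(
                    id=str(row["id"]),
                    text=row["text"],
                    label=int(label) if label not in (None, "") else None,
                )
            )
    return docs


def write_corpus_csv(docs: Iterable[Document], path: str | Path, delimiter: str = ",") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["id", "label", "text"])
        for d in docs:
            writer.writerow([d.id, "" if d.label is None else d.label, d.text])


def read_corpus_lines(path: str | Path) -> list[Document]:
    """Plain-text variant: one unlabeled document per line."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            docs.append(Document(id=str(i), text=line.rstrip("\n")))
    return docs
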