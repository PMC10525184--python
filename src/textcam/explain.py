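"""Gradient-weighted class activation mapping over the token grid.

For a chosen convolutional stage with activations A^k, the per-channel
weight for class c is the spatial mean of d(logit_c)/dA^k; the raw map is
ReLU(sum_k alpha_k A^k), which is upsampled to the H x W token grid and
min-max normalized. Every grid cell's score is then attached to its token
for heatmap and highlighted-text rendering.
"""

from __future__ import annotations

import html
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from textcam.embedding import EmbeddedGrid
from textcam.nn.autograd import Tensor
from textcam.preprocess import TokenGrid

logger = logging.getLogger(__name__)

MIN_LOCALIZABLE_EXTENT = 4  # smallest spatial side considered localizing


@dataclass(frozen=True)
class CamConfig:
    target_layer: Optional[str] = None  # None: deepest stage >= 4x4
    upsample: str = "bilinear"  # or "nearest"
    normalize: str = "minmax"

    def validate(self) -> None:
        if self.upsample not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")
        if self.normalize != "minmax":
            raise ValueError(f"unknown normalization {self.normalize!r}")


@dataclass
class ClassActivationMap:
    raw: np.ndarray  # (h, w) nonnegative, pre-upsample
    grid_scores: np.ndarray  # (H, W) in [0, 1], aligned with the token grid
    target_class: int
    alpha: np.ndarray  # (K,) per-channel weights
    target_layer: str = ""


@dataclass(frozen=True)
class TokenScore:
    token: str
    row: int
    col: int
    score: float
    is_pad: bool


@dataclass
class TokenAttribution:
    entries: list[TokenScore]

    def scores_grid(self) -> np.ndarray:
        h = max(e.row for e in self.entries) + 1
        w = max(e.col for e in self.entries) + 1
        out = np.zeros((h, w), dtype=np.float32)
        for e in self.entries:
            out[e.row, e.col] = e.score
        return out


def default_target_layer(model, input_shape: tuple[int, ...]) -> str:
    """Deepest capturable stage whose spatial map is at least 4x4 for this
    input size (localization/depth trade-off)."""
    x = Tensor(np.zeros((1,) + tuple(input_shape), dtype=np.float32))
    was_training = model.training
    model.eval()
    model.forward(x, capture=model.stage_names)
    best = model.stage_names[0]
    for name in model.stage_names:
        act = model.captured(name).data
        if min(act.shape[-2:]) >= MIN_LOCALIZABLE_EXTENT:
            best = name
    if was_training:
        model.train()
    return best


def _upsample(raw: np.ndarray, height: int, width: int, mode: str) -> np.ndarray:
    h, w = raw.shape
    if (h, w) == (height, width):
        return raw.astype(np.float64)
    rows = (np.arange(height) + 0.5) * h / height - 0.5
    cols = (np.arange(width) + 0.5) * w / width - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    order = 1 if mode == "bilinear" else 0
    return map_coordinates(raw.astype(np.float64), [rr, cc], order=order, mode="nearest")


def _minmax(scores: np.ndarray) -> np.ndarray:
    lo, hi = float(scores.min()), float(scores.max())
    if hi <= 0.0:
        return np.zeros_like(scores)
    if hi - lo < np.finfo(np.float64).tiny:
        return np.ones_like(scores)  # degenerate constant positive map
    return (scores - lo) / (hi - lo)


def compute_gradcam(
    model,
    input_grid: EmbeddedGrid | np.ndarray,
    class_id: Optional[int] = None,
    cfg: CamConfig = CamConfig(),
    grid_shape: Optional[tuple[int, int]] = None,
) -> ClassActivationMap:
    """Grad-CAM for one embedded grid and one class (default: predicted).

    Gradients are taken with respect to the pre-softmax logit of the target
    class.
    """
    cfg.validate()
    values = input_grid.values if isinstance(input_grid, EmbeddedGrid) else np.asarray(input_grid)
    if values.ndim != 3:
        raise ValueError(f"expected a (D, H, W) array, got shape {values.shape}")
    if grid_shape is None:
        grid_shape = (values.shape[1], values.shape[2])
    layer = cfg.target_layer or default_target_layer(model, values.shape)
    model.eval()
    model.zero_grad()
    x = Tensor(values[None])
    logits = model.forward(x, capture=[layer])
    if class_id is None:
        class_id = int(logits.data[0].argmax())
    if not (0 <= class_id < logits.data.shape[1]):
        raise ValueError(f"class_id {class_id} outside [0, {logits.data.shape[1]})")
    seed = np.zeros_like(logits.data)
    seed[0, class_id] = 1.0
    logits.backward(seed)
    captured = model.captured(layer)
    act = captured.data[0]
    grad = np.zeros_like(act) if captured.grad is None else captured.grad[0]
    if act.ndim == 2:  # 1D backbone: (K, L) -> treat as (K, 1, L)
        act, grad = act[:, None, :], grad[:, None, :]
    alpha = grad.mean(axis=(1, 2))
    raw = np.maximum((alpha[:, None, None] * act).sum(axis=0), 0.0)
    up = _upsample(raw, grid_shape[0], grid_shape[1], cfg.upsample)
    model.zero_grad()
    return ClassActivationMap(
        raw=raw,
        grid_scores=_minmax(up),
        target_class=class_id,
        alpha=alpha,
        target_layer=layer,
    )


def attribute_tokens(cam: ClassActivationMap, grid: TokenGrid) -> TokenAttribution:
    """Pair every grid cell's token with its activation score."""
    scores = cam.grid_scores
    if scores.shape != (grid.height, grid.width):
        raise ValueError(
            f"CAM shape {scores.shape} does not match grid {grid.height}x{grid.width}"
        )
    entries = [
        TokenScore(
            token=str(grid.tokens[r, c]),
            row=r,
            col=c,
            score=float(scores[r, c]),
            is_pad=bool(grid.pad_mask[r, c]),
        )
        for r in range(grid.height)
        for c in range(grid.width)
    ]
    return TokenAttribution(entries=entries)


def render_heatmap(cam: ClassActivationMap, path: str | Path, upscale: int = 16,
                   cmap: str = "gray") -> None:
    """Write the grid-aligned activation map as a raster image; pixel
    intensity is monotone in the score (dark = low attention)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.kron(cam.grid_scores, np.ones((upscale, upscale)))
    plt.imsave(str(path), img, cmap=cmap, vmin=0.0, vmax=1.0)


def render_highlight(
    attr: TokenAttribution,
    threshold: float = 0.5,
    quantile: Optional[float] = None,
    title: str = "Token attribution",
) -> str:
    """Reconstruct the document in reading order as standalone HTML, wrapping
    tokens scoring at or above the threshold in highlight markup whose
    opacity is proportional to the score. Pad cells are omitted.

    ``quantile`` (in [0, 1]), when given, sets the threshold at that quantile
    of the non-pad scores.
    """
    nonpad = [e for e in attr.entries if not e.is_pad]
    if quantile is not None:
        if not (0.0 <= quantile <= 1.0):
            raise ValueError("quantile must be in [0, 1]")
        threshold = float(np.quantile([e.score for e in nonpad], quantile)) if nonpad else 1.0
    parts = []
    for e in nonpad:
        word = html.escape(e.token)
        if e.score >= threshold:
            parts.append(
                f'<mark style="background-color: rgba(255, 80, 0, {e.score:.3f})" '
                f'title="score {e.score:.3f}">{word}</mark>'
            )
        else:
            parts.append(word)
    body = " ".join(parts)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{html.escape(title)}</title></head>\n"
        f"<body><p>{body}</p></body></html>\n"
    )


def attribution_to_json(attr: TokenAttribution, path: str | Path) -> None:
    payload = [
        {"token": e.token, "row": e.row, "col": e.col, "score": e.score, "is_pad": e.is_pad}
        for e in attr.entries
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
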