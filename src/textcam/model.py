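"""Classifier construction, transfer-learning surgery and SGD training.

The main classifier is an 18-layer residual network whose first convolution
is rebuilt for ``in_channels`` embedding channels and whose head is rebuilt
for ``n_classes``; interior weights may be initialized from a donor state
dict (transfer learning), in which case surgery is guaranteed to leave every
non-replaced tensor bit-identical to the donor. A LeNet-style 1D CNN
baseline shares the same training loop.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from textcam.nn import functional as F
from textcam.nn.autograd import Tensor
from textcam.nn.cnn1d import CNN1d
from textcam.nn.optim import SGD
from textcam.nn.resnet import ResNet18, adapt_for_transfer
from textcam.preprocess import Document

logger = logging.getLogger(__name__)

BACKBONES = ("resnet18", "cnn1d")


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int
    n_classes: int
    backbone: str = "resnet18"
    pretrained: bool = False
    fine_tune_io: bool = True
    seq_len: int = 625  # cnn1d only

    def validate(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 128
    epochs: int = 25
    seed: Optional[int] = None
    val_fraction: float = 0.2

    def validate(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class Prediction:
    logits: np.ndarray
    probabilities: np.ndarray
    predicted_class: int


@dataclass
class TrainHistory:
    """Per-iteration training metrics and per-epoch validation metrics."""

    iter_loss: list[float] = field(default_factory=list)
    iter_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    iterations_per_epoch: int = 0
    best_epoch: int = -1

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("iteration,train_loss,train_acc\n")
            for i, (l, a) in enumerate(zip(self.iter_loss, self.iter_acc)):
                fh.write(f"{i},{l},{a}\n")
            fh.write("epoch,val_loss,val_acc\n")
            for e, (l, a) in enumerate(zip(self.val_loss, self.val_acc)):
                fh.write(f"{e},{l},{a}\n")


def split_dataset(
    docs: Sequence[Document], val_fraction: float, seed: Optional[int] = None
) -> tuple[list[Document], list[Document]]:
    """Disjoint, exhaustive, class-stratified train/validation split."""
    if not (0.0 < val_fraction < 1.0):
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    by_class: dict[int, list[int]] = {}
    for i, d in enumerate(docs):
        if d.label is None:
            raise ValueError(f"document {d.id!r} has no label; cannot stratify")
        by_class.setdefault(d.label, []).append(i)
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        n_val = int(round(len(idx) * val_fraction))
        n_val = min(n_val, len(idx) - 1)  # keep at least one training doc per class
        val_idx.extend(idx[:n_val].tolist())
    val_set = set(val_idx)
    train = [docs[i] for i in range(len(docs)) if i not in val_set]
    val = [docs[i] for i in range(len(docs)) if i in val_set]
    return train, val


def build_model(
    cfg: ModelConfig,
    donor_state: Optional[dict[str, np.ndarray]] = None,
    seed: Optional[int] = None,
):
    """Construct the classifier described by ``cfg``.

    With ``pretrained=True`` a donor state dict must be supplied; its
    interior weights are transplanted while the replaced input convolution
    and output head keep their fresh initialization. The deliberately
    mismatched ablation mode (``pretrained=True, fine_tune_io=False`` with a
    non-matching channel count) is constructed but flagged via
    ``model.ablation_frozen`` and receives no parameter updates in
    :func:`train`.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    if cfg.backbone == "cnn1d":
        model = CNN1d(cfg.in_channels, cfg.n_classes, seq_len=cfg.seq_len, rng=rng)
        model.ablation_frozen = False
        return model
    model = ResNet18(cfg.in_channels, cfg.n_classes, rng=rng)
    model.ablation_frozen = False
    if cfg.pretrained:
        if donor_state is None:
            raise ValueError(
                "pretrained=True requires donor weights (a state dict or checkpoint); "
                "none are bundled with the package"
            )
        loaded = adapt_for_transfer(model, donor_state)
        logger.info("transfer surgery loaded %d interior tensors", len(loaded))
        if not cfg.fine_tune_io:
            # Mismatched ablation mode: pretrained interior, input/output
            # layers neither matched to the donor nor trained.
            model.ablation_frozen = True
            logger.warning(
                "pretrained backbone without input/output fine-tuning: "
                "this configuration is only meaningful for the ablation study "
                "and is expected to perform at chance"
            )
    return model


def _forward(model, x: Tensor) -> Tensor:
    return model.forward(x)


def evaluate(model, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> tuple[float, float]:
    """Mean cross-entropy loss and accuracy in evaluation mode."""
    model.eval()
    n = len(x)
    losses, correct = [], 0
    for start in range(0, n, batch_size):
        xb = Tensor(x[start : start + batch_size])
        yb = y[start : start + batch_size]
        logits = _forward(model, xb)
        loss = F.cross_entropy(logits, yb)
        losses.append(float(loss.data) * len(yb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    return sum(losses) / n, correct / n


def train(
    model,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
):
    """SGD training with per-iteration train metrics, per-epoch validation
    metrics and best-validation-accuracy checkpointing.

    Returns ``(model, history)`` with the best checkpoint restored in-place.
    """
    cfg.validate()
    x_train, y_train = train_data
    x_val, y_val = val_data
    if len(x_train) == 0:
        raise ValueError("training data is empty")
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    frozen = bool(getattr(model, "ablation_frozen", False))
    optimizer = SGD(
        model.parameters(), lr=cfg.learning_rate,
        momentum=cfg.momentum, weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(cfg.seed)
    n = len(x_train)
    iters = math.ceil(n / cfg.batch_size)
    history = TrainHistory(iterations_per_epoch=iters)
    best_acc, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        for it in range(iters):
            idx = order[it * cfg.batch_size : (it + 1) * cfg.batch_size]
            xb = Tensor(x_train[idx])
            yb = y_train[idx]
            logits = _forward(model, xb)
            loss = F.cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, iteration {it}: {loss.data!r}"
                )
            history.iter_loss.append(float(loss.data))
            history.iter_acc.append(float((logits.data.argmax(axis=1) == yb).mean()))
            if not frozen:
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
        val_loss, val_acc = evaluate(model, x_val, y_val, batch_size=cfg.batch_size)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        logger.info("epoch %d: val_loss=%.4f val_acc=%.4f", epoch, val_loss, val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
            history.best_epoch = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def predict(model, grid) -> Prediction:
    """Run the classifier on one embedded grid (or raw channels-first array)."""
    values = grid.values if hasattr(grid, "values") else np.asarray(grid, dtype=np.float32)
    model.eval()
    logits = _forward(model, Tensor(values[None])).data[0]
    probs = F.softmax(logits)
    return Prediction(
        logits=logits,
        probabilities=probs,
        predicted_class=int(logits.argmax()),
    )


def save_checkpoint(model, cfg: ModelConfig, path: str | Path) -> None:
    meta = json.dumps(
        {**cfg.__dict__, "format": 1},
    )
    state = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
    meta.pop("format", None)
    cfg = ModelConfig(**meta)
    # rebuild without donor weights, then overwrite everything from the file
    build_cfg = ModelConfig(**{**meta, "pretrained": False})
    model = build_model(build_cfg, seed=0)
    model.load_state_dict(state)
    model.ablation_frozen = cfg.pretrained and not cfg.fine_tune_io
    return model, cfg
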