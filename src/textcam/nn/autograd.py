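"""A minimal reverse-mode automatic-differentiation engine over numpy arrays.

Only the operations required by the classifiers live here (dense/conv
layers, batch norm, pooling, ReLU, residual adds, softmax cross-entropy).
Every operation returns a new :class:`Tensor` holding a closure that
back-propagates an upstream gradient to its parents; ``Tensor.backward``
topologically sorts the graph and runs those closures. Gradients are kept on
every interior node, which is what lets Grad-CAM read d(logit)/d(activation)
at an arbitrary captured layer.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def needs_grad(self) -> bool:
        """True if a gradient should flow into this node."""
        return self.requires_grad or self._backward is not None

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float32)
        else:
            self.grad = self.grad + grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Back-propagate from this node.

        ``grad`` seeds the output gradient; it defaults to 1 for scalars
        (e.g. a loss). Grad-CAM seeds a one-hot over logits instead.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.needs_grad for p in parents):
        out._parents = parents
        out._backward = backward
    return out
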