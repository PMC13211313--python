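"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the primitives the
transformer needs: broadcast arithmetic, linear layers, batched matrix
products, softmax (with additive masks), layer normalization, ReLU,
embedding lookup, token gather/concat, and a fused masked cross-entropy.
Everything is float32 and vectorized; gradients are accumulated by a
topological backward sweep from the loss.

Inference code wraps calls in :func:`no_grad` to skip graph building.
"""

from __future__ import annotations

import contextlib
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "mul",
    "scale",
    "linear",
    "bmm",
    "reshape",
    "transpose",
    "softmax",
    "relu",
    "layer_norm",
    "embedding",
    "take_tokens",
    "concat",
    "cross_entropy_masked",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        track = _GRAD_ENABLED and (requires_grad or any(p.requires_grad for p in parents))
        self.requires_grad = track
        self._parents = parents if track else ()
        self._backward = backward if track else None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: List[Tensor] = []
        visited = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a.accumulate(g * s)

    return Tensor(a.data * s, parents=(a,), backward=backward)


def linear(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """``y = x @ w + b`` with ``x`` of shape (..., D) and ``w`` (D, K)."""
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        if x.requires_grad:
            x.accumulate(g @ w.data.T)
        if w.requires_grad:
            g2 = g.reshape(-1, g.shape[-1])
            x2 = x.data.reshape(-1, x.data.shape[-1])
            w.accumulate(x2.T @ g2)
        if b is not None and b.requires_grad:
            b.accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def bmm(a: Tensor, b: Tensor) -> Tensor:
    """Batched matmul with identical leading batch dimensions."""
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            b.accumulate(np.swapaxes(a.data, -1, -2) @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def reshape(x: Tensor, shape: Tuple[int, ...]) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.data.shape))

    return Tensor(x.data.reshape(shape), parents=(x,), backward=backward)


def transpose(x: Tensor, axes: Tuple[int, ...]) -> Tensor:
    inv = tuple(np.argsort(axes))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g.transpose(inv))

    return Tensor(x.data.transpose(axes), parents=(x,), backward=backward)


def softmax(x: Tensor, additive_mask: Optional[np.ndarray] = None) -> Tensor:
    """Softmax over the last axis, with an optional additive (mask) term."""
    z = x.data if additive_mask is None else x.data + additive_mask
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=-1, keepdims=True)
            x.accumulate((g - dot) * s)

    return Tensor(s, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).reshape(-1, g.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta.accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            d = g * gamma.data
            n = x.data.shape[-1]
            dx = (
                d - d.mean(axis=-1, keepdims=True)
                - xhat * (d * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x.accumulate(dx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]``; gradient scatter-adds into the table."""
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def backward(g):
        if table.requires_grad:
            grad = np.zeros_like(table.data)
            np.add.at(grad, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
            table.accumulate(grad)

    return Tensor(out_data, parents=(table,), backward=backward)


def take_tokens(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select tokens along axis 1: ``x[b, idx[b], :]`` for each batch row.

    ``x`` has shape (B, L, D) and ``idx`` (B, K); used for patch dropout
    survivor selection.
    """
    idx = np.asarray(idx)
    batch = np.arange(x.data.shape[0])[:, None]
    out_data = x.data[batch, idx]

    def backward(g):
        if x.requires_grad:
            grad = np.zeros_like(x.data)
            np.add.at(grad, (batch, idx), g)
            x.accumulate(grad)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(part)

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def cross_entropy_masked(
    logits: Tensor, targets: np.ndarray, mask: np.ndarray,
    label_smoothing: float = 0.0,
) -> Tensor:
    """Mean token-level cross-entropy over masked positions.

    ``logits`` (B, L, V), ``targets`` (B, L) int ids, ``mask`` (B, L)
    with 1 at supervised positions (SMILES tokens + EOS) and 0 at
    formula-prefix and padding positions, whose gradient is exactly zero.
    With ``label_smoothing`` epsilon, the target distribution mixes the
    one-hot label with the uniform distribution over the vocabulary.
    """
    targets = np.asarray(targets)
    mask = np.asarray(mask, dtype=np.float32)
    eps = float(label_smoothing)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    b_idx = np.arange(z.shape[0])[:, None]
    l_idx = np.arange(z.shape[1])[None, :]
    nll = logsumexp - z[b_idx, l_idx, targets]
    if eps > 0:
        nll = (1 - eps) * nll + eps * (logsumexp - z.mean(axis=-1))
    denom = max(mask.sum(), 1.0)
    loss = float((nll * mask).sum() / denom)

    def backward(g):
        if logits.requires_grad:
            p = np.exp(z - logsumexp[..., None])
            p[b_idx, l_idx, targets] -= 1.0 - eps
            if eps > 0:
                p -= eps / z.shape[-1]
            logits.accumulate(g * p * (mask[..., None] / denom))

    return Tensor(np.float32(loss), parents=(logits,), backward=backward)
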