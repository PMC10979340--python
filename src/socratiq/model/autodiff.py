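"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based scalar-loss autodiff sufficient for the recurrent
classifier in this package: dense matmul, elementwise arithmetic,
sigmoid/tanh nonlinearities, concatenation, row stacking/indexing and a
softmax cross-entropy loss. Graphs are built dynamically per example
(training uses batch size 1), and `backward()` runs a topological sweep
accumulating gradients into `Tensor.grad`.

This is not a general framework: no broadcasting beyond row-vector bias
addition, no higher-order gradients, float64 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softmax_cross_entropy", "softmax"]


class Tensor:
    """A node in the computation graph wrapping a 2-d float64 array."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- ops ---------------------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    def __add__(self, other: "Tensor") -> "Tensor":
        # supports equal shapes and (n,k)+(1,k) row-bias broadcasting
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    def scale(self, c: float) -> "Tensor":
        out = Tensor(self.data * c, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * c)

        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y * y))

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = bw
        return out

    def concat(self, other: "Tensor") -> "Tensor":
        """Concatenate along axis 1 (feature axis)."""
        k = self.data.shape[1]
        out = Tensor(np.concatenate([self.data, other.data], axis=1), parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g[:, :k])
            if other.requires_grad:
                other._accumulate(g[:, k:])

        out._backward = bw
        return out

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; caller skips this entirely in eval mode."""
        if rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def mean_rows(self) -> "Tensor":
        """Mean over axis 0, keeping a (1,k) row."""
        n = self.data.shape[0]
        out = Tensor(self.data.mean(axis=0, keepdims=True), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.repeat(g, n, axis=0) / n)

        out._backward = bw
        return out

    def rows(self, indices) -> "Tensor":
        """Gather rows by integer index (embedding lookup); gradients
        scatter-add back into the source rows."""
        idx = np.asarray(indices, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bw
        return out

    def row(self, i: int) -> "Tensor":
        out = Tensor(self.data[i : i + 1], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[i : i + 1] = g
                self._accumulate(full)

        out._backward = bw
        return out

    # -- graph traversal ---------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recurrent graphs get deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    # only (1,k) <- (n,k) broadcasting is produced by __add__/__mul__
    return g.sum(axis=0, keepdims=True)


def stack_rows(rows: list[Tensor]) -> Tensor:
    """Stack (1,k) tensors into an (n,k) tensor."""
    out = Tensor(np.concatenate([r.data for r in rows], axis=0), parents=tuple(rows))

    def bw(g):
        for i, r in enumerate(rows):
            if r.requires_grad:
                r._accumulate(g[i : i + 1])

    out._backward = bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, target: int) -> Tensor:
    """Cross-entropy of a (1,k) logit row against an integer class."""
    p = softmax(logits.data)
    loss_val = -np.log(max(p[0, target], 1e-300))
    out = Tensor(np.array([[loss_val]]), parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[0, target] -= 1.0
            logits._accumulate(g[0, 0] * grad)

    out._backward = bw
    return out
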