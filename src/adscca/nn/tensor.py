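"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's two trainable models (the deep sparse-CCA network and the
bidirectional recurrent Cox head) optimise custom composite losses, so the
gradients are obtained by reverse-mode differentiation on a dynamically
built computation graph.  Only the operations those models need are
implemented; everything is float64 and single-threaded, which keeps runs
bit-reproducible from a seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were 1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the computation graph.

    Parameters
    ----------
    data : array-like
        Value of the node (converted to float64).
    requires_grad : bool
        Whether gradients should flow into this node.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    # -- graph construction helpers -------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + g

    @staticmethod
    def _lift(x: Union["Tensor", ArrayLike]) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._backward = backward
            out._parents = tuple(parents)
        return out

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1))

        return self._make(a.data ** exponent, (a,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            g = np.asarray(g)
            if a.requires_grad:
                if b.data.ndim == 1 and a.data.ndim == 2:
                    a._accumulate(np.outer(g, b.data))
                elif a.data.ndim == 1:
                    a._accumulate(g @ b.data.T if b.data.ndim == 2 else g * b.data)
                else:
                    a._accumulate(g @ b.data.T)
            if b.requires_grad:
                if a.data.ndim == 2 and b.data.ndim == 1:
                    b._accumulate(a.data.T @ g)
                elif a.data.ndim == 1 and b.data.ndim == 2:
                    b._accumulate(np.outer(a.data, g))
                elif a.data.ndim == 1 and b.data.ndim == 1:
                    b._accumulate(g * a.data)
                else:
                    b._accumulate(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * (1.0 - out_data ** 2))

        return self._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        a = self
        out_data = np.logaddexp(0.0, a.data)
        sig = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * sig)

        return self._make(out_data, (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)  # subgradient 0 at 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * sign)

        return self._make(np.abs(a.data), (a,), backward)

    # -- reductions and shape ops ----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        a = self
        old_shape = a.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(np.asarray(g).reshape(old_shape))

        return self._make(a.data.reshape(*shape), (a,), backward)

    @property
    def T(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(np.asarray(g).T)

        return self._make(a.data.T, (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)

        return self._make(a.data[idx], (a,), backward)

    # -- graph traversal --------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this node (must be scalar unless grad given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate state so big graphs do not pin memory
                node._backward = None
                node._parents = ()


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Differentiable concatenation along `axis`."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        g = np.asarray(g)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Differentiable stack along a new axis."""
    tensors = [Tensor._lift(t) for t in tensors]

    def backward(g):
        g = np.asarray(g)
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    data = np.stack([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tensors, backward)


def mean_pearson(tx: Tensor, ty: Tensor, eps: float = 1e-8) -> Tensor:
    """Pearson correlation of two 1-D tensors, guarded against zero variance."""
    n = tx.data.size
    cx = tx - tx.mean()
    cy = ty - ty.mean()
    cov = (cx * cy).sum() / float(n)
    vx = (cx * cx).sum() / float(n)
    vy = (cy * cy).sum() / float(n)
    return cov / ((vx * vy + eps) ** 0.5)


def variance(t: Tensor) -> Tensor:
    """Population variance of a 1-D tensor."""
    c = t - t.mean()
    return (c * c).sum() / float(t.data.size)


def gradcheck(fn: Callable[..., Tensor], inputs: Iterable[Tensor],
              eps: float = 1e-6, rtol: float = 1e-4, atol: float = 1e-6) -> bool:
    """Compare reverse-mode gradients of scalar `fn(*inputs)` against
    central finite differences. Raises AssertionError on mismatch."""
    inputs = list(inputs)
    out = fn(*inputs)
    for t in inputs:
        t.grad = None
    out.backward()
    analytic = [np.zeros_like(t.data) if t.grad is None else t.grad.copy()
                for t in inputs]
    for t, ga in zip(inputs, analytic):
        flat = t.data.ravel()
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(*inputs).item()
            flat[i] = orig - eps
            lo = fn(*inputs).item()
            flat[i] = orig
            num[i] = (hi - lo) / (2 * eps)
        num = num.reshape(t.data.shape)
        if not np.allclose(ga, num, rtol=rtol, atol=atol):
            raise AssertionError(
                f"gradcheck failed: max abs diff {np.max(np.abs(ga - num)):.3g}")
    return True
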