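"""Minimal reverse-mode automatic differentiation on numpy arrays.

The variational objective used here has to be differentiated with respect
to variational parameters *and* the weights of three small fully-connected
networks. This module provides the small set of tensor operations that the
objective needs (broadcasted arithmetic, batched matmul, exp/log/tanh/
softplus, reductions, indexing, concatenation), each with an exact
vector-Jacobian product, plus an Adam optimizer.

Gradients are accumulated by a topological-order backward sweep; broadcast
semantics follow numpy, with gradients summed back over broadcast axes.
All gradient rules are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph.

    Parameters created with ``requires_grad=True`` accumulate ``.grad``
    after ``backward()`` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None  # callable(out_grad) -> tuple of parent grads

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data - other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)),
        )

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor._make(
            self.data**exponent,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data

        def vjp(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a_ = a[None, :]
                ga = (g[..., None, :] @ np.swapaxes(b, -1, -2))[..., 0, :]
            else:
                ga = g @ np.swapaxes(b, -1, -2)
            if b.ndim == 1:
                gb = np.swapaxes(a if a.ndim > 1 else a[None, :], -1, -2) @ g[..., None]
                gb = gb[..., 0]
            else:
                ga_in = a if a.ndim > 1 else a[None, :]
                gl = g if a.ndim > 1 else g[..., None, :]
                gb = np.swapaxes(ga_in, -1, -2) @ gl
            return (
                _unbroadcast(np.asarray(ga), self.shape),
                _unbroadcast(np.asarray(gb), other.shape),
            )

        return Tensor._make(out, (self, other), vjp)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1.0 - out**2),))

    def softplus(self):
        # numerically stable log(1 + e^x)
        out = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * sig,))

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            if not keepdims:
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in ((axis,) if np.isscalar(axis) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def __getitem__(self, idx):
        out = self.data[idx]

        def vjp(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out, (self,), vjp)

    def take(self, indices, axis: int = 0):
        """Gather rows along `axis` (with repetition allowed)."""
        indices = np.asarray(indices)
        out = np.take(self.data, indices, axis=axis)

        def vjp(g):
            full = np.zeros_like(self.data)
            sl = [slice(None)] * self.ndim
            # scatter-add per unique index to handle repeats
            np.add.at(full, tuple(sl[:axis]) + (indices,), g)
            return (full,)

        return Tensor._make(out, (self,), vjp)

    # -- backward ----------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tuple(tensors), vjp)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64) for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64) for v in state["v"]]


class SGD:
    """Vanilla stochastic gradient descent (no momentum)."""

    def __init__(self, params, lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def state_dict(self):
        return {}

    def load_state_dict(self, state):
        pass
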