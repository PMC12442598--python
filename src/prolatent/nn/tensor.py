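"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the models in this package: broadcasting
arithmetic, matmul, reductions, shape ops, row gathers (embeddings) and a
1-D unfold (convolutions).  Gradients are accumulated into ``.grad`` by a
topological-order backward pass; every primitive is finite-difference
checked in the test suite.
"""

from __future__ import annotations

import numpy as np

#: Global float dtype for all tensors.  float64 gives the accuracy the
#: finite-difference gradient checks need; float32 roughly halves training
#: time and is the default for the training loops.
DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    global DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    DTYPE = np.dtype(dtype).type


class default_dtype:
    """Context manager pinning the tensor dtype (used by training loops)."""

    def __init__(self, dtype):
        self.dtype = dtype

    def __enter__(self):
        global DTYPE
        self._saved = DTYPE
        set_default_dtype(self.dtype)

    def __exit__(self, *exc):
        global DTYPE
        DTYPE = self._saved


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
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
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            if node._parents and node is not self:
                # interior node: free its grad and unlink so refcounting can
                # reclaim the graph immediately (no gc cycles)
                node.grad = None
                node._backward = None
                node._parents = ()

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        if a.ndim > 2 and b.ndim == 2:
            # stacked-batch linear: one flat BLAS call instead of a gufunc loop
            val = (np.ascontiguousarray(a).reshape(-1, a.shape[-1]) @ b)
            val = val.reshape(a.shape[:-1] + (b.shape[1],))
        else:
            val = np.ascontiguousarray(a) @ np.ascontiguousarray(b)
        out = Tensor(val, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                if b.ndim == 2:
                    ga = (np.ascontiguousarray(g).reshape(-1, b.shape[1]) @ b.T)
                    ga = ga.reshape(a.shape)
                else:
                    bt = np.ascontiguousarray(np.swapaxes(b, -1, -2))
                    ga = _unbroadcast(g @ bt, a.shape)
                self._accum(ga)
            if other.requires_grad:
                if a.ndim >= 2 and b.ndim == 2:
                    af = np.ascontiguousarray(a).reshape(-1, a.shape[-1])
                    gb = af.T @ np.ascontiguousarray(g).reshape(-1, g.shape[-1])
                else:
                    at = np.ascontiguousarray(np.swapaxes(a, -1, -2))
                    gb = _unbroadcast(at @ g, b.shape)
                other._accum(gb)
        out._backward = bwd
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        val = np.exp(self.data)   # captured by value: no closure->output cycle
        out = Tensor(val, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * val)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1 - val ** 2))
        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        out._backward = bwd
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * val * (1 - val))
        out._backward = bwd
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:       # unique positions: direct assignment
                    full[idx] = g
                else:
                    np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# free functions


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bwd
    return out


def take_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Gather ``table[ids]`` (embedding lookup); scatter-add on backward.

    For small tables the scatter-add is realized as a one-hot matmul,
    which hits BLAS instead of numpy's slow ``ufunc.at`` path.
    """
    ids = np.asarray(ids)
    out = Tensor(table.data[ids], parents=(table,))
    n_rows = table.data.shape[0]

    def bwd(g):
        if not table.requires_grad:
            return
        flat_ids = ids.ravel()
        g2 = np.ascontiguousarray(g).reshape(flat_ids.size, -1)
        if n_rows <= 4096:
            onehot = np.zeros((flat_ids.size, n_rows), dtype=g2.dtype)
            onehot[np.arange(flat_ids.size), flat_ids] = 1.0
            table._accum(onehot.T @ g2)
        else:
            full = np.zeros_like(table.data)
            np.add.at(full, flat_ids, g2)
            table._accum(full)
    out._backward = bwd
    return out


def unfold1d(x: Tensor, kernel: int, pad: int) -> Tensor:
    """Sliding windows over the last axis: (..., L) -> (..., L_out, kernel).

    Zero padding of ``pad`` on each side; L_out = L + 2*pad - kernel + 1.
    """
    L = x.data.shape[-1]
    pads = [(0, 0)] * (x.data.ndim - 1) + [(pad, pad)]
    xp = np.pad(x.data, pads)
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=-1)
    out = Tensor(win.copy(), parents=(x,))
    L_out = win.shape[-2]

    def bwd(g):
        if not x.requires_grad:
            return
        gp = np.zeros(x.data.shape[:-1] + (L + 2 * pad,))
        for k in range(kernel):  # overlap pattern is fixed: k shifted adds
            gp[..., k:k + L_out] += g[..., :, k]
        x._accum(gp[..., pad:pad + L] if pad else gp)
    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, stable
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
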