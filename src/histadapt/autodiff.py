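"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Provides exactly the operations the 2.5D patch network and its losses need:
same-padding 2D convolution (via im2col), dense layers, ReLU, concatenation,
fused softmax cross-entropy, and a log-cosh distance to a constant tensor
(the stop-gradient side of histogram alignment).  Parameters are float32;
losses accumulate in float64.

The design is deliberately minimal: stride-1 convolutions only, no broadcasting
beyond bias addition, scalar results for losses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "conv2d", "dense", "relu", "concat",
           "softmax_cross_entropy", "logcosh_to_const", "scalar_sum", "softmax"]


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p, _ in parents)
        # parents: sequence of (tensor, grad_fn) with grad_fn(out_grad) -> parent grad
        self._parents = tuple((p, fn) for p, fn in parents if p.requires_grad)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data, dtype=np.float64)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, grad_fn in node._parents:
                g = grad_fn(node.grad)
                if parent.grad is None:
                    dtype = parent.data.dtype if parent.data.dtype == np.float32 else np.float64
                    parent.grad = np.zeros(parent.data.shape, dtype=dtype)
                parent.grad += g

    # scalar arithmetic (used to combine loss terms)
    def __add__(self, other: "Tensor") -> "Tensor":
        if not isinstance(other, Tensor):
            other = Tensor(np.asarray(other, dtype=self.data.dtype))
        if self.data.shape != other.data.shape:
            raise ValueError("Tensor addition requires matching shapes")
        return Tensor(self.data + other.data,
                      parents=[(self, lambda g: g), (other, lambda g: g)])

    def __mul__(self, scale: float) -> "Tensor":
        scale = float(scale)
        return Tensor(self.data * scale, parents=[(self, lambda g: g * scale)])

    __rmul__ = __mul__


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) with same zero padding, stride 1."""
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c * k * k, h * w), dtype=x.dtype)
    view = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            view[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
    return cols


def _col2im(cols: np.ndarray, x_shape, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add back to image layout)."""
    n, c, h, w = x_shape
    pad = k // 2
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + h, j:j + w] += cols[:, :, i, j]
    return out[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, same-padding convolution: x (N,C,H,W), w (O,C,k,k), b (O,)."""
    n, c, h, wd = x.data.shape
    o, c2, k, k2 = w.data.shape
    if c != c2 or k != k2:
        raise ValueError("kernel shape incompatible with input")
    cols = _im2col(x.data, k)                        # (N, C*k*k, H*W)
    wmat = w.data.reshape(o, c * k * k)
    out = np.matmul(wmat, cols)                      # batched BLAS -> (N, O, H*W)
    out += b.data[None, :, None]
    out = out.reshape(n, o, h, wd).astype(np.float32, copy=False)

    def grad_x(g):
        g2 = np.asarray(g.reshape(n, o, h * wd), dtype=np.float32)
        dcols = np.matmul(wmat.T, g2)
        return _col2im(dcols, (n, c, h, wd), k)

    def grad_w(g):
        g2 = np.asarray(g.reshape(n, o, h * wd), dtype=np.float32)
        dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
        return dw.reshape(o, c, k, k)

    def grad_b(g):
        return g.reshape(n, o, h * wd).sum(axis=(0, 2))

    return Tensor(out, parents=[(x, grad_x), (w, grad_w), (b, grad_b)])


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine layer: x (N, F) @ w (F, U) + b (U,)."""
    out = (x.data @ w.data + b.data).astype(np.float32)
    return Tensor(out, parents=[
        (x, lambda g: g @ w.data.T),
        (w, lambda g: x.data.T @ g),
        (b, lambda g: g.sum(axis=0)),
    ])


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(np.maximum(x.data, 0), parents=[(x, lambda g: g * mask)])


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    shape = x.data.shape
    return Tensor(x.data.reshape(n, -1),
                  parents=[(x, lambda g: g.reshape(shape))])


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along axis 1."""
    data = np.concatenate([t.data for t in tensors], axis=1)
    parents = []
    start = 0
    for t in tensors:
        width = t.data.shape[1]
        sl = slice(start, start + width)
        parents.append((t, lambda g, sl=sl: g[:, sl]))
        start += width
    return Tensor(data, parents=parents)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy with integer labels, fused with softmax."""
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must be a vector matching the batch size")
    p = softmax(logits.data.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()

    def grad(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        return g * d / n

    return Tensor(np.asarray(loss), parents=[(logits, grad)])


def logcosh_to_const(a: Tensor, const: np.ndarray) -> Tensor:
    """Mean log-cosh distance between ``a`` and a constant (detached) tensor.

    Computed stably as |d| + log1p(exp(-2|d|)) - log 2; the gradient flows
    only into ``a`` (the constant side is a stored, stop-gradient matrix).
    """
    c = np.asarray(const)
    if c.shape != a.data.shape:
        raise ValueError("shape mismatch in log-cosh distance")
    d = a.data.astype(np.float64) - c.astype(np.float64)
    ad = np.abs(d)
    val = (ad + np.log1p(np.exp(-2.0 * ad)) - np.log(2.0)).mean()
    size = d.size

    def grad(g):
        return g * np.tanh(d) / size

    return Tensor(np.asarray(val), parents=[(a, grad)])


def scalar_sum(terms: list[Tensor]) -> Tensor:
    """Sum of scalar loss terms."""
    if not terms:
        raise ValueError("need at least one term")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


class Adam:
    """Adaptive-moment optimiser over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]
        self._v = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
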