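"""Minimal define-by-run autodiff engine for small fully convolutional networks.

Implements exactly the primitives the spot-detection network needs — 3x3 and
1x1 convolutions in NHWC layout, 2x2 max-pooling, nearest-neighbour
upsampling, channel concatenation, squeeze-and-excitation gating, spatial
dropout, sigmoid/ReLU — plus the dice and masked-offset losses and an
Adam/AMSGrad optimizer.  Forward passes build a graph of ``Tensor`` nodes;
``Tensor.backward`` runs reverse-mode accumulation over a topological sort.

All array data is float32; convolutions are evaluated as nine shifted
matrix products, which keeps memory low and lets BLAS do the heavy lifting.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Adam",
    "conv3x3",
    "conv1x1",
    "maxpool2",
    "upsample2",
    "concat",
    "relu",
    "sigmoid",
    "global_avg_pool",
    "dense",
    "channel_gate",
    "spatial_dropout",
    "dice_loss_op",
    "offset_rmse_op",
    "add_scaled",
    "slice_channels",
]


class Tensor:
    """A node in the computation graph: an ndarray plus backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def item(self):
        return float(self.data)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def conv3x3(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Same-padded 3x3 convolution.  x: (N,H,W,Ci), w: (3,3,Ci,Co), b: (Co,)."""
    n, h, wd, ci = x.data.shape
    co = w.data.shape[-1]
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.empty((n, h, wd, co), dtype=np.float32)
    out[:] = b.data
    for i in range(3):
        for j in range(3):
            out += xp[:, i : i + h, j : j + wd, :] @ w.data[i, j]

    def bwd(g):
        if w.requires_grad:
            wg = np.empty_like(w.data)
            for i in range(3):
                for j in range(3):
                    wg[i, j] = np.tensordot(
                        xp[:, i : i + h, j : j + wd, :], g, axes=([0, 1, 2], [0, 1, 2])
                    )
            w._accumulate(wg)
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(3):
                for j in range(3):
                    gxp[:, i : i + h, j : j + wd, :] += g @ w.data[i, j].T
            x._accumulate(gxp[:, 1 : h + 1, 1 : wd + 1, :])

    return Tensor(out, (x, w, b), bwd)


def conv1x1(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Pointwise convolution.  w: (Ci,Co)."""
    out = x.data @ w.data + b.data

    def bwd(g):
        if w.requires_grad:
            w._accumulate(
                np.tensordot(x.data, g, axes=([0, 1, 2], [0, 1, 2]))
            )
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            x._accumulate(g @ w.data.T)

    return Tensor(out, (x, w, b), bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2.  First-occurrence argmax on ties."""
    n, h, w, c = x.data.shape
    h2, w2 = h // 2, w // 2
    r = (
        x.data.reshape(n, h2, 2, w2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h2, w2, c, 4)
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(n, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )
        x._accumulate(gx)

    return Tensor(out, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    n, h, w, c = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))

    return Tensor(out, (x,), bwd)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    ca = a.data.shape[-1]
    out = np.concatenate([a.data, b.data], axis=-1)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g[..., :ca])
        if b.requires_grad:
            b._accumulate(g[..., ca:])

    return Tensor(out, (a, b), bwd)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.where(x.data > 0, g, 0.0))

    return Tensor(out, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    # overflow-safe logistic: exp of a non-positive argument only
    z = np.exp(-np.abs(x.data))
    out = np.where(x.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * out * (1.0 - out))

    return Tensor(out, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,H,W,C) -> (N,C) spatial mean (the 'squeeze')."""
    n, h, w, c = x.data.shape
    out = x.data.mean(axis=(1, 2))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(
                np.broadcast_to(g[:, None, None, :] / (h * w), x.data.shape)
            )

    return Tensor(out, (x,), bwd)


def dense(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """(N,Ci) @ (Ci,Co) + (Co,)."""
    out = x.data @ w.data + b.data

    def bwd(g):
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
            b._accumulate(g.sum(axis=0))
        if x.requires_grad:
            x._accumulate(g @ w.data.T)

    return Tensor(out, (x, w, b), bwd)


def channel_gate(x: Tensor, gate: Tensor) -> Tensor:
    """Rescale feature maps by per-channel gates (the 'excitation').

    x: (N,H,W,C), gate: (N,C).
    """
    out = x.data * gate.data[:, None, None, :]

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * gate.data[:, None, None, :])
        if gate.requires_grad:
            gate._accumulate((g * x.data).sum(axis=(1, 2)))

    return Tensor(out, (x, gate), bwd)


def spatial_dropout(x: Tensor, rate: float, rng: np.random.Generator,
                    training: bool) -> Tensor:
    """Zero whole feature maps with probability ``rate`` (inverted scaling)."""
    if not training or rate <= 0.0:
        return x
    n, _, _, c = x.data.shape
    keep = (rng.random((n, 1, 1, c)) >= rate).astype(np.float32) / (1.0 - rate)
    out = x.data * keep

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return Tensor(out, (x,), bwd)


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    """View of channels [start:stop) along the last axis."""
    out = x.data[..., start:stop]

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[..., start:stop] = g
            x._accumulate(gx)

    return Tensor(out, (x,), bwd)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def dice_loss_op(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Soft-dice loss 1 - (2*sum(p*y)+eps)/(sum(p)+sum(y)+eps) over the batch."""
    y = np.asarray(target, dtype=np.float32)
    p = pred.data
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + eps
    out = 1.0 - (2.0 * inter + eps) / denom

    def bwd(g):
        if pred.requires_grad:
            # d/dp of -(2*sum(p*y)+eps)/denom with denom depending on p
            gp = -(2.0 * y * denom - (2.0 * inter + eps)) / (denom * denom)
            pred._accumulate(g * gp)

    return Tensor(np.float32(out), (pred,), bwd)


def offset_rmse_op(pred: Tensor, target: np.ndarray, mask: np.ndarray,
                   eps: float = 1e-12) -> Tensor:
    """RMSE of the two offset channels over cells where ``mask`` is 1.

    pred, target: (..., 2); mask broadcasts over the trailing axis.  Each
    masked cell contributes the squared errors of both channels and counts
    once in n.  Returns 0 for an empty mask.
    """
    y = np.asarray(target, dtype=np.float32)
    m = np.asarray(mask, dtype=np.float32)[..., None]
    n_spots = float(m.sum())
    if n_spots == 0:
        return Tensor(np.float32(0.0), (pred,), lambda g: None)
    diff = (pred.data - y) * m
    sq = float((diff * diff).sum())
    val = np.sqrt(sq / n_spots + eps)

    def bwd(g):
        if pred.requires_grad:
            pred._accumulate(g * diff / (n_spots * max(val, 1e-8)))

    return Tensor(np.float32(val), (pred,), bwd)


def add_scaled(a: Tensor, b: Tensor, k: float) -> Tensor:
    """Scalar combination a + k*b."""
    out = a.data + np.float32(k) * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g * np.float32(k))

    return Tensor(out, (a, b), bwd)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with the optional AMSGrad correction (max of second moments)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 amsgrad=True):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vhat = [np.zeros_like(p.data) for p in self.params] if amsgrad else None

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            if self.amsgrad:
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                v = self.vhat[i]
            else:
                v = self.v[i]
            p.data -= (
                self.lr * (self.m[i] / bc1) / (np.sqrt(v / bc2) + self.eps)
            ).astype(np.float32)
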