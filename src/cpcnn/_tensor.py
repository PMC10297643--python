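"""Reverse-mode automatic differentiation over NumPy arrays.

This is the compute core for the network tiers: a small tape-based
``Tensor`` plus the handful of differentiable operations a residual
classification network needs (convolution, batch normalization, max
pooling, bilinear resizing, global average pooling, softmax losses).

Activations are float32 and laid out channels-last ``(N, H, W, C)``;
convolution weights are ``(KH, KW, Cin, Cout)``. With this layout every
convolution decomposes into per-offset GEMMs on slices whose rows are
long contiguous runs, so the engine stays close to BLAS speed on a
single core instead of paying for strided im2col transposes.

The engine is deliberately minimal: no views/in-place mutation of graph
tensors, no higher-order gradients. ``Tensor.backward`` clears the
gradients of every node in the traversed graph before accumulating, so
one forward/backward pair per step needs no explicit ``zero_grad``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import _malloc  # noqa: F401  (heap tuning side effect)

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "conv2d",
    "max_pool2d",
    "batch_norm2d",
    "linear",
    "gap2d",
    "resize_bilinear",
    "spatial_softmax",
    "softmax_cross_entropy",
    "softmax",
    "interp_matrix",
    "resize_bilinear_array",
]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


class Tensor:
    """A node in the autodiff graph holding a float32 array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._backward = _backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self._parents
        )

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph ---------------------------------------------------------
    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        """Backpropagate ``grad`` (default: ones) from this node.

        Gradients of every node reachable from this one are reset first,
        then populated; leaves keep their ``.grad`` for the optimizer and
        intermediates keep theirs for Grad-CAM style inspection.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        grad = _as_f32(grad)
        if grad.shape != self.data.shape:
            raise ValueError(
                f"backward seed shape {grad.shape} != tensor shape {self.data.shape}"
            )
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), Tensor(np.float32(-1.0))))

    def __neg__(self):
        return mul(self, Tensor(np.float32(-1.0)))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _acc(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        _acc(a, _unbroadcast(g, a.data.shape))
        _acc(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        _acc(a, _unbroadcast(g * b.data, a.data.shape))
        _acc(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=backward)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, np.float32(0.0))

    def backward(g):
        _acc(x, g * (out_data > 0))

    return Tensor(out_data, _parents=(x,), _backward=backward)


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

def _pad_hw(a: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if not p:
        return a
    n, h, w, c = a.shape
    out = np.full((n, h + 2 * p, w + 2 * p, c), np.float32(value), dtype=np.float32)
    out[:, p:p + h, p:p + w, :] = a
    return out


def _shift_views(xp: np.ndarray, kh: int, kw: int, s: int, oh: int, ow: int):
    """Yield ``(ki, kj, view)`` where ``view`` is the (N, OH, OW, C) slice of
    the padded input seen by kernel offset (ki, kj).

    For stride > 1 the input is first split into its s*s phase subgrids
    (one strided copy each) so that every per-offset slice is a cheap
    row-contiguous view.
    """
    if s == 1:
        for ki in range(kh):
            for kj in range(kw):
                yield ki, kj, xp[:, ki:ki + oh, kj:kj + ow, :]
        return
    phases: dict[tuple[int, int], np.ndarray] = {}
    for a in range(min(s, kh)):
        for b in range(min(s, kw)):
            phases[(a, b)] = np.ascontiguousarray(xp[:, a::s, b::s, :])
    for ki in range(kh):
        for kj in range(kw):
            p = phases[(ki % s, kj % s)]
            di, dj = ki // s, kj // s
            yield ki, kj, p[:, di:di + oh, dj:dj + ow, :]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation of (N,H,W,Cin) with weights (KH,KW,Cin,Cout),
    computed as a sum of per-offset GEMMs on shifted slices."""
    n, h, wid, cin = x.data.shape
    kh, kw, cin_w, cout = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    s, p = int(stride), int(padding)
    oh = (h + 2 * p - kh) // s + 1
    ow = (wid + 2 * p - kw) // s + 1
    if kh == 1 and kw == 1 and s == 1 and p == 0:
        # pure channel mixing: one GEMM
        xm = x.data.reshape(n * h * wid, cin)
        out = xm @ w.data.reshape(cin, cout)
        if b is not None:
            out += b.data
        out_data = out.reshape(n, h, wid, cout)

        def backward1(g):
            gm = g.reshape(n * h * wid, cout)
            _acc(w, (xm.T @ gm).reshape(w.data.shape))
            if b is not None:
                _acc(b, gm.sum(axis=0))
            if x.requires_grad:
                _acc(x, (gm @ w.data.reshape(cin, cout).T).reshape(x.data.shape))

        parents = (x, w) if b is None else (x, w, b)
        return Tensor(out_data, _parents=parents, _backward=backward1)

    xp = _pad_hw(x.data, p)
    out = np.zeros((n * oh * ow, cout), dtype=np.float32)
    cols: list[tuple[int, int, np.ndarray]] = []
    for ki, kj, view in _shift_views(xp, kh, kw, s, oh, ow):
        xs = np.ascontiguousarray(view).reshape(n * oh * ow, cin)
        cols.append((ki, kj, xs))
        out += xs @ w.data[ki, kj]
    if b is not None:
        out += b.data
    out_data = out.reshape(n, oh, ow, cout)

    def backward(g):
        gm = g.reshape(n * oh * ow, cout)
        dw = np.empty_like(w.data)
        for ki, kj, xs in cols:
            dw[ki, kj] = xs.T @ gm
        _acc(w, dw)
        if b is not None:
            _acc(b, gm.sum(axis=0))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            if s == 1:
                for ki, kj, _ in cols:
                    dxp[:, ki:ki + oh, kj:kj + ow, :] += (
                        gm @ w.data[ki, kj].T
                    ).reshape(n, oh, ow, cin)
            else:
                dphase: dict[tuple[int, int], np.ndarray] = {}
                for ki, kj, _ in cols:
                    key = (ki % s, kj % s)
                    if key not in dphase:
                        dphase[key] = np.zeros(
                            xp[:, key[0]::s, key[1]::s, :].shape, dtype=np.float32
                        )
                    di, dj = ki // s, kj // s
                    dphase[key][:, di:di + oh, dj:dj + ow, :] += (
                        gm @ w.data[ki, kj].T
                    ).reshape(n, oh, ow, cin)
                for (a, bb), dp in dphase.items():
                    dxp[:, a::s, bb::s, :] += dp
            _acc(x, dxp[:, p:p + h, p:p + wid, :] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, _parents=parents, _backward=backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2,
               padding: int = 1) -> Tensor:
    """Max pooling via shifted-slice maxima (no window materialization).

    Backward routes each output gradient to the first window position in
    raster order attaining the maximum, matching argmax tie-breaking.
    """
    n, h, wid, c = x.data.shape
    k, s, p = int(kernel), int(stride), int(padding)
    xp = _pad_hw(x.data, p, value=-np.inf)
    oh = (h + 2 * p - k) // s + 1
    ow = (wid + 2 * p - k) // s + 1
    out_data = np.full((n, oh, ow, c), -np.inf, dtype=np.float32)
    views = list(_shift_views(xp, k, k, s, oh, ow))
    for _, _, view in views:
        np.maximum(out_data, view, out=out_data)

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros(xp.shape, dtype=np.float32)
        assigned = np.zeros(out_data.shape, dtype=bool)
        if s == 1:
            for ki, kj, view in views:
                hit = (view == out_data) & ~assigned
                dxp[:, ki:ki + oh, kj:kj + ow, :] += g * hit
                assigned |= hit
        else:
            dphase: dict[tuple[int, int], np.ndarray] = {}
            for ki, kj, view in views:
                hit = (view == out_data) & ~assigned
                key = (ki % s, kj % s)
                if key not in dphase:
                    dphase[key] = np.zeros(
                        xp[:, key[0]::s, key[1]::s, :].shape, dtype=np.float32
                    )
                di, dj = ki // s, kj // s
                dphase[key][:, di:di + oh, dj:dj + ow, :] += g * hit
                assigned |= hit
            for (a, b), dp in dphase.items():
                dxp[:, a::s, b::s, :] += dp
        _acc(x, dxp[:, p:p + h, p:p + wid, :] if p else dxp)

    return Tensor(out_data, _parents=(x,), _backward=backward)


# ---------------------------------------------------------------------------
# normalization / heads
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 momentum: float = 0.1, eps: float = 1e-5,
                 training: bool = False) -> Tensor:
    """Spatial batch normalization over (N,H,W,C); running buffers are
    updated in place. The normalization is applied as one fused
    per-channel affine map and the backward pass never materializes the
    normalized tensor."""
    n, h, w_, c = x.data.shape
    m = n * h * w_
    xm = x.data.reshape(m, c)
    if training:
        mean = xm.mean(axis=0)
        sq = xm * xm
        var = np.maximum(sq.mean(axis=0) - mean * mean, 0.0)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean = running_mean.astype(np.float32)
        var = running_var.astype(np.float32)
    ivar = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    mean = mean.astype(np.float32)
    scale = gamma.data * ivar
    shift = beta.data - mean * scale
    out_data = x.data * scale
    out_data += shift

    def backward(g):
        gm = g.reshape(m, c)
        sum_g = gm.sum(axis=0)
        sum_gx = np.einsum("ij,ij->j", gm, xm, optimize=True)
        dgamma = (sum_gx - mean * sum_g) * ivar
        _acc(gamma, dgamma.astype(np.float32))
        _acc(beta, sum_g.astype(np.float32))
        if not x.requires_grad:
            return
        if training:
            # dx = scale * (g - sum_g/m - xhat * dgamma/m), expanded into
            # fused per-channel affine passes over g and x.
            aa = scale
            bb = (-scale * dgamma * ivar / m).astype(np.float32)
            cc = (-scale * sum_g / m + mean * scale * dgamma * ivar / m).astype(np.float32)
            dx = g * aa
            dx += x.data * bb
            dx += cc
        else:
            dx = g * scale
        _acc(x, dx.astype(np.float32, copy=False))

    return Tensor(out_data, _parents=(x, gamma, beta), _backward=backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Affine map of (N, Cin) with weight (Cout, Cin)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data

    def backward(g):
        _acc(w, g.T @ x.data)
        if b is not None:
            _acc(b, g.sum(axis=0))
        if x.requires_grad:
            _acc(x, g @ w.data)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, _parents=parents, _backward=backward)


def gap2d(x: Tensor) -> Tensor:
    """Global average pooling: (N,H,W,C) -> (N,C)."""
    n, h, w, c = x.data.shape
    out = x.data.mean(axis=(1, 2))

    def backward(g):
        if x.requires_grad:
            _acc(x, np.broadcast_to(
                g[:, None, None, :] / np.float32(h * w), x.data.shape
            ).astype(np.float32))

    return Tensor(out, _parents=(x,), _backward=backward)


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (n_out, n_in), half-pixel
    centers, edge-clamped. Exactly linear, hence trivially transposable."""
    if n_in == n_out:
        return np.eye(n_in, dtype=np.float32)
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * n_in / n_out - 0.5
    i0 = np.floor(src).astype(int)
    t = src - i0
    lo = np.clip(i0, 0, n_in - 1)
    hi = np.clip(i0 + 1, 0, n_in - 1)
    m = np.zeros((n_out, n_in), dtype=np.float64)
    rows = np.arange(n_out)
    np.add.at(m, (rows, lo), 1.0 - t)
    np.add.at(m, (rows, hi), t)
    return m.astype(np.float32)


def _resize_nhwc(a: np.ndarray, r: np.ndarray, cm: np.ndarray) -> np.ndarray:
    """Apply row matrix ``r`` (OH,H) and column matrix ``cm`` (OW,W) to the
    middle axes of (N,H,W,C)."""
    n, h, w, c = a.shape
    # rows: (N,H,W*C) -> (N,OH,W*C)
    t = np.matmul(r, a.reshape(n, h, w * c))
    # cols: (N*OH, W, C) -> transpose to put W last for GEMM
    t = t.reshape(n * r.shape[0], w, c)
    out = np.einsum("bwc,Ww->bWc", t, cm, optimize=True)
    return out.reshape(n, r.shape[0], cm.shape[0], c)


def resize_bilinear_array(a: np.ndarray, out_hw) -> np.ndarray:
    """Bilinear resize of a plain (H,W), (N,H,W) or (N,H,W,C) array."""
    oh, ow = int(out_hw[0]), int(out_hw[1])
    a = _as_f32(a)
    if a.ndim == 2:
        return _resize_nhwc(a[None, :, :, None], interp_matrix(a.shape[0], oh),
                            interp_matrix(a.shape[1], ow))[0, :, :, 0]
    if a.ndim == 3:
        return _resize_nhwc(a[..., None], interp_matrix(a.shape[1], oh),
                            interp_matrix(a.shape[2], ow))[..., 0]
    return _resize_nhwc(a, interp_matrix(a.shape[1], oh),
                        interp_matrix(a.shape[2], ow))


def resize_bilinear(x: Tensor, out_hw) -> Tensor:
    """Differentiable bilinear resize of (N,H,W,C) to ``out_hw``."""
    n, ih, iw, c = x.data.shape
    oh, ow = int(out_hw[0]), int(out_hw[1])
    if oh <= 0 or ow <= 0:
        raise ValueError(f"target size must be positive, got {(oh, ow)}")
    r = interp_matrix(ih, oh)
    cm = interp_matrix(iw, ow)
    out = _resize_nhwc(x.data, r, cm)

    def backward(g):
        if x.requires_grad:
            _acc(x, _resize_nhwc(g, r.T.copy(), cm.T.copy()))

    return Tensor(out, _parents=(x,), _backward=backward)


# ---------------------------------------------------------------------------
# softmax heads
# ---------------------------------------------------------------------------

def spatial_softmax(x: Tensor) -> Tensor:
    """Softmax over the spatial positions of each (N,H,W,1) map."""
    n, h, w, c = x.data.shape
    flat = x.data.reshape(n, h * w * c)
    z = flat - flat.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    out = p.reshape(n, h, w, c)

    def backward(g):
        if not x.requires_grad:
            return
        gf = g.reshape(n, h * w * c)
        dot = (gf * p).sum(axis=-1, keepdims=True)
        _acc(x, (p * (gf - dot)).reshape(n, h, w, c).astype(np.float32))

    return Tensor(out, _parents=(x,), _backward=backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain (non-differentiable) row softmax for reporting scores."""
    z = _as_f32(logits)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray):
    """Mean cross-entropy of (N,K) logits against integer labels.

    Returns ``(loss, probabilities)`` where loss is a scalar Tensor.
    """
    y = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    if y.shape != (n,):
        raise ValueError(
            f"labels shape {y.shape} incompatible with logits {logits.data.shape}"
        )
    probs = softmax(logits.data)
    eps = np.float32(1e-12)
    loss_val = -np.log(probs[np.arange(n), y] + eps).mean()

    def backward(g):
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y] = 1.0
        _acc(logits, (probs - onehot) * (np.float32(g) / np.float32(n)))

    return Tensor(loss_val, _parents=(logits,), _backward=backward), probs
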