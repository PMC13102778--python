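"""Minimal NumPy neural-network layer framework.

Implements exactly the layer vocabulary the viability regressor needs —
convolutions (dense and depthwise), batch/layer normalization, ReLU/GELU,
max/global-average pooling, dense layers, dropout, residual blocks, and
multi-head self-attention — each with an explicit ``forward``/``backward``
pair, plus an Adam optimizer with L2 weight decay.  Parameters are single
precision (see ``DTYPE``) and everything runs on a single CPU; training is
deterministic given seeds and a fixed thread count.

Tensors follow the (N, C, H, W) convention for images and (N, L, D) for
token sequences.  ``backward`` must be called right after the ``forward``
whose intermediates it consumes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

# Parameters are float32: single precision is the working precision of CNN
# training and roughly halves matmul time; tests that need double precision
# can feed float64 inputs (ops then upcast).
DTYPE = np.float32

__all__ = [
    "Layer", "Sequential", "Dense", "Conv2d", "DepthwiseConv2d",
    "BatchNorm2d", "LayerNorm", "ReLU", "GELU", "Dropout", "MaxPool2d",
    "GlobalAvgPool", "Flatten", "Residual", "TokensFromImage",
    "MultiHeadSelfAttention", "AddPositionEmbedding", "MeanPoolTokens",
    "Adam", "n_parameters",
]


class Layer:
    """Base layer: ``params``/``grads`` are aligned name->array dicts."""

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def param_items(self):
        return [(self, name) for name in self.params]

    def buffer_items(self):
        """Non-trainable state (e.g. normalization running stats)."""
        return []

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


def n_parameters(layer) -> int:
    """Total number of trainable scalars in a layer tree."""
    return int(sum(p.size for (lyr, name) in layer.param_items()
                   for p in [lyr.params[name]]))


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
        return x

    def backward(self, grad):
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)
        return grad

    def param_items(self):
        return [it for lyr in self.layers for it in lyr.param_items()]

    def buffer_items(self):
        return [it for lyr in self.layers for it in lyr.buffer_items()]


# ---------------------------------------------------------------------------
# dense / activation / dropout

class Dense(Layer):
    """Affine map over the last axis; He-uniform initialization."""

    def __init__(self, n_in, n_out, rng, bias=True):
        super().__init__()
        bound = np.sqrt(6.0 / n_in)
        self.params["w"] = rng.uniform(
            -bound, bound, size=(n_in, n_out)).astype(DTYPE)
        if bias:
            self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.params["w"]
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, grad):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.grads["w"] = x2.T @ g2
        if "b" in self.params:
            self.grads["b"] = g2.sum(axis=0)
        return grad @ self.params["w"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class GELU(Layer):
    """Exact Gaussian-error-linear unit."""

    def forward(self, x, train=False):
        from scipy.special import erf
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        return x * self._cdf

    def backward(self, grad):
        pdf = np.exp(-0.5 * self._x**2) / np.sqrt(2.0 * np.pi)
        return grad * (self._cdf + self._x * pdf)


class Dropout(Layer):
    """Inverted dropout; identity at inference.  Own seeded generator."""

    def __init__(self, rate, seed=0):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


# ---------------------------------------------------------------------------
# convolutions

def _window_view(x, kh, kw, stride):
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    return as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    ), oh, ow


def _col2im(dcols, x_shape, kh, kw, stride, oh, ow):
    """Scatter-add (n, c, kh, kw, oh, ow) gradients back onto the input."""
    n, c, h, w = x_shape
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += \
                dcols[:, :, i, j]
    return dx


class Conv2d(Layer):
    def __init__(self, c_in, c_out, kernel, rng, stride=1, pad=0, bias=True):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        bound = np.sqrt(6.0 / fan_in)
        self.params["w"] = rng.uniform(
            -bound, bound, size=(c_out, c_in, kernel, kernel)).astype(DTYPE)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp_shape = x.shape
        win, oh, ow = _window_view(x, k, k, s)
        cols = win.reshape(x.shape[0], -1, oh * ow)  # (n, c*k*k, L)
        self._cols = cols
        self._oh, self._ow = oh, ow
        wf = self.params["w"].reshape(self.params["w"].shape[0], -1)
        y = np.einsum("fk,nkl->nfl", wf, cols).reshape(
            x.shape[0], -1, oh, ow)
        if "b" in self.params:
            y = y + self.params["b"][None, :, None, None]
        return y

    def backward(self, grad):
        n, f, oh, ow = grad.shape
        g = grad.reshape(n, f, oh * ow)
        wf = self.params["w"].reshape(f, -1)
        self.grads["w"] = np.einsum("nfl,nkl->fk", g, self._cols).reshape(
            self.params["w"].shape)
        if "b" in self.params:
            self.grads["b"] = g.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfl->nkl", wf, g)
        c = self._xp_shape[1]
        k, s, p = self.kernel, self.stride, self.pad
        dcols = dcols.reshape(n, c, k, k, oh, ow)
        dxp = _col2im(dcols, self._xp_shape, k, k, s, oh, ow)
        return dxp[:, :, p:dxp.shape[2] - p, p:dxp.shape[3] - p] if p else dxp


class DepthwiseConv2d(Layer):
    """Per-channel spatial convolution (groups == channels)."""

    def __init__(self, channels, kernel, rng, stride=1, pad=0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        bound = np.sqrt(6.0 / (kernel * kernel))
        self.params["w"] = rng.uniform(
            -bound, bound, size=(channels, kernel, kernel)).astype(DTYPE)

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp_shape = x.shape
        win, oh, ow = _window_view(x, k, k, s)  # (n, c, k, k, oh, ow)
        self._win = win
        self._oh, self._ow = oh, ow
        return np.einsum("nckhij,ckh->ncij", win, self.params["w"])

    def backward(self, grad):
        self.grads["w"] = np.einsum("nckhij,ncij->ckh", self._win, grad)
        k, s, p = self.kernel, self.stride, self.pad
        dcols = np.einsum("ckh,ncij->nckhij", self.params["w"], grad)
        dxp = _col2im(dcols, self._xp_shape, k, k, s, self._oh, self._ow)
        return dxp[:, :, p:dxp.shape[2] - p, p:dxp.shape[3] - p] if p else dxp


class MaxPool2d(Layer):
    def __init__(self, kernel, stride=None, pad=0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        self._xp_shape = x.shape
        win, oh, ow = _window_view(x, k, k, s)
        n, c = x.shape[:2]
        flat = win.reshape(n, c, k * k, oh, ow)
        self._argmax = flat.argmax(axis=2)
        self._oh, self._ow = oh, ow
        return flat.max(axis=2)

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, oh, ow = grad.shape
        dcols = np.zeros((n, c, k * k, oh, ow), dtype=grad.dtype)
        np.put_along_axis(dcols, self._argmax[:, :, None], grad[:, :, None],
                          axis=2)
        dxp = _col2im(dcols.reshape(n, c, k, k, oh, ow), self._xp_shape,
                      k, k, s, oh, ow)
        return dxp[:, :, p:dxp.shape[2] - p, p:dxp.shape[3] - p] if p else dxp


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


# ---------------------------------------------------------------------------
# normalization

class BatchNorm2d(Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def buffer_items(self):
        return [(self, "running_mean"), (self, "running_var")]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / \
            self._std[None, :, None, None]
        self._train = train
        return self.params["gamma"][None, :, None, None] * self._xhat + \
            self.params["beta"][None, :, None, None]

    def backward(self, grad):
        self.grads["gamma"] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = grad.sum(axis=(0, 2, 3))
        g = grad * self.params["gamma"][None, :, None, None]
        if not self._train:
            return g / self._std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = g.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gx = (g * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (g - sum_g / m - self._xhat * sum_gx / m) / \
            self._std[None, :, None, None]


class LayerNorm(Layer):
    """Normalization over the last axis, as used in transformer blocks."""

    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(dim, dtype=DTYPE)
        self.params["beta"] = np.zeros(dim, dtype=DTYPE)
        self.eps = eps

    def forward(self, x, train=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        d = grad.shape[-1]
        axes = tuple(range(grad.ndim - 1))
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * self.params["gamma"]
        mean_g = g.mean(axis=-1, keepdims=True)
        mean_gx = (g * self._xhat).mean(axis=-1, keepdims=True)
        return (g - mean_g - self._xhat * mean_gx) / self._std


# ---------------------------------------------------------------------------
# composites

class Residual(Layer):
    """y = act(main(x) + shortcut(x)); shortcut defaults to identity.

    ``post_relu=False`` gives the plain pre-activation add used in
    transformer blocks.
    """

    def __init__(self, main, shortcut=None, post_relu=True):
        super().__init__()
        self.main = main
        self.shortcut = shortcut
        self.relu = ReLU() if post_relu else None

    def forward(self, x, train=False):
        a = self.main.forward(x, train=train)
        b = self.shortcut.forward(x, train=train) if self.shortcut else x
        y = a + b
        return self.relu.forward(y, train=train) if self.relu else y

    def backward(self, grad):
        g = self.relu.backward(grad) if self.relu else grad
        dx = self.main.backward(g)
        dx = dx + (self.shortcut.backward(g) if self.shortcut else g)
        return dx

    def param_items(self):
        items = self.main.param_items()
        if self.shortcut:
            items = items + self.shortcut.param_items()
        return items

    def buffer_items(self):
        items = self.main.buffer_items()
        if self.shortcut:
            items = items + self.shortcut.buffer_items()
        return items


class TokensFromImage(Layer):
    """(N, C, H, W) -> (N, H*W, C) token sequence."""

    def forward(self, x, train=False):
        self._shape = x.shape
        n, c, h, w = x.shape
        return x.reshape(n, c, h * w).transpose(0, 2, 1)

    def backward(self, grad):
        n, c, h, w = self._shape
        return grad.transpose(0, 2, 1).reshape(self._shape)


class AddPositionEmbedding(Layer):
    def __init__(self, n_tokens, dim, rng):
        super().__init__()
        self.params["pos"] = rng.normal(
            0.0, 0.02, size=(n_tokens, dim)).astype(DTYPE)

    def forward(self, x, train=False):
        return x + self.params["pos"][None]

    def backward(self, grad):
        self.grads["pos"] = grad.sum(axis=0)
        return grad


class MeanPoolTokens(Layer):
    """(N, L, D) -> (N, D)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, grad):
        n, l, d = self._shape
        return np.broadcast_to(grad[:, None, :], self._shape) / l


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    def __init__(self, dim, n_heads, rng):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Dense(dim, 3 * dim, rng)
        self.proj = Dense(dim, dim, rng)

    def forward(self, x, train=False):
        n, l, d = x.shape
        qkv = self.qkv.forward(x)  # (n, l, 3d)
        qkv = qkv.reshape(n, l, 3, self.n_heads, self.d_head)
        q, k, v = (qkv[:, :, i].transpose(0, 2, 1, 3) for i in range(3))
        att = _softmax(q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.d_head))
        self._q, self._k, self._v, self._att = q, k, v, att
        out = (att @ v).transpose(0, 2, 1, 3).reshape(n, l, d)
        return self.proj.forward(out)

    def backward(self, grad):
        n, l, d = grad.shape
        g = self.proj.backward(grad)
        g = g.reshape(n, l, self.n_heads, self.d_head).transpose(0, 2, 1, 3)
        q, k, v, att = self._q, self._k, self._v, self._att
        datt = g @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ g
        # softmax backward
        dz = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dz = dz / np.sqrt(self.d_head)
        dq = dz @ k
        dk = dz.transpose(0, 1, 3, 2) @ q
        dqkv = np.stack(
            [t.transpose(0, 2, 1, 3) for t in (dq, dk, dv)], axis=2
        ).reshape(n, l, 3 * d)
        return self.qkv.backward(dqkv)

    def param_items(self):
        return self.qkv.param_items() + self.proj.param_items()


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, param_items, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.items = list(param_items)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(lyr.params[name]) for lyr, name in self.items]
        self._v = [np.zeros_like(lyr.params[name]) for lyr, name in self.items]

    def step(self):
        self.t += 1
        for i, (lyr, name) in enumerate(self.items):
            g = lyr.grads[name]
            if self.weight_decay:
                g = g + self.weight_decay * lyr.params[name]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            lyr.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
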