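"""Minimal NumPy layer stack with hand-written backward passes.

Implements exactly the pieces the hybrid encoder-decoder needs: im2col
convolutions (3x3 / 1x1 / 7x7, stride 1 or 2), 2x2-stride-2 transposed
convolutions for decoder upsampling, batch normalization, ReLU, max pooling,
residual basic blocks, and an Adam optimizer.  Every layer caches its forward
context and returns the input gradient from ``backward``; correctness of all
gradients is covered by finite-difference tests.

All floating-point work defaults to float32; layers accept ``dtype=np.float64``
for gradient checking.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Sequential",
    "BasicBlock",
    "Adam",
    "collect_params",
    "collect_buffers",
    "softmax",
    "sigmoid",
    "softmax_cross_entropy",
    "soft_jaccard_loss",
    "soft_dice_loss",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. BN running stats), for checkpointing."""
        return []

    def load_buffers(self, arrays: list[np.ndarray]) -> None:
        pass

    __call__ = forward


def _im2col(x, k, s, p, pad_value=0.0):
    B, C, H, W = x.shape
    OH = (H + 2 * p - k) // s + 1
    OW = (W + 2 * p - k) // s + 1
    if p > 0:
        xp = np.full((B, C, H + 2 * p, W + 2 * p), pad_value, dtype=x.dtype)
        xp[:, :, p:p + H, p:p + W] = x
    else:
        xp = x
    cols = np.empty((B, C, k, k, OH, OW), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + s * OH:s, j:j + s * OW:s]
    return cols.reshape(B, C * k * k, OH * OW), (OH, OW)


def _col2im(dcols, xshape, k, s, p, OH, OW):
    B, C, H, W = xshape
    dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dcols.dtype)
    dcols = dcols.reshape(B, C, k, k, OH, OW)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + s * OH:s, j:j + s * OW:s] += dcols[:, :, i, j]
    return dxp[:, :, p:p + H, p:p + W] if p > 0 else dxp


class Conv2d(Layer):
    """2-D convolution via im2col + GEMM; He-normal initialization."""

    def __init__(self, cin, cout, k, stride=1, pad=0, bias=False,
                 rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin, k, k)).astype(dtype))
        self.bias = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def forward(self, x, train=True):
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        cols, (OH, OW) = _im2col(x, self.k, self.stride, self.pad)
        W2 = self.weight.value.reshape(self.cout, -1)
        out = np.matmul(W2, cols)  # (B, cout, P)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        self._ctx = (x.shape, cols, OH, OW)
        return out.reshape(x.shape[0], self.cout, OH, OW)

    def backward(self, grad):
        xshape, cols, OH, OW = self._ctx
        B = xshape[0]
        g2 = grad.reshape(B, self.cout, OH * OW)
        self.weight.grad += np.tensordot(g2, cols, axes=([0, 2], [0, 2])).reshape(
            self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=(0, 2))
        W2 = self.weight.value.reshape(self.cout, -1)
        dcols = np.matmul(W2.T, g2)
        return _col2im(dcols, xshape, self.k, self.stride, self.pad, OH, OW)

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class ConvTranspose2d(Layer):
    """2x2, stride-2 transposed convolution (non-overlapping upsampling)."""

    def __init__(self, cin, cout, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, std, size=(cin, cout, 2, 2)).astype(dtype))
        self.cin, self.cout = cin, cout

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        # out[b,o,2h+k,2w+l] = sum_c x[b,c,h,w] W[c,o,k,l]
        t = np.tensordot(x, self.weight.value, axes=([1], [0]))  # (B,H,W,O,2,2)
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(B, self.cout, 2 * H, 2 * W)
        self._x = x
        return np.ascontiguousarray(out)

    def backward(self, grad):
        x = self._x
        B, C, H, W = x.shape
        g = grad.reshape(B, self.cout, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)
        # dW[c,o,k,l] = sum_{b,h,w} x[b,c,h,w] g[b,h,w,o,k,l]
        self.weight.grad += np.tensordot(x, g, axes=([0, 2, 3], [0, 1, 2]))
        # dx[b,c,h,w] = sum_{o,k,l} g[b,h,w,o,k,l] W[c,o,k,l]
        dx = np.tensordot(g, self.weight.value, axes=([3, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def params(self):
        return [self.weight]


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._ctx = (xhat, std, train)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, std, train = self._ctx
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not train:
            return g / std[None, :, None, None]
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        # standard batch-norm backward
        sum_g = g.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gx = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (g - sum_g / n - xhat * sum_gx / n) / std[None, :, None, None]

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def load_buffers(self, arrays):
        self.running_mean, self.running_var = arrays[0].copy(), arrays[1].copy()


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class MaxPool2d(Layer):
    """Max pooling (used only by the optional 7x7-stem configuration)."""

    def __init__(self, k=3, stride=2, pad=1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        xr = x.reshape(B * C, 1, H, W)
        cols, (OH, OW) = _im2col(xr, self.k, self.stride, self.pad,
                                 pad_value=-np.inf)
        self._arg = cols.argmax(axis=1)
        out = cols.max(axis=1)
        self._ctx = (x.shape, cols.shape, OH, OW)
        return out.reshape(B, C, OH, OW)

    def backward(self, grad):
        xshape, cshape, OH, OW = self._ctx
        B, C, H, W = xshape
        dcols = np.zeros(cshape, dtype=grad.dtype)
        g = grad.reshape(B * C, OH * OW)
        rows = np.arange(cshape[0])[:, None]
        pcols = np.arange(cshape[2])[None, :]
        dcols[rows, self._arg, pcols] = g
        dx = _col2im(dcols, (B * C, 1, H, W), self.k, self.stride, self.pad, OH, OW)
        return dx.reshape(B, C, H, W)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self):
        return [b for layer in self.layers for b in layer.buffers()]

    def load_buffers(self, arrays):
        i = 0
        for layer in self.layers:
            n = len(layer.buffers())
            layer.load_buffers(arrays[i:i + n])
            i += n


class BasicBlock(Layer):
    """Two-convolution residual block with identity/projection shortcut.

    ``conv(3x3,stride)-BN-ReLU-conv(3x3)-BN`` plus a 1x1 projection shortcut
    whenever the stride or channel count changes, followed by a ReLU.
    """

    def __init__(self, cin, cout, stride=1, rng=None, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.relu_out = ReLU()
        if stride != 1 or cin != cout:
            self.proj = Sequential(Conv2d(cin, cout, 1, stride, 0, rng=rng, dtype=dtype),
                                   BatchNorm2d(cout, dtype=dtype))
        else:
            self.proj = None

    def forward(self, x, train=True):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train))
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        sc = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu_out.forward(h + sc)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        gh = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        gsc = self.proj.backward(g) if self.proj is not None else g
        return gh + gsc

    def params(self):
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            out += self.proj.params()
        return out

    def buffers(self):
        out = self.bn1.buffers() + self.bn2.buffers()
        if self.proj is not None:
            out += self.proj.buffers()
        return out

    def load_buffers(self, arrays):
        self.bn1.load_buffers(arrays[0:2])
        self.bn2.load_buffers(arrays[2:4])
        if self.proj is not None:
            self.proj.load_buffers(arrays[4:6])


def collect_params(*layers) -> list[Param]:
    return [p for layer in layers for p in layer.params()]


def collect_buffers(*layers) -> list[np.ndarray]:
    return [b for layer in layers for b in layer.buffers()]


class Adam:
    """Adam with bias correction; state allocated lazily per parameter."""

    def __init__(self, params: list[Param], lr=5e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


# ---------------------------------------------------------------------------
# losses (operate on raw class scores / logits)

def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _check_finite(z):
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite values in class scores")


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray):
    """Mean per-pixel multi-class cross-entropy. Returns (loss, dlogits)."""
    _check_finite(logits)
    B, C, H, W = logits.shape
    p = softmax(logits, axis=1)
    n = B * H * W
    onehot_ll = np.take_along_axis(
        np.log(np.clip(p, 1e-12, None)), target[:, None, :, :], axis=1)
    loss = -float(onehot_ll.sum()) / n
    dlogits = p.copy()
    np.put_along_axis(dlogits, target[:, None, :, :],
                      np.take_along_axis(dlogits, target[:, None, :, :], axis=1) - 1.0,
                      axis=1)
    return loss, (dlogits / n).astype(logits.dtype)


def _soft_overlap_terms(logits, target):
    B, C, H, W = logits.shape
    p = softmax(logits, axis=1)
    y = np.zeros_like(p)
    np.put_along_axis(y, target[:, None, :, :], 1.0, axis=1)
    axes = (0, 2, 3)
    inter = (p * y).sum(axis=axes)      # per-class, pooled over the batch
    sum_p = p.sum(axis=axes)
    sum_y = y.sum(axis=axes)
    return p, y, inter, sum_p, sum_y


def soft_jaccard_loss(logits: np.ndarray, target: np.ndarray, eps: float = 1e-7):
    """1 - mean soft IoU over foreground classes. Returns (loss, dlogits)."""
    _check_finite(logits)
    p, y, inter, sum_p, sum_y = _soft_overlap_terms(logits, target)
    C = logits.shape[1]
    fg = np.arange(1, C)
    union = sum_p + sum_y - inter
    iou = (inter[fg] + eps) / (union[fg] + eps)
    loss = 1.0 - float(iou.mean())
    K = len(fg)
    dp = np.zeros_like(p)
    for c in fg:
        u = union[c] + eps
        i = inter[c] + eps
        dp[:, c] = -(y[:, c] * u - i * (1.0 - y[:, c])) / (u * u) / K
    dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    return loss, dz.astype(logits.dtype)


def soft_dice_loss(logits: np.ndarray, target: np.ndarray, eps: float = 1e-7):
    """1 - mean soft Dice over foreground classes. Returns (loss, dlogits)."""
    _check_finite(logits)
    p, y, inter, sum_p, sum_y = _soft_overlap_terms(logits, target)
    C = logits.shape[1]
    fg = np.arange(1, C)
    denom = sum_p + sum_y
    dice = (2.0 * inter[fg] + eps) / (denom[fg] + eps)
    loss = 1.0 - float(dice.mean())
    K = len(fg)
    dp = np.zeros_like(p)
    for c in fg:
        s = denom[c] + eps
        dp[:, c] = -(2.0 * y[:, c] * s - (2.0 * inter[c] + eps)) / (s * s) / K
    dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    return loss, dz.astype(logits.dtype)
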