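"""Minimal numpy layers with hand-derived backprop for the DCCA branches.

The branch networks are small (a few thousand parameters) and the cohorts are
small (tens to hundreds of subjects), so a compact im2col-based numpy
implementation is fast enough and keeps the whole training loop exactly
reproducible from a seed.  Layers cache what their backward pass needs;
``Sequential.backward`` accumulates parameter gradients in ``layer.grads``.

Conventions: activations are ``(n, channels, height, width)`` float64 arrays;
convolutions use stride 1 with 'same' zero padding for 3x3 kernels and no
padding for 1x1; max pooling is 2x2 after zero-padding odd spatial dims to
even (branch inputs are nonnegative past the first ReLU, so zero padding is
neutral there).
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError

__all__ = ["Conv2D", "ReLU", "MaxPool2", "GlobalAvgPool", "Sequential", "Adam",
           "build_branch"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(n, c, h, w) -> (n * oh * ow, c * kh * kw) patches for stride-1 convolution."""
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    n, c, oh, ow = view.shape[:4]
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw), (n, oh, ow)


class Conv2D(Layer):
    """Stride-1 2-D convolution; 'same' zero padding when the kernel is 3x3."""

    def __init__(self, c_in: int, c_out: int, kh: int, kw: int,
                 rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kh, self.kw = c_in, c_out, kh, kw
        self.pad = (kh // 2, kw // 2)
        fan_in = c_in * kh * kw
        limit = np.sqrt(1.0 / fan_in)  # seeded uniform fan-in initialization
        w = rng.uniform(-limit, limit, size=(c_out, c_in, kh, kw))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x):
        ph, pw = self.pad
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols, (n, oh, ow) = _im2col(x, self.kh, self.kw)
        w, b = self.params
        y = cols @ w.reshape(self.c_out, -1).T + b
        self._cache = (cols, x.shape, (n, oh, ow))
        return y.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, (n, oh, ow) = self._cache
        w, _ = self.params
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads[0][...] = (dyf.T @ cols).reshape(w.shape)
        self.grads[1][...] = dyf.sum(axis=0)
        dcols = dyf @ w.reshape(self.c_out, -1)
        dx = np.zeros(xshape)
        dcols = dcols.reshape(n, oh, ow, self.c_in, self.kh, self.kw)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, :, i:i + oh, j:j + ow] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        ph, pw = self.pad
        if ph or pw:
            dx = dx[:, :, ph:xshape[2] - ph, pw:xshape[3] - pw]
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with zero padding of odd spatial dimensions."""

    def forward(self, x):
        n, c, h, w = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        self._in_shape = (n, c, h, w)
        hp, wp = x.shape[2], x.shape[3]
        xr = x.reshape(n, c, hp // 2, 2, wp // 2, 2)
        y = xr.max(axis=(3, 5))
        mask = xr == y[:, :, :, None, :, None]
        # ties share the gradient equally (a valid subgradient)
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._padded_shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._in_shape
        dxr = self._mask * dy[:, :, :, None, :, None]
        dx = dxr.reshape(self._padded_shape)
        return dx[:, :, :h, :w]


class GlobalAvgPool(Layer):
    """(n, c, h, w) -> (n, c) spatial mean; the branch output head."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class Adam:
    """Adaptive-moment optimizer; first-moment decay 0.9, second 0.999, eps 1e-8."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_branch(k_dcca: int, rng: np.random.Generator,
                 linear_probe: bool = False, in_channels: int = 1) -> Sequential:
    """Construct one view branch.

    Standard architecture: three conv pairs at 8, 16 and 32 channels (3x3
    kernels, stride 1, ReLU after every conv), a 2x2 max pool between
    consecutive pairs, then a 1x1 projection to ``k_dcca`` channels followed
    by global average pooling to a ``k_dcca``-vector.

    ``linear_probe=True`` builds the degenerate linear configuration used in
    equivalence tests: a single 1x1 convolution (no activation, no pooling)
    straight into global average pooling, so with the latent dimensions laid
    out as input channels the branch is exactly an affine map of the
    per-dimension temporal means.
    """
    if k_dcca < 1:
        raise ValidationError(f"k_dcca must be >= 1, got {k_dcca}")
    if linear_probe:
        return Sequential([Conv2D(in_channels, k_dcca, 1, 1, rng), GlobalAvgPool()])
    return Sequential([
        Conv2D(in_channels, 8, 3, 3, rng), ReLU(),
        Conv2D(8, 8, 3, 3, rng), ReLU(),
        MaxPool2(),
        Conv2D(8, 16, 3, 3, rng), ReLU(),
        Conv2D(16, 16, 3, 3, rng), ReLU(),
        MaxPool2(),
        Conv2D(16, 32, 3, 3, rng), ReLU(),
        Conv2D(32, 32, 3, 3, rng), ReLU(),
        Conv2D(32, k_dcca, 1, 1, rng),
        GlobalAvgPool(),
    ])
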