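"""A small, self-contained numpy engine for the convolutional subclassifiers.

The execution environment offers no deep-learning framework, so the layers
needed by the two multi-stream convolutional predictors are implemented here
directly: 2-D convolution (im2col), depthwise-separable convolution, batch
normalization, max pooling, dropout, dense layers, channel-wise
parallel/concat/add combinators, softmax with class-weighted cross-entropy,
and an Adam optimizer.  Data layout is NHWC with odd kernels and "same"
padding throughout.  Feature maps are tiny (17 x 20 at most), so each
convolution is computed as a sum of kernel-offset matmuls over slices that
stay resident in cache, in single precision — considerably faster here
than materializing im2col patch matrices.

Everything is deterministic given the ``numpy.random.Generator`` threaded
through construction (weight init) and training (dropout masks, shuffling).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # single precision: adequate for SGD, half the traffic


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Layer:
    """Base class: forward/backward plus parameter bookkeeping."""

    def forward(self, x, training: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running moments)."""
        return []


class Conv2D(Layer):
    """Same-padding convolution as a sum of kernel-offset matmuls.

    Kernels are small (1x1 to 5x5) and maps are tiny (17 x 20 at most), so
    accumulating ``x_shifted @ W[i, j]`` per offset beats materializing
    im2col patches: the input is re-read from cache instead of written out
    kh*kw times.
    """

    def __init__(self, in_ch, out_ch, kh, kw, rng: np.random.Generator):
        fan_in = kh * kw * in_ch
        self.w = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (kh, kw, in_ch, out_ch)
        ).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.kh, self.kw, self.in_ch, self.out_ch = kh, kw, in_ch, out_ch
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        n, h, w, _ = x.shape
        self._shape = x.shape
        if self.kh == 1 and self.kw == 1:  # pointwise: plain channel matmul
            self._xp = x
            return x @ self.w[0, 0] + self.b
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        self._xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        out = np.empty((n, h, w, self.out_ch), dtype=DTYPE)
        out[...] = self.b
        for i in range(self.kh):
            for j in range(self.kw):
                out += self._xp[:, i : i + h, j : j + w, :] @ self.w[i, j]
        return out

    def backward(self, grad):
        n, h, w, c = self._shape
        gm = grad.reshape(-1, self.out_ch)
        self.db[...] = gm.sum(axis=0)
        if self.kh == 1 and self.kw == 1:
            self.dw[0, 0] = self._xp.reshape(-1, c).T @ gm
            return grad @ self.w[0, 0].T
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        dxp = np.zeros_like(self._xp)
        for i in range(self.kh):
            for j in range(self.kw):
                xs = self._xp[:, i : i + h, j : j + w, :]
                self.dw[i, j] = (
                    np.ascontiguousarray(xs).reshape(-1, c).T @ gm
                )
                dxp[:, i : i + h, j : j + w, :] += grad @ self.w[i, j].T
        return dxp[:, ph : ph + h, pw : pw + w, :]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class DepthwiseConv2D(Layer):
    """Per-channel spatial convolution (the first half of a separable conv)."""

    def __init__(self, channels, kh, kw, rng: np.random.Generator):
        self.w = rng.normal(
            0.0, np.sqrt(2.0 / (kh * kw)), (kh, kw, channels)
        ).astype(DTYPE)
        self.b = np.zeros(channels, dtype=DTYPE)
        self.kh, self.kw = kh, kw
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        n, h, w, c = x.shape
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        self._xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        self._shape = x.shape
        out = np.zeros_like(x)
        for i in range(self.kh):
            for j in range(self.kw):
                out += self._xp[:, i : i + h, j : j + w, :] * self.w[i, j]
        return out + self.b

    def backward(self, grad):
        n, h, w, c = self._shape
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        dxp = np.zeros_like(self._xp)
        for i in range(self.kh):
            for j in range(self.kw):
                self.dw[i, j] = np.einsum(
                    "nhwc,nhwc->c", self._xp[:, i : i + h, j : j + w, :], grad
                )
                dxp[:, i : i + h, j : j + w, :] += grad * self.w[i, j]
        self.db[...] = grad.sum(axis=(0, 1, 2))
        return dxp[:, ph : ph + h, pw : pw + w, :]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class BatchNorm(Layer):
    """Channel-wise batch normalization over (N, H, W) or (N,) axes."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes, m = self._axes, self._m
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        return (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def buffers(self):
        return [self.running_mean, self.running_var]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """3x3 (or k x k) max pooling with stride 1 and same padding."""

    def __init__(self, k=3):
        self.k = k

    def forward(self, x, training):
        n, h, w, c = x.shape
        p = (self.k - 1) // 2
        xp = np.full((n, h + 2 * p, w + 2 * p, c), -np.inf, dtype=x.dtype)
        xp[:, p : p + h, p : p + w, :] = x
        best = np.full(x.shape, -np.inf)
        arg = np.zeros(x.shape, dtype=np.int8)
        for idx in range(self.k * self.k):
            i, j = divmod(idx, self.k)
            cand = xp[:, i : i + h, j : j + w, :]
            better = cand > best
            np.copyto(best, cand, where=better)
            arg[better] = idx
        self._arg = arg
        self._shape = x.shape
        return best

    def backward(self, grad):
        n, h, w, c = self._shape
        p = (self.k - 1) // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for idx in range(self.k * self.k):
            i, j = divmod(idx, self.k)
            mask = self._arg == idx
            dxp[:, i : i + h, j : j + w, :] += grad * mask
        return dxp[:, p : p + h, p : p + w, :]


class Dropout(Layer):
    def __init__(self, rate, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape) >= self.rate
        self._mask = keep.astype(DTYPE) / DTYPE(1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng: np.random.Generator):
        self.w = rng.normal(
            0.0, np.sqrt(2.0 / in_dim), (in_dim, out_dim)
        ).astype(DTYPE)
        self.b = np.zeros(out_dim, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


# ---------------------------------------------------------------------------
# Combinators
# ---------------------------------------------------------------------------


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]


class Parallel(Layer):
    """Run branches on the same input, concatenate outputs channel-wise."""

    def __init__(self, branches):
        self.branches = list(branches)

    def forward(self, x, training):
        outs = [b.forward(x, training) for b in self.branches]
        self._splits = np.cumsum([o.shape[-1] for o in outs])[:-1]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        pieces = np.split(grad, self._splits, axis=-1)
        dx = None
        for branch, piece in zip(self.branches, pieces):
            g = branch.backward(piece)
            dx = g if dx is None else dx + g
        return dx

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def grads(self):
        return [g for b in self.branches for g in b.grads()]

    def buffers(self):
        return [b for br in self.branches for b in br.buffers()]


class ConcatShortcut(Layer):
    """concat_channels(body(x), shortcut(x)) — the concatenating skip path."""

    def __init__(self, body, shortcut):
        self.body = body
        self.shortcut = shortcut

    def forward(self, x, training):
        b = self.body.forward(x, training)
        s = self.shortcut.forward(x, training)
        self._split = b.shape[-1]
        return np.concatenate([b, s], axis=-1)

    def backward(self, grad):
        gb, gs = grad[..., : self._split], grad[..., self._split :]
        return self.body.backward(gb) + self.shortcut.backward(gs)

    def params(self):
        return self.body.params() + self.shortcut.params()

    def grads(self):
        return self.body.grads() + self.shortcut.grads()

    def buffers(self):
        return self.body.buffers() + self.shortcut.buffers()


class AddShortcut(Layer):
    """body(x) + x (identity residual connection)."""

    def __init__(self, body):
        self.body = body

    def forward(self, x, training):
        return self.body.forward(x, training) + x

    def backward(self, grad):
        return self.body.backward(grad) + grad

    def params(self):
        return self.body.params()

    def grads(self):
        return self.body.grads()

    def buffers(self):
        return self.body.buffers()


class MultiStreamNet:
    """Several input streams, feature concatenation, and a dense head.

    ``streams`` map each input to an (N, F_i) feature block; the head maps
    the concatenation to 2-class logits.  ``predict_proba`` applies softmax.
    """

    def __init__(self, streams, head):
        self.streams = list(streams)
        self.head = head

    def forward(self, inputs, training):
        outs = [s.forward(x, training) for s, x in zip(self.streams, inputs)]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        feats = np.concatenate(outs, axis=1)
        return self.head.forward(feats, training)

    def backward(self, grad):
        gfeats = self.head.backward(grad)
        pieces = np.split(gfeats, self._splits, axis=1)
        for stream, piece in zip(self.streams, pieces):
            stream.backward(piece)

    def params(self):
        out = [p for s in self.streams for p in s.params()]
        return out + self.head.params()

    def grads(self):
        out = [g for s in self.streams for g in s.grads()]
        return out + self.head.grads()

    def buffers(self):
        out = [b for s in self.streams for b in s.buffers()]
        return out + self.head.buffers()

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params() + self.buffers()]

    def set_state(self, state) -> None:
        targets = self.params() + self.buffers()
        if len(state) != len(targets):
            raise ValueError("state does not match network structure")
        for dst, src in zip(targets, state):
            dst[...] = src


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class WeightedSoftmaxCE:
    """Fused softmax + class-weighted cross-entropy (mean over the batch)."""

    def __init__(self, class_weights: np.ndarray):
        self.class_weights = np.asarray(class_weights, dtype=DTYPE)

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        self._probs = softmax(logits)
        self._labels = labels
        n = logits.shape[0]
        w = self.class_weights[labels]
        logp = np.log(np.clip(self._probs[np.arange(n), labels], 1e-12, None))
        self._w = w
        return float(-(w * logp).mean())

    def backward(self) -> np.ndarray:
        n = self._probs.shape[0]
        grad = self._probs.copy()
        grad[np.arange(n), self._labels] -= 1.0
        return grad * self._w[:, None] / n


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
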