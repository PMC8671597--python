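"""Minimal convolutional network machinery for the F0 classifiers.

Implemented directly on NumPy with hand-written backpropagation: valid
unstrided convolution, ReLU, Hanning-window weighted average pooling (the
anti-aliasing pooling rule: window extent 1 when the stride is 1, otherwise
4x the stride in each dimension), batch normalization, fully connected
layers, dropout (active during both training and evaluation), and a softmax
cross-entropy head, trained with the Adam optimizer.

Layouts are channels-last: feature maps are (batch, freq, time, channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ArchitectureSpec",
    "sample_architecture",
    "hanning_pool",
    "Conv2D",
    "ReLU",
    "HanningPool",
    "BatchNorm",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "softmax",
    "softmax_xent",
]

KERNEL_COUNT_BOUNDS = (16, 1024)
KERNEL_AREA_CAP = 256


# ---------------------------------------------------------------------------
# Architecture sampling
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Hyperparameters fully describing one convolutional F0 classifier."""

    input_shape: tuple[int, int]
    kernel_counts: list[int]
    kernel_sizes: list[tuple[int, int]]
    pool_strides: list[tuple[int, int]]
    fc_width: int | None
    n_classes: int = 700
    dropout_rate: float = 0.5

    @property
    def n_conv_layers(self) -> int:
        return len(self.kernel_counts)


def _pool_out(n: int, s: int) -> int:
    return -(-n // s)  # ceil division ("same" padding)


def sample_architecture(
    rng: np.random.Generator,
    input_shape: tuple[int, int] = (100, 1000),
    n_classes: int = 700,
) -> ArchitectureSpec:
    """Draw a random architecture from the search distribution.

    1-8 conv layers; first-layer kernel count 16/32/64 with probability 1/3
    each, then x2 (p=1/2), x1 (p=1/3) or /2 (p=1/6) per layer, bounded to
    [16, 1024]; kernel frequency dims uniform on 1..Nf/2 and time dims on
    Nt/20..Nt/2 with the freq x time area capped at 256 by resampling;
    pooling strides uniform on 1..4 (freq) and 1..8 (time); a penultimate
    fully connected layer exists with probability 1/2 with width in
    {128, 256, 512, 1024}.  Pure function of the generator state.
    """
    n_layers = int(rng.integers(1, 9))
    counts, sizes, strides = [], [], []
    nf, nt = input_shape
    count = int(rng.choice([16, 32, 64]))
    for layer in range(n_layers):
        if layer > 0:
            factor = rng.choice([2.0, 1.0, 0.5], p=[1 / 2, 1 / 3, 1 / 6])
            count = int(np.clip(count * factor, *KERNEL_COUNT_BOUNDS))
        kf_hi = max(nf // 2, 1)
        kt_lo, kt_hi = max(nt // 20, 1), max(nt // 2, 1)
        for _ in range(10000):
            kf = int(rng.integers(1, kf_hi + 1))
            kt = int(rng.integers(kt_lo, kt_hi + 1))
            if kf * kt <= KERNEL_AREA_CAP:
                break
        else:  # pragma: no cover - distribution always admits area <= cap
            kf, kt = 1, min(kt_lo, KERNEL_AREA_CAP)
        sf = int(rng.integers(1, 5))
        st = int(rng.integers(1, 9))
        counts.append(count)
        sizes.append((kf, kt))
        strides.append((sf, st))
        nf = _pool_out(nf - kf + 1, sf)
        nt = _pool_out(nt - kt + 1, st)
    fc = int(rng.choice([128, 256, 512, 1024])) if rng.random() < 0.5 else None
    return ArchitectureSpec(tuple(input_shape), counts, sizes, strides, fc,
                            n_classes)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """Valid, unstrided 2-D convolution (cross-correlation), channels-last."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        fan_in = kh * kw * in_ch
        self.W = (rng.standard_normal((kh, kw, in_ch, out_ch))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.kernel = kernel

    def forward(self, x, train=False, rng=None):
        kh, kw = self.kernel
        # patches: (B, Ho, Wo, C, kh, kw)
        p = sliding_window_view(x, (kh, kw), axis=(1, 2))
        B, Ho, Wo = p.shape[:3]
        # patches flattened in (kh, kw, C) order to match W's layout
        self._patches = p.transpose(0, 1, 2, 4, 5, 3).reshape(B, Ho, Wo, -1)
        Wflat = self.W.reshape(kh * kw * self.W.shape[2], -1)
        y = self._patches @ Wflat + self.b
        self._x_shape = x.shape
        return y

    def backward(self, grad):
        kh, kw = self.kernel
        B, Ho, Wo, Cout = grad.shape
        Cin = self.W.shape[2]
        g2 = grad.reshape(-1, Cout).astype(np.float32)
        dW = (self._patches.reshape(-1, kh * kw * Cin).T @ g2)
        self.grads[0][...] = dW.reshape(self.W.shape)
        self.grads[1][...] = g2.sum(axis=0)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        Wr = self.W  # (kh, kw, Cin, Cout)
        for i in range(kh):
            for j in range(kw):
                dx[:, i:i + Ho, j:j + Wo, :] += grad @ Wr[i, j].T
        self._patches = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


def _hanning_kernel(s: int) -> np.ndarray:
    """1-D Hanning pooling window: length 1 if the stride is 1, else 4*s."""
    if s == 1:
        return np.ones(1)
    return np.hanning(4 * s)


def hanning_pool(x: np.ndarray, stride_f: int, stride_t: int) -> np.ndarray:
    """Functional Hanning-window weighted average pooling (channels-last).

    Strided convolution with a normalized 2-D Hanning kernel ("same"
    padding); output spatial dims are ceil(input / stride).  Constant inputs
    are preserved up to edge effects of the zero padding.
    """
    layer = HanningPool(stride_f, stride_t)
    return layer.forward(np.asarray(x, dtype=np.float32))


class HanningPool(Layer):
    """Strided convolution with a separable, sum-normalized 2-D Hanning
    kernel and "same"-style zero padding, realized as one dense pooling
    matrix per axis (exact, and fast as two BLAS matmuls)."""

    def __init__(self, stride_f: int, stride_t: int):
        super().__init__()
        if stride_f < 1 or stride_t < 1:
            raise ValueError("strides must be >= 1")
        self.s = (stride_f, stride_t)
        kf = _hanning_kernel(stride_f)
        kt = _hanning_kernel(stride_t)
        self.kernel = np.outer(kf, kt)
        self.kernel = (self.kernel / self.kernel.sum()).astype(np.float32)
        self._kf = (kf / kf.sum()).astype(np.float32)
        self._kt = (kt / kt.sum()).astype(np.float32)
        self._mats: dict = {}

    @staticmethod
    def _pool_matrix(n: int, s: int, k1d: np.ndarray) -> np.ndarray:
        """(out, n) matrix: row m holds the kernel at offset m*s - pad_left."""
        k = len(k1d)
        out = _pool_out(n, s)
        pad = max((out - 1) * s + k - n, 0)
        left = pad // 2
        P = np.zeros((out, n), dtype=np.float32)
        for m in range(out):
            start = m * s - left
            for i in range(k):
                if 0 <= start + i < n:
                    P[m, start + i] = k1d[i]
        return P

    def _matrices(self, H: int, W: int):
        key = (H, W)
        if key not in self._mats:
            self._mats[key] = (self._pool_matrix(H, self.s[0], self._kf),
                               self._pool_matrix(W, self.s[1], self._kt))
        return self._mats[key]

    def forward(self, x, train=False, rng=None):
        B, H, W, C = x.shape
        if self.s[0] > H or self.s[1] > W:
            raise ValueError("pooling stride exceeds input dimension")
        Pf, Pt = self._matrices(H, W)
        # y[b,h,w,c] = sum_{H,W} Pf[h,H] x[b,H,W,c] Pt[w,W]
        t = np.tensordot(x, Pt, axes=([2], [1]))       # (B, H, C, Wo)
        y = np.tensordot(t, Pf, axes=([1], [1]))       # (B, C, Wo, Ho)
        self._shape = (B, H, W, C)
        return np.ascontiguousarray(
            y.transpose(0, 3, 2, 1)).astype(np.float32)

    def backward(self, grad):
        B, H, W, C = self._shape
        Pf, Pt = self._matrices(H, W)
        g = grad.transpose(0, 3, 2, 1)                 # (B, C, Wo, Ho)
        t = np.tensordot(g, Pf, axes=([3], [0]))       # (B, C, Wo, H)
        dx = np.tensordot(t, Pt, axes=([2], [0]))      # (B, C, H, W)
        return np.ascontiguousarray(
            dx.transpose(0, 2, 3, 1)).astype(np.float32)


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics.

    Running moments are zero-initialized and bias-corrected by
    1 - momentum**n_updates at evaluation time, so short training runs do not
    evaluate against the (arbitrary) initialization."""

    def __init__(self, n_ch: int, eps: float = 1e-3, momentum: float = 0.99):
        super().__init__()
        self.gamma = np.ones(n_ch, dtype=np.float32)
        self.beta = np.zeros(n_ch, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.eps, self.momentum = eps, momentum
        self.run_mean = np.zeros(n_ch, dtype=np.float32)
        self.run_var = np.zeros(n_ch, dtype=np.float32)
        self.n_updates = 0

    def _running_moments(self):
        if self.n_updates == 0:
            return self.run_mean, np.ones_like(self.run_var)
        corr = 1.0 - self.momentum**self.n_updates
        return self.run_mean / corr, self.run_var / corr

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mu)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var)
            self.n_updates += 1
        else:
            mu, var = self._running_moments()
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._axes, self._n = axes, x.size // x.shape[-1]
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        if not self._train:
            return grad * self.gamma / self._std
        n = self._n
        gxh = grad * self.gamma
        dx = (gxh - gxh.mean(axis=axes)
              - self._xhat * (gxh * self._xhat).mean(axis=axes)) / self._std
        return dx.astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Random zeroing with 1/(1-r) rescaling; active at train AND eval."""

    def __init__(self, rate: float = 0.5):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if rng is None:
            raise ValueError("dropout requires an rng (it is active at eval too)")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


# ---------------------------------------------------------------------------
# Softmax cross-entropy
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-12)))
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

class Network:
    """Conv blocks (Conv-ReLU-HanningPool-BatchNorm), optional penultimate
    fully connected layer (Dense-ReLU-BatchNorm), dropout, softmax head."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        layers = []
        self.conv_relu_idx = []  # indices of per-conv-layer ReLU activations
        nf, nt = spec.input_shape
        ch = 1
        for count, (kf, kt), (sf, st) in zip(spec.kernel_counts,
                                             spec.kernel_sizes,
                                             spec.pool_strides):
            if kf > nf or kt > nt:
                raise ValueError("kernel larger than its input feature map")
            layers.append(Conv2D(ch, count, (kf, kt), rng))
            layers.append(ReLU())
            self.conv_relu_idx.append(len(layers) - 1)
            layers.append(HanningPool(sf, st))
            layers.append(BatchNorm(count))
            nf, nt = _pool_out(nf - kf + 1, sf), _pool_out(nt - kt + 1, st)
            ch = count
        layers.append(Flatten())
        n_flat = nf * nt * ch
        self.fc_relu_idx = None
        if spec.fc_width is not None:
            layers.append(Dense(n_flat, spec.fc_width, rng))
            layers.append(ReLU())
            self.fc_relu_idx = len(layers) - 1
            layers.append(BatchNorm(spec.fc_width))
            n_flat = spec.fc_width
        layers.append(Dropout(spec.dropout_rate))
        layers.append(Dense(n_flat, spec.n_classes, rng))
        self.layers = layers

    def forward(self, x, train: bool, rng: np.random.Generator,
                collect: bool = False):
        """Logits for a (B, nf, nt) batch; optionally collect ReLU activations."""
        x = np.asarray(x, dtype=np.float32)[..., None]
        acts = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train, rng=rng)
            if collect and (i in self.conv_relu_idx or i == self.fc_relu_idx):
                acts.append(x)
        return (x, acts) if collect else x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def layer_names(self):
        names = [f"conv{i + 1}" for i in range(len(self.conv_relu_idx))]
        if self.fc_relu_idx is not None:
            names.append("fc_intermediate")
        names.append("fc_output")
        return names


class Adam:
    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
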