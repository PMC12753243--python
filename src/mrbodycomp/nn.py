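"""Minimal CPU conv-net framework (numpy, manual backprop).

Provides exactly the pieces a small 2D encoder–decoder segmentation network
needs: 3×3/1×1 same-padding convolutions (im2col + BLAS matmul), ReLU, 2×2 max
pooling, nearest-neighbor ×2 upsampling, channel concatenation, softmax, a
combined cross-entropy + soft-Dice loss with its analytic gradient, and Adam.
Everything is float32, deterministic for a fixed seed, and gradient-checked
numerically in the test suite.

Tensors are ``(N, C, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D", "InstanceNorm2D", "ReLU", "MaxPool2", "Upsample2", "Adam",
    "softmax", "ce_dice_loss_and_grad", "softmax_cross_entropy",
    "soft_dice_loss",
]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2D:
    """Same-padding convolution with kernel size 1 or 3, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.w = _he_init(rng, (out_ch, in_ch, kernel, kernel),
                          fan_in=in_ch * kernel * kernel)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._x_shape = None

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.k == 1:
            return x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # win: (n, c, h, w, 3, 3) -> (n*h*w, c*9)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * 9)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x_shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        wm = self.w.reshape(self.out_ch, -1)
        y = cols @ wm.T + self.b
        return np.ascontiguousarray(
            y.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        dyc = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        wm = self.w.reshape(self.out_ch, -1)
        self.dw[...] = (dyc.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dyc.sum(axis=0)
        dcols = dyc @ wm  # (n*h*w, c*k*k)
        if self.k == 1:
            return np.ascontiguousarray(
                dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2))
        dcols = dcols.reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]


class InstanceNorm2D:
    """Per-sample, per-channel normalization with learned scale/shift.

    Stable for very small batches (unlike batch statistics) and markedly
    accelerates convergence of small segmentation networks.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5):
        self.gamma = np.ones(n_ch, dtype=np.float32)
        self.beta = np.zeros(n_ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps

    @property
    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return (self.gamma[None, :, None, None] * self._xhat
                + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        m = xhat.shape[2] * xhat.shape[3]
        dx = (dxhat - dxhat.mean(axis=(2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)) * inv
        return dx.astype(np.float32)


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2:
    """2×2 max pooling, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbor ×2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam over a flat list of (param, grad) array pairs (updated in place)."""

    def __init__(self, params, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                          eps: float = 1e-12) -> float:
    """Mean per-pixel categorical cross-entropy of predicted probabilities."""
    n_pix = probs.shape[0] * probs.shape[2] * probs.shape[3]
    return float(-(onehot * np.log(probs + eps)).sum() / n_pix)


def soft_dice_loss(probs: np.ndarray, onehot: np.ndarray,
                   smooth: float = 1e-6) -> float:
    """``1 - mean_c soft-Dice(c)`` where soft-Dice uses predicted
    probabilities: ``(2 Σ p y + s) / (Σ p + Σ y + s)`` per class, summed over
    batch and pixels."""
    axes = (0, 2, 3)
    inter = (probs * onehot).sum(axis=axes)
    denom = probs.sum(axis=axes) + onehot.sum(axis=axes)
    d = (2.0 * inter + smooth) / (denom + smooth)
    return float(1.0 - d.mean())


def ce_dice_loss_and_grad(logits: np.ndarray, onehot: np.ndarray,
                          w_ce: float = 1.0, w_dice: float = 1.0,
                          smooth: float = 1e-6):
    """Combined ``w_ce·CE + w_dice·(1 − mean soft-Dice)`` and its analytic
    gradient with respect to the logits."""
    probs = softmax(logits)
    n, c, h, w = probs.shape
    n_pix = n * h * w

    ce = softmax_cross_entropy(probs, onehot)
    dice_l = soft_dice_loss(probs, onehot, smooth)
    loss = w_ce * ce + w_dice * dice_l

    # CE gradient wrt logits
    dlogits = w_ce * (probs - onehot) / n_pix

    # Dice gradient wrt probabilities, then through the softmax Jacobian
    axes = (0, 2, 3)
    inter = (probs * onehot).sum(axis=axes)
    denom = probs.sum(axis=axes) + onehot.sum(axis=axes)
    # d(1 - mean_c D_c)/dp_c(i) = -(1/C)(2 y_i (denom+s) - (2 inter + s)) / (denom+s)^2
    num = 2.0 * inter + smooth
    den = denom + smooth
    dD_dp = (2.0 * onehot * den[None, :, None, None]
             - num[None, :, None, None]) / (den ** 2)[None, :, None, None]
    dl_dp = -(w_dice / c) * dD_dp
    inner = (dl_dp * probs).sum(axis=1, keepdims=True)
    dlogits += probs * (dl_dp - inner)

    return loss, dlogits.astype(np.float32)
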