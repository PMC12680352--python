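"""Compact numpy convolutional autoencoder for AFM image stacks.

The encoder is three stride-2 3x3 convolution blocks followed by a dense
projection to the latent space; the decoder mirrors it with nearest-
neighbor upsampling + convolution and a sigmoid output.  Training
minimizes the weighted structural-dissimilarity loss

    L = 1 - (alpha * SSIM + beta * SSIM_masked) / (alpha + beta)

whose gradient is computed analytically: every local SSIM statistic is a
Gaussian filtering of the input, and with zero-padded boundaries the
Gaussian filter is self-adjoint, so backpropagation through the SSIM map
is again a Gaussian filtering (verified against finite differences in the
test suite).  A plain MSE loss is available as an option.

Images fed to the network are expected in [0, 1] (stack-max normalized);
input height/width must be divisible by 8.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["CAE", "ssim_loss_and_grad", "mse_loss_and_grad"]

_C1 = 0.01**2  # stabilizers for data_range 1
_C2 = 0.03**2


def _gauss(a: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian filter over the last two axes, zero-pad boundary."""
    a = gaussian_filter1d(a, sigma, axis=-1, mode="constant", cval=0.0, truncate=3.5)
    return gaussian_filter1d(a, sigma, axis=-2, mode="constant", cval=0.0, truncate=3.5)


def ssim_loss_and_grad(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    beta: float = 0.5,
    sigma: float = 1.5,
    mask_fraction: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Weighted 1-SSIM loss between targets ``x`` and reconstructions ``y``.

    Both are (B, H, W) in [0, 1].  Returns (loss, dloss/dy).  The
    foreground mask (pixels above ``mask_fraction`` of each pair's max) is
    treated as a constant with respect to ``y``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    b, h, w = x.shape
    mu_x, mu_y = _gauss(x, sigma), _gauss(y, sigma)
    sxx, syy, sxy = _gauss(x * x, sigma), _gauss(y * y, sigma), _gauss(x * y, sigma)
    vx = sxx - mu_x**2
    vy = syy - mu_y**2
    cxy = sxy - mu_x * mu_y
    a1 = 2.0 * mu_x * mu_y + _C1
    a2 = 2.0 * cxy + _C2
    b1 = mu_x**2 + mu_y**2 + _C1
    b2 = vx + vy + _C2
    s = (a1 * a2) / (b1 * b2)

    pair_max = np.maximum(x.max(axis=(1, 2)), y.max(axis=(1, 2)))
    thr = (mask_fraction * pair_max)[:, None, None]
    mask = (x > thr) | (y > thr)
    counts = mask.sum(axis=(1, 2))
    # fall back to the global mean for images with an empty foreground
    safe = counts > 0
    g_term = s.mean(axis=(1, 2))
    m_term = np.where(safe, (s * mask).sum(axis=(1, 2)) / np.maximum(counts, 1), g_term)
    denom = alpha + beta
    loss = 1.0 - float(np.mean((alpha * g_term + beta * m_term) / denom))

    # dL/dS per pixel
    w_glob = alpha / (h * w)
    w_mask = np.where(safe, beta / np.maximum(counts, 1), beta / (h * w))[:, None, None]
    mask_w = np.where(safe[:, None, None], mask, True)
    dlds = -(w_glob + w_mask * mask_w) / (denom * b)

    ds_dmu_y = 2.0 * a2 * (mu_x * b1 - mu_y * a1) / (b1**2 * b2)
    ds_dvy = -(a1 * a2) / (b1 * b2**2)
    ds_dcxy = 2.0 * a1 / (b1 * b2)
    grad = (
        _gauss(dlds * (ds_dmu_y - 2.0 * mu_y * ds_dvy - mu_x * ds_dcxy), sigma)
        + 2.0 * y * _gauss(dlds * ds_dvy, sigma)
        + x * _gauss(dlds * ds_dcxy, sigma)
    )
    return loss, grad


def mse_loss_and_grad(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    diff = y - x
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


# --------------------------------------------------------------------------
# Layers.  Each exposes forward(x) and backward(grad) and lists its
# (param, grad) pairs for the optimizer.


class _Layer:
    params: list

    def __init__(self) -> None:
        self.params = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(_Layer):
    """3x3 'same' convolution with configurable stride."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        k = 3
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        bsz, ci, h, w = x.shape
        s = self.stride
        ho, wo = h // s, w // s
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.empty((bsz, ci, 3, 3, ho, wo))
        for i in range(3):
            for j in range(3):
                cols[:, :, i, j] = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
        self._cols, self._xshape = cols, x.shape
        y = np.einsum("bcijhw,ocij->bohw", cols, self.W, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        bsz, ci, h, w = self._xshape
        s = self.stride
        ho, wo = g.shape[2], g.shape[3]
        self.dW += np.einsum("bcijhw,bohw->ocij", self._cols, g, optimize=True)
        self.db += g.sum(axis=(0, 2, 3))
        dcols = np.einsum("ocij,bohw->bcijhw", self.W, g, optimize=True)
        dxp = np.zeros((bsz, ci, h + 2, w + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, i, j]
        return dxp[:, :, 1:-1, 1:-1]


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ g
        self.db += g.sum(axis=0)
        return g @ self.W.T


class ReLU(_Layer):
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, g):
        return g * self._m


class Sigmoid(_Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class Upsample2(_Layer):
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g):
        b, c, h, w = g.shape
        return g.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Reshape(_Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, g):
        return g.reshape(g.shape[0], -1)


class CAE:
    """Convolutional autoencoder with Adam training.

    All randomness (weight init, batch order) derives from ``seed``.
    """

    def __init__(
        self,
        input_shape: tuple[int, int],
        latent_dim: int = 64,
        conv_channels: tuple[int, int, int] = (16, 32, 64),
        seed: int = 0,
    ):
        h, w = input_shape
        if h % 8 or w % 8:
            raise ValueError("input height and width must be divisible by 8")
        self.input_shape = input_shape
        rng = np.random.default_rng(seed)
        c1, c2, c3 = conv_channels
        hb, wb = h // 8, w // 8
        self.encoder = [
            Conv2D(1, c1, 2, rng), ReLU(),
            Conv2D(c1, c2, 2, rng), ReLU(),
            Conv2D(c2, c3, 2, rng), ReLU(),
            Flatten(),
            Dense(c3 * hb * wb, latent_dim, rng),
        ]
        self.decoder = [
            Dense(latent_dim, c3 * hb * wb, rng), ReLU(),
            Reshape((c3, hb, wb)),
            Upsample2(), Conv2D(c3, c2, 1, rng), ReLU(),
            Upsample2(), Conv2D(c2, c1, 1, rng), ReLU(),
            Upsample2(), Conv2D(c1, 1, 1, rng),
            Sigmoid(),
        ]
        self._layers = self.encoder + self.decoder
        self._adam_m = [np.zeros_like(p) for lyr in self._layers for p, _ in lyr.params]
        self._adam_v = [np.zeros_like(p) for lyr in self._layers for p, _ in lyr.params]
        self._adam_t = 0
        self.history: list[float] = []
        self._rng = rng

    # -- forward / backward -------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        """x: (B, H, W) in [0, 1] -> latent (B, latent_dim)."""
        h = x[:, None, :, :]
        for lyr in self.encoder:
            h = lyr.forward(h)
        return h

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = self.encode(x)
        h = z
        for lyr in self.decoder:
            h = lyr.forward(h)
        return z, h[:, 0, :, :]

    def _backward(self, gy: np.ndarray) -> None:
        g = gy[:, None, :, :]
        for lyr in reversed(self.decoder):
            g = lyr.backward(g)
        for lyr in reversed(self.encoder):
            g = lyr.backward(g)

    def _zero_grads(self) -> None:
        for lyr in self._layers:
            for _, grad in lyr.params:
                grad[...] = 0.0

    def _adam_step(self, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        i = 0
        for lyr in self._layers:
            for p, g in lyr.params:
                self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g
                self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g * g
                mh = self._adam_m[i] / (1 - b1**self._adam_t)
                vh = self._adam_v[i] / (1 - b2**self._adam_t)
                p -= lr * mh / (np.sqrt(vh) + eps)
                i += 1

    # -- training -----------------------------------------------------------
    def fit(
        self,
        images: np.ndarray,
        epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        loss: str = "ssim",
        loss_weights: tuple[float, float] = (0.5, 0.5),
    ) -> list[float]:
        """Train on (N, H, W) images in [0, 1]; returns per-epoch mean loss."""
        images = np.asarray(images, dtype=np.float64)
        n = images.shape[0]
        batch_size = min(batch_size, n)
        alpha, beta = loss_weights
        for _ in range(epochs):
            order = self._rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, batch_size):
                xb = images[order[start : start + batch_size]]
                self._zero_grads()
                _, yb = self.forward(xb)
                if loss == "ssim":
                    lval, gy = ssim_loss_and_grad(xb, yb, alpha, beta)
                elif loss == "mse":
                    lval, gy = mse_loss_and_grad(xb, yb)
                else:
                    raise ValueError(f"unknown loss '{loss}'")
                if not np.isfinite(lval):
                    raise FloatingPointError("training diverged: non-finite loss")
                self._backward(gy)
                self._adam_step(learning_rate)
                epoch_losses.append(lval)
            self.history.append(float(np.mean(epoch_losses)))
        return self.history
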