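"""Minimal convolutional autoencoder on the (landmark x time) grid.

The network is the anomaly-detection backbone: a 7-layer convolutional
encoder and a 7-layer convolutional decoder over the 21 x 128
(landmark x time) grid, with the 3 coordinates as input channels.  All
convolutions are 3 x 3 with same padding; the encoder downsamples with
strided convolutions (time stride 2 on alternating layers, one landmark
stride 3), the decoder mirrors them with nearest-neighbour
resize-convolutions, and the final layer is linear so reconstructed
coordinates are unbounded.

Everything is plain numpy: convolution forward/backward are expressed as nine
shifted-slice matrix products (one per kernel tap), which keeps memory flat
and vectorizes over the batch.  Training uses Adam on the mean-squared
reconstruction error with an early-stopping rule on the smoothed loss.
Float32 arithmetic; fully deterministic for a given seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import NonFiniteLoss, ShapeMismatch

KERNEL = 3
PAD = 1

INPUT_SHAPE = (3, 21, 128)  # channels (x,y,z), landmarks, time samples


@dataclasses.dataclass(frozen=True)
class AutoencoderConfig:
    """Architecture and optimization settings.

    ``encoder_channels[i]`` is the output-channel count of encoder layer ``i``
    and ``encoder_strides[i]`` its (landmark, time) stride; the decoder is the
    mirror image (reversed channel schedule, nearest-neighbour upsampling by
    the reversed strides).  The default bottleneck is a 4-channel 7 x 8
    feature map, i.e. a 224-dimensional latent code for the 8 064-element
    input.
    """

    encoder_channels: Sequence[int] = (8, 8, 16, 16, 32, 32, 4)
    encoder_strides: Sequence[tuple[int, int]] = (
        (1, 2), (1, 1), (3, 2), (1, 1), (1, 2), (1, 1), (1, 2),
    )
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 300
    patience: int = 20
    tol: float = 1e-6

    def __post_init__(self):
        if len(self.encoder_channels) != len(self.encoder_strides):
            raise ValueError("channel and stride schedules differ in length")

    @property
    def n_encoder_layers(self) -> int:
        return len(self.encoder_channels)

    @property
    def n_decoder_layers(self) -> int:
        return len(self.encoder_channels)

    def bottleneck_shape(self, input_shape=INPUT_SHAPE) -> tuple[int, int, int]:
        _, h, w = input_shape
        for (sh, sw) in self.encoder_strides:
            h = (h + 2 * PAD - KERNEL) // sh + 1
            w = (w + 2 * PAD - KERNEL) // sw + 1
        return (self.encoder_channels[-1], h, w)

    @property
    def latent_dim(self) -> int:
        return int(np.prod(self.bottleneck_shape()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoder_channels"] = list(self.encoder_channels)
        d["encoder_strides"] = [list(s) for s in self.encoder_strides]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AutoencoderConfig":
        d = dict(d)
        d["encoder_channels"] = tuple(d["encoder_channels"])
        d["encoder_strides"] = tuple(tuple(s) for s in d["encoder_strides"])
        return cls(**d)


# ---------------------------------------------------------------------------
# convolution primitives (3x3, same padding, arbitrary stride)
# ---------------------------------------------------------------------------

def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                 stride: tuple[int, int]) -> np.ndarray:
    sh, sw = stride
    n, _, h, wd = x.shape
    c_out = w.shape[0]
    ho = (h + 2 * PAD - KERNEL) // sh + 1
    wo = (wd + 2 * PAD - KERNEL) // sw + 1
    xp = np.pad(x, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD)))
    acc = np.zeros((n, ho, wo, c_out), dtype=x.dtype)
    for ki in range(KERNEL):
        for kj in range(KERNEL):
            xs = xp[:, :, ki:ki + sh * ho:sh, kj:kj + sw * wo:sw]
            # (N,Ho,Wo,Cin) @ (Cin,Cout)
            acc += np.tensordot(xs, w[:, :, ki, kj], axes=([1], [1]))
    acc += b
    return np.ascontiguousarray(acc.transpose(0, 3, 1, 2))


def conv_backward(dy: np.ndarray, x: np.ndarray, w: np.ndarray,
                  stride: tuple[int, int]):
    sh, sw = stride
    n, _, h, wd = x.shape
    _, _, ho, wo = dy.shape
    xp = np.pad(x, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    db = dy.sum(axis=(0, 2, 3))
    dy_nhwc = dy.transpose(0, 2, 3, 1)
    for ki in range(KERNEL):
        for kj in range(KERNEL):
            xs = xp[:, :, ki:ki + sh * ho:sh, kj:kj + sw * wo:sw]
            dw[:, :, ki, kj] = np.tensordot(dy, xs, axes=([0, 2, 3], [0, 2, 3]))
            dxs = np.tensordot(dy_nhwc, w[:, :, ki, kj], axes=([3], [0]))
            dxp[:, :, ki:ki + sh * ho:sh, kj:kj + sw * wo:sw] += dxs.transpose(0, 3, 1, 2)
    dx = dxp[:, :, PAD:PAD + h, PAD:PAD + wd]
    return dx, dw, db


def upsample_forward(x: np.ndarray, factor: tuple[int, int]) -> np.ndarray:
    fh, fw = factor
    if fh == 1 and fw == 1:
        return x
    return x.repeat(fh, axis=2).repeat(fw, axis=3)


def upsample_backward(dy: np.ndarray, factor: tuple[int, int]) -> np.ndarray:
    fh, fw = factor
    if fh == 1 and fw == 1:
        return dy
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // fh, fh, w // fw, fw).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# the autoencoder
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _ConvLayer:
    w: np.ndarray
    b: np.ndarray
    stride: tuple[int, int]       # encoder: conv stride; decoder: (1,1)
    upsample: tuple[int, int]     # decoder: pre-conv resize factor
    relu: bool


class ConvAutoencoder:
    """7+7-layer convolutional autoencoder trained by Adam on MSE."""

    def __init__(self, config: AutoencoderConfig | None = None, seed: int = 0,
                 input_shape: tuple[int, int, int] = INPUT_SHAPE):
        self.config = config or AutoencoderConfig()
        self.input_shape = input_shape
        self.loss_history: list[float] = []
        self._build(np.random.default_rng(seed))

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        self.layers: list[_ConvLayer] = []

        def make(c_in, c_out, stride, upsample, relu):
            std = np.sqrt(2.0 / (c_in * KERNEL * KERNEL))
            w = rng.normal(0.0, std, size=(c_out, c_in, KERNEL, KERNEL)).astype(np.float32)
            b = np.zeros(c_out, dtype=np.float32)
            self.layers.append(_ConvLayer(w, b, stride, upsample, relu))

        c_prev = self.input_shape[0]
        for c_out, stride in zip(cfg.encoder_channels, cfg.encoder_strides):
            make(c_prev, c_out, stride, (1, 1), relu=True)
            c_prev = c_out
        self.n_encoder_layers = len(self.layers)

        dec_channels = list(cfg.encoder_channels[-2::-1]) + [self.input_shape[0]]
        dec_upsamples = list(cfg.encoder_strides[::-1])
        for i, (c_out, up) in enumerate(zip(dec_channels, dec_upsamples)):
            last = i == len(dec_channels) - 1
            make(c_prev, c_out, (1, 1), up, relu=not last)
            c_prev = c_out

        out_shape = self._forward(np.zeros((1, *self.input_shape), dtype=np.float32))[0].shape
        if out_shape[1:] != self.input_shape:
            raise ShapeMismatch(
                f"decoder output {out_shape[1:]} does not match input {self.input_shape}"
            )

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        caches = []
        h = x
        latent = None
        for i, layer in enumerate(self.layers):
            h_up = upsample_forward(h, layer.upsample)
            z = conv_forward(h_up, layer.w, layer.b, layer.stride)
            a = np.maximum(z, 0.0) if layer.relu else z
            if want_cache:
                caches.append((h_up, z))
            h = a
            if i == self.n_encoder_layers - 1:
                latent = h
        return h, latent, caches

    def _backward(self, dy: np.ndarray, caches) -> list[tuple[np.ndarray, np.ndarray]]:
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.layers)
        for i in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[i]
            h_up, z = caches[i]
            if layer.relu:
                dy = dy * (z > 0)
            dx, dw, db = conv_backward(dy, h_up, layer.w, layer.stride)
            grads[i] = (dw, db)
            dy = upsample_backward(dx, layer.upsample)
        return grads

    # -- public API ----------------------------------------------------------

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Reconstruct a batch (N, C, H, W) or a single sample (C, H, W)."""
        single = x.ndim == 3
        xb = x[None] if single else x
        if xb.shape[1:] != self.input_shape:
            raise ShapeMismatch(f"expected {self.input_shape}, got {xb.shape[1:]}")
        out = self._forward(xb.astype(np.float32))[0]
        return out[0] if single else out

    def encode(self, x: np.ndarray) -> np.ndarray:
        single = x.ndim == 3
        xb = x[None] if single else x
        latent = self._forward(xb.astype(np.float32))[1]
        return latent[0] if single else latent

    def fit(self, x: np.ndarray, seed: int = 0, verbose: bool = False) -> list[float]:
        """Train to convergence of the mean reconstruction error.

        Stops when the patience-window moving average of the epoch loss has
        not improved by more than ``tol`` for ``patience`` epochs, or at
        ``max_epochs``.  Returns the per-epoch loss history.
        """
        cfg = self.config
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise ShapeMismatch(f"training array must be (N, {self.input_shape})")
        n = x.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(seed)

        adam_m = [(np.zeros_like(l.w), np.zeros_like(l.b)) for l in self.layers]
        adam_v = [(np.zeros_like(l.w), np.zeros_like(l.b)) for l in self.layers]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best = np.inf
        stale = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = x[order[start:start + cfg.batch_size]]
                out, _, caches = self._forward(batch, want_cache=True)
                diff = out - batch
                loss = float(np.mean(diff.astype(np.float64) ** 2))
                if not np.isfinite(loss):
                    raise NonFiniteLoss(f"loss {loss} at epoch {epoch}")
                epoch_loss += loss * batch.shape[0]
                dy = (2.0 / diff.size) * diff
                grads = self._backward(dy, caches)
                t += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
                for layer, (dw, db), m, v in zip(self.layers, grads, adam_m, adam_v):
                    for p, g, m_, v_ in ((layer.w, dw, m[0], v[0]),
                                         (layer.b, db, m[1], v[1])):
                        m_ *= beta1
                        m_ += (1 - beta1) * g
                        v_ *= beta2
                        v_ += (1 - beta2) * g * g
                        p -= lr_t * m_ / (np.sqrt(v_) + eps)
            epoch_loss /= n
            self.loss_history.append(epoch_loss)
            if verbose and epoch % 10 == 0:  # pragma: no cover
                print(f"epoch {epoch:4d}  mse {epoch_loss:.3e}")
            window = np.mean(self.loss_history[-cfg.patience:])
            if window < best - cfg.tol:
                best = window
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        return self.loss_history

    # -- persistence ----------------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            out[f"w{i}"] = layer.w
            out[f"b{i}"] = layer.b
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            w, b = weights[f"w{i}"], weights[f"b{i}"]
            if w.shape != layer.w.shape or b.shape != layer.b.shape:
                raise ShapeMismatch(f"weight shape mismatch at layer {i}")
            layer.w = w.astype(np.float32)
            layer.b = b.astype(np.float32)
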