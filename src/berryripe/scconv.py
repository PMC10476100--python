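"""Self-calibrated convolution: a standalone forward-pass implementation.

A standard convolution layer with C input and C output channels applies one
kernel set of shape (C, C, w, h).  Self-calibrated convolution splits that
set into four groups K1..K4, each of shape (C/2, C/2, w, h), and the input
feature map into halves A and B:

* branch A: plain convolution with K1;
* branch B: a calibration path — B is average-pool down-sampled by a rate
  ``r``, convolved with K2, bilinearly up-sampled back, added to B and
  passed through a logistic map, yielding weights in (0, 1); those weights
  gate (element-wise multiply) the K3 convolution of B, which is then
  convolved with K4.

The two halves are concatenated to form the output, which has the same
shape as the input.  The down-sampled path sees a receptive field ``r``
times larger, so deep context calibrates shallow detail — at exactly the
parameter count of the standard convolution (4 · (C/2)² = C² kernels).

All convolutions here are stride-1 cross-correlations with zero
same-padding and no bias, the CNN convention.  Pure NumPy/SciPy, inference
only: no gradients, no training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import BadShape


@dataclass(frozen=True)
class SCConvParams:
    """The four kernel groups and the down-sampling rate of the block.

    Each kernel has shape (C/2, C/2, w, h) = (out-channels, in-channels,
    kernel rows, kernel cols).
    """

    K1: np.ndarray
    K2: np.ndarray
    K3: np.ndarray
    K4: np.ndarray
    r: int

    def __post_init__(self):
        shapes = {k.shape for k in (self.K1, self.K2, self.K3, self.K4)}
        if len(shapes) != 1:
            raise BadShape(f"kernel groups must share one shape, got {shapes}")
        shape = next(iter(shapes))
        if len(shape) != 4 or shape[0] != shape[1]:
            raise BadShape(
                f"kernels must have shape (C/2, C/2, w, h), got {shape}"
            )
        if self.r < 2:
            raise BadShape(f"down-sampling rate must be >= 2, got {self.r}")

    @property
    def channels(self) -> int:
        """Total channel count C of the block (twice the per-group count)."""
        return 2 * self.K1.shape[0]

    @property
    def kernel_size(self) -> tuple[int, int]:
        return self.K1.shape[2], self.K1.shape[3]

    def shape_summary(self) -> dict:
        """JSON-friendly description of the parameter layout."""
        return {
            "channels": self.channels,
            "kernel_size": list(self.kernel_size),
            "group_shape": list(self.K1.shape),
            "down_sampling_rate": self.r,
            "param_count": param_count(self),
        }


def init_params(C: int, w: int, h: int, r: int = 4, seed: int = 0) -> SCConvParams:
    """Draw the four kernel groups from a seeded normal distribution.

    ``C`` must be even (the channel split), ``w``/``h`` odd (so same-padding
    is symmetric), ``r`` at least 2.
    """
    if C % 2 != 0 or C < 2:
        raise BadShape(f"channel count must be even and >= 2, got {C}")
    if w % 2 != 1 or h % 2 != 1:
        raise BadShape(f"kernel dims must be odd, got {w}x{h}")
    if r < 2:
        raise BadShape(f"down-sampling rate must be >= 2, got {r}")
    rng = np.random.default_rng(seed)
    half = C // 2
    scale = 1.0 / np.sqrt(half * w * h)  # He-style fan-in scaling
    kernels = [
        rng.normal(0.0, scale, size=(half, half, w, h)) for _ in range(4)
    ]
    return SCConvParams(*kernels, r=r)


def param_count(params: SCConvParams) -> int:
    """Total scalar parameter count; equals C²·w·h, the standard-conv count."""
    return sum(int(k.size) for k in (params.K1, params.K2, params.K3, params.K4))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def conv2d(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Multi-channel stride-1 cross-correlation with zero same-padding.

    ``x``: (C_in, H, W); ``kernel``: (C_out, C_in, w, h) → (C_out, H, W).
    """
    c_out, c_in, _, _ = kernel.shape
    if x.shape[0] != c_in:
        raise BadShape(f"input has {x.shape[0]} channels, kernel expects {c_in}")
    out = np.zeros((c_out, x.shape[1], x.shape[2]))
    for o in range(c_out):
        for i in range(c_in):
            out[o] += signal.correlate2d(
                x[i], kernel[o, i], mode="same", boundary="fill", fillvalue=0.0
            )
    return out


def avg_pool(x: np.ndarray, r: int) -> np.ndarray:
    """Average pooling with an r×r window and stride r over (C, H, W)."""
    c, h, w = x.shape
    if h % r or w % r:
        raise BadShape(f"spatial dims ({h}, {w}) not divisible by rate {r}")
    return x.reshape(c, h // r, r, w // r, r).mean(axis=(2, 4))


def bilinear_upsample(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear up-sampling of (C, h, w) to (C, out_h, out_w).

    Uses pixel-center alignment (the ``align_corners=False`` convention):
    output pixel centers map to ``(i + 0.5) * h/out_h - 0.5`` in the input,
    clamped at the borders.
    """
    c, h, w = x.shape
    ys = np.clip((np.arange(out_h) + 0.5) * h / out_h - 0.5, 0, h - 1)
    xs = np.clip((np.arange(out_w) + 0.5) * w / out_w - 0.5, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[None, :, None]
    wx = (xs - x0)[None, None, :]
    top = x[:, y0][:, :, x0] * (1 - wx) + x[:, y0][:, :, x1] * wx
    bot = x[:, y1][:, :, x0] * (1 - wx) + x[:, y1][:, :, x1] * wx
    return top * (1 - wy) + bot * wy


def calibration_weights(x_b: np.ndarray, params: SCConvParams) -> np.ndarray:
    """The logistic gate of the calibrated branch, strictly inside (0, 1)."""
    h, w = x_b.shape[1], x_b.shape[2]
    pooled = avg_pool(x_b, params.r)
    context = conv2d(pooled, params.K2)
    upsampled = bilinear_upsample(context, h, w)
    return _sigmoid(x_b + upsampled)


def scconv_forward(x: np.ndarray, params: SCConvParams) -> np.ndarray:
    """Forward pass of the self-calibrated convolution block.

    ``x`` has shape (C, H, W) with C the block's channel count and H, W
    divisible by the down-sampling rate.  Output shape equals input shape.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise BadShape(f"expected a (C, H, W) feature map, got shape {x.shape}")
    c, h, w = x.shape
    if c != params.channels:
        raise BadShape(f"input has {c} channels, block expects {params.channels}")
    if h % params.r or w % params.r:
        raise BadShape(
            f"spatial dims ({h}, {w}) must be divisible by rate {params.r}"
        )
    half = c // 2
    part_a, part_b = x[:half], x[half:]

    out_a = conv2d(part_a, params.K1)
    weights = calibration_weights(part_b, params)
    calibrated = conv2d(part_b, params.K3) * weights
    out_b = conv2d(calibrated, params.K4)
    return np.concatenate([out_a, out_b], axis=0)
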