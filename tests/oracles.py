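"""Independent brute-force oracles used to verify the library's fast paths.

Everything here is deliberately naive — per-pixel loops, all-pairs scans,
textbook formulas — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def loop_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Mean foreground coordinate via an explicit per-pixel loop."""
    sx = sy = n = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                sx += x
                sy += y
                n += 1
    return sx / n, sy / n


def projection_point_line_distance(p, q, z) -> float:
    """Distance from point ``z`` to the infinite line through ``p`` and ``q``,
    via vector rejection."""
    p, q, z = (np.asarray(v, dtype=float) for v in (p, q, z))
    d = q - p
    u = d / np.linalg.norm(d)
    r = z - p
    return float(np.linalg.norm(r - (r @ u) * u))


def brute_force_chord(contour: np.ndarray, centroid, eps: float = 1.0) -> float:
    """Longest segment between two contour points passing within ``eps``
    pixels of the centroid (all-pairs point-to-segment scan)."""
    pts = np.asarray(contour, dtype=float)
    i, j = np.triu_indices(len(pts), 1)
    p, q = pts[i], pts[j]
    c = np.array([centroid.x, centroid.y])
    d = q - p
    l2 = (d**2).sum(1)
    t = np.clip(((c - p) * d).sum(1) / np.maximum(l2, 1e-12), 0.0, 1.0)
    dist = np.linalg.norm(c - (p + t[:, None] * d), axis=1)
    ok = dist <= eps
    if not ok.any():
        return np.nan
    return float(np.sqrt(l2[ok].max()))


def loop_masked_mean(plane: np.ndarray, mask: np.ndarray) -> float:
    """Masked mean via an explicit loop."""
    total = n = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                total += plane[y, x]
                n += 1
    return total / n


def srgb_to_lab_reference(rgb8) -> tuple[float, float, float]:
    """Textbook sRGB (D65) → CIELAB conversion for one 8-bit pixel."""

    def linearize(u):
        u = u / 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    r, g, b = (linearize(v) for v in rgb8)
    # sRGB → XYZ (D65)
    x = 0.4124564 * r + 0.3575761 * g + 0.1804375 * b
    y = 0.2126729 * r + 0.7151522 * g + 0.0721750 * b
    z = 0.0193339 * r + 0.1191920 * g + 0.9503041 * b
    xn, yn, zn = 0.95047, 1.0, 1.08883

    def f(t):
        return t ** (1 / 3) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    return 116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)


def loop_conv2d(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nested-loop multi-channel cross-correlation, zero same-padding, stride 1."""
    c_out, c_in, kh, kw = kernel.shape
    _, h, w = x.shape
    out = np.zeros((c_out, h, w))
    py, px = kh // 2, kw // 2
    for o in range(c_out):
        for ci in range(c_in):
            for y in range(h):
                for xx in range(w):
                    acc = 0.0
                    for ky in range(kh):
                        for kx in range(kw):
                            yy = y + ky - py
                            xs = xx + kx - px
                            if 0 <= yy < h and 0 <= xs < w:
                                acc += x[ci, yy, xs] * kernel[o, ci, ky, kx]
                    out[o, y, xx] += acc
    return out
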