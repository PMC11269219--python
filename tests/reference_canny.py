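"""Independent straightforward reference Canny, written with naive
per-pixel loops, used only as a test oracle.

Implements the same mathematical definition as the library chain —
normalized sampled Gaussian, symmetric border reflection, 3x3 Sobel,
4-bin non-maximum suppression with ties kept (>= both neighbours,
out-of-bounds neighbours treated as zero), and 8-connected
double-threshold hysteresis grown by breadth-first search — but shares
no code with it.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def _reflect_pad(img: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(img, pad, mode="symmetric")


def _convolve_naive(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    h, w = img.shape
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = _reflect_pad(img.astype(float), max(ph, pw))
    off = max(ph, pw)
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += kernel[a, b] * padded[off + i - ph + a, off + j - pw + b]
            out[i, j] = acc
    return out


def reference_gaussian_kernel(sigma: float, size: int) -> np.ndarray:
    half = size // 2
    k = np.zeros((size, size))
    for a in range(size):
        for b in range(size):
            k[a, b] = math.exp(-((a - half) ** 2 + (b - half) ** 2) / (2 * sigma * sigma))
    return k / k.sum()


def reference_canny(image: np.ndarray, sigma: float, kernel_size: int, low: float, high: float) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    smoothed = _convolve_naive(img, reference_gaussian_kernel(sigma, kernel_size))

    sx = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
    gx = _convolve_naive(smoothed, sx)
    gy = _convolve_naive(smoothed, sx.T)
    h, w = img.shape
    mag = np.zeros((h, w))
    ang = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            mag[i, j] = math.hypot(gx[i, j], gy[i, j])
            ang[i, j] = math.degrees(math.atan2(gy[i, j], gx[i, j])) % 180.0

    def neighbours(i, j):
        a = ang[i, j]
        if a < 22.5 or a >= 157.5:
            return (i, j + 1), (i, j - 1)
        if a < 67.5:
            return (i + 1, j + 1), (i - 1, j - 1)
        if a < 112.5:
            return (i + 1, j), (i - 1, j)
        return (i + 1, j - 1), (i - 1, j + 1)

    def mag_at(i, j):
        if 0 <= i < h and 0 <= j < w:
            return mag[i, j]
        return 0.0

    thinned = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            (i1, j1), (i2, j2) = neighbours(i, j)
            if mag[i, j] >= mag_at(i1, j1) and mag[i, j] >= mag_at(i2, j2):
                thinned[i, j] = mag[i, j]

    strong = thinned >= high
    weak = (thinned >= low) & ~strong
    edges = np.zeros((h, w), dtype=np.uint8)
    queue = deque()
    for i in range(h):
        for j in range(w):
            if strong[i, j]:
                edges[i, j] = 1
                queue.append((i, j))
    while queue:
        i, j = queue.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and edges[ni, nj] == 0 and (weak[ni, nj] or strong[ni, nj]):
                    edges[ni, nj] = 1
                    queue.append((ni, nj))
    return edges
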