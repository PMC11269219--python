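"""From-scratch Canny edge chain for binary radicle masks.

The measurement pipeline counts edge-contour pixels on the merged
binary mask, so the edge detector's exact behaviour (not just its
qualitative output) matters. The chain is the classical four stages:

1. Gaussian smoothing (normalized sampled kernel, reflected borders);
2. Sobel gradients, magnitude = sqrt(Gx^2 + Gy^2), direction = atan2(Gy, Gx);
3. non-maximum suppression with the direction quantized to 4 bins
   (0/45/90/135 degrees), keeping a pixel iff its magnitude is >= both
   neighbours along the gradient (ties kept, so plateau edges survive);
4. double-threshold hysteresis: pixels >= high are strong, pixels in
   [low, high) are weak, and the output keeps strong pixels plus weak
   pixels 8-connected (transitively) to a strong one.

Out-of-bounds neighbours in NMS are treated as zero magnitude.
Thresholds apply to the raw Sobel magnitude of the smoothed 8-bit
image (which can exceed 255: a full-contrast step reaches ~1020).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CannyParams",
    "GradientField",
    "gaussian_kernel",
    "gaussian_smooth",
    "sobel_gradients",
    "non_max_suppress",
    "hysteresis_threshold",
    "canny",
]


@dataclass(frozen=True)
class CannyParams:
    """Chain parameters.

    Defaults (sigma 1.4, 5x5 kernel, thresholds 50/150 on the 8-bit
    gradient scale) follow common Canny practice; all are overridable.
    """

    sigma: float = 1.4
    kernel_size: int = 5
    low_threshold: float = 50.0
    high_threshold: float = 150.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and positive, got {self.kernel_size}")
        if not (0 <= self.low_threshold < self.high_threshold):
            raise ValueError(
                f"need 0 <= low < high, got low={self.low_threshold}, high={self.high_threshold}"
            )


@dataclass
class GradientField:
    """Gradient magnitude (non-negative) and direction (radians, (-pi, pi])."""

    magnitude: np.ndarray
    direction: np.ndarray

    def validate(self) -> None:
        if self.magnitude.shape != self.direction.shape:
            raise ValueError("magnitude and direction must share dimensions")
        if (self.magnitude < 0).any():
            raise ValueError("magnitude must be non-negative")


def gaussian_kernel(sigma: float, kernel_size: int) -> np.ndarray:
    """Sampled 2-D Gaussian, normalized to sum to 1."""
    if kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd, got {kernel_size}")
    half = kernel_size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_smooth(image: np.ndarray, sigma: float, kernel_size: int) -> np.ndarray:
    """Convolve with a normalized Gaussian; borders reflected."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    k = gaussian_kernel(sigma, kernel_size)
    return ndimage.correlate(img, k, mode="reflect")


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)  # d/dcol
_SOBEL_Y = _SOBEL_X.T  # d/drow


def sobel_gradients(image: np.ndarray) -> GradientField:
    """3x3 Sobel gradients with reflected borders.

    Gx is the column-direction derivative, Gy the row-direction one;
    direction = atan2(Gy, Gx) so 0 rad means a horizontal gradient
    (vertical edge).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got shape {img.shape}")
    gx = ndimage.correlate(img, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(img, _SOBEL_Y, mode="reflect")
    return GradientField(magnitude=np.hypot(gx, gy), direction=np.arctan2(gy, gx))


# Neighbour offsets per direction bin: 0 deg -> horizontal gradient,
# compare across columns; 90 deg -> across rows; diagonals accordingly.
_BIN_OFFSETS = {
    0: ((0, 1), (0, -1)),
    1: ((1, 1), (-1, -1)),
    2: ((1, 0), (-1, 0)),
    3: ((1, -1), (-1, 1)),
}


def _direction_bins(direction: np.ndarray) -> np.ndarray:
    """Quantize gradient direction to 4 bins (0, 45, 90, 135 degrees)."""
    ang = np.mod(np.degrees(direction), 180.0)
    bins = np.zeros(ang.shape, dtype=np.int8)
    bins[(ang >= 22.5) & (ang < 67.5)] = 1
    bins[(ang >= 67.5) & (ang < 112.5)] = 2
    bins[(ang >= 112.5) & (ang < 157.5)] = 3
    return bins


def non_max_suppress(field: GradientField) -> np.ndarray:
    """Keep a pixel iff its magnitude >= both neighbours along its
    quantized gradient direction; suppressed pixels become 0."""
    field.validate()
    mag = np.asarray(field.magnitude, dtype=float)
    bins = _direction_bins(field.direction)
    padded = np.pad(mag, 1, mode="constant", constant_values=0.0)
    out = np.zeros_like(mag)
    for b, ((dr1, dc1), (dr2, dc2)) in _BIN_OFFSETS.items():
        sel = bins == b
        n1 = padded[1 + dr1 : padded.shape[0] - 1 + dr1, 1 + dc1 : padded.shape[1] - 1 + dc1]
        n2 = padded[1 + dr2 : padded.shape[0] - 1 + dr2, 1 + dc2 : padded.shape[1] - 1 + dc2]
        keep = sel & (mag >= n1) & (mag >= n2)
        out[keep] = mag[keep]
    return out


_EIGHT = np.ones((3, 3), dtype=bool)


def hysteresis_threshold(thinned: np.ndarray, low: float, high: float) -> np.ndarray:
    """Strong pixels (>= high) plus weak pixels ([low, high)) that are
    8-connected, transitively, to a strong pixel. Returns a {0,1} grid."""
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got low={low}, high={high}")
    mag = np.asarray(thinned, dtype=float)
    strong = mag >= high
    candidate = mag >= low
    labels, n = ndimage.label(candidate, structure=_EIGHT)
    if n == 0:
        return np.zeros(mag.shape, dtype=np.uint8)
    has_strong = ndimage.labeled_comprehension(
        strong, labels, np.arange(1, n + 1), np.any, bool, False
    )
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = has_strong
    return keep[labels].astype(np.uint8)


def canny(image: np.ndarray, params: CannyParams | None = None) -> np.ndarray:
    """Full chain: smooth -> gradients -> NMS -> hysteresis. Returns {0,1}."""
    p = params or CannyParams()
    smoothed = gaussian_smooth(image, p.sigma, p.kernel_size)
    field = sobel_gradients(smoothed)
    thinned = non_max_suppress(field)
    return hysteresis_threshold(thinned, p.low_threshold, p.high_threshold)
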