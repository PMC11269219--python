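"""Synthetic radicle imagery with exact ground-truth centerline lengths.

Real germination trays hold seeds in a fixed 6x6 layout on a 25 cm
acrylic frame imaged at 1500x1500 px; each seed grows a thin, curved
radicle whose length is the quantity of interest. This module renders
such scenes from parametric centerlines so that every downstream stage
(mask merging, edge detection, length calibration, tracking) can be
validated against a known arc length.

Centerlines are uniform Catmull-Rom splines through user-supplied
control points; the ground-truth length is the spline arc length
computed by adaptive polyline refinement to 1e-3 px. Masks are rendered
by sweeping a disc of radius ``thickness_px // 2`` along the centerline,
which makes the perimeter of straight bars analytically predictable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as _draw_ellipse
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "RadicleSpec",
    "GrowthSchedule",
    "generate_radicle_mask",
    "generate_tray",
    "generate_growth_series",
    "random_radicle_spec",
    "three_phase_schedule",
    "augment_brightness",
    "augment_sharpen",
    "augment_rotate",
    "centerline_polyline",
    "polyline_arc_length",
    "write_truth_csv",
]

ARC_LENGTH_TOL = 1e-3  # px; adaptive refinement stopping tolerance


@dataclass(frozen=True)
class RadicleSpec:
    """One synthetic radicle: centerline control points plus rendering info.

    Control points are (row, col) in continuous pixel coordinates where
    pixel (i, j) covers the half-open square [i, i+1) x [j, j+1).
    """

    centerline_control_points: tuple[tuple[float, float], ...]
    thickness_px: int
    image_size: tuple[int, int]
    grid_cell: tuple[int, int]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        pts = tuple((float(r), float(c)) for r, c in self.centerline_control_points)
        object.__setattr__(self, "centerline_control_points", pts)
        if len(pts) < 2:
            raise ValueError("centerline needs at least 2 control points")
        if self.thickness_px < 1:
            raise ValueError(f"thickness_px must be >= 1, got {self.thickness_px}")
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError(f"image_size must be positive, got {self.image_size}")


@dataclass(frozen=True)
class GrowthSchedule:
    """Target centerline lengths (px) at each frame time (hours).

    ``phase_labels`` labels the interval between consecutive frames as
    one of {"slow", "plateau", "fast"}; germinating radicles show an
    early slow phase, a stable plateau, then a burst of fast elongation.
    """

    frame_times: tuple[float, ...]
    target_lengths_px: tuple[float, ...]
    phase_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.frame_times)
        lengths = tuple(float(v) for v in self.target_lengths_px)
        object.__setattr__(self, "frame_times", times)
        object.__setattr__(self, "target_lengths_px", lengths)
        object.__setattr__(self, "phase_labels", tuple(self.phase_labels))
        if len(times) != len(lengths):
            raise ValueError("frame_times and target_lengths_px must have equal length")
        if any(v < 0 for v in lengths):
            raise ValueError("target lengths must be non-negative")
        if any(b < a for a, b in zip(lengths, lengths[1:])):
            raise ValueError("target_lengths_px must be non-decreasing")
        if self.phase_labels and len(self.phase_labels) != max(len(times) - 1, 0):
            raise ValueError("need one phase label per inter-frame interval")
        bad = set(self.phase_labels) - {"slow", "plateau", "fast"}
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Centerline geometry
# ---------------------------------------------------------------------------

def _catmull_rom_samples(points: np.ndarray, n_per_segment: int) -> np.ndarray:
    """Sample a uniform Catmull-Rom spline through ``points`` (N,2).

    End tangents come from reflected phantom points, so a 2-point spline
    is exactly the straight segment between them.
    """
    p = np.asarray(points, dtype=float)
    first = 2.0 * p[0] - p[1]
    last = 2.0 * p[-1] - p[-2]
    ext = np.vstack([first, p, last])
    t = np.linspace(0.0, 1.0, n_per_segment, endpoint=False)
    out = []
    for i in range(len(p) - 1):
        p0, p1, p2, p3 = ext[i], ext[i + 1], ext[i + 2], ext[i + 3]
        a = 2.0 * p1
        b = p2 - p0
        c = 2.0 * p0 - 5.0 * p1 + 4.0 * p2 - p3
        d = -p0 + 3.0 * p1 - 3.0 * p2 + p3
        tt = t[:, None]
        out.append(0.5 * (a + b * tt + c * tt**2 + d * tt**3))
    out.append(p[-1][None, :])
    return np.vstack(out)


def polyline_arc_length(polyline: np.ndarray) -> float:
    """Total Euclidean length of an (N,2) polyline."""
    diffs = np.diff(np.asarray(polyline, dtype=float), axis=0)
    return float(np.sqrt((diffs**2).sum(axis=1)).sum())


def centerline_polyline(spec: RadicleSpec, tol: float = ARC_LENGTH_TOL) -> np.ndarray:
    """Dense polyline along the spec's spline, refined until the arc
    length changes by less than ``tol`` px between refinement levels."""
    pts = np.asarray(spec.centerline_control_points, dtype=float)
    n = 16
    poly = _catmull_rom_samples(pts, n)
    length = polyline_arc_length(poly)
    while n < 4096:
        n *= 2
        poly2 = _catmull_rom_samples(pts, n)
        length2 = polyline_arc_length(poly2)
        if abs(length2 - length) < tol:
            return poly2
        poly, length = poly2, length2
    return poly


def _resample_by_arclength(polyline: np.ndarray, s_values: np.ndarray) -> np.ndarray:
    """Points at the given arc-length positions along the polyline."""
    poly = np.asarray(polyline, dtype=float)
    seg = np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    rows = np.interp(s_values, cum, poly[:, 0])
    cols = np.interp(s_values, cum, poly[:, 1])
    return np.column_stack([rows, cols])


def _disk_footprint(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


def _rasterize(polyline: np.ndarray, total_length: float, spec: RadicleSpec) -> np.ndarray:
    """Render the centerline as a binary mask by half-open pixel coverage
    plus a disc dilation of radius thickness//2."""
    h, w = spec.image_size
    radius = spec.thickness_px // 2
    # half-open sampling: a straight axis-aligned run of integer length L
    # covers exactly L pixels
    n_samples = max(int(math.ceil(total_length / 0.2)), 1)
    s = np.linspace(0.0, total_length, n_samples, endpoint=False)
    pts = _resample_by_arclength(polyline, s)
    pix = np.floor(pts).astype(int)
    for (pr, pc), (fr, fc) in zip(pix, pts):
        if pr - radius < 0 or pc - radius < 0 or pr + radius >= h or pc + radius >= w:
            raise ValueError(
                f"centerline point ({fr:.2f}, {fc:.2f}) renders outside image bounds {spec.image_size}"
            )
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[pix[:, 0], pix[:, 1]] = 1
    if radius > 0:
        mask = ndimage.binary_dilation(mask, structure=_disk_footprint(radius)).astype(np.uint8)
    return mask


def generate_radicle_mask(spec: RadicleSpec) -> tuple[np.ndarray, float]:
    """Render one radicle; returns (binary 0/1 mask, true centerline length px)."""
    poly = centerline_polyline(spec)
    true_length = polyline_arc_length(poly)
    mask = _rasterize(poly, true_length, spec)
    return mask, true_length


# ---------------------------------------------------------------------------
# Tray and growth series
# ---------------------------------------------------------------------------

def generate_tray(
    n_rows: int,
    n_cols: int,
    specs: Sequence[RadicleSpec],
    image_size: tuple[int, int] = (1500, 1500),
) -> tuple[list[np.ndarray], np.ndarray]:
    """Render a seed tray: one instance mask per spec plus a composite
    8-bit grayscale image with elliptical seed bodies.

    Returns (list of binary masks at ``image_size``, composite image).
    """
    cells = [s.grid_cell for s in specs]
    if len(set(cells)) != len(cells):
        seen: set[tuple[int, int]] = set()
        for c in cells:
            if c in seen:
                raise ValueError(f"duplicate grid_cell {c}")
            seen.add(c)
    for s in specs:
        r, c = s.grid_cell
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"grid_cell {s.grid_cell} outside {n_rows}x{n_cols} layout")

    h, w = image_size
    composite = np.full((h, w), 10, dtype=np.uint8)
    masks: list[np.ndarray] = []
    for s in specs:
        s_full = dataclasses.replace(s, image_size=image_size)
        mask, _ = generate_radicle_mask(s_full)
        masks.append(mask)
        rng = np.random.default_rng(s.rng_seed)
        r0, c0 = s.centerline_control_points[0]
        ry = 12 + rng.integers(0, 5)
        rx = 9 + rng.integers(0, 4)
        rr, cc = _draw_ellipse(r0, c0, ry, rx, shape=(h, w))
        composite[rr, cc] = 180
        composite[mask > 0] = 255
    return masks, composite


def generate_growth_series(
    spec: RadicleSpec, schedule: GrowthSchedule
) -> list[tuple[float, np.ndarray, float]]:
    """Render one radicle at each scheduled length.

    Frame k's centerline is the spec centerline truncated to
    ``target_lengths_px[k]`` of arc length, so the ground-truth length
    tracks the schedule exactly (to sampling resolution).
    """
    poly = centerline_polyline(spec)
    full_length = polyline_arc_length(poly)
    frames: list[tuple[float, np.ndarray, float]] = []
    for t, target in zip(schedule.frame_times, schedule.target_lengths_px):
        if target > full_length + ARC_LENGTH_TOL:
            raise ValueError(
                f"target length {target:.2f} px exceeds renderable centerline ({full_length:.2f} px)"
            )
        target = min(target, full_length)
        if target <= 0:
            mask = np.zeros(spec.image_size, dtype=np.uint8)
            frames.append((t, mask, 0.0))
            continue
        n = max(int(math.ceil(target)), 2)
        s = np.linspace(0.0, target, 8 * n)
        sub = _resample_by_arclength(poly, s)
        true_len = polyline_arc_length(sub)
        mask = _rasterize(sub, true_len, spec)
        frames.append((t, mask, true_len))
    return frames


def three_phase_schedule(
    start_length_px: float = 40.0,
    rates_px_per_h: tuple[float, float, float] = (6.0, 0.5, 25.0),
    durations_h: tuple[int, int, int] = (3, 3, 3),
    dt_h: float = 1.0,
    t0_h: float = 0.0,
) -> GrowthSchedule:
    """Slow / plateau / fast growth schedule, one frame per ``dt_h``.

    Defaults emulate the observed germination pattern: moderate early
    elongation, a stable plateau, then a burst where the growth rate
    peaks.
    """
    names = ("slow", "plateau", "fast")
    times = [t0_h]
    lengths = [float(start_length_px)]
    labels: list[str] = []
    for name, rate, dur in zip(names, rates_px_per_h, durations_h):
        for _ in range(dur):
            times.append(times[-1] + dt_h)
            lengths.append(lengths[-1] + rate * dt_h)
            labels.append(name)
    return GrowthSchedule(tuple(times), tuple(lengths), tuple(labels))


def random_radicle_spec(
    rng_seed: int,
    length_px: float,
    thickness_px: int = 3,
    image_size: tuple[int, int] = (256, 256),
    grid_cell: tuple[int, int] = (0, 0),
    max_turn_rad: float = 0.35,
    step_px: float = 20.0,
) -> RadicleSpec:
    """Random bounded-curvature radicle: control points follow a heading
    walk whose turn per ``step_px`` is limited to ``max_turn_rad``.

    The spec's true length is the resulting spline arc length (close to,
    but not exactly, ``length_px``); obtain it from
    :func:`generate_radicle_mask`.
    """
    rng = np.random.default_rng(rng_seed)
    h, w = image_size
    margin = thickness_px + 4.0
    pos = np.array(
        [rng.uniform(0.3 * h, 0.7 * h), rng.uniform(0.3 * w, 0.7 * w)], dtype=float
    )
    heading = rng.uniform(-math.pi, math.pi)
    points = [tuple(pos)]
    remaining = float(length_px)
    while remaining > 0:
        step = min(step_px, remaining)
        heading += rng.uniform(-max_turn_rad, max_turn_rad)
        for _ in range(32):  # steer back toward the interior if needed
            nxt = pos + step * np.array([math.sin(heading), math.cos(heading)])
            if margin <= nxt[0] < h - margin and margin <= nxt[1] < w - margin:
                break
            center = np.array([h / 2.0, w / 2.0])
            to_center = math.atan2(*(center - pos))
            heading = 0.7 * heading + 0.3 * to_center + rng.uniform(-0.1, 0.1)
        pos = nxt
        points.append(tuple(pos))
        remaining -= step
    return RadicleSpec(
        centerline_control_points=tuple(points),
        thickness_px=thickness_px,
        image_size=image_size,
        grid_cell=grid_cell,
        rng_seed=rng_seed,
    )


def write_truth_csv(path, rows: Sequence[dict]) -> pd.DataFrame:
    """Ground-truth table: (frame, grid_row, grid_col, true_length_px, true_length_cm)."""
    df = pd.DataFrame(rows, columns=["frame", "grid_row", "grid_col", "true_length_px", "true_length_cm"])
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Augmentation operators
# ---------------------------------------------------------------------------

def _as_u8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image, got dtype {img.dtype}")
    return img


def augment_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Multiply intensities by ``factor`` and clamp to [0, 255]."""
    img = _as_u8(image)
    if factor < 0:
        raise ValueError(f"brightness factor must be >= 0, got {factor}")
    return np.clip(img.astype(np.float64) * factor, 0, 255).round().astype(np.uint8)


_SHARPEN_KERNEL = np.array([[0, -1, 0], [-1, 5, -1], [0, -1, 0]], dtype=float)


def augment_sharpen(image: np.ndarray) -> np.ndarray:
    """Laplacian-style sharpening (centre 5, cross -1), clamped to [0, 255]."""
    img = _as_u8(image)
    if img.ndim == 2:
        out = ndimage.correlate(img.astype(float), _SHARPEN_KERNEL, mode="reflect")
    else:
        out = np.stack(
            [
                ndimage.correlate(img[..., c].astype(float), _SHARPEN_KERNEL, mode="reflect")
                for c in range(img.shape[-1])
            ],
            axis=-1,
        )
    return np.clip(out, 0, 255).round().astype(np.uint8)


def augment_rotate(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image centre.

    Multiples of 90 degrees are exact pixel permutations; other angles
    use nearest-neighbour resampling so binary masks stay binary.
    """
    img = _as_u8(image)
    if angle_deg % 90 == 0:
        k = int(angle_deg // 90) % 4
        return np.ascontiguousarray(np.rot90(img, k))
    out = _sk_rotate(img, angle_deg, order=0, preserve_range=True, resize=False)
    return out.astype(np.uint8)
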