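"""Full-time-sequence tracking of per-seed radicle measurements.

Seeds sit at fixed positions in a tray, so tracks are built by grid-cell
association rather than nearest-neighbour matching: the image is split
into an n_rows x n_cols grid of equal cells and each contour is assigned
to the cell containing its centroid. Early-germination frames can lack a
detectable radicle (short radicles are easily mistaken for background),
so missing observations are recorded as gaps, never interpolated.

Growth rates are per-interval slopes of the calibrated length series;
the "amplify AVE" transform (mean length - offset) * scale, default
offset 1 and scale 2, magnifies trends for visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from radiclemorph.length import CalibrationRatio, ContourMeasurement, measure_radicle

__all__ = [
    "SeedTrack",
    "GrowthCurve",
    "associate_seeds",
    "growth_rates",
    "amplify_average",
    "contour_overlay",
    "tracks_to_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class SeedTrack:
    """Time-ordered observations for one grid cell; ``None`` marks a
    frame where no contour was detected in the cell."""

    grid_cell: tuple[int, int]
    observations: list[tuple[float, ContourMeasurement | None]] = field(default_factory=list)

    def validate(self) -> None:
        times = [t for t, _ in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"track {self.grid_cell}: timestamps must be strictly increasing")


@dataclass
class GrowthCurve:
    """Calibrated length series with amplified values and interval rates."""

    times: np.ndarray  # hours, non-missing observations only
    lengths_cm: np.ndarray
    amplified: np.ndarray
    interval_rates: np.ndarray  # cm/hour between consecutive non-missing frames


def associate_seeds(
    frames: Sequence[tuple[float, Sequence[ContourMeasurement]]],
    layout: tuple[int, int],
    image_size: tuple[int, int],
) -> list[SeedTrack]:
    """Assign each frame's contours to tray cells by centroid.

    At most one contour per cell per frame is kept (largest sum_pixels
    wins; losers are logged). Cells without a contour get a missing
    marker so every track has one entry per frame.
    """
    n_rows, n_cols = layout
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError(f"layout must be positive, got {layout}")
    h, w = image_size
    cell_h, cell_w = h / n_rows, w / n_cols
    tracks = {
        (r, c): SeedTrack(grid_cell=(r, c)) for r in range(n_rows) for c in range(n_cols)
    }
    for t, measurements in frames:
        best: dict[tuple[int, int], ContourMeasurement] = {}
        for m in measurements:
            cr, cc = m.centroid
            if not (0 <= cr < h and 0 <= cc < w):
                raise ValueError(f"centroid {m.centroid} outside image {image_size}")
            cell = (min(int(cr // cell_h), n_rows - 1), min(int(cc // cell_w), n_cols - 1))
            prev = best.get(cell)
            if prev is None or m.sum_pixels > prev.sum_pixels:
                if prev is not None:
                    logger.info(
                        "frame %s cell %s: dropping contour %d (%d px) for larger contour %d (%d px)",
                        t, cell, prev.contour_id, prev.sum_pixels, m.contour_id, m.sum_pixels,
                    )
                best[cell] = m
            else:
                logger.info(
                    "frame %s cell %s: dropping contour %d (%d px), smaller than kept %d px",
                    t, cell, m.contour_id, m.sum_pixels, prev.sum_pixels,
                )
        for cell, track in tracks.items():
            track.observations.append((t, best.get(cell)))
    result = [tracks[(r, c)] for r in range(n_rows) for c in range(n_cols)]
    for tr in result:
        tr.validate()
    return result


def growth_rates(track: SeedTrack, cal: CalibrationRatio) -> GrowthCurve:
    """Per-interval elongation rates (cm/hour) for one seed.

    Missing observations are skipped; each rate then spans the longer
    interval between the surrounding non-missing frames. Needs at least
    two non-missing observations.
    """
    track.validate()
    times = []
    lengths = []
    for t, m in track.observations:
        if m is not None:
            times.append(t)
            lengths.append(measure_radicle(m.sum_pixels, cal))
    if len(times) < 2:
        raise ValueError(
            f"track {track.grid_cell}: need >= 2 non-missing observations, got {len(times)}"
        )
    times_a = np.asarray(times, dtype=float)
    lengths_a = np.asarray(lengths, dtype=float)
    rates = np.diff(lengths_a) / np.diff(times_a)
    return GrowthCurve(
        times=times_a,
        lengths_cm=lengths_a,
        amplified=amplify_average(lengths_a),
        interval_rates=rates,
    )


def amplify_average(mean_lengths: Sequence[float], offset: float = 1.0, scale: float = 2.0) -> np.ndarray:
    """Visualization transform (x - offset) * scale, defaulting to the
    germination-curve convention of subtracting 1 cm and doubling."""
    return (np.asarray(mean_lengths, dtype=float) - offset) * scale


def contour_overlay(
    contours_per_frame: Sequence[Sequence[tuple[int, np.ndarray]]],
    cal: CalibrationRatio,
    image_size: tuple[int, int],
    axis_unit_cm: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale contour pixel coordinates into physical axis units and lay
    frames side by side in time order.

    Each input frame is a list of (contour_id, (N,2) pixel coordinate
    array). Coordinates are multiplied by R (cm/px) and divided by
    ``axis_unit_cm`` (default 0.1 cm per axis unit); frame k is shifted
    right by k frame-widths. Returns (points, labels) DataFrames; labels
    carry each contour's cm length (half-perimeter rule on its pixel
    count).
    """
    if axis_unit_cm <= 0:
        raise ValueError(f"axis_unit_cm must be positive, got {axis_unit_cm}")
    _, w = image_size
    frame_width_units = w * cal.R / axis_unit_cm
    points_rows = []
    label_rows = []
    for k, contours in enumerate(contours_per_frame):
        for contour_id, coords in contours:
            coords = np.asarray(coords, dtype=float)
            x = coords[:, 1] * cal.R / axis_unit_cm + k * frame_width_units
            y = coords[:, 0] * cal.R / axis_unit_cm
            for xi, yi in zip(x, y):
                points_rows.append(
                    {"frame": k, "contour_id": contour_id, "x_axis_units": xi, "y_axis_units": yi}
                )
            label_rows.append(
                {
                    "frame": k,
                    "contour_id": contour_id,
                    "length_cm": measure_radicle(len(coords), cal),
                }
            )
    points = pd.DataFrame(points_rows, columns=["frame", "contour_id", "x_axis_units", "y_axis_units"])
    labels = pd.DataFrame(label_rows, columns=["frame", "contour_id", "length_cm"])
    return points, labels


def tracks_to_csv(tracks: Sequence[SeedTrack], cal: CalibrationRatio, path) -> pd.DataFrame:
    """Export tracks as CSV: (grid_row, grid_col, timestamp_h, sum_pixels, length_cm)."""
    rows = []
    for tr in tracks:
        for t, m in tr.observations:
            rows.append(
                {
                    "grid_row": tr.grid_cell[0],
                    "grid_col": tr.grid_cell[1],
                    "timestamp_h": t,
                    "sum_pixels": m.sum_pixels if m is not None else "",
                    "length_cm": measure_radicle(m.sum_pixels, cal) if m is not None else "",
                }
            )
    df = pd.DataFrame(rows, columns=["grid_row", "grid_col", "timestamp_h", "sum_pixels", "length_cm"])
    df.to_csv(path, index=False)
    return df
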