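"""Mask-to-length geometry: contours, perimeters and physical root length.

The measurement chain converts an instance-segmentation mask of a root into
a physical length in three steps:

1. trace the closed outer contour of each 8-connected foreground component
   (Moore border following on pixel centres, clockwise in screen
   coordinates, row 0 at top);
2. sum Euclidean distances between consecutive contour pixels, closing the
   polygon (``k_0 == k_n``), giving the pixel perimeter ``S_p``;
3. divide by the calibration factor ``r`` (pixels per millimetre) to get the
   metric perimeter ``S_r = S_p / r`` and take half of it as the root length
   ``L = S_r / 2``.

The half-perimeter rule exploits the fact that the outer contour of a thin,
elongated root traverses its length twice (once down each side), so halving
the perimeter cancels the doubling.  For a root of finite width the rule
overestimates length by roughly ``width / r`` per root; no width correction
is applied.

Seeds are detected and segmented jointly with roots to sharpen boundaries,
but only ``root`` instances are ever measured.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "Contour",
    "Calibration",
    "RootMeasurement",
    "CalibrationError",
    "extract_contours",
    "contour_perimeter_px",
    "pixels_to_mm",
    "root_length",
    "measure_instances",
    "measurements_to_csv",
    "measurements_to_json",
]

DEFAULT_PIXELS_PER_MM = 7.0  # steel-ruler calibration: 1 mm = 7 px

# 8-neighbour ring in clockwise screen order (x right, y down), starting East
_CLOCKWISE_RING = (
    (1, 0),
    (1, 1),
    (0, 1),
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
)

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


class CalibrationError(ValueError):
    """Raised for a non-positive pixels-per-mm factor."""


@dataclass(frozen=True)
class BinaryMask:
    """Boolean H x W raster; row-major, 0-based, row 0 at the top."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("mask grid must be 2-D and non-empty")
        if g.dtype != bool:
            if not np.isin(g, (0, 1)).all():
                raise ValueError("mask values must be strictly boolean (0/1)")
            g = g.astype(bool)
        object.__setattr__(self, "grid", g)

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def area(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class Contour:
    """Ordered pixel polygon, clockwise; closure ``k_0 == k_n`` is implicit.

    Points are (x, y) = (column, row).  ``enclosed_area`` is the pixel count
    of the component the contour bounds (used to rank contours).
    """

    points: tuple[tuple[int, int], ...]
    enclosed_area: int = 0
    closed: bool = True

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("contour needs at least one point")
        for a, b in zip(self.points, self.points[1:]):
            if a == b:
                raise ValueError("consecutive contour points must differ")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Calibration:
    """Pixels per millimetre; the bundled acquisition setup gives r = 7."""

    r: float = DEFAULT_PIXELS_PER_MM

    def __post_init__(self) -> None:
        if not (self.r > 0 and math.isfinite(self.r)):
            raise CalibrationError(f"pixels-per-mm must be positive, got {self.r!r}")


@dataclass(frozen=True)
class RootMeasurement:
    instance_id: str
    perimeter_px: float
    perimeter_mm: float
    length_mm: float
    n_contours: int = 1

    def __post_init__(self) -> None:
        vals = (self.perimeter_px, self.perimeter_mm, self.length_mm)
        if not all(math.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("measurements must be finite and non-negative")


def _trace_outer_contour(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore border following from the topmost-leftmost component pixel.

    Returns boundary pixels as (x, y) in clockwise screen order.  Stops on
    re-entering the start pixel from the initial backtrack direction
    (Jacob's criterion), which handles one-pixel-wide spurs correctly.
    """
    h, w = mask.shape
    sy, sx = start

    def ring_index(dx: int, dy: int) -> int:
        return _CLOCKWISE_RING.index((dx, dy))

    # backtrack starts at the exterior pixel left of the start
    # (start is leftmost in its topmost row, so (sx-1, sy) is background)
    bx, by = sx - 1, sy
    cx, cy = sx, sy
    # The walk is deterministic in the (pixel, backtrack) state, so it
    # eventually revisits a state; the cycle between the two visits is the
    # complete outer boundary (one-pixel spurs are traversed out and back).
    points: list[tuple[int, int]] = []
    seen: dict[tuple[int, int, int, int], int] = {}
    while True:
        key = (cx, cy, bx, by)
        if key in seen:
            return points[seen[key]:]
        seen[key] = len(points)
        points.append((cx, cy))
        base = ring_index(bx - cx, by - cy)
        nxt = None
        for i in range(1, 9):
            dx, dy = _CLOCKWISE_RING[(base + i) % 8]
            nx, ny = cx + dx, cy + dy
            if 0 <= nx < w and 0 <= ny < h and mask[ny, nx]:
                nxt = (nx, ny)
                break
            bx, by = nx, ny  # last examined background neighbour
        if nxt is None:
            return points  # isolated pixel
        cx, cy = nxt


def extract_contours(mask: BinaryMask) -> list[Contour]:
    """Closed outer contour of every 8-connected foreground component.

    Contours are ordered by decreasing enclosed pixel count; interior holes
    are ignored.  An empty mask yields an empty list.
    """
    grid = mask.grid
    labels, n = ndimage.label(grid, structure=_EIGHT_CONN)
    if n == 0:
        return []
    areas = ndimage.sum_labels(np.ones_like(grid, dtype=np.int64), labels, range(1, n + 1))
    order = np.argsort(-areas, kind="stable") + 1
    contours = []
    for lab in order:
        comp = labels == lab
        ys, xs = np.nonzero(comp)
        top = ys.min()
        left = xs[ys == top].min()
        pts = _trace_outer_contour(comp, (int(top), int(left)))
        # Jacob's criterion can re-append the start pixel; drop a trailing
        # duplicate of the first point so closure stays implicit
        if len(pts) > 1 and pts[-1] == pts[0]:
            pts = pts[:-1]
        contours.append(
            Contour(points=tuple(pts), enclosed_area=int(areas[lab - 1]))
        )
    return contours


def contour_perimeter_px(contour: Contour) -> float:
    """Closed-polygon perimeter: sum of |k_m - k_{m-1}| with k_0 == k_n.

    A single-point contour has zero perimeter.
    """
    pts = contour.points
    n = len(pts)
    if n == 1:
        return 0.0
    arr = np.asarray(pts, dtype=float)
    diffs = np.diff(np.vstack([arr, arr[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def pixels_to_mm(perimeter_px: float, calibration: Calibration) -> float:
    """S_r = S_p / r."""
    if perimeter_px < 0:
        raise ValueError("perimeter must be non-negative")
    return perimeter_px / calibration.r


def root_length(perimeter_mm: float) -> float:
    """L = S_r / 2 (half-perimeter rule for thin elongated roots)."""
    if perimeter_mm < 0:
        raise ValueError("perimeter must be non-negative")
    return perimeter_mm / 2.0


def measure_instance_mask(
    mask: BinaryMask,
    calibration: Calibration,
    instance_id: str = "root-0",
    min_component_area: int = 1,
) -> RootMeasurement | None:
    """Measure one root mask; fragmented masks use the largest contour.

    Returns None for an empty mask.  When the mask fragments into several
    components (a known failure mode of discontinuous segmentations), the
    largest-area contour is measured and the fragment count logged, so one
    root yields exactly one measurement.
    """
    contours = [c for c in extract_contours(mask) if c.enclosed_area >= min_component_area]
    if not contours:
        return None
    if len(contours) > 1:
        logger.warning(
            "instance %s: mask fragments into %d contours; measuring largest "
            "(area %d px)",
            instance_id,
            len(contours),
            contours[0].enclosed_area,
        )
    s_p = contour_perimeter_px(contours[0])
    s_r = pixels_to_mm(s_p, calibration)
    return RootMeasurement(
        instance_id=instance_id,
        perimeter_px=s_p,
        perimeter_mm=s_r,
        length_mm=root_length(s_r),
        n_contours=len(contours),
    )


def measure_instances(
    predictions: Iterable,
    calibration: Calibration,
    min_component_area: int = 1,
) -> tuple[list[RootMeasurement], list[dict]]:
    """Measure every ``root``-class prediction; seeds are skipped.

    Predictions are duck-typed: objects with ``class_label``, ``mask`` and
    optionally ``instance_id`` attributes.  Returns (measurements, errors);
    a prediction without a mask produces an error record and the rest are
    still processed.  Input order is preserved.
    """
    out: list[RootMeasurement] = []
    errors: list[dict] = []
    for i, pred in enumerate(predictions):
        label = getattr(pred, "class_label", None)
        if label != "root":
            continue
        iid = str(getattr(pred, "instance_id", i))
        mask = getattr(pred, "mask", None)
        if mask is None:
            errors.append({"instance_id": iid, "error": "prediction has no mask"})
            continue
        m = measure_instance_mask(mask, calibration, instance_id=iid,
                                  min_component_area=min_component_area)
        if m is not None:
            out.append(m)
    return out, errors


def measurements_to_csv(
    rows: Sequence[tuple[str, RootMeasurement]], path: str | Path
) -> None:
    """Write (image_id, measurement) pairs as the standard per-image CSV."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["image_id", "instance_id", "class",
                    "perimeter_px", "perimeter_mm", "length_mm"])
        for image_id, m in rows:
            w.writerow([image_id, m.instance_id, "root",
                        f"{m.perimeter_px:.4f}", f"{m.perimeter_mm:.4f}",
                        f"{m.length_mm:.4f}"])


def measurements_to_json(
    rows: Sequence[tuple[str, RootMeasurement]], path: str | Path
) -> None:
    with open(path, "w") as f:
        json.dump(
            [
                {
                    "image_id": image_id,
                    "instance_id": m.instance_id,
                    "class": "root",
                    "perimeter_px": m.perimeter_px,
                    "perimeter_mm": m.perimeter_mm,
                    "length_mm": m.length_mm,
                }
                for image_id, m in rows
            ],
            f,
            indent=2,
        )
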