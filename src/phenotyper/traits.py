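"""Holistic growth traits and derived series.

Per plant per imaging day, the segmented mask yields projected leaf area
(plant pixel count), convex hull area, height/width extents and, for side
views, the plant area below the pot rim. The masked RGB raster yields the
Excess Green Index. Derived quantities: estimated biovolume
``sqrt(side_area**2 * top_area)`` — a biomass proxy — and day-to-day
trait differences (Δ). A per-trait, per-day outlier rule
(median +- 3 standard deviations) cleans cross-plant trait tables.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError


@dataclasses.dataclass
class TraitRecord:
    """Scalar traits of one plant on one day in one view (pixel units)."""

    plant_id: str = ""
    das: int = 0
    view: str = "top"
    pixels: int = 0
    hull_area: float = 0.0
    height: int = 0
    width: int = 0
    exg_mean: Optional[float] = None
    exg_variant: str = "paper"
    area_below_rim: Optional[int] = None
    empty: bool = False  # true when the mask had no foreground


def extract_holistic(
    mask: np.ndarray, view: str = "top", rim_row: Optional[int] = None
) -> TraitRecord:
    """Extract pixel count, hull area and extents from a binary mask.

    Extents are inclusive pixel counts (``max - min + 1``), so a single
    foreground pixel has height = width = 1. The hull area is the shoelace
    area of the convex hull of foreground pixel centers: degenerate point
    sets (fewer than 3 points, or all collinear) have hull area 0.
    ``area_below_rim`` counts foreground pixels with ``y > rim_row``
    (side view only; the rim row is a camera-setup constant).

    An empty mask yields an all-zero record flagged ``empty=True`` rather
    than an exception — plants can be fully occluded or dead on some days.
    """
    mask = np.asarray(mask, bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return TraitRecord(view=view, empty=True)
    rec = TraitRecord(
        view=view,
        pixels=int(ys.size),
        hull_area=hull_area(np.column_stack([xs, ys])),
        height=int(ys.max() - ys.min() + 1),
        width=int(xs.max() - xs.min() + 1),
    )
    if view == "side" and rim_row is not None:
        rec.area_below_rim = int(np.count_nonzero(ys > rim_row))
    return rec


def hull_area(points: np.ndarray) -> float:
    """Area of the convex hull of 2-D points; 0 for degenerate sets."""
    pts = np.asarray(points, float)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0  # collinear


def excess_green(
    rgb_raster: np.ndarray, mask: np.ndarray, variant: str = "paper"
) -> Optional[float]:
    """Mean Excess Green Index over masked pixels.

    Two variants: ``"paper"`` computes ``2G - R + B`` (the formula printed by
    the source workflow this package reimplements) and ``"canonical"``
    computes the classical Woebbecke index ``2G - R - B``. The two differ by
    ``2B``; the canonical form is what most of the vegetation-index
    literature means by ExG, so both are exposed and the variant is recorded
    alongside the value. Returns None on an empty mask.
    """
    if variant not in ("paper", "canonical"):
        raise ValueError(f"unknown ExG variant {variant!r}")
    mask = np.asarray(mask, bool)
    if not mask.any():
        return None
    rgb = np.asarray(rgb_raster, dtype=np.int64)
    r, g, b = (rgb[..., i][mask] for i in range(3))
    exg = 2 * g - r + (b if variant == "paper" else -b)
    return float(exg.mean())


def biovolume(side_pixels: float, top_pixels: float) -> float:
    """Biomass proxy ``sqrt(side_area**2 * top_area)`` in px^1.5 scale."""
    if side_pixels < 0 or top_pixels < 0:
        raise ValueError("pixel areas must be >= 0")
    return math.sqrt(side_pixels**2 * top_pixels)


def day_deltas(trait_series: Dict[int, float]) -> Dict[int, float]:
    """Day-to-day differences of a per-day trait series.

    ``delta[d] = value[d] - value[previous available imaging day]``. The
    first imaging day has no delta. Missing days are bridged: the previous
    *available* day is used, matching an every-other-day imaging schedule.
    """
    days = sorted(trait_series)
    return {
        d: trait_series[d] - trait_series[prev]
        for prev, d in zip(days, days[1:])
    }


def remove_outliers(
    values: Sequence[float],
) -> Tuple[np.ndarray, np.ndarray]:
    """Median +- 3 SD outlier filter for one trait on one day.

    Applied independently per trait and per day across plants. SD is the
    sample (n-1) standard deviation of the day's values. Returns
    ``(kept values, removed indices)``; fewer than two finite values pass
    through unchanged.
    """
    arr = np.asarray(values, float)
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        return arr, np.array([], dtype=int)
    med = np.median(arr[finite])
    sd = np.std(arr[finite], ddof=1)
    lo, hi = med - 3 * sd, med + 3 * sd
    outlier = finite & ((arr < lo) | (arr > hi))
    return arr[~outlier], np.nonzero(outlier)[0]
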