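"""NIR intensity summaries via RGB-to-NIR mask transfer.

The RGB and NIR top-view cameras image the same pot with different fields of
view and resolutions. Leaf near-infrared reflectance tracks tissue water
status, so the plant mask segmented from the RGB frame is transferred onto
the NIR frame geometry (scale + offset, nearest-neighbor) and the masked NIR
intensities are summarized by their mean and 75th percentile.

Registration is a fixed affine scale-plus-offset (no rotation): both cameras
look straight down. Parameters come from config, with
:func:`calibrate_registration` as a grid-search helper that maximizes mask
overlap on a bright calibration target.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Tuple

import numpy as np
import yaml


@dataclasses.dataclass
class CameraRegistration:
    """RGB→NIR frame mapping: NIR position = RGB position * scale + offset."""

    scale_x: float = 1.0
    scale_y: float = 1.0
    offset_x: float = 0.0
    offset_y: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("registration scales must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "CameraRegistration":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def transfer_mask(
    rgb_mask: np.ndarray,
    registration: CameraRegistration,
    nir_shape: Tuple[int, int],
) -> Tuple[np.ndarray, bool]:
    """Resample an RGB-frame mask into the NIR frame.

    Inverse nearest-neighbor mapping: NIR pixel (x, y) samples RGB pixel
    ``round((x - offset_x) / scale_x), round((y - offset_y) / scale_y)``;
    positions falling outside the RGB frame are background. Returns
    ``(mask, empty_flag)`` — an empty transferred mask is flagged so NIR
    summaries become missing instead of crashing.
    """
    rgb_mask = np.asarray(rgb_mask, bool)
    rows, cols = nir_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    src_x = np.rint((xx - registration.offset_x) / registration.scale_x).astype(int)
    src_y = np.rint((yy - registration.offset_y) / registration.scale_y).astype(int)
    inside = (
        (src_x >= 0)
        & (src_x < rgb_mask.shape[1])
        & (src_y >= 0)
        & (src_y < rgb_mask.shape[0])
    )
    out = np.zeros(nir_shape, bool)
    out[inside] = rgb_mask[src_y[inside], src_x[inside]]
    return out, not out.any()


def summarize_nir(
    nir_raster: np.ndarray, mask: np.ndarray
) -> Tuple[Optional[float], Optional[float]]:
    """Mean and 75th percentile of masked NIR intensities.

    The percentile uses linear interpolation between order statistics.
    Returns ``(None, None)`` on an empty mask.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return None, None
    vals = np.asarray(nir_raster, float)[mask]
    return float(vals.mean()), float(np.percentile(vals, 75))


def calibrate_registration(
    rgb_mask: np.ndarray,
    nir_mask: np.ndarray,
    scale_range: Tuple[float, float] = (0.25, 1.0),
    n_scales: int = 16,
    offset_range: int = 10,
) -> CameraRegistration:
    """Grid-search scale and offset maximizing Jaccard overlap.

    Coarse helper for calibrating the camera pair from one bright fixture
    (e.g. a white card segmented in both frames); refine ranges manually if
    the search grid is too coarse for a given rig.
    """
    nir_mask = np.asarray(nir_mask, bool)
    best, best_score = CameraRegistration(), -1.0
    scales = np.linspace(scale_range[0], scale_range[1], n_scales)
    offsets = range(-offset_range, offset_range + 1)
    for sx, sy in itertools.product(scales, repeat=2):
        for ox, oy in itertools.product(offsets, repeat=2):
            reg = CameraRegistration(sx, sy, ox, oy)
            cand, empty = transfer_mask(rgb_mask, reg, nir_mask.shape)
            if empty:
                continue
            inter = np.count_nonzero(cand & nir_mask)
            union = np.count_nonzero(cand | nir_mask)
            score = inter / union if union else 0.0
            if score > best_score:
                best, best_score = reg, score
    return best
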