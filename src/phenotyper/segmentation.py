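"""Color-threshold plant segmentation.

The plant is separated from the imaging-chamber background by thresholding
channels of the HSV and CIELAB color spaces, combining the per-channel masks
with a boolean rule, and cleaning the result (small-object removal, hole
filling). The exact thresholds are experiment-specific — they were tuned
visually against the plants in each imaging campaign — so they live in a
config object / YAML file rather than in code. The defaults shipped here are
tuned against the synthetic generator in :mod:`phenotyper.synth`.

Channel conventions: H in degrees [0, 360), S and V in [0, 1]; CIELAB under
D65/2 degrees with L in [0, 100] and a, b roughly in [-128, 127].
"""

from __future__ import annotations

import ast
import dataclasses
from typing import Dict, Optional

import numpy as np
import yaml
from skimage import color as skcolor
from skimage import morphology

HSV_CHANNELS = {"H": 0, "S": 1, "V": 2}
LAB_CHANNELS = {"L": 0, "a": 1, "b": 2}


class ConfigError(ValueError):
    """A segmentation config is internally inconsistent."""


@dataclasses.dataclass
class ChannelThreshold:
    """Inclusive band ``low <= value <= high`` on one color channel."""

    space: str  # "HSV" or "CIELAB"
    channel: str  # H/S/V or L/a/b
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ConfigError(
                f"threshold low {self.low} > high {self.high} on "
                f"{self.space}:{self.channel}"
            )
        table = HSV_CHANNELS if self.space == "HSV" else LAB_CHANNELS
        if self.channel not in table:
            raise ConfigError(f"unknown channel {self.channel!r} for {self.space}")


@dataclasses.dataclass
class SegmentationConfig:
    """Named channel thresholds plus the rule that combines them.

    ``combine_rule`` is a boolean expression over the mask names using
    ``&``, ``|``, ``^``, ``~`` and parentheses, evaluated pixelwise,
    e.g. ``"(sat | lab_b) & bright"``.
    """

    thresholds: Dict[str, ChannelThreshold]
    combine_rule: str = ""
    min_object_px: int = 0
    fill_hole_px: int = 0
    das_range: Optional[tuple] = None  # inclusive (lo, hi); None = any day

    def __post_init__(self) -> None:
        if self.min_object_px < 0 or self.fill_hole_px < 0:
            raise ConfigError("cleanup sizes must be >= 0")
        if not self.combine_rule:
            self.combine_rule = " | ".join(sorted(self.thresholds))

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        thresholds = {
            name: ChannelThreshold(**spec) for name, spec in d["thresholds"].items()
        }
        return cls(
            thresholds=thresholds,
            combine_rule=d.get("combine_rule", ""),
            min_object_px=int(d.get("min_object_px", 0)),
            fill_hole_px=int(d.get("fill_hole_px", 0)),
            das_range=tuple(d["das_range"]) if d.get("das_range") else None,
        )

    @classmethod
    def from_yaml(cls, path) -> "SegmentationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config() -> SegmentationConfig:
    """Defaults bracketing the synthetic generator's color distributions.

    Plant tissue (leaves and flowers) is saturated and/or strongly yellow-green
    in CIELAB b; the chamber background is dark, desaturated and neutral. The
    saturation and b masks are OR-ed, then AND-ed with a brightness guard that
    rejects dark noise pixels.
    """
    return SegmentationConfig(
        thresholds={
            "sat": ChannelThreshold("HSV", "S", 0.40, 1.0),
            "lab_b": ChannelThreshold("CIELAB", "b", 20.0, 127.0),
            "bright": ChannelThreshold("HSV", "V", 0.12, 1.0),
        },
        combine_rule="(sat | lab_b) & bright",
        min_object_px=12,
        fill_hole_px=16,
    )


def convert_colorspace(rgb_raster: np.ndarray, target: str) -> np.ndarray:
    """Convert an 8-bit RGB raster to HSV or CIELAB.

    Returns a float array of the same spatial shape with three channels:
    HSV as (H degrees, S, V) or CIELAB as (L, a, b) under D65/2 degrees.
    """
    rgb = np.asarray(rgb_raster)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (rows, cols, 3) RGB raster, got {rgb.shape}")
    if target == "HSV":
        out = skcolor.rgb2hsv(rgb)
        out[..., 0] *= 360.0  # skimage returns H in [0, 1)
        return out
    if target == "CIELAB":
        return skcolor.rgb2lab(rgb)
    raise ValueError(f"unknown target colorspace {target!r}")


def threshold_channel(channel_raster: np.ndarray, low: float, high: float) -> np.ndarray:
    """Boolean mask, true where ``low <= value <= high`` (inclusive band)."""
    if low > high:
        raise ConfigError(f"threshold low {low} > high {high}")
    ch = np.asarray(channel_raster)
    return (ch >= low) & (ch <= high)


_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.BitAnd,
    ast.BitOr,
    ast.BitXor,
    ast.UnaryOp,
    ast.Invert,
    ast.Name,
    ast.Load,
)


def _evaluate_rule(rule: str, masks: Dict[str, np.ndarray]) -> np.ndarray:
    try:
        tree = ast.parse(rule, mode="eval")
    except SyntaxError as exc:
        raise ConfigError(f"cannot parse combine rule {rule!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ConfigError(
                f"combine rule {rule!r} uses disallowed syntax "
                f"({type(node).__name__}); only names, ~, &, |, ^ are allowed"
            )
        if isinstance(node, ast.Name) and node.id not in masks:
            raise ConfigError(
                f"combine rule references unknown mask {node.id!r}; "
                f"known masks: {sorted(masks)}"
            )
    return np.asarray(eval(compile(tree, "<combine_rule>", "eval"), {"__builtins__": {}}, dict(masks)))


def combine_and_clean(
    named_masks: Dict[str, np.ndarray],
    combine_rule: str,
    min_object_px: int = 0,
    fill_hole_px: int = 0,
) -> np.ndarray:
    """Combine named masks with a boolean rule and clean the result.

    Foreground components (8-connectivity) smaller than ``min_object_px``
    are removed; enclosed background holes smaller than ``fill_hole_px``
    are filled.
    """
    shapes = {m.shape for m in named_masks.values()}
    if len(shapes) > 1:
        raise ValueError(f"masks have differing shapes: {shapes}")
    mask = _evaluate_rule(combine_rule, {k: np.asarray(v, bool) for k, v in named_masks.items()})
    # max_size removes components <= its value; the contract here is strictly
    # smaller than min_object_px / fill_hole_px, hence the -1.
    if min_object_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1, connectivity=2)
    if fill_hole_px > 1:
        mask = morphology.remove_small_holes(mask, max_size=fill_hole_px - 1, connectivity=2)
    return mask


def segment(
    rgb_raster: np.ndarray, config: Optional[SegmentationConfig] = None
) -> np.ndarray:
    """Full segmentation: colorspace conversion, thresholds, combine, clean."""
    cfg = config or default_config()
    hsv = lab = None
    masks = {}
    for name, thr in cfg.thresholds.items():
        if thr.space == "HSV":
            if hsv is None:
                hsv = convert_colorspace(rgb_raster, "HSV")
            ch = hsv[..., HSV_CHANNELS[thr.channel]]
        else:
            if lab is None:
                lab = convert_colorspace(rgb_raster, "CIELAB")
            ch = lab[..., LAB_CHANNELS[thr.channel]]
        masks[name] = threshold_channel(ch, thr.low, thr.high)
    return combine_and_clean(masks, cfg.combine_rule, cfg.min_object_px, cfg.fill_hole_px)


def apply_mask(raster: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero background pixels, keep foreground unchanged. Idempotent."""
    raster = np.asarray(raster)
    mask = np.asarray(mask, bool)
    if raster.shape[: mask.ndim] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} incompatible with raster shape {raster.shape}"
        )
    out = raster.copy()
    out[~mask] = 0
    return out
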