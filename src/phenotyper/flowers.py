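"""Flower detection, phenology and raceme-branch clustering.

Open *B. napus* flowers are bright yellow, so inside the segmented plant they
stand out in the blue-yellow (b) channel of CIELAB. The flower mask is
``(b >= threshold) AND plant_mask``, with the threshold chosen per plant age
and treatment group by a small rule table (flower color and background
change as plants mature and senesce). Connected components of the flower
mask, filtered at a minimum pixel size, are single flowers or clumps of
overlapping flowers; their pixel counts, centroids, bounding boxes and hull
areas drive everything downstream:

* anthesis — the first imaging day with any surviving component;
* flower-count estimation — big components are split by the pixel area of
  one fully open flower;
* canopy width/angle; and
* raceme-branch assignment by hierarchical clustering of component
  coordinates.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from skimage import measure

from .segmentation import ConfigError, convert_colorspace
from .traits import hull_area

#: Components below this size are noise (sepals, specks), not flowers.
DEFAULT_MIN_COMPONENT_PX = 100

#: A component counts as a multi-flower clump above split_factor * flower_ref_px.
DEFAULT_SPLIT_FACTOR = 1.5


@dataclasses.dataclass
class ThresholdRule:
    """One policy row: b-channel threshold for a DAS range and treatment."""

    das_min: int
    das_max: int
    treatment: str  # "control", "drought" or "any"
    b_low: float

    def matches(self, das: int, treatment: str) -> bool:
        return self.das_min <= das <= self.das_max and self.treatment in (
            "any",
            treatment,
        )


@dataclasses.dataclass
class FlowerThresholdPolicy:
    """Ordered rule table; the first matching rule wins."""

    rules: List[ThresholdRule]

    def threshold(self, das: int, treatment: str) -> float:
        for rule in self.rules:
            if rule.matches(das, treatment):
                return rule.b_low
        raise ConfigError(
            f"no flower-threshold rule matches das={das}, treatment={treatment!r}"
        )

    @classmethod
    def from_yaml(cls, path) -> "FlowerThresholdPolicy":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls(rules=[ThresholdRule(**row) for row in spec["rules"]])


def default_policy(b_low: float = 60.0) -> FlowerThresholdPolicy:
    """Single-rule policy calibrated on the synthetic generator.

    Synthetic leaves sit at b ~ 30-40, flowers at b ~ 75-85, so one
    age/treatment-independent threshold of 60 separates them; real imaging
    campaigns need an age- and treatment-stratified table.
    """
    return FlowerThresholdPolicy(rules=[ThresholdRule(1, 365, "any", b_low)])


@dataclasses.dataclass
class FlowerComponent:
    """One connected flower-mask component (possibly several open flowers)."""

    pixel_count: int
    centroid: Tuple[float, float]  # (x, y)
    bbox: Tuple[int, int, int, int]  # half-open (min_x, min_y, max_x, max_y)
    bbox_area: int
    hull_area: float

    @property
    def feature_vector(self) -> np.ndarray:
        """Clustering features: min x, max x, min y, max y, centroid x, centroid y."""
        min_x, min_y, max_x, max_y = self.bbox
        return np.array(
            [min_x, max_x, min_y, max_y, self.centroid[0], self.centroid[1]], float
        )


def flower_mask(
    rgb_top: np.ndarray,
    plant_mask: np.ndarray,
    policy: FlowerThresholdPolicy,
    das: int,
    treatment: str,
) -> np.ndarray:
    """Threshold the CIELAB b channel inside the plant mask.

    Flower pixels are by construction a subset of plant pixels, which keeps
    yellow clutter outside the plant (fallen petals of neighbors, pot tags)
    out of the phenology calls.
    """
    b = convert_colorspace(rgb_top, "CIELAB")[..., 2]
    return (b >= policy.threshold(das, treatment)) & np.asarray(plant_mask, bool)


def extract_components(
    mask: np.ndarray, min_component_px: int = DEFAULT_MIN_COMPONENT_PX
) -> List[FlowerComponent]:
    """8-connected components of the flower mask, size-filtered.

    Components with fewer than ``min_component_px`` pixels are dropped
    (a component of exactly the minimum size survives).
    """
    mask = np.asarray(mask, bool)
    labels = measure.label(mask, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        if region.num_pixels < min_component_px:
            continue
        min_row, min_col, max_row, max_col = region.bbox
        cy, cx = region.centroid
        coords = region.coords  # (y, x) rows
        out.append(
            FlowerComponent(
                pixel_count=int(region.num_pixels),
                centroid=(float(cx), float(cy)),
                bbox=(int(min_col), int(min_row), int(max_col), int(max_row)),
                bbox_area=int((max_col - min_col) * (max_row - min_row)),
                hull_area=hull_area(coords[:, ::-1]),
            )
        )
    return out


def detect_anthesis(
    components_by_day: Dict[int, Sequence[FlowerComponent]]
) -> Optional[int]:
    """First imaging day with at least one surviving flower component.

    Returns None for plants that never flowered in the experiment. Yellow
    petals protruding from unopened buds are a known false-positive source;
    no bud filter is applied.
    """
    for das in sorted(components_by_day):
        if len(components_by_day[das]) > 0:
            return das
    return None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_flower_count(
    components: Sequence[FlowerComponent],
    flower_ref_px: float,
    split_factor: float = DEFAULT_SPLIT_FACTOR,
) -> int:
    """Estimate open flowers, splitting clumps by the one-flower pixel area.

    A component up to ``split_factor * flower_ref_px`` pixels counts as one
    flower; a larger one is a clump of overlapping flowers and contributes
    ``round(pixel_count / flower_ref_px)`` (half-up, at least 1).
    ``flower_ref_px`` — the pixel area of one fully open flower seen from
    the top — is a per-rig calibration constant.
    """
    if flower_ref_px <= 0:
        raise ConfigError("flower_ref_px must be > 0")
    total = 0
    for comp in components:
        if comp.pixel_count <= split_factor * flower_ref_px:
            total += 1
        else:
            total += max(1, _round_half_up(comp.pixel_count / flower_ref_px))
    return total


def canopy_metrics(
    components: Sequence[FlowerComponent], plant_height_px: float
) -> Tuple[Optional[float], Optional[float]]:
    """Maximum canopy width and apex canopy angle from flower components.

    Width is the horizontal span of all component bounding boxes in the top
    view. The canopy angle treats the inflorescence as an isoceles triangle
    of that width standing on the side-view plant height:
    ``2 * atan(width / (2 * height))`` in degrees — 90 degrees when the
    canopy is twice as wide as the plant is tall. Returns (None, None) with
    no components.
    """
    if not components:
        return None, None
    if plant_height_px <= 0:
        raise ValueError("plant_height_px must be > 0")
    min_x = min(c.bbox[0] for c in components)
    max_x = max(c.bbox[2] for c in components)
    width = float(max_x - min_x)
    angle = math.degrees(2.0 * math.atan2(width, 2.0 * plant_height_px))
    return width, angle


def cluster_racemes(
    components: Sequence[FlowerComponent], k: int, method: str = "complete"
) -> np.ndarray:
    """Assign flower components to k raceme branches.

    Agglomerative hierarchical clustering (complete linkage by default,
    Euclidean distance) on the six coordinate features of each component
    (min x, max x, min y, max y, centroid x, centroid y); the tree is cut
    into k flat clusters labeled 1..k. k comes from a manual branch count or
    a model prediction. Labels are renumbered by first occurrence so the
    output is deterministic, but only the partition is meaningful.
    """
    n = len(components)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= {n} components, got k={k}")
    if n == 1:
        return np.array([1])
    feats = np.vstack([c.feature_vector for c in components])
    raw = fcluster(linkage(feats, method=method), t=k, criterion="maxclust")
    remap: Dict[int, int] = {}
    labels = np.empty(n, int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    return labels
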