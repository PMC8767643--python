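"""Synthetic rosette-plant image generator with exact ground truth.

Every pipeline stage needs inputs whose true answer is known: plant pixel
sets for segmentation, flower counts and onset days for phenology, branch
counts for the regression, a stress label with a learnable morphological
signal for the classifier. This module renders small RGB top/side views and
a lower-resolution NIR top view of rosette plants whose geometry, color and
phenology are controlled by explicit parameters, and returns the rendered
truth alongside the images.

What is emulated: genotype-specific leaf number/size/aspect/hue, sigmoidal
growth over days after seeding (DAS), flowering onset with yellow disc
flowers grouped into k raceme-branch clusters (optionally overlapping),
drought morphology (daily area shrink, sinusoidal boundary ruffling, a hue
shift that depresses greenness, reduced NIR intensity, lighter pots), and an
NIR camera with half the RGB resolution and a fixed offset. What is not:
petal shape, self-occlusion, soil texture, specular lighting, plant motion
between the RGB and NIR exposures.

Determinism: one integer seed drives everything through
``numpy.random.SeedSequence``; each plant-day gets an independent child
stream, so any cohort slice can be re-rendered in isolation. The same seed
renders a bit-identical image, and a control/stress pair at the same seed
differs only through the deterministic stress transforms (the random draws
are consumed identically), giving true "stressed twin" contrasts.
"""

from __future__ import annotations

import colorsys
import csv
import dataclasses
import math
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .io import ExperimentSchedule
from .nir import CameraRegistration

# Frame geometry (pixels). The NIR camera sees the same pot at half the RGB
# resolution, shifted by a fixed offset -- a known registration that the
# mask-transfer stage must reproduce.
RGB_SHAPE = (160, 160)
SIDE_SHAPE = (160, 160)
NIR_SHAPE = (80, 80)
NIR_REGISTRATION = CameraRegistration(scale_x=0.5, scale_y=0.5, offset_x=3.0, offset_y=2.0)

#: Side-view row of the pot rim; plant pixels below it droop over the pot.
SIDE_RIM_ROW = 110

_BG_RGB = np.array([70.0, 62.0, 55.0])  # desaturated brown chamber background
_SOIL_RGB = np.array([55.0, 48.0, 40.0])
_NIR_BG = 55.0
_NIR_PLANT = 172.0
_RGB_NOISE_SD = 3.0
_NIR_NOISE_SD = 4.0


@dataclasses.dataclass
class GenotypeParams:
    """Geometry, color and phenology of one genotype."""

    name: str = "G0"
    n_leaves: int = 8
    leaf_length_px: float = 60.0
    leaf_aspect: float = 0.45  # minor/major axis ratio
    hue_center: float = 115.0  # degrees; ~green
    hue_jitter: float = 5.0  # per-leaf SD, degrees
    growth_rate: float = 0.08  # per day; sigmoidal saturation rate
    flowering_onset_das: Optional[int] = 45
    branches_k: int = 3
    flowers_per_branch_per_day: float = 4.0
    flower_radius_px: int = 6
    flowers_per_branch_cap: int = 4
    flower_overlap: bool = True  # pack flowers tight enough to touch

    def __post_init__(self) -> None:
        if min(self.n_leaves, self.leaf_length_px, self.leaf_aspect, self.growth_rate,
               self.branches_k, self.flowers_per_branch_per_day, self.flower_radius_px) <= 0:
            raise ValueError("genotype parameters must be positive")
        if self.flower_radius_px * 2 >= min(RGB_SHAPE):
            raise ValueError("flower radius exceeds the image frame")


@dataclasses.dataclass
class StressParams:
    """Drought-symptom model: shrink, ruffle, discolor, dry out."""

    onset_das: int = 39
    area_shrink_fraction: float = 0.03  # daily projected-area loss
    boundary_ruffle_amplitude: float = 0.18  # relative radius modulation
    boundary_ruffle_frequency: float = 9.0  # lobes per leaf boundary
    exg_shift: float = 9.0  # hue shift toward yellow, degrees
    nir_shift: float = 22.0  # NIR intensity drop of stressed tissue

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_shrink_fraction <= 1.0:
            raise ValueError("area_shrink_fraction must lie in [0, 1]")
        if not 0.0 <= self.boundary_ruffle_amplitude <= 1.0:
            raise ValueError("boundary_ruffle_amplitude must lie in [0, 1]")


@dataclasses.dataclass
class TruthRecord:
    """Rendered ground truth for one plant-day."""

    das: int
    mask_top: np.ndarray
    mask_side: np.ndarray
    mask_nir: np.ndarray
    flower_count: int
    flower_centers: List[Tuple[float, float]]  # (x, y) in the RGB top frame
    branch_count: int
    stressed: bool
    flowering_onset_das: Optional[int]

    @property
    def plant_pixels_top(self) -> int:
        return int(np.count_nonzero(self.mask_top))

    @property
    def plant_pixels_side(self) -> int:
        return int(np.count_nonzero(self.mask_side))


@dataclasses.dataclass
class RenderedPlant:
    rgb_top: np.ndarray
    rgb_side: np.ndarray
    nir_top: np.ndarray
    truth: TruthRecord


def flower_reference_px(params: GenotypeParams) -> int:
    """Pixel area of one fully open synthetic flower (a filled disc)."""
    return _disc_area(params.flower_radius_px)


def _disc_area(radius: int) -> int:
    span = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    return int(np.count_nonzero(dy**2 + dx**2 <= radius**2))


def _size_factor(das: int, growth_rate: float) -> float:
    """Saturating growth curve: 0 at ~10 DAS, ->1 as the rosette matures."""
    return max(0.0, 1.0 - math.exp(-growth_rate * (das - 10)))


def _hsv_to_rgb255(h_deg: float, s: float, v: float) -> np.ndarray:
    r, g, b = colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, min(max(s, 0), 1), min(max(v, 0), 1))
    return np.array([r, g, b]) * 255.0


def _paint_ellipse(
    mask: np.ndarray,
    color_img: Optional[np.ndarray],
    center: Tuple[float, float],  # (x, y)
    a: float,
    b: float,
    theta: float,
    color: Optional[np.ndarray],
    ruffle_amp: float = 0.0,
    ruffle_freq: float = 0.0,
    ruffle_phase: float = 0.0,
) -> None:
    """Rasterize a (possibly ruffled) rotated ellipse into mask and image.

    A pixel is inside when its elliptical radius is below
    ``1 + amp * sin(freq * phi + phase)`` where phi is the polar angle in the
    leaf frame -- amp 0 gives a plain ellipse, amp > 0 a lobed boundary.
    """
    cx, cy = center
    reach = max(a, b) * (1.0 + ruffle_amp) + 1.0
    y0, y1 = max(0, int(cy - reach)), min(mask.shape[0], int(cy + reach) + 2)
    x0, x1 = max(0, int(cx - reach)), min(mask.shape[1], int(cx + reach) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    r_ell = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if ruffle_amp > 0.0:
        phi = np.arctan2(v, u)
        limit = 1.0 + ruffle_amp * np.sin(ruffle_freq * phi + ruffle_phase)
    else:
        limit = 1.0
    inside = r_ell <= limit
    mask[y0:y1, x0:x1][inside] = True
    if color_img is not None and color is not None:
        color_img[y0:y1, x0:x1][inside] = color


def _paint_disc(mask, color_img, center, radius, color) -> None:
    _paint_ellipse(mask, color_img, center, radius, radius, 0.0, color)


def _flower_layout(params: GenotypeParams, das: int, size: float, jitter: np.ndarray) -> List[Tuple[float, float]]:
    """Deterministic flower centers for a given day, grouped by branch.

    Within each branch, flowers occupy successive slots of a fixed ring
    layout around the branch center; spacing is tight enough to overlap when
    ``flower_overlap`` is set, otherwise strictly disjoint.
    """
    if params.flowering_onset_das is None or das < params.flowering_onset_das:
        return []
    days_open = das - params.flowering_onset_das + 1
    per_branch = min(
        params.flowers_per_branch_cap,
        max(1, int(round(params.flowers_per_branch_per_day * days_open))),
    )
    cx0, cy0 = RGB_SHAPE[1] / 2.0, RGB_SHAPE[0] / 2.0
    branch_radius = 0.55 * params.leaf_length_px * size
    r = params.flower_radius_px
    step = (1.6 if params.flower_overlap else 2.3) * r
    centers: List[Tuple[float, float]] = []
    for b in range(params.branches_k):
        ang = 2.0 * math.pi * b / params.branches_k + float(jitter[b])
        bx = cx0 + branch_radius * math.cos(ang)
        by = cy0 + branch_radius * math.sin(ang)
        # slot 0 at the branch center, further slots on a ring around it
        for j in range(per_branch):
            if j == 0:
                fx, fy = bx, by
            else:
                slot_ang = ang + 2.0 * math.pi * (j - 1) / max(1, params.flowers_per_branch_cap - 1)
                fx = bx + step * math.cos(slot_ang)
                fy = by + step * math.sin(slot_ang)
            fx = min(max(fx, r + 1.0), RGB_SHAPE[1] - r - 2.0)
            fy = min(max(fy, r + 1.0), RGB_SHAPE[0] - r - 2.0)
            centers.append((fx, fy))
    return centers


def render_plant(
    genotype: GenotypeParams,
    das: int,
    stress: Optional[StressParams] = None,
    seed: int = 0,
) -> RenderedPlant:
    """Render one plant on one day; same seed gives bit-identical output.

    The random stream is consumed identically whether or not ``stress`` is
    given, so a control/stress pair at equal seed is a true morphological
    twin: identical leaf placement and palette, differing only in the
    deterministic stress transforms.
    """
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed)
    n = genotype.n_leaves
    # draw every random quantity up-front (stress-independent stream)
    ang_jit = rng.normal(0.0, 0.12, size=n)
    len_jit = rng.uniform(0.85, 1.15, size=n)
    hue_jit = rng.normal(0.0, genotype.hue_jitter, size=n)
    sat = rng.uniform(0.55, 0.72, size=n)
    val = rng.uniform(0.38, 0.55, size=n)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=n)
    branch_jit = rng.normal(0.0, 0.10, size=genotype.branches_k)
    side_jit = rng.uniform(0.9, 1.1, size=4)
    noise_top = rng.normal(0.0, _RGB_NOISE_SD, size=RGB_SHAPE + (3,))
    noise_side = rng.normal(0.0, _RGB_NOISE_SD, size=SIDE_SHAPE + (3,))
    noise_nir = rng.normal(0.0, _NIR_NOISE_SD, size=NIR_SHAPE)

    stressed_today = stress is not None and das >= stress.onset_das
    if stressed_today:
        days = das - stress.onset_das
        axis_shrink = (1.0 - stress.area_shrink_fraction) ** (days / 2.0)
        ruffle_amp = stress.boundary_ruffle_amplitude
        ruffle_freq = stress.boundary_ruffle_frequency
        hue_shift = -stress.exg_shift  # toward yellow
        nir_level = _NIR_PLANT - stress.nir_shift
    else:
        axis_shrink, ruffle_amp, ruffle_freq, hue_shift = 1.0, 0.0, 0.0, 0.0
        nir_level = _NIR_PLANT

    size = _size_factor(das, genotype.growth_rate)
    L = genotype.leaf_length_px * size * axis_shrink

    # ---- top view ----
    img_top = np.empty(RGB_SHAPE + (3,))
    img_top[:] = _BG_RGB
    mask_top = np.zeros(RGB_SHAPE, bool)
    cx0, cy0 = RGB_SHAPE[1] / 2.0, RGB_SHAPE[0] / 2.0
    _paint_disc(np.zeros(RGB_SHAPE, bool), img_top, (cx0, cy0), 0.65 * genotype.leaf_length_px, _SOIL_RGB)
    for i in range(n):
        theta = 2.0 * math.pi * i / n + ang_jit[i]
        a = 0.35 * L * len_jit[i]
        b = a * genotype.leaf_aspect
        lx = cx0 + 0.50 * L * len_jit[i] * math.cos(theta)
        ly = cy0 + 0.50 * L * len_jit[i] * math.sin(theta)
        color = _hsv_to_rgb255(genotype.hue_center + hue_jit[i] + hue_shift, sat[i], val[i])
        _paint_ellipse(mask_top, img_top, (lx, ly), a, b, theta, color,
                       ruffle_amp, ruffle_freq, phases[i])

    centers = _flower_layout(genotype, das, size * axis_shrink, branch_jit)
    for fx, fy in centers:
        _paint_disc(mask_top, img_top, (fx, fy), genotype.flower_radius_px,
                    _hsv_to_rgb255(52.0, 0.85, 0.92))
    img_top = np.clip(img_top + noise_top, 0, 255).astype(np.uint8)

    # ---- side view: stem + canopy ellipse, drooping leaves below the rim ----
    img_side = np.empty(SIDE_SHAPE + (3,))
    img_side[:] = _BG_RGB
    img_side[SIDE_RIM_ROW + 8:, :] = _SOIL_RGB  # pot body below the rim
    mask_side = np.zeros(SIDE_SHAPE, bool)
    H = 1.15 * L * side_jit[0]
    cx = SIDE_SHAPE[1] / 2.0
    canopy_cy = SIDE_RIM_ROW - 0.62 * H
    stem_color = _hsv_to_rgb255(genotype.hue_center + hue_shift, 0.55, 0.42)
    _paint_ellipse(mask_side, img_side, (cx, (SIDE_RIM_ROW + canopy_cy) / 2.0),
                   0.55 * H, 2.2, math.pi / 2.0, stem_color)
    leaf_color = _hsv_to_rgb255(genotype.hue_center + hue_shift, 0.62, 0.46)
    _paint_ellipse(mask_side, img_side, (cx, canopy_cy), 0.52 * L * side_jit[1],
                   0.36 * H, 0.0, leaf_color, ruffle_amp, ruffle_freq, phases[0])
    # two basal leaves drooping over the rim (more with stress-induced turgor loss)
    droop = 6.0 + (8.0 if stressed_today else 0.0)
    for sgn, j in ((-1, 2), (1, 3)):
        _paint_ellipse(mask_side, img_side,
                       (cx + sgn * 0.45 * L * side_jit[j], SIDE_RIM_ROW + droop - 4.0),
                       0.22 * L, 0.10 * L + droop * 0.5, sgn * 0.35, leaf_color,
                       ruffle_amp, ruffle_freq, phases[j % n])
    img_side = np.clip(img_side + noise_side, 0, 255).astype(np.uint8)

    # ---- NIR top view: inverse nearest-neighbor mapping of the truth mask ----
    reg = NIR_REGISTRATION
    yy, xx = np.mgrid[0:NIR_SHAPE[0], 0:NIR_SHAPE[1]]
    sx = np.rint((xx - reg.offset_x) / reg.scale_x).astype(int)
    sy = np.rint((yy - reg.offset_y) / reg.scale_y).astype(int)
    inb = (sx >= 0) & (sx < RGB_SHAPE[1]) & (sy >= 0) & (sy < RGB_SHAPE[0])
    mask_nir = np.zeros(NIR_SHAPE, bool)
    mask_nir[inb] = mask_top[sy[inb], sx[inb]]
    nir = np.full(NIR_SHAPE, _NIR_BG)
    nir[mask_nir] = nir_level
    nir = np.clip(nir + noise_nir, 0, 255).astype(np.uint8)

    truth = TruthRecord(
        das=das,
        mask_top=mask_top,
        mask_side=mask_side,
        mask_nir=mask_nir,
        flower_count=len(centers),
        flower_centers=centers,
        branch_count=genotype.branches_k if centers else 0,
        stressed=stressed_today,
        flowering_onset_das=genotype.flowering_onset_das,
    )
    return RenderedPlant(img_top, img_side, nir, truth)


def sample_genotype(rng: np.random.Generator, name: str) -> GenotypeParams:
    """Draw one genotype's parameters, emulating panel diversity."""
    return GenotypeParams(
        name=name,
        n_leaves=int(rng.integers(6, 11)),
        leaf_length_px=float(rng.uniform(50, 68)),
        leaf_aspect=float(rng.uniform(0.38, 0.52)),
        hue_center=float(rng.uniform(108, 122)),
        hue_jitter=float(rng.uniform(3, 7)),
        growth_rate=float(rng.uniform(0.06, 0.10)),
        flowering_onset_das=int(rng.integers(41, 52)),
        branches_k=int(rng.integers(1, 7)),
        flowers_per_branch_per_day=float(rng.uniform(4.0, 6.0)),
        flower_radius_px=6,
    )


def default_schedule() -> ExperimentSchedule:
    """Every-other-day imaging through the treatment phase (35-57 DAS)."""
    return ExperimentSchedule(
        imaging_days=list(range(35, 58, 2)),
        treatment_window=(35, 55),
        treatment_map={},
    )


@dataclasses.dataclass
class Cohort:
    """Generated dataset: file layout root plus in-memory truth tables."""

    root: Path
    metadata_path: Path
    truth_path: Path
    genotypes: List[GenotypeParams]
    truth_rows: List[dict]
    schedule: ExperimentSchedule
    seed: int


def _plant_seed(seed: int, g: int, rep: int, das: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, g, rep, das])


def generate_cohort(
    n_genotypes: int,
    reps_per_treatment: int,
    schedule: Optional[ExperimentSchedule] = None,
    seed: int = 0,
    out_dir: Optional[Path] = None,
    stress: Optional[StressParams] = None,
    write_images: bool = True,
) -> Cohort:
    """Generate a full experiment in the dataset-IO layout.

    Per genotype, ``reps_per_treatment`` plants grow under control watering
    and the same number under drought, each imaged (RGB top + RGB side + NIR
    top) on every schedule day. Emits ``metadata.csv``, ``truth.csv`` and the
    PNG images under ``out_dir``; with ``write_images=False`` only the CSVs
    are written (rasters can always be re-rendered from the seed).

    Pot weights: control pots are watered back to field capacity, drought
    pots to 40% of it, so weights carry a strong treatment signal -- as they
    do on a real gravimetric watering platform.
    """
    schedule = schedule or default_schedule()
    stress = stress or StressParams(onset_das=schedule.treatment_window[0] + 4)
    root = Path(out_dir) if out_dir is not None else None
    if root is not None:
        (root / "images").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    genotypes = [sample_genotype(master, f"G{g:02d}") for g in range(n_genotypes)]

    meta_rows: List[dict] = []
    truth_rows: List[dict] = []
    for g, geno in enumerate(genotypes):
        for rep in range(2 * reps_per_treatment):
            treatment = "control" if rep < reps_per_treatment else "drought"
            plant_id = f"{geno.name}_r{rep}_{treatment[0]}"
            wrng = np.random.default_rng(np.random.SeedSequence([seed, g, rep, 999]))
            for das in schedule.imaging_days:
                plant = render_plant(
                    geno,
                    das,
                    stress if treatment == "drought" else None,
                    seed=_plant_seed(seed, g, rep, das),
                )
                in_window = schedule.treatment_window[0] <= das <= schedule.treatment_window[1]
                dry = treatment == "drought" and in_window
                w_before = float(wrng.normal(3400 if not dry else 2300, 60))
                w_after = w_before + float(wrng.normal(450 if not dry else 160, 25))
                for view, modality, arr in (
                    ("top", "RGB", plant.rgb_top),
                    ("side", "RGB", plant.rgb_side),
                    ("top", "NIR", plant.nir_top),
                ):
                    rel = f"images/{plant_id}_d{das}_{view}_{modality}.png"
                    if root is not None and write_images:
                        Image.fromarray(arr).save(root / rel)
                    meta_rows.append(
                        {
                            "plant_id": plant_id,
                            "genotype": geno.name,
                            "das": das,
                            "treatment": treatment,
                            "view": view,
                            "modality": modality,
                            "path": rel,
                            "weight_before": f"{w_before:.1f}",
                            "weight_after": f"{w_after:.1f}",
                        }
                    )
                truth_rows.append(
                    {
                        "plant_id": plant_id,
                        "genotype": geno.name,
                        "das": das,
                        "treatment": treatment,
                        "plant_pixels_top": plant.truth.plant_pixels_top,
                        "plant_pixels_side": plant.truth.plant_pixels_side,
                        "flower_count": plant.truth.flower_count,
                        "branch_count": geno.branches_k,
                        "flowering_onset_das": geno.flowering_onset_das,
                        "stressed": int(plant.truth.stressed),
                    }
                )

    metadata_path = truth_path = None
    if root is not None:
        metadata_path = root / "metadata.csv"
        with open(metadata_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(meta_rows[0]))
            writer.writeheader()
            writer.writerows(meta_rows)
        truth_path = root / "truth.csv"
        with open(truth_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(truth_rows[0]))
            writer.writeheader()
            writer.writerows(truth_rows)

    return Cohort(
        root=root,
        metadata_path=metadata_path,
        truth_path=truth_path,
        genotypes=genotypes,
        truth_rows=truth_rows,
        schedule=schedule,
        seed=seed,
    )
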