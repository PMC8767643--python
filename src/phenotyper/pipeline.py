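"""End-to-end orchestration: images in, trait tables and CV reports out.

Stage order: index -> segment -> (holistic traits | NIR summaries | boundary
curvature | flower phenology) -> feature assembly -> cross-validated models.
All intermediate products are plain CSV/JSON so any downstream environment
can consume them; the run manifest records the config hash, seed and row
tallies per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import flowers as fl
from . import hocs as hc
from . import io as dio
from . import ml
from . import nir as nr
from . import segmentation as seg
from . import traits as tr

log = logging.getLogger("phenotyper")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible run needs, loadable from YAML."""

    root: Path
    metadata: Path
    labels: Optional[Path] = None  # manual annotations: branch counts, stress, onset
    out_dir: Path = Path("phenotyper_out")
    segmentation: Optional[seg.SegmentationConfig] = None
    policy: Optional[fl.FlowerThresholdPolicy] = None
    registration: Optional[nr.CameraRegistration] = None
    rim_row: Optional[int] = None
    flower_ref_px: float = 113.0
    min_component_px: int = fl.DEFAULT_MIN_COMPONENT_PX
    assessment_das: int = 49
    nir_window: tuple = dio.DEFAULT_NIR_PAIRING_WINDOW
    hocs_radii: Sequence[int] = hc.DEFAULT_RADII
    hocs_bins: int = hc.DEFAULT_N_BINS
    exg_variant: str = "paper"
    cv_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        self.metadata = Path(self.metadata)
        if not self.metadata.is_file():
            raise PipelineError(f"config.metadata does not exist: {self.metadata}")
        if self.labels is not None:
            self.labels = Path(self.labels)
            if not self.labels.is_file():
                raise PipelineError(f"config.labels does not exist: {self.labels}")
        self.segmentation = self.segmentation or seg.default_config()
        self.policy = self.policy or fl.default_policy()
        self.registration = self.registration or nr.CameraRegistration()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("root", "metadata"):
            if key not in raw:
                raise PipelineError(f"run config is missing required field {key!r}")
        kwargs = dict(raw)
        if "segmentation" in raw and raw["segmentation"]:
            kwargs["segmentation"] = seg.SegmentationConfig.from_dict(raw["segmentation"])
        if "policy" in raw and raw["policy"]:
            kwargs["policy"] = fl.FlowerThresholdPolicy(
                rules=[fl.ThresholdRule(**r) for r in raw["policy"]["rules"]]
            )
        if "registration" in raw and raw["registration"]:
            kwargs["registration"] = nr.CameraRegistration(**raw["registration"])
        return cls(**kwargs)

    def digest(self) -> str:
        blob = repr(sorted(dataclasses.asdict(self).items(), key=lambda kv: kv[0]))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------- stages


def segment_observations(index: dio.IndexResult, config: RunConfig) -> Dict[tuple, np.ndarray]:
    """Plant masks for every RGB observation, keyed by (plant_id, das, view)."""
    masks = {}
    for obs in index.observations:
        if obs.modality != "RGB":
            continue
        try:
            masks[(obs.plant_id, obs.das, obs.view)] = seg.segment(obs.raster, config.segmentation)
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(f"segmentation failed for {obs.key}: {exc}") from exc
    return masks


def trait_table(
    index: dio.IndexResult, masks: Dict[tuple, np.ndarray], config: RunConfig
) -> pd.DataFrame:
    """Holistic traits per RGB observation (long on view, wide on trait)."""
    rows = []
    for obs in index.observations:
        if obs.modality != "RGB":
            continue
        mask = masks[(obs.plant_id, obs.das, obs.view)]
        rec = tr.extract_holistic(mask, view=obs.view, rim_row=config.rim_row)
        exg = tr.excess_green(obs.raster, mask, config.exg_variant) if obs.view == "top" else None
        rows.append(
            {
                "plant_id": obs.plant_id,
                "genotype": obs.genotype,
                "das": obs.das,
                "treatment": obs.treatment,
                "view": obs.view,
                "pixels": rec.pixels,
                "hull_area": rec.hull_area,
                "height": rec.height,
                "width": rec.width,
                "exg": exg,
                "area_below_rim": rec.area_below_rim,
                "empty": rec.empty,
                "weight_before": obs.weight_before,
                "weight_after": obs.weight_after,
            }
        )
    return pd.DataFrame(rows)


def nir_table(
    index: dio.IndexResult, masks: Dict[tuple, np.ndarray], config: RunConfig
) -> pd.DataFrame:
    """Masked NIR summaries for every RGB/NIR top-view pair in the window."""
    pairs = dio.pair_rgb_nir(index.observations, das_window=config.nir_window)
    rows = []
    for rgb_obs, nir_obs in pairs:
        mask = masks[(rgb_obs.plant_id, rgb_obs.das, "top")]
        transferred, empty = nr.transfer_mask(mask, config.registration, nir_obs.raster.shape)
        mean, p75 = (None, None) if empty else nr.summarize_nir(nir_obs.raster, transferred)
        rows.append(
            {
                "plant_id": rgb_obs.plant_id,
                "das": rgb_obs.das,
                "nir_mean": mean,
                "nir_p75": p75,
                "empty_transfer": empty,
            }
        )
    return pd.DataFrame(rows)


def hocs_table(
    index: dio.IndexResult, masks: Dict[tuple, np.ndarray], config: RunConfig
) -> pd.DataFrame:
    """Boundary-curvature descriptors of top-view masks on the assessment day."""
    rows = []
    names = None
    for obs in index.observations:
        if obs.modality != "RGB" or obs.view != "top" or obs.das != config.assessment_das:
            continue
        mask = masks[(obs.plant_id, obs.das, "top")]
        if not mask.any():
            continue
        desc = hc.hocs_descriptor(mask, radii=config.hocs_radii, n_bins=config.hocs_bins)
        names = names or desc.feature_names()
        rows.append(
            {"plant_id": obs.plant_id, "das": obs.das, "treatment": obs.treatment,
             **dict(zip(names, desc.flatten()))}
        )
    return pd.DataFrame(rows)


def flower_table(
    index: dio.IndexResult,
    masks: Dict[tuple, np.ndarray],
    config: RunConfig,
    branch_k: Optional[Dict[tuple, int]] = None,
) -> pd.DataFrame:
    """Per-plant-day flower phenology from top-view RGB observations.

    ``branch_k`` optionally maps (plant_id, das) to a raceme-branch count
    (manual or predicted) at which the component clustering tree is cut;
    without it the branch_labels column stays empty.
    """
    per_plant: Dict[str, List[dio.PlantObservation]] = {}
    for obs in index.observations:
        if obs.modality == "RGB" and obs.view == "top":
            per_plant.setdefault(obs.plant_id, []).append(obs)

    side_height = {}
    for obs in index.observations:
        if obs.modality == "RGB" and obs.view == "side":
            mask = masks[(obs.plant_id, obs.das, "side")]
            rec = tr.extract_holistic(mask, view="side")
            side_height[(obs.plant_id, obs.das)] = rec.height

    rows = []
    for plant_id, obs_list in per_plant.items():
        obs_list.sort(key=lambda o: o.das)
        comp_by_day = {}
        for obs in obs_list:
            mask = masks[(plant_id, obs.das, "top")]
            fmask = fl.flower_mask(obs.raster, mask, config.policy, obs.das, obs.treatment)
            comps = fl.extract_components(fmask, config.min_component_px)
            comp_by_day[obs.das] = (obs, fmask, comps)
        anthesis = fl.detect_anthesis({d: c for d, (_, _, c) in comp_by_day.items()})
        for das, (obs, fmask, comps) in sorted(comp_by_day.items()):
            height = side_height.get((plant_id, das), 0)
            if comps and height and height > 0:
                width, angle = fl.canopy_metrics(comps, height)
            else:
                width = angle = None
            k = (branch_k or {}).get((plant_id, das))
            labels = (
                fl.cluster_racemes(comps, min(int(k), len(comps))).tolist()
                if comps and k
                else []
            )
            rows.append(
                {
                    "plant_id": plant_id,
                    "genotype": obs.genotype,
                    "das": das,
                    "treatment": obs.treatment,
                    "flower_pixels": int(np.count_nonzero(fmask)),
                    "n_components": len(comps),
                    "est_flowers": fl.estimate_flower_count(comps, config.flower_ref_px)
                    if comps
                    else 0,
                    "anthesis_das": anthesis,
                    "flowering": int(anthesis is not None and das >= anthesis),
                    "canopy_width": width,
                    "canopy_angle": angle,
                    "branch_labels": json.dumps(labels),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------- feature assembly


def flowering_groups(anthesis_by_plant: Dict[str, Optional[int]]) -> Dict[str, int]:
    """Ordinal early/intermediate/late (0/1/2) by terciles of anthesis day.

    Plants that never flowered in the experiment are coded late (2).
    """
    days = sorted(d for d in anthesis_by_plant.values() if d is not None)
    if not days:
        return {p: 2 for p in anthesis_by_plant}
    lo, hi = np.quantile(days, [1 / 3, 2 / 3])
    out = {}
    for plant, d in anthesis_by_plant.items():
        if d is None:
            out[plant] = 2
        else:
            out[plant] = 0 if d <= lo else (1 if d <= hi else 2)
    return out


def build_branch_table(flowers_df: pd.DataFrame, labels_df: pd.DataFrame) -> pd.DataFrame:
    """Join flower outputs with manual branch counts on (plant_id, das).

    Only flowering observations are kept: a branch count is only defined
    once an inflorescence exists.
    """
    lab = labels_df[["plant_id", "das", "branch_count"]]
    merged = flowers_df.merge(lab, on=["plant_id", "das"], how="inner")
    return merged[merged["flowering"] == 1].reset_index(drop=True)


def build_stress_table(
    traits_df: pd.DataFrame,
    nir_df: pd.DataFrame,
    flowers_df: pd.DataFrame,
    labels_df: pd.DataFrame,
    assessment_das: int = 49,
) -> pd.DataFrame:
    """Assemble the stress feature table (one row per plant, assessment day).

    Δ columns are differences between the assessment day and the previous
    imaging day, computed per plant with :func:`phenotyper.traits.day_deltas`.
    Plant height comes from the side view, plant width from the top view.
    """
    if assessment_das not in set(traits_df["das"]):
        raise PipelineError(f"assessment day {assessment_das} has no trait rows")

    def per_view(view: str, col: str) -> pd.DataFrame:
        sub = traits_df[traits_df["view"] == view][["plant_id", "das", col]]
        return sub

    def value_and_delta(view: str, col: str, plant: str):
        sub = traits_df[(traits_df["view"] == view) & (traits_df["plant_id"] == plant)]
        series = dict(zip(sub["das"], sub[col]))
        deltas = tr.day_deltas({d: v for d, v in series.items() if v is not None})
        return series.get(assessment_das), deltas.get(assessment_das)

    anthesis = {
        p: (None if pd.isna(a) else int(a))
        for p, a in flowers_df.groupby("plant_id")["anthesis_das"].first().items()
    }
    groups = flowering_groups(anthesis)
    nir_at = nir_df[nir_df["das"] == assessment_das].set_index("plant_id")
    lab_at = labels_df[labels_df["das"] == assessment_das].set_index("plant_id")
    top_at = traits_df[
        (traits_df["view"] == "top") & (traits_df["das"] == assessment_das)
    ].set_index("plant_id")
    side_at = traits_df[
        (traits_df["view"] == "side") & (traits_df["das"] == assessment_das)
    ].set_index("plant_id")

    rows = []
    for plant in sorted(set(traits_df["plant_id"])):
        if plant not in top_at.index or plant not in side_at.index or plant not in lab_at.index:
            continue
        px_tv, d_px_tv = value_and_delta("top", "pixels", plant)
        hull_tv, d_hull_tv = value_and_delta("top", "hull_area", plant)
        px_sv, d_px_sv = value_and_delta("side", "pixels", plant)
        hull_sv, d_hull_sv = value_and_delta("side", "hull_area", plant)
        height, d_height = value_and_delta("side", "height", plant)
        width, d_width = value_and_delta("top", "width", plant)
        nrow = nir_at.loc[plant] if plant in nir_at.index else None
        rows.append(
            {
                "plant_id": plant,
                "das": assessment_das,
                "nir_mean": None if nrow is None else nrow["nir_mean"],
                "nir_p75": None if nrow is None else nrow["nir_p75"],
                "pixels_tv": px_tv,
                "d_pixels_tv": d_px_tv,
                "hull_tv": hull_tv,
                "d_hull_tv": d_hull_tv,
                "pixels_sv": px_sv,
                "d_pixels_sv": d_px_sv,
                "hull_sv": hull_sv,
                "d_hull_sv": d_hull_sv,
                "weight_before": top_at.loc[plant]["weight_before"],
                "weight_after": top_at.loc[plant]["weight_after"],
                "area_below_rim": side_at.loc[plant]["area_below_rim"],
                "height": height,
                "d_height": d_height,
                "width": width,
                "d_width": d_width,
                "exg": top_at.loc[plant]["exg"],
                "flowering_group": groups.get(plant, 2),
                "n_branches": lab_at.loc[plant]["branch_count"],
                "stress": lab_at.loc[plant]["stressed"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- driver


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order; return the run manifest.

    Writes traits.csv, nir.csv, flowers.csv, hocs.csv, feature tables, the
    ML report JSON and manifest.json under ``config.out_dir``. Identical
    config and seed produce byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_digest": config.digest(), "seed": config.seed, "stages": {}}

    index = dio.index_dataset(config.root, config.metadata)
    manifest["stages"]["index"] = {
        "observations": len(index.observations),
        "failures": len(index.failures),
    }
    if not index.observations:
        raise PipelineError("index stage produced no observations")

    masks = segment_observations(index, config)
    manifest["stages"]["segment"] = {"masks": len(masks)}

    labels_df = pd.read_csv(config.labels) if config.labels is not None else None
    branch_k = (
        {
            (r.plant_id, r.das): int(r.branch_count)
            for r in labels_df.itertuples()
            if "branch_count" in labels_df.columns and r.branch_count > 0
        }
        if labels_df is not None
        else None
    )

    traits_df = trait_table(index, masks, config)
    traits_df.to_csv(out / "traits.csv", index=False)
    nir_df = nir_table(index, masks, config)
    nir_df.to_csv(out / "nir.csv", index=False)
    hocs_df = hocs_table(index, masks, config)
    hocs_df.to_csv(out / "hocs.csv", index=False)
    flowers_df = flower_table(index, masks, config, branch_k=branch_k)
    flowers_df.to_csv(out / "flowers.csv", index=False)
    manifest["stages"]["tables"] = {
        "traits": len(traits_df),
        "nir": len(nir_df),
        "hocs": len(hocs_df),
        "flowers": len(flowers_df),
    }

    reports = {}
    if labels_df is not None:
        branch_df = build_branch_table(flowers_df, labels_df)
        branch_df.to_csv(out / "branch_features.csv", index=False)
        if len(branch_df) >= config.cv_k:
            table = ml.assemble_branch_features(branch_df)
            for algo in ml.REGRESSORS:
                reports[f"branch_{algo}"] = ml.cv_regression(
                    table, algorithm=algo, k=config.cv_k, seed=config.seed
                ).to_dict()
        stress_df = build_stress_table(
            traits_df, nir_df, flowers_df, labels_df, config.assessment_das
        )
        stress_df.to_csv(out / "stress_features.csv", index=False)
        stable = ml.assemble_stress_features(stress_df, das=config.assessment_das)
        balanced = ml.downsample_balance(stable, seed=config.seed)
        if len(balanced) >= config.cv_k:
            for algo in ml.CLASSIFIER_NAMES:
                reports[f"stress_{algo}"] = ml.cv_classification(
                    balanced, algorithm=algo, k=config.cv_k, seed=config.seed
                ).to_dict()
        (out / "ml_report.json").write_text(json.dumps(reports, indent=1))
        manifest["stages"]["ml"] = {
            "branch_rows": len(branch_df),
            "stress_rows": len(stress_df),
            "reports": sorted(reports),
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    log.info("pipeline complete: %s", manifest_path)
    return manifest
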