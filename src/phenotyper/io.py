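"""Dataset indexing and loading.

An experiment is a directory of per-plant, per-day images (RGB top view at
90 degrees, RGB side view at 0 degrees, grayscale NIR top view) plus a CSV
metadata sidecar that is authoritative for plant identity, genotype, imaging
day (DAS, days after seeding), treatment group, view, modality and optional
pot weights before/after watering.

Coordinate convention used throughout the package: x is the column index
increasing rightward, y is the row index increasing downward, both 0-based;
bounding boxes are half-open ``[min, max)``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from PIL import Image

TREATMENTS = ("control", "drought")
VIEWS = ("top", "side")
MODALITIES = ("RGB", "NIR")

#: Required columns of the metadata CSV, in canonical order.
METADATA_COLUMNS = (
    "plant_id",
    "genotype",
    "das",
    "treatment",
    "view",
    "modality",
    "path",
    "weight_before",
    "weight_after",
)

#: DAS window in which the RGB and NIR camera fields of view overlap enough
#: for mask transfer; outside it RGB/NIR pairing is not attempted.
DEFAULT_NIR_PAIRING_WINDOW = (37, 59)


class SchemaError(ValueError):
    """The metadata table violates the required schema."""


@dataclasses.dataclass
class PlantObservation:
    """One image of one plant on one day.

    The pixel raster is loaded lazily from ``path`` on first access of
    :attr:`raster`; RGB rasters are ``(rows, cols, 3)`` uint8, NIR rasters
    ``(rows, cols)`` uint8.
    """

    plant_id: str
    genotype: str
    das: int
    treatment: str
    view: str
    modality: str
    path: Optional[Path] = None
    weight_before: Optional[float] = None
    weight_after: Optional[float] = None
    _raster: Optional[np.ndarray] = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.das < 1:
            raise ValueError(f"das must be >= 1, got {self.das}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self._raster is not None:
            self._raster = _validate_raster(self._raster, self.modality)

    @property
    def raster(self) -> np.ndarray:
        if self._raster is None:
            if self.path is None:
                raise ValueError("observation has neither raster nor path")
            arr = np.asarray(Image.open(self.path))
            self._raster = _validate_raster(arr, self.modality)
        return self._raster

    @property
    def key(self) -> tuple:
        """Uniqueness key within an experiment."""
        return (self.plant_id, self.das, self.view, self.modality)

    def to_row(self) -> dict:
        """Serialize the metadata fields back to a CSV row dict."""
        return {
            "plant_id": self.plant_id,
            "genotype": self.genotype,
            "das": self.das,
            "treatment": self.treatment,
            "view": self.view,
            "modality": self.modality,
            "path": "" if self.path is None else str(self.path),
            "weight_before": _fmt_opt(self.weight_before),
            "weight_after": _fmt_opt(self.weight_after),
        }


def _validate_raster(arr: np.ndarray, modality: str) -> np.ndarray:
    arr = np.asarray(arr)
    if modality == "RGB":
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"RGB raster must be (rows, cols, 3), got {arr.shape}")
    else:
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim != 2:
            raise ValueError(f"NIR raster must be 2-D, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def _fmt_opt(v: Optional[float]) -> str:
    return "" if v is None else repr(float(v))


@dataclasses.dataclass
class ExperimentSchedule:
    """Imaging timeline and treatment design of one experiment."""

    imaging_days: list
    treatment_window: tuple
    treatment_map: dict

    def __post_init__(self) -> None:
        days = list(self.imaging_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("imaging_days must be strictly increasing")
        lo, hi = self.treatment_window
        if not (days[0] <= lo <= hi <= days[-1]):
            raise ValueError("treatment window must lie within the imaging span")


@dataclasses.dataclass
class IndexResult:
    """Outcome of indexing: valid observations plus per-row failures."""

    observations: list
    failures: list  # list of (row_number, message)

    def __iter__(self):
        return iter(self.observations)

    def __len__(self) -> int:
        return len(self.observations)


def read_metadata(metadata_path) -> list:
    """Read the metadata CSV, checking the schema.

    Raises :class:`SchemaError` if a required column is absent.
    """
    with open(metadata_path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in METADATA_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"metadata missing required columns: {missing}")
        return list(reader)


def index_dataset(root_path, metadata_path) -> IndexResult:
    """Index an image collection from its metadata CSV.

    Each valid row becomes a :class:`PlantObservation` with a lazily loaded
    raster. Rows whose image file is missing or whose fields do not validate
    are collected as failures rather than raised, so one bad record does not
    abort an experiment. Duplicate ``(plant_id, das, view, modality)`` rows
    are a validation error: the same plant cannot be imaged twice the same
    way on the same day.
    """
    root = Path(root_path)
    rows = read_metadata(metadata_path)
    seen = {}
    for i, row in enumerate(rows):
        key = (row["plant_id"], row["das"], row["view"], row["modality"])
        if key in seen:
            raise SchemaError(
                f"duplicate observation {key} at metadata rows {seen[key]} and {i}"
            )
        seen[key] = i

    observations, failures = [], []
    for i, row in enumerate(rows):
        path = root / row["path"]
        if not path.is_file():
            failures.append((i, f"image file not found: {path}"))
            continue
        try:
            obs = PlantObservation(
                plant_id=row["plant_id"],
                genotype=row["genotype"],
                das=int(row["das"]),
                treatment=row["treatment"],
                view=row["view"],
                modality=row["modality"],
                path=path,
                weight_before=_parse_opt(row.get("weight_before")),
                weight_after=_parse_opt(row.get("weight_after")),
            )
        except (ValueError, KeyError) as exc:
            failures.append((i, str(exc)))
            continue
        observations.append(obs)
    return IndexResult(observations, failures)


def _parse_opt(v) -> Optional[float]:
    if v is None or str(v).strip() == "":
        return None
    return float(v)


@dataclasses.dataclass
class PairingResult:
    """RGB/NIR top-view pairs plus the count of unpaired observations."""

    pairs: list  # list of (rgb_obs, nir_obs)
    n_unpaired: int

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def pair_rgb_nir(
    observations: Iterable[PlantObservation],
    das_window: tuple = DEFAULT_NIR_PAIRING_WINDOW,
) -> PairingResult:
    """Pair RGB top-view and NIR top-view observations of the same plant-day.

    The RGB top-view plant mask is later transferred onto the NIR frame, which
    is only geometrically feasible inside the DAS window where the two camera
    fields of view overlap (default 37-59 DAS). Pairing is deterministic:
    pairs are sorted by ``(plant_id, das)`` regardless of input order.
    """
    lo, hi = das_window
    rgb, nir = {}, {}
    n_candidates = 0
    for obs in observations:
        if obs.view != "top":
            continue
        n_candidates += 1
        if not (lo <= obs.das <= hi):
            continue
        bucket = rgb if obs.modality == "RGB" else nir
        bucket[(obs.plant_id, obs.das)] = obs
    keys = sorted(set(rgb) & set(nir))
    pairs = [(rgb[k], nir[k]) for k in keys]
    return PairingResult(pairs, n_unpaired=n_candidates - 2 * len(pairs))


def write_manifest(result: IndexResult, out_path) -> None:
    """Write an index manifest (observation rows + failures) as JSON."""
    payload = {
        "observations": [obs.to_row() for obs in result.observations],
        "failures": [{"row": r, "error": msg} for r, msg in result.failures],
    }
    Path(out_path).write_text(json.dumps(payload, indent=1))
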