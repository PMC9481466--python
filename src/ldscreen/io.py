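"""File formats: TIFF images and masks, CSV tables, YAML/JSON config.

Plate layouts, well records and screen results round-trip through CSV
with fixed column names; field images and label masks are 16-bit TIFF;
configuration objects serialize to a single YAML (or JSON) file.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .quantify import WellRecord
from .segmentation import PixelClassifierModel
from .simulate import (PlateLayout, SimulationConfig, WellSpec, ROLES,
                       FieldImage, FieldGroundTruth, layout_to_frame)

__all__ = [
    "normalize_well",
    "read_plate_layout",
    "write_plate_layout",
    "read_well_records",
    "write_well_records",
    "write_field_tiff",
    "read_field_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_ground_truth",
    "save_config",
    "load_config",
    "save_classifier",
    "load_classifier",
]

_WELL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


def normalize_well(coord: str, n_rows: int = 16, n_cols: int = 24) -> str:
    """Normalize a well coordinate to letter + two digits ('a1' -> 'A01')."""
    m = _WELL_RE.match(str(coord).strip())
    if not m:
        raise ValueError(f"malformed well coordinate {coord!r}")
    row = m.group(1).upper()
    col = int(m.group(2))
    if ord(row) - ord("A") >= n_rows or not (1 <= col <= n_cols):
        raise ValueError(f"well coordinate {coord!r} outside the {n_rows}x{n_cols} grid")
    return f"{row}{col:02d}"


def read_plate_layout(path) -> list[PlateLayout]:
    """Read plate layouts from CSV (plate, replicate, well, gene, dsrna_id, role).

    Rejects malformed coordinates, unknown roles and duplicate wells,
    naming the offending data row (1-based, excluding the header).
    """
    frame = pd.read_csv(path)
    if len(frame) == 0:
        raise ValueError(f"{path}: empty layout file")
    required = {"plate", "well", "role"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in frame.columns:
        frame["replicate"] = 1
    plates: dict[tuple[int, int], list[WellSpec]] = {}
    seen: dict[tuple[int, int, str], int] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            well = normalize_well(row.well)
        except ValueError as e:
            raise ValueError(f"{path}: row {i}: {e}") from None
        role = str(row.role)
        if role not in ROLES:
            raise ValueError(f"{path}: row {i}: unknown role {role!r}")
        key = (int(row.plate), int(row.replicate), well)
        if key in seen:
            raise ValueError(
                f"{path}: row {i}: duplicate well {well} on plate {row.plate} "
                f"(first seen at row {seen[key]})")
        seen[key] = i
        gene = None if pd.isna(getattr(row, "gene", None)) else str(row.gene)
        ds = None if pd.isna(getattr(row, "dsrna_id", None)) else str(row.dsrna_id)
        plates.setdefault((int(row.plate), int(row.replicate)), []).append(
            WellSpec(well=well, gene=gene, dsrna_id=ds, role=role))
    return [PlateLayout(plate_id=p, replicate=r, wells=tuple(ws))
            for (p, r), ws in sorted(plates.items())]


def write_plate_layout(plates, path) -> None:
    layout_to_frame(plates).to_csv(path, index=False)


WELL_RECORD_COLUMNS = ["plate", "well", "gene", "dsrna_id", "replicate", "x_i",
                       "cell_count", "median_rel_ld_area", "n_cells_with_ratio"]


def write_well_records(records: list[WellRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records],
                 columns=WELL_RECORD_COLUMNS).to_csv(path, index=False)


def read_well_records(path) -> list[WellRecord]:
    frame = pd.read_csv(path)
    out = []
    for row in frame.itertuples(index=False):
        out.append(WellRecord(
            plate=int(row.plate), well=str(row.well),
            gene=None if pd.isna(row.gene) else str(row.gene),
            dsrna_id=None if pd.isna(row.dsrna_id) else str(row.dsrna_id),
            replicate=int(row.replicate), x_i=float(row.x_i),
            cell_count=int(row.cell_count),
            median_rel_ld_area=float(row.median_rel_ld_area),
            n_cells_with_ratio=int(row.n_cells_with_ratio)))
    return out


def write_field_tiff(field: FieldImage, path) -> None:
    """Write a field as multi-channel 16-bit TIFF (protein, nuclei, LD)."""
    data = np.clip(np.round(field.channels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack",
                     metadata={"axes": "CYX",
                               "pixel_size_um": field.pixel_size_um})


def read_field_tiff(path, pixel_size_um: float = 0.065) -> FieldImage:
    data = tifffile.imread(path).astype(np.float32)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a (C, H, W) stack")
    return FieldImage(channels=data, pixel_size_um=pixel_size_um)


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint16))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_ground_truth(gt: FieldGroundTruth, stem: Path) -> None:
    """Label masks as TIFF plus a JSON sidecar with per-cell truth."""
    stem = Path(stem)
    write_mask_tiff(gt.nuclei, stem.with_suffix(".nuclei.tif"))
    write_mask_tiff(gt.cells, stem.with_suffix(".cells.tif"))
    write_mask_tiff(gt.lds, stem.with_suffix(".lds.tif"))
    sidecar = {
        "ld_owner": {str(k): int(v) for k, v in gt.ld_owner.items()},
        "cell_true_ratio": {str(k): float(v) for k, v in gt.cell_true_ratio.items()},
    }
    stem.with_suffix(".truth.json").write_text(json.dumps(sidecar, indent=1))


def save_config(cfg, path) -> None:
    """Serialize a dataclass config to YAML (or JSON by extension)."""
    payload = dataclasses.asdict(cfg)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=1))
    else:
        path.write_text(yaml.safe_dump(payload))


def load_config(path, cls=SimulationConfig):
    path = Path(path)
    raw = (json.loads(path.read_text()) if path.suffix == ".json"
           else yaml.safe_load(path.read_text()))
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in raw.items():
        if k not in fields:
            raise ValueError(f"{path}: unknown config key {k!r}")
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def save_classifier(model: PixelClassifierModel, path) -> None:
    """Single binary file holding the forest plus JSON-able metadata."""
    joblib.dump({
        "metadata": {
            "compartment": model.compartment,
            "sigmas": list(model.sigmas),
            "n_train_images": model.n_train_images,
            "seed": model.seed,
            "holdout_accuracy": model.holdout_accuracy,
        },
        "forest": model.forest,
    }, path)


def load_classifier(path) -> PixelClassifierModel:
    payload = joblib.load(path)
    md = payload["metadata"]
    return PixelClassifierModel(
        compartment=md["compartment"], sigmas=tuple(md["sigmas"]),
        forest=payload["forest"], n_train_images=md["n_train_images"],
        seed=md["seed"], holdout_accuracy=md["holdout_accuracy"])
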