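"""Run orchestration: wire the stages into one reproducible pipeline.

A run is fully determined by a :class:`RunConfig` plus its input files.
Stages mirror the analysis: ``simulate`` (layouts, effects, well-level
screen table, plus a handful of rendered image wells), ``train`` (the
three pixel classifiers), ``segment``/``quantify`` (image wells through
segmentation to well records), ``score`` (robust-Z hit calling) and
``spatial`` (3D ERES-LD association demo).  Every stage writes CSV/TIFF
outputs under the run directory and contributes to a JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ldio
from . import segmentation as seg
from . import simulate as sim
from .quantify import aggregate_well, autofluorescence_correct, measure_field
from .screen import PUBLISHED_SCREEN_CONSTANTS, ScreenConstants, TargetingScreenModel
from .spatial import eres_ld_association, objects_from_labels, segment_objects_3d

log = logging.getLogger("ldscreen")

ALL_STAGES = ("simulate", "train", "segment", "quantify", "score", "spatial")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    out_dir: str = "ldscreen_run"
    seed: int = 0
    n_plates: int = 1
    wells_per_plate: int = 384
    n_replicates: int = 2
    n_genes: int = 300
    n_fields: int = 2
    n_image_wells: int = 4
    decrease_fraction: float = 0.05
    cell_death_fraction: float = 0.02
    constants_mode: str = "computed"  # or "published"
    z_cutoff: float = 2.5
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    noise: sim.ScreenNoiseModel = field(default_factory=sim.ScreenNoiseModel)
    min_nucleus_area_px: int = 50
    min_ld_area_px: int = 4
    prob_threshold: float = 0.5


def _write_report(out: Path, report: dict) -> None:
    path = out / "report.json"
    existing = json.loads(path.read_text()) if path.exists() else {}
    existing.update(report)
    path.write_text(json.dumps(existing, indent=1, sort_keys=True))


def _train_models(cfg: RunConfig, out: Path):
    """Train the three compartment classifiers on simulated annotated fields."""
    models = {}
    lacz = sim.WellSpec("A01", "LacZ", "ds_LacZ", "control_lacz")
    effect = sim.GroundTruthEffect("ds_LacZ", cfg.noise.baseline_ratio)
    train_fields = [
        sim.simulate_field(lacz, effect, cfg.simulation, sim.derive_seed("train", cfg.seed, i))
        for i in range(7)
    ]
    for compartment, channel, truth in (
        ("nucleus", "nuclei", "nuclei"),
        ("cell", "nuclei", "cells"),
        ("LD", "ld", "lds"),
    ):
        annotated = [
            (getattr(img, channel), (getattr(gt, truth) > 0).astype(np.uint8) + 1)
            for img, gt in train_fields
        ]
        model = seg.train_pixel_classifier(annotated, compartment,
                                           seed=sim.derive_seed("rf", cfg.seed, compartment))
        models[compartment] = model
        ldio.save_classifier(model, out / f"classifier_{compartment}.joblib")
        log.info("trained %s classifier, held-out accuracy %.4f",
                 compartment, model.holdout_accuracy)
    return models


def segment_field(img, models, cfg: RunConfig):
    """Classify all three channels and build label masks for one field."""
    p_nuc = models["nucleus"].predict_proba(img.nuclei)
    p_cell = models["cell"].predict_proba(img.nuclei)
    p_ld = models["LD"].predict_proba(img.ld)
    nuclei = seg.segment_nuclei(p_nuc >= cfg.prob_threshold, cfg.min_nucleus_area_px)
    cells = seg.segment_cells(p_cell >= cfg.prob_threshold, nuclei, cell_probability=p_cell)
    lds = seg.segment_lds(p_ld >= cfg.prob_threshold, cfg.min_ld_area_px)
    assignment = seg.assign_lds_to_cells(lds, cells)
    return nuclei, cells, lds, assignment


def quantify_image_wells(layout, effects, models, cfg: RunConfig):
    """Render, segment and quantify the first image wells of plate 1."""
    records = []
    plate = layout[0]
    candidates = [w for w in plate.wells if w.dsrna_id is not None]
    candidates += [w for w in plate.wells
                   if w.dsrna_id is None and w.role != "autofluorescence_control"]
    image_wells = candidates[: cfg.n_image_wells]
    af_wells = [w for w in plate.wells if w.role == "autofluorescence_control"]
    # plate-level autofluorescence estimate from the control wells
    af_means = []
    for w in af_wells[:2]:
        for img, _ in sim.simulate_well(w, None, cfg.simulation, n_fields=1,
                                        seed=cfg.seed, plate=plate.plate_id):
            af_means.append(float(img.protein.mean()))
    control_mean = float(np.mean(af_means)) if af_means else (
        cfg.simulation.background + cfg.simulation.autofluorescence)

    well_records = []
    for w in image_wells:
        eff = effects[w.dsrna_id] if w.dsrna_id else sim.GroundTruthEffect(
            "none", cfg.noise.baseline_ratio)
        cell_records = []
        for f, (img, _gt) in enumerate(sim.simulate_well(
                w, eff, cfg.simulation, n_fields=cfg.n_fields,
                seed=cfg.seed, plate=plate.plate_id)):
            nuclei, cells, lds, assignment = segment_field(img, models, cfg)
            corrected = autofluorescence_correct(img.protein, control_mean)
            cell_records += measure_field(corrected, cells, lds, assignment,
                                          plate=plate.plate_id, well=w.well, field=f)
        if cell_records:
            well_records.append(aggregate_well(cell_records, gene=w.gene,
                                               dsrna_id=w.dsrna_id,
                                               replicate=plate.replicate))
        records += cell_records
    return records, well_records, control_mean


def run_pipeline(config: RunConfig, stages=ALL_STAGES) -> dict:
    """Execute the requested stages in order; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(stages)}
    stages = [s for s in ALL_STAGES if s in set(stages)]
    if not stages:
        raise ValueError("no known stages requested")

    layout = effects = None
    if "simulate" in stages:
        genes = [f"gene{i:05d}" for i in range(config.n_genes)]
        layout = sim.generate_screen_layout(
            config.n_plates, config.wells_per_plate, config.n_replicates,
            genes, seed=config.seed)
        effects = sim.make_effects(
            layout, baseline_ratio=config.noise.baseline_ratio,
            decrease_fraction=config.decrease_fraction,
            cell_death_fraction=config.cell_death_fraction, seed=config.seed)
        wells = sim.simulate_screen_wells(layout, effects, config.noise, seed=config.seed)
        ldio.write_plate_layout(layout, out / "layout.csv")
        wells.to_csv(out / "wells.csv", index=False)
        pd.DataFrame([dataclasses.asdict(e) for e in effects.values()]).to_csv(
            out / "effects.csv", index=False)
        report["n_well_records"] = int(len(wells))
        report["n_plates"] = len(layout)

    models = None
    if "train" in stages:
        models = _train_models(config, out)
        report["classifier_holdout_accuracy"] = {
            k: m.holdout_accuracy for k, m in models.items()}

    if "segment" in stages or "quantify" in stages:
        if layout is None:
            layout = ldio.read_plate_layout(out / "layout.csv")
            eff_frame = pd.read_csv(out / "effects.csv")
            effects = {r.dsrna_id: sim.GroundTruthEffect(
                r.dsrna_id, r.true_ratio, r.true_cell_count_multiplier,
                r.true_ld_area_multiplier) for r in eff_frame.itertuples(index=False)}
        if models is None:
            models = {c: ldio.load_classifier(out / f"classifier_{c}.joblib")
                      for c in ("nucleus", "cell", "LD")}
        cell_records, image_well_records, control_mean = quantify_image_wells(
            layout, effects, models, config)
        pd.DataFrame([dataclasses.asdict(r) for r in cell_records]).to_csv(
            out / "cells.csv", index=False)
        ldio.write_well_records(image_well_records, out / "wells_imaged.csv")
        report["autofluorescence_control_mean"] = control_mean
        report["n_cells_measured"] = len(cell_records)

    if "score" in stages:
        wells = pd.read_csv(out / "wells.csv")
        model = TargetingScreenModel(wells)
        constants = PUBLISHED_SCREEN_CONSTANTS if config.constants_mode == "published" else None
        results = model.fit(constants=constants)
        frame = results.call_hits(z_cutoff=config.z_cutoff)
        frame.to_csv(out / "results.csv", index=False)
        results.gene_level().to_csv(out / "results_gene_level.csv", index=False)
        tc = results.constants["targeting"]
        report["constants"] = {"median": tc.median, "mad": tc.mad, "scale": tc.scale}
        report["n_decrease_hits"] = int((frame["hit_call"] == "decrease").sum())
        report["n_increase_hits"] = int((frame["hit_call"] == "increase").sum())
        report["n_flag_cell_death"] = int(frame["flag_cell_death"].sum())
        report["n_flag_small_ld"] = int(frame["flag_small_ld"].sum())
        try:
            report["replicate_correlation"] = results.replicate_correlation()
        except ValueError:
            report["replicate_correlation"] = None
        (out / "summary.txt").write_text(results.summary() + "\n")

    if "spatial" in stages:
        spec = [(60, 0.0), (60, 0.0), (60, 8.0), (60, 12.0)]
        vol, truth = sim.simulate_volume(config.simulation, spec,
                                         seed=sim.derive_seed("vol", config.seed))
        eres = segment_objects_3d(vol.channels[0], min_size_vox=30)
        lds = segment_objects_3d(vol.channels[1], min_size_vox=30)
        frac, dists = eres_ld_association(eres, lds, vol.voxel_size_um)
        true_objs_e = objects_from_labels(truth.eres)
        true_objs_l = objects_from_labels(truth.lds)
        true_frac, _ = eres_ld_association(true_objs_e, true_objs_l, vol.voxel_size_um)
        pd.DataFrame({"eres_label": [e.label for e in eres],
                      "nearest_ld_distance_um": dists}).to_csv(
            out / "spatial_distances.csv", index=False)
        report["eres_ld_association"] = frac
        report["eres_ld_association_truth"] = true_frac

    _write_report(out, report)
    return report
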