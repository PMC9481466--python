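"""Shared fixtures: a desk-scale simulation config and trained classifiers.

The simulation config shrinks the field to 192x192 px with five cells so
the whole suite runs on one CPU in minutes; all noise parameters are the
package defaults.
"""

import numpy as np
import pytest

import ldscreen as ld
from ldscreen import segmentation as seg


SMALL_CFG = ld.SimulationConfig(
    shape=(192, 192),
    cell_radius_px=26.0,
    nucleus_radius_px=8.0,
    cells_per_field=5,
    lds_per_cell=6,
    ld_radius_range_px=(3.0, 5.0),
)

LIB_WELL = ld.WellSpec("B02", "gene1", "ds_gene1", "library")


@pytest.fixture(scope="session")
def sim_cfg() -> ld.SimulationConfig:
    return SMALL_CFG


@pytest.fixture(scope="session")
def lib_well() -> ld.WellSpec:
    return LIB_WELL


def _training_fields(cfg, n=7, seed=515001):
    eff = ld.GroundTruthEffect("ds_train", 2.15)
    return [ld.simulate_field(LIB_WELL, eff, cfg, seed=seed + i) for i in range(n)]


@pytest.fixture(scope="session")
def trained_models(sim_cfg):
    """Three compartment classifiers trained on seven annotated fields."""
    fields = _training_fields(sim_cfg)
    models = {}
    for compartment, channel, truth in (
        ("nucleus", "nuclei", "nuclei"),
        ("cell", "nuclei", "cells"),
        ("LD", "ld", "lds"),
    ):
        annotated = [
            (getattr(img, channel), (getattr(gt, truth) > 0).astype(np.uint8) + 1)
            for img, gt in fields
        ]
        models[compartment] = seg.train_pixel_classifier(annotated, compartment, seed=7)
    return models


def segment_with_models(img, models, min_nucleus_area=50, min_ld_area=4):
    """Classify all three channels of a field and build label masks."""
    p_nuc = models["nucleus"].predict_proba(img.nuclei)
    p_cell = models["cell"].predict_proba(img.nuclei)
    p_ld = models["LD"].predict_proba(img.ld)
    nuclei = seg.segment_nuclei(p_nuc >= 0.5, min_nucleus_area)
    cells = seg.segment_cells(p_cell >= 0.5, nuclei, cell_probability=p_cell)
    lds = seg.segment_lds(p_ld >= 0.5, min_ld_area)
    return nuclei, cells, lds, seg.assign_lds_to_cells(lds, cells)
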