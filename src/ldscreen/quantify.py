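"""Intensity readouts: per-cell LD targeting ratios and well medians.

The screen readout is, per cell, the mean protein intensity inside the
LD mask divided by the mean outside it (within the cell mask), after
plate-level autofluorescence correction; per well, the median of those
ratios pooled over the well's fields.  The confocal variant segments
LDs by Otsu thresholding within a manually drawn cell outline and
dilates the LD mask by one pixel to include LD surfaces before taking
the same ratio.  The screen variant deliberately uses the raw LD mask
without dilation; pass ``dilate=True`` to harmonize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

__all__ = [
    "CellRecord",
    "WellRecord",
    "autofluorescence_correct",
    "cell_targeting_ratio",
    "measure_field",
    "aggregate_well",
    "huang_threshold",
    "confocal_targeting_ratio",
    "area_near_ld_fraction",
]

SQUARE_3x3 = np.ones((3, 3), bool)
CROSS_3x3 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


@dataclass
class CellRecord:
    """One segmented cell's measurements.

    ``targeting_ratio`` is NaN when the cell has no assigned LD pixels
    or the outside-LD mean is nonpositive; such cells still count
    toward ``cell_count`` at the well level but not toward the median.
    """

    plate: int
    well: str
    field: int
    cell_label: int
    targeting_ratio: float
    cell_area_px: int
    ld_area_px: int
    ld_count: int


@dataclass
class WellRecord:
    """Per-well aggregate; ``x_i`` is the screen's final readout."""

    plate: int
    well: str
    gene: str | None
    dsrna_id: str | None
    replicate: int
    x_i: float
    cell_count: int
    median_rel_ld_area: float
    n_cells_with_ratio: int

    @property
    def x_i_defined(self) -> bool:
        return bool(np.isfinite(self.x_i))


def autofluorescence_correct(protein_channel: np.ndarray, control_mean: float) -> np.ndarray:
    """Subtract the plate's autofluorescence-control mean, clipped at 0."""
    if control_mean < 0:
        raise ValueError("control_mean must be >= 0")
    return np.clip(np.asarray(protein_channel, np.float64) - control_mean, 0, None)


def cell_targeting_ratio(protein_corrected: np.ndarray, cell_mask: np.ndarray,
                         ld_mask: np.ndarray) -> float:
    """mean(protein | LD within cell) / mean(protein | cell outside LD).

    NaN when the cell holds no LD pixels or the denominator is <= 0.
    """
    cell = np.asarray(cell_mask, bool)
    if not cell.any():
        raise ValueError("empty cell mask")
    ld = np.asarray(ld_mask, bool) & cell
    outside = cell & ~ld
    if not ld.any() or not outside.any():
        return float("nan")
    denom = float(protein_corrected[outside].mean())
    if denom <= 0:
        return float("nan")
    return float(protein_corrected[ld].mean()) / denom


def measure_field(
    protein_corrected: np.ndarray,
    cells: np.ndarray,
    lds: np.ndarray,
    assignment: dict[int, int],
    plate: int = 0,
    well: str = "",
    field: int = 0,
) -> list[CellRecord]:
    """Per-cell records for one segmented field.

    LD pixels count toward a cell's inside-mean only if the LD object
    is assigned to that cell; pixels of LDs assigned elsewhere are
    excluded from both sides of the ratio.
    """
    cells = np.asarray(cells)
    lds = np.asarray(lds)
    records = []
    owner = np.zeros(int(lds.max()) + 1, np.int64)
    for ld, cell in assignment.items():
        owner[ld] = cell
    owner_img = owner[lds]
    for c in np.unique(cells):
        if c == 0:
            continue
        cell_mask = cells == c
        inside = cell_mask & (owner_img == c) & (lds > 0)
        outside = cell_mask & (lds == 0)
        ld_labels = np.unique(lds[inside])
        ratio = float("nan")
        if inside.any() and outside.any():
            denom = float(protein_corrected[outside].mean())
            if denom > 0:
                ratio = float(protein_corrected[inside].mean()) / denom
        records.append(CellRecord(
            plate=plate, well=well, field=field, cell_label=int(c),
            targeting_ratio=ratio,
            cell_area_px=int(cell_mask.sum()),
            ld_area_px=int(inside.sum()),
            ld_count=int((ld_labels > 0).sum()),
        ))
    return records


def aggregate_well(
    cell_records: list[CellRecord],
    gene: str | None = None,
    dsrna_id: str | None = None,
    replicate: int = 1,
) -> WellRecord:
    """Pool a well's fields and take the median defined ratio.

    The median is the standard one (mean of the two central order
    statistics for even counts); cells with undefined ratios count
    toward ``cell_count`` only.
    """
    if not cell_records:
        raise ValueError("no cell records")
    keys = {(r.plate, r.well) for r in cell_records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple wells: {sorted(keys)}")
    plate, well = next(iter(keys))
    ratios = np.array([r.targeting_ratio for r in cell_records], float)
    defined = ratios[np.isfinite(ratios)]
    rel_areas = np.array([
        r.ld_area_px / r.cell_area_px for r in cell_records if r.cell_area_px > 0
    ])
    return WellRecord(
        plate=plate, well=well, gene=gene, dsrna_id=dsrna_id, replicate=replicate,
        x_i=float(np.median(defined)) if defined.size else float("nan"),
        cell_count=len(cell_records),
        median_rel_ld_area=float(np.median(rel_areas)) if rel_areas.size else float("nan"),
        n_cells_with_ratio=int(defined.size),
    )


# --------------------------------------------------------------------------
# thresholding helpers and confocal metrics
# --------------------------------------------------------------------------

def _roi_hist(values: np.ndarray, nbins: int = 256):
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("cannot threshold a constant region")
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return hist.astype(np.float64), centers


def huang_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Huang's fuzzy-entropy threshold on a 256-bin histogram.

    For each candidate cutoff the membership of a grey level to its
    side's mean is u = 1 / (1 + |g - mu| / C) with C the grey-level
    range; the threshold minimizing total Shannon fuzziness
    sum h(g) * S(u(g)) is returned (as a grey value, foreground > t).
    """
    values = np.asarray(values, np.float64).ravel()
    hist, centers = _roi_hist(values, nbins)
    C = centers[-1] - centers[0]
    csum = np.cumsum(hist)
    cmean = np.cumsum(hist * centers)
    total, total_mean = csum[-1], cmean[-1]
    best_t, best_s = centers[0], np.inf
    for k in range(nbins - 1):
        w0 = csum[k]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cmean[k] / w0
        mu1 = (total_mean - cmean[k]) / w1
        mu = np.where(np.arange(nbins) <= k, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(centers - mu) / C)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        s = -(u * np.log(u) + (1 - u) * np.log(1 - u))
        score = float(np.sum(hist * s))
        if score < best_s:
            best_s, best_t = score, float(centers[k])
    return best_t


def _otsu(values: np.ndarray, nbins: int = 256) -> float:
    values = np.asarray(values, np.float64).ravel()
    if values.min() == values.max():
        raise ValueError("cannot threshold a constant region")
    hist, centers = _roi_hist(values, nbins)
    return float(threshold_otsu(hist=(hist, centers)))


def confocal_targeting_ratio(
    protein: np.ndarray,
    cell_outline: np.ndarray,
    ld_stain: np.ndarray,
    exclude_nuclear: np.ndarray | None = None,
    dilate: bool = True,
    footprint: np.ndarray = SQUARE_3x3,
) -> float:
    """Targeting ratio within a manually drawn cell outline (mask 1).

    LDs are Otsu-segmented on the LD-stain values inside mask 1 and
    dilated by one pixel to include LD surfaces (mask 2); the result is
    mean(protein | mask 2) / mean(protein | mask 1 - mask 2).  An
    optional nuclear mask is removed from mask 1 first (used for
    nucleus-excluded proteins such as CCT1).  NaN if mask 2 is empty.
    """
    mask1 = np.asarray(cell_outline, bool)
    if exclude_nuclear is not None:
        mask1 = mask1 & ~np.asarray(exclude_nuclear, bool)
    if not mask1.any():
        raise ValueError("empty cell outline")
    thr = _otsu(np.asarray(ld_stain, np.float64)[mask1])
    ld_mask = (ld_stain > thr) & mask1
    if dilate:
        ld_mask = ndi.binary_dilation(ld_mask, structure=footprint)
    mask2 = ld_mask & mask1
    rest = mask1 & ~mask2
    if not mask2.any() or not rest.any():
        return float("nan")
    return float(np.mean(protein[mask2])) / float(np.mean(protein[rest]))


def area_near_ld_fraction(
    marker: np.ndarray,
    ld: np.ndarray,
    roi: np.ndarray,
    footprint: np.ndarray = SQUARE_3x3,
) -> float:
    """Fraction of the marker mask lying within one pixel of LDs.

    Marker thresholded by Otsu and LDs by Huang (both on in-ROI
    values); the LD mask is dilated by one pixel and the returned value
    is |marker and dilated LD| / |marker|.  NaN if the marker mask is
    empty.
    """
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if marker.shape != ld.shape:
        raise ValueError("marker and LD images must share a shape")
    marker_mask = (marker > _otsu(np.asarray(marker, np.float64)[roi])) & roi
    ld_mask = (ld > huang_threshold(np.asarray(ld, np.float64)[roi])) & roi
    dilated = ndi.binary_dilation(ld_mask, structure=footprint)
    if not marker_mask.any():
        return float("nan")
    return float((marker_mask & dilated).sum()) / float(marker_mask.sum())
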