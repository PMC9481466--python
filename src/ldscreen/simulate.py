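"""Synthetic screening data with known ground truth.

Everything downstream of the microscope is testable against this module:
it fabricates 384-well plate layouts, per-well knockdown effects, 2D
three-channel fields (protein / nuclei / LD stain) with pixel-accurate
label masks, 3D volumes with ER-exit-site and lipid-droplet objects at
requested boundary distances, and a well-level statistical screen
generator for plate-scale experiments where rendering every field would
be pointless.

Cells are drawn as perturbed disks with an interior nuclear disk; lipid
droplets (LDs) as small disks fully contained in one cell, with
rim-weighted protein signal.  The protein channel is constructed so that
the mean intensity inside the LD mask divided by the mean outside it
(within the same cell) equals the requested targeting ratio *exactly*
after PSF blur: blur is linear, so the per-cell LD amplitudes are the
solution of a small linear system.  Poisson-Gaussian noise and additive
autofluorescence are applied afterwards.
"""

from __future__ import annotations

import hashlib
import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw

__all__ = [
    "WellSpec",
    "PlateLayout",
    "GroundTruthEffect",
    "SimulationConfig",
    "FieldImage",
    "FieldGroundTruth",
    "VolumeImage",
    "VolumeGroundTruth",
    "ScreenNoiseModel",
    "ROLES",
    "derive_seed",
    "generate_screen_layout",
    "simulate_field",
    "simulate_well",
    "simulate_volume",
    "make_effects",
    "simulate_screen_wells",
]

ROLES = (
    "library",
    "control_lacz",
    "control_pos_decrease",
    "control_pos_increase",
    "autofluorescence_control",
)

#: default positive-control genes: two that abolish targeting on
#: depletion (coatomer/Arf) and one that enhances it (seipin).
POSITIVE_DECREASE_GENES = ("betaCOP", "Arf79F")
POSITIVE_INCREASE_GENES = ("seipin",)


# --------------------------------------------------------------------------
# layout types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WellSpec:
    """One well of a plate: coordinate, targeted gene and its role."""

    well: str
    gene: str | None
    dsrna_id: str | None
    role: str = "library"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")


@dataclass(frozen=True)
class PlateLayout:
    plate_id: int
    replicate: int
    wells: tuple[WellSpec, ...]

    def __post_init__(self):
        coords = [w.well for w in self.wells]
        if len(set(coords)) != len(coords):
            raise ValueError(f"duplicate well coordinates on plate {self.plate_id}")


@dataclass(frozen=True)
class GroundTruthEffect:
    """True per-well effect of a knockdown on the simulated readouts."""

    dsrna_id: str
    true_ratio: float
    true_cell_count_multiplier: float = 1.0
    true_ld_area_multiplier: float = 1.0

    def __post_init__(self):
        for name in ("true_ratio", "true_cell_count_multiplier", "true_ld_area_multiplier"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A01' style coordinate."""
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def plate_well_grid(wells_per_plate: int, n_cols: int = 24) -> list[str]:
    n_rows = -(-wells_per_plate // n_cols)
    names = [well_name(r, c) for r in range(n_rows) for c in range(n_cols)]
    return names[:wells_per_plate]


def derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary hashable parts (blake2b, < 2**31)."""
    h = hashlib.blake2b("\x1f".join(map(repr, parts)).encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") & 0x7FFFFFFF


def generate_screen_layout(
    n_plates: int,
    wells_per_plate: int,
    n_replicates: int,
    gene_table: Sequence[tuple[str, str] | str],
    seed: int,
    n_lacz: int = 4,
    n_autofluorescence: int = 2,
    pos_decrease_genes: Sequence[str] = POSITIVE_DECREASE_GENES,
    pos_increase_genes: Sequence[str] = POSITIVE_INCREASE_GENES,
) -> list[PlateLayout]:
    """Randomized arrayed-library layout, duplicated across replicates.

    Each plate carries ``n_lacz`` negative-control (LacZ) wells, one well
    per positive-control gene, and ``n_autofluorescence`` wells left
    untransfected for autofluorescence estimation; the remaining wells
    hold library dsRNAs.  Replicates are identical in gene placement.
    """
    if n_plates < 1 or wells_per_plate < 1 or n_replicates < 1:
        raise ValueError("n_plates, wells_per_plate and n_replicates must be >= 1")
    genes = [(g, f"ds_{g}") if isinstance(g, str) else tuple(g) for g in gene_table]
    if not genes:
        raise ValueError("gene_table must be nonempty")

    n_controls = n_lacz + n_autofluorescence + len(pos_decrease_genes) + len(pos_increase_genes)
    if n_controls >= wells_per_plate:
        raise ValueError("controls do not fit on the plate")
    lib_per_plate = wells_per_plate - n_controls
    capacity = n_plates * lib_per_plate
    if len(genes) > capacity:
        raise ValueError(
            f"{len(genes) - capacity} more library genes than available library wells "
            f"({len(genes)} genes, {capacity} wells)"
        )

    grid = plate_well_grid(wells_per_plate)
    plates: list[PlateLayout] = []
    gene_iter = iter(genes)
    plate_specs: list[tuple[WellSpec, ...]] = []
    for p in range(n_plates):
        rng = np.random.default_rng(derive_seed("layout", seed, p))
        order = [grid[i] for i in rng.permutation(len(grid))]
        specs: list[WellSpec] = []
        it = iter(order)
        for _ in range(n_lacz):
            specs.append(WellSpec(next(it), "LacZ", "ds_LacZ", "control_lacz"))
        for g in pos_decrease_genes:
            specs.append(WellSpec(next(it), g, f"ds_{g}", "control_pos_decrease"))
        for g in pos_increase_genes:
            specs.append(WellSpec(next(it), g, f"ds_{g}", "control_pos_increase"))
        for _ in range(n_autofluorescence):
            specs.append(WellSpec(next(it), None, None, "autofluorescence_control"))
        for coord in it:
            try:
                gene, ds = next(gene_iter)
                specs.append(WellSpec(coord, gene, ds, "library"))
            except StopIteration:
                specs.append(WellSpec(coord, None, None, "library"))
        specs.sort(key=lambda w: w.well)
        plate_specs.append(tuple(specs))

    for rep in range(1, n_replicates + 1):
        for p in range(n_plates):
            plates.append(PlateLayout(plate_id=p + 1, replicate=rep, wells=plate_specs[p]))
    return plates


def layout_to_frame(plates: Iterable[PlateLayout]) -> pd.DataFrame:
    rows = [
        {"plate": p.plate_id, "replicate": p.replicate, "well": w.well,
         "gene": w.gene, "dsrna_id": w.dsrna_id, "role": w.role}
        for p in plates for w in p.wells
    ]
    return pd.DataFrame(rows, columns=["plate", "replicate", "well", "gene", "dsrna_id", "role"])


# --------------------------------------------------------------------------
# field simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the virtual microscope and virtual cells.

    Intensities are camera counts in a 16-bit range.  ``poisson_scale``
    converts counts to virtual photons before Poisson sampling (shot
    noise SD = sqrt(counts / poisson_scale)); ``read_noise_sd`` is
    additive Gaussian camera noise in counts.  Setting ``psf_sigma_px``,
    ``poisson_scale`` and ``read_noise_sd`` to 0 gives a noise-free,
    blur-free field.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.065
    z_step_um: float = 0.3
    cells_per_field: int = 10
    cell_radius_px: float = 45.0
    cell_irregularity: float = 0.25
    nucleus_radius_px: float = 14.0
    lds_per_cell: int = 8
    ld_radius_range_px: tuple[float, float] = (3.0, 5.0)
    ld_rim_boost: float = 0.6
    protein_cyto_level: float = 400.0
    cell_brightness_cv: float = 0.15
    nucleus_level: float = 3000.0
    cell_body_level: float = 400.0
    ld_stain_level: float = 3000.0
    background: float = 100.0
    autofluorescence: float = 150.0
    psf_sigma_px: float = 1.0
    poisson_scale: float = 0.05
    read_noise_sd: float = 20.0

    def __post_init__(self):
        for name in ("psf_sigma_px", "poisson_scale", "read_noise_sd", "background",
                     "autofluorescence", "pixel_size_um", "z_step_um"):
            if float(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be >= 0")

    def noiseless(self) -> "SimulationConfig":
        return replace(self, psf_sigma_px=0.0, poisson_scale=0.0, read_noise_sd=0.0)


@dataclass
class FieldImage:
    """One 2D multi-channel field; channel order (protein, nuclei, LD)."""

    channels: np.ndarray  # float32 (3, H, W)
    pixel_size_um: float

    @property
    def protein(self) -> np.ndarray:
        return self.channels[0]

    @property
    def nuclei(self) -> np.ndarray:
        return self.channels[1]

    @property
    def ld(self) -> np.ndarray:
        return self.channels[2]


@dataclass
class FieldGroundTruth:
    nuclei: np.ndarray        # uint16 labels
    cells: np.ndarray
    lds: np.ndarray
    ld_owner: dict[int, int]  # LD label -> cell label
    cell_true_ratio: dict[int, float]


def _cell_polygon(rng: np.random.Generator, center, radius, irregularity, n_vertices=72):
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full_like(theta, radius)
    for k in range(2, 6):
        amp = rng.uniform(0, irregularity / k) * radius
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return center[0] + r * np.sin(theta), center[1] + r * np.cos(theta)


def _place_geometry(rng: np.random.Generator, cfg: SimulationConfig):
    h, w = cfg.shape
    cells = np.zeros((h, w), np.uint16)
    nuclei = np.zeros_like(cells)
    lds = np.zeros_like(cells)
    ld_owner: dict[int, int] = {}

    centers: list[tuple[float, float]] = []
    min_sep = 1.7 * cfg.cell_radius_px
    margin = 0.55 * cfg.cell_radius_px
    tries = 0
    while len(centers) < cfg.cells_per_field and tries < 200 * max(cfg.cells_per_field, 1):
        tries += 1
        c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all((c[0] - y) ** 2 + (c[1] - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append(c)

    ld_label = 0
    for label, center in enumerate(centers, start=1):
        rr, cc = draw.polygon(*_cell_polygon(rng, center, cfg.cell_radius_px,
                                             cfg.cell_irregularity), shape=(h, w))
        free = cells[rr, cc] == 0
        cells[rr[free], cc[free]] = label
        nrr, ncc = draw.disk(center, cfg.nucleus_radius_px, shape=(h, w))
        inside = cells[nrr, ncc] == label
        nuclei[nrr[inside], ncc[inside]] = label

        cell_mask = cells == label
        for _ in range(cfg.lds_per_cell):
            for _attempt in range(10):
                r_ld = rng.uniform(*cfg.ld_radius_range_px)
                rad = rng.uniform(cfg.nucleus_radius_px + r_ld + 2,
                                  max(cfg.nucleus_radius_px + r_ld + 3, 0.85 * cfg.cell_radius_px))
                ang = rng.uniform(0, 2 * np.pi)
                pos = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
                drr, dcc = draw.disk(pos, r_ld, shape=(h, w))
                if drr.size == 0:
                    continue
                # droplets keep a 2-px clearance so they stay resolvable puncta
                grr, gcc = draw.disk(pos, r_ld + 2, shape=(h, w))
                if (cell_mask[drr, dcc].all() and (lds[grr, gcc] == 0).all()
                        and (nuclei[drr, dcc] == 0).all()):
                    ld_label += 1
                    lds[drr, dcc] = ld_label
                    ld_owner[ld_label] = label
                    break
    return cells, nuclei, lds, ld_owner


def _blur(img: np.ndarray, sigma) -> np.ndarray:
    if np.all(np.asarray(sigma) <= 0):
        return img
    return ndi.gaussian_filter(img, sigma, mode="reflect")


def _solve_ld_amplitudes(cyto, ld_weight_per_cell, cells, lds, ld_owner, ratios, sigma):
    """Per-cell LD amplitudes making the blurred on/off-LD mean ratio exact.

    mean_in(c) = a_c + sum_d M_in[c,d] D_d, similarly mean_out; imposing
    mean_in = ratio * mean_out for every cell gives a linear system in
    the amplitudes D (blur is linear so this is exact, including signal
    bleeding across neighbouring cells).
    """
    labels = sorted(ratios)
    n = len(labels)
    blurred_cyto = _blur(cyto, sigma)
    in_masks, out_masks = {}, {}
    for c in labels:
        cell = cells == c
        owned = np.isin(lds, [l for l, o in ld_owner.items() if o == c]) & cell
        in_masks[c] = owned
        out_masks[c] = cell & (lds == 0)
    A = np.zeros((n, n))
    b = np.zeros(n)
    blurred_w = {c: _blur(ld_weight_per_cell[c], sigma) for c in labels}
    for i, c in enumerate(labels):
        r = ratios[c]
        b[i] = r * blurred_cyto[out_masks[c]].mean() - blurred_cyto[in_masks[c]].mean()
        for j, d in enumerate(labels):
            A[i, j] = (blurred_w[d][in_masks[c]].mean()
                       - r * blurred_w[d][out_masks[c]].mean())
    D = np.linalg.solve(A, b)
    return dict(zip(labels, D))


def simulate_field(
    layout_well: WellSpec,
    effect: GroundTruthEffect | None,
    cfg: SimulationConfig,
    seed: int,
) -> tuple[FieldImage, FieldGroundTruth]:
    """Render one three-channel field plus its ground truth.

    Wells with role ``autofluorescence_control`` carry cells but no
    labelled protein, so their protein channel is pure background plus
    autofluorescence — exactly what the plate-level correction
    subtracts.
    """
    rng = np.random.default_rng(seed)
    h, w = cfg.shape
    express_protein = layout_well.role != "autofluorescence_control"
    if express_protein:
        if effect is None:
            raise ValueError("effect required for protein-expressing wells")
        true_ratio = float(effect.true_ratio)
        if true_ratio <= 0:
            raise ValueError("true_ratio must be positive")
        n_cells = int(round(cfg.cells_per_field * effect.true_cell_count_multiplier))
        ld_scale = float(effect.true_ld_area_multiplier)
    else:
        true_ratio, n_cells, ld_scale = np.nan, cfg.cells_per_field, 1.0

    geo_cfg = replace(
        cfg,
        cells_per_field=n_cells,
        ld_radius_range_px=(cfg.ld_radius_range_px[0] * np.sqrt(ld_scale),
                            cfg.ld_radius_range_px[1] * np.sqrt(ld_scale)),
    )
    cells, nuclei, lds, ld_owner = _place_geometry(rng, geo_cfg)
    labels = [int(c) for c in np.unique(cells) if c > 0]

    # per-cell cytoplasmic brightness
    bright = {c: cfg.protein_cyto_level * rng.uniform(1 - cfg.cell_brightness_cv,
                                                      1 + cfg.cell_brightness_cv)
              for c in labels}

    protein = np.zeros((h, w), np.float64)
    cell_true_ratio: dict[int, float] = {}
    if express_protein and labels:
        cyto = np.zeros((h, w), np.float64)
        for c in labels:
            cyto[cells == c] = bright[c]
        # rim-weighted LD profile, one weight image per owning cell
        rim = (lds > 0) & (ndi.minimum_filter(lds, size=3) != lds)
        weight = np.where(lds > 0, 1.0, 0.0) + cfg.ld_rim_boost * rim
        w_per_cell = {}
        ratios = {}
        for c in labels:
            owned = [l for l, o in ld_owner.items() if o == c]
            if not owned:
                continue
            w_per_cell[c] = np.where(np.isin(lds, owned), weight, 0.0)
            ratios[c] = true_ratio
        if ratios:
            amps = _solve_ld_amplitudes(cyto, w_per_cell, cells, lds, ld_owner,
                                        ratios, cfg.psf_sigma_px)
            signal = cyto + sum(amps[c] * w_per_cell[c] for c in amps)
        else:
            signal = cyto
        protein = _blur(signal, cfg.psf_sigma_px)
        cell_true_ratio = {c: true_ratio for c in ratios}

    nuclei_ch = _blur(cfg.cell_body_level * (cells > 0)
                      + cfg.nucleus_level * (nuclei > 0), cfg.psf_sigma_px)
    ld_ch = _blur(cfg.ld_stain_level * (lds > 0), cfg.psf_sigma_px)

    stack = np.stack([
        protein + cfg.background + cfg.autofluorescence,
        nuclei_ch + cfg.background,
        ld_ch + cfg.background,
    ])
    if cfg.poisson_scale > 0:
        stack = rng.poisson(np.clip(stack, 0, None) * cfg.poisson_scale) / cfg.poisson_scale
    if cfg.read_noise_sd > 0:
        stack = stack + rng.normal(0, cfg.read_noise_sd, stack.shape)
    stack = np.clip(stack, 0, 65535).astype(np.float32)

    img = FieldImage(channels=stack, pixel_size_um=cfg.pixel_size_um)
    gt = FieldGroundTruth(nuclei=nuclei, cells=cells, lds=lds,
                          ld_owner=ld_owner, cell_true_ratio=cell_true_ratio)
    return img, gt


def simulate_well(
    well: WellSpec,
    effect: GroundTruthEffect | None,
    cfg: SimulationConfig,
    n_fields: int = 8,
    seed: int = 0,
    plate: int = 1,
) -> list[tuple[FieldImage, FieldGroundTruth]]:
    """Simulate ``n_fields`` independent fields of one well (default 8)."""
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    return [
        simulate_field(well, effect, cfg, derive_seed("field", seed, plate, well.well, f))
        for f in range(n_fields)
    ]


# --------------------------------------------------------------------------
# 3D volumes
# --------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """3D stack; ``channels`` is (C, Z, Y, X), channel 0 = ERES, 1 = LD."""

    channels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (0.3, 0.065, 0.065)
    axis_order: str = "czyx"


@dataclass
class VolumeGroundTruth:
    lds: np.ndarray        # uint16 3D labels
    eres: np.ndarray
    eres_distance_vox: dict[int, float]  # ERES label -> planted boundary distance


def _ball_voxels(center, radius, shape):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius**2


def simulate_volume(
    cfg: SimulationConfig,
    eres_spec: Sequence[tuple[int, float]],
    seed: int,
    shape: tuple[int, int, int] = (32, 96, 96),
    ld_radius_vox: float = 4.0,
    intensity: float = 2000.0,
) -> tuple[VolumeImage, VolumeGroundTruth]:
    """3D stack of LD spheres with ERES puncta at requested distances.

    ``eres_spec`` lists (object size in voxels, boundary distance to the
    nearest LD in voxels).  Each ERES is paired with its own LD sphere
    and placed along +x, so the planted voxel-space boundary distance is
    achieved within half a voxel (fractional requests round to the
    voxel grid).  Distance 0 means overlapping voxel sets.
    """
    rng = np.random.default_rng(seed)
    for size, dist in eres_spec:
        if size < 1:
            raise ValueError("ERES size must be >= 1 voxel")
        if dist < 0:
            raise ValueError("distances must be >= 0")

    n_sites = max(1, len(eres_spec))
    lds = np.zeros(shape, np.uint16)
    eres = np.zeros(shape, np.uint16)
    dist_truth: dict[int, float] = {}

    # one LD per site; sites stack along y, overflow into new x columns;
    # each site's ERES is offset along +x from its LD
    max_reach = ld_radius_vox + max([np.ceil(d) + 2 * (3 * s) ** (1 / 3) + 3
                                     for s, d in eres_spec], default=0)
    pitch_y = int(2 * ld_radius_vox + 5)
    pitch_x = int(max_reach + ld_radius_vox + 4)
    y0 = x0 = int(ld_radius_vox) + 3
    per_col = max(1, (shape[1] - 2 * y0) // pitch_y + 1)
    for i in range(n_sites):
        gx, gy = divmod(i, per_col)
        cz = shape[0] // 2 + int(rng.integers(-2, 3))
        cy = y0 + gy * pitch_y
        cx = x0 + gx * pitch_x
        if cy >= shape[1] - ld_radius_vox - 1 or cx >= shape[2] - ld_radius_vox - 1:
            raise ValueError("volume too small for requested ERES placements")
        ball = _ball_voxels((cz, cy, cx), ld_radius_vox, shape)
        lds[ball & (lds == 0)] = i + 1

        if i < len(eres_spec):
            size, dist = eres_spec[i]
            r_e = max(1.0, ((3 * size) / (4 * np.pi)) ** (1 / 3))
            ld_xmax = cx + int(np.floor(ld_radius_vox))
            d_int = int(round(dist))
            if d_int == 0:
                ex = ld_xmax  # overlap: share at least one voxel column
            else:
                ex = ld_xmax + d_int + int(np.floor(r_e))
            if ex + r_e >= shape[2]:
                raise ValueError("volume too small for requested ERES placements")
            ball_e = _ball_voxels((cz, cy, ex), r_e, shape)
            eres[ball_e] = i + 1
            dist_truth[i + 1] = 0.0 if d_int == 0 else float(d_int)

    stack = np.stack([
        intensity * (eres > 0) + cfg.background,
        intensity * (lds > 0) + cfg.background,
    ]).astype(np.float64)
    if cfg.psf_sigma_px > 0:
        stack = np.stack([_blur(c, (0.5, 0.8, 0.8)) for c in stack])
    if cfg.poisson_scale > 0:
        stack = rng.poisson(np.clip(stack, 0, None) * cfg.poisson_scale) / cfg.poisson_scale
    if cfg.read_noise_sd > 0:
        stack = stack + rng.normal(0, cfg.read_noise_sd, stack.shape)
    vol = VolumeImage(channels=np.clip(stack, 0, 65535).astype(np.float32),
                      voxel_size_um=(cfg.z_step_um, cfg.pixel_size_um, cfg.pixel_size_um))
    return vol, VolumeGroundTruth(lds=lds, eres=eres, eres_distance_vox=dist_truth)


# --------------------------------------------------------------------------
# well-level statistical screen generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenNoiseModel:
    """Dispersion of per-well median targeting ratios at screen scale.

    ``gene_sd`` is the biological spread of knockdown effects across
    library genes (shared between replicates); ``well_sd`` the
    well-to-well technical noise.  The defaults reproduce the published
    screen's dispersion: total robust SD per replicate
    sqrt(gene_sd^2 + well_sd^2) = 0.169 and expected replicate Pearson
    correlation gene_sd^2 / (gene_sd^2 + well_sd^2) = 0.765.
    """

    baseline_ratio: float = 2.15
    gene_sd: float = 0.148
    well_sd: float = 0.082
    mean_cells_per_well: int = 800
    baseline_rel_ld_area: float = 0.06
    ld_area_cv: float = 0.10

    @property
    def expected_replicate_r(self) -> float:
        vg, ve = self.gene_sd**2, self.well_sd**2
        return vg / (vg + ve)


def make_effects(
    plates: Sequence[PlateLayout],
    baseline_ratio: float = 2.15,
    decrease_fraction: float = 0.0,
    decrease_multiplier: float = 0.5,
    cell_death_fraction: float = 0.0,
    cell_death_multiplier: float = 0.3,
    seed: int = 0,
) -> dict[str, GroundTruthEffect]:
    """Ground-truth effects per dsRNA; optionally plant decrease hits
    and cell-death wells among the library dsRNAs."""
    rng = np.random.default_rng(derive_seed("effects", seed))
    dsrnas, roles = [], {}
    for p in plates:
        for wl in p.wells:
            if wl.dsrna_id is not None and wl.dsrna_id not in roles:
                dsrnas.append(wl.dsrna_id)
                roles[wl.dsrna_id] = wl.role
    effects: dict[str, GroundTruthEffect] = {}
    library = [d for d in dsrnas if roles[d] == "library"]
    n_dec = int(round(decrease_fraction * len(library)))
    n_death = int(round(cell_death_fraction * len(library)))
    shuffled = list(rng.permutation(library))
    planted_dec = set(shuffled[:n_dec])
    planted_death = set(shuffled[n_dec:n_dec + n_death])
    for d in dsrnas:
        role = roles[d]
        ratio, cells, ld = baseline_ratio, 1.0, 1.0
        if role == "control_pos_decrease":
            ratio = baseline_ratio * 0.6
        elif role == "control_pos_increase":
            ratio = baseline_ratio * 1.5
        elif role == "library":
            if d in planted_dec:
                ratio = baseline_ratio * decrease_multiplier
            elif d in planted_death:
                cells = cell_death_multiplier
        effects[d] = GroundTruthEffect(d, ratio, cells, ld)
    return effects


def simulate_screen_wells(
    plates: Sequence[PlateLayout],
    effects: Mapping[str, GroundTruthEffect],
    noise: ScreenNoiseModel = ScreenNoiseModel(),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-well median targeting ratios for a whole screen, without
    rendering images.

    Each library dsRNA receives a gene-level offset (drawn once, shared
    by both replicates) plus independent well-level noise; control
    wells get well-level noise only.  Returns one row per well with the
    columns the scoring model consumes.
    """
    rows = []
    for p in plates:
        rng = np.random.default_rng(derive_seed("wells", seed, p.plate_id, p.replicate))
        for wl in p.wells:
            if wl.dsrna_id is None:
                x = np.nan
                cells = noise.mean_cells_per_well
                ld = np.nan
            else:
                eff = effects[wl.dsrna_id]
                gene_offset = 0.0
                if wl.role == "library":
                    g_rng = np.random.default_rng(derive_seed("gene", seed, wl.dsrna_id))
                    gene_offset = g_rng.normal(0, noise.gene_sd)
                x = eff.true_ratio + gene_offset + rng.normal(0, noise.well_sd)
                x = max(x, 0.05)
                cells = rng.poisson(noise.mean_cells_per_well * eff.true_cell_count_multiplier)
                ld = (noise.baseline_rel_ld_area * eff.true_ld_area_multiplier
                      * max(rng.normal(1.0, noise.ld_area_cv), 0.05))
            rows.append({
                "plate": p.plate_id, "replicate": p.replicate, "well": wl.well,
                "gene": wl.gene, "dsrna_id": wl.dsrna_id, "role": wl.role,
                "x_i": x, "cell_count": int(cells),
                "rel_ld_area": ld,
                "n_cells_with_ratio": int(cells) if np.isfinite(x) else 0,
            })
    return pd.DataFrame(rows)
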