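"""Robust-Z scoring and hit calling for per-well median targeting ratios.

The screen standardizes each dsRNA's readout X_i with a robust Z-score,

    Z = (X_i - median(X)) / (1.4826 * MAD(X)),
    MAD(X) = median(|X_i - median(X)|),

where the 1.4826 factor makes the MAD a consistent estimator of the
standard deviation under normality.  Knockdowns with Z < -2.5 decrease
targeting and Z > +2.5 increase it (strict inequalities); calls are
demoted when the knockdown also causes significant cell death
(cell-count Z < -2.5), extremely small LDs (relative-LD-area Z below a
cutoff, which makes the ratio unreliable), or the gene belongs to an
excluded housekeeping category (ribosome, proteasome, spliceosome).

The published screen's constants (median 2.147287, MAD 0.113917) are
packaged as :data:`PUBLISHED_SCREEN_CONSTANTS`.

The module is organised as a statsmodels-style model:
:class:`TargetingScreenModel` wraps a table of per-well records and
``fit()`` returns :class:`ScreenResults` with the per-dsRNA Z-scores,
constants used, hit calls, replicate correlation and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import WellRecord

__all__ = [
    "ScreenConstants",
    "PUBLISHED_SCREEN_CONSTANTS",
    "MAD_SCALE",
    "mad",
    "robust_z",
    "TargetingScreenModel",
    "ScreenResults",
    "score_screen",
    "call_hits",
    "replicate_correlation",
]

MAD_SCALE = 1.4826

WELL_COLUMNS = ["plate", "replicate", "well", "gene", "dsrna_id", "role",
                "x_i", "cell_count", "rel_ld_area"]


@dataclass(frozen=True)
class ScreenConstants:
    """Centre and robust spread used to standardize a readout."""

    median: float
    mad: float
    scale: float = MAD_SCALE

    def __post_init__(self):
        if self.mad < 0:
            raise ValueError("MAD must be >= 0")


#: Centre and spread of the published genome-wide screen.
PUBLISHED_SCREEN_CONSTANTS = ScreenConstants(median=2.147287, mad=0.113917)


def mad(values: Sequence[float]) -> float:
    """Median absolute deviation, median(|x - median(x)|)."""
    v = np.asarray(values, np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("mad of an empty sequence")
    return float(np.median(np.abs(v - np.median(v))))


def robust_z(x, constants: ScreenConstants):
    """Robust Z-score of x under the given screen constants."""
    if constants.mad <= 0:
        raise ValueError("degenerate spread: MAD must be > 0 for robust Z-scores")
    return (np.asarray(x, np.float64) - constants.median) / (constants.scale * constants.mad)


def _constants_from(values: np.ndarray) -> ScreenConstants:
    v = values[np.isfinite(values)]
    if v.size == 0:
        raise ValueError("no defined readouts to estimate screen constants from")
    return ScreenConstants(median=float(np.median(v)), mad=mad(v))


class TargetingScreenModel:
    """Scoring model over a table of per-well records.

    Parameters
    ----------
    well_table : DataFrame
        One row per well with columns ``plate, replicate, well, gene,
        dsrna_id, role, x_i, cell_count, rel_ld_area`` (``x_i`` the
        well's median targeting ratio; NaN where undefined).
    """

    def __init__(self, well_table: pd.DataFrame):
        missing = [c for c in WELL_COLUMNS if c not in well_table.columns]
        if missing:
            raise ValueError(f"well table missing columns: {missing}")
        if len(well_table) == 0:
            raise ValueError("empty well table")
        self.wells = well_table.reset_index(drop=True).copy()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "TargetingScreenModel":
        return cls(frame)

    @classmethod
    def from_records(cls, records: Iterable[WellRecord],
                     roles: Mapping[str, str] | None = None) -> "TargetingScreenModel":
        rows = []
        for r in records:
            rows.append({
                "plate": r.plate, "replicate": r.replicate, "well": r.well,
                "gene": r.gene, "dsrna_id": r.dsrna_id,
                "role": (roles or {}).get(r.dsrna_id, "library"),
                "x_i": r.x_i, "cell_count": r.cell_count,
                "rel_ld_area": r.median_rel_ld_area,
            })
        return cls(pd.DataFrame(rows, columns=WELL_COLUMNS))

    @classmethod
    def from_csv(cls, path) -> "TargetingScreenModel":
        return cls(pd.read_csv(path))

    def fit(
        self,
        constants: ScreenConstants | None = None,
        pooled_replicates: bool = True,
        include_controls_in_constants: bool = False,
    ) -> "ScreenResults":
        """Combine replicates per dsRNA and compute robust Z-scores.

        Replicate well medians are averaged per dsRNA before scoring.
        Unless ``constants`` is given, the targeting-ratio centre and
        MAD are estimated from library wells of this run (controls
        excluded by default); cell-count and LD-area Z-scores always
        use their own run-estimated constants.  ``pooled_replicates``
        pools both replicates' wells when estimating constants;
        otherwise replicate 1 alone is used.
        """
        wells = self.wells
        scored = wells[wells["dsrna_id"].notna()]
        if len(scored) == 0 or not np.isfinite(scored["x_i"]).any():
            raise ValueError("all well readouts undefined; nothing to score")

        per_ds = scored.groupby("dsrna_id", sort=True).agg(
            gene=("gene", "first"),
            role=("role", "first"),
            x=("x_i", "mean"),
            cell_count=("cell_count", "mean"),
            rel_ld_area=("rel_ld_area", "mean"),
            n_replicates=("replicate", "nunique"),
        ).reset_index()

        est_wells = scored if pooled_replicates else scored[scored["replicate"] == scored["replicate"].min()]
        if not include_controls_in_constants:
            est_wells = est_wells[est_wells["role"] == "library"]
        if len(est_wells) == 0:
            est_wells = scored

        lib = per_ds[per_ds["role"] == "library"] if not include_controls_in_constants else per_ds
        if len(lib) == 0:
            lib = per_ds
        targeting_constants = constants or _constants_from(est_wells["x_i"].to_numpy(float))
        cc = _constants_from(lib["cell_count"].to_numpy(float))
        la = _constants_from(lib["rel_ld_area"].to_numpy(float))

        per_ds["z_targeting"] = robust_z(per_ds["x"].to_numpy(float), targeting_constants)
        # a spread-free secondary metric cannot flag anything: Z stays NaN
        for col, const in (("cell_count", cc), ("rel_ld_area", la)):
            zcol = {"cell_count": "z_cell_count", "rel_ld_area": "z_ld_area"}[col]
            if const.mad > 0:
                per_ds[zcol] = robust_z(per_ds[col].to_numpy(float), const)
            else:
                per_ds[zcol] = np.nan
        return ScreenResults(self, per_ds, {
            "targeting": targeting_constants, "cell_count": cc, "ld_area": la,
        })


class ScreenResults:
    """Per-dsRNA robust Z-scores, filters and hit calls."""

    def __init__(self, model: TargetingScreenModel, frame: pd.DataFrame,
                 constants: dict[str, ScreenConstants]):
        self.model = model
        self.frame = frame
        self.constants = constants
        self.cutoffs: dict[str, float] = {}

    def call_hits(
        self,
        z_cutoff: float = 2.5,
        cell_death_cutoff: float = -2.5,
        small_ld_cutoff: float = -2.5,
        excluded_categories: set[str] | frozenset[str] = frozenset(),
    ) -> pd.DataFrame:
        """Strict-inequality hit calls with the screen's exclusion filters.

        ``decrease`` if Z < -z_cutoff, ``increase`` if Z > +z_cutoff;
        dsRNAs flagged for cell death, extremely small LDs or an
        excluded gene category keep their Z but are demoted to ``none``.
        Only library wells are eligible for hit calls.
        """
        f = self.frame
        call = np.where(f["z_targeting"] < -z_cutoff, "decrease",
                        np.where(f["z_targeting"] > z_cutoff, "increase", "none"))
        flag_death = f["z_cell_count"].to_numpy() < cell_death_cutoff
        flag_small = f["z_ld_area"].to_numpy() < small_ld_cutoff
        flag_cat = f["gene"].isin(set(excluded_categories)).to_numpy()
        flagged = flag_death | flag_small | flag_cat
        call = np.where(flagged | (f["role"] != "library"), "none", call)
        out = f.copy()
        out["flag_cell_death"] = flag_death
        out["flag_small_ld"] = flag_small
        out["flag_excluded_category"] = flag_cat
        out["hit_call"] = call
        self.frame = out
        self.cutoffs = {"z": z_cutoff, "cell_death": cell_death_cutoff,
                        "small_ld": small_ld_cutoff}
        return out

    def gene_level(self) -> pd.DataFrame:
        """One row per gene: the dsRNA with the largest |Z| represents it."""
        f = self.frame[self.frame["gene"].notna()].copy()
        f["abs_z"] = f["z_targeting"].abs()
        idx = f.groupby("gene")["abs_z"].idxmax()
        return f.loc[idx].drop(columns="abs_z").reset_index(drop=True)

    def replicate_correlation(self) -> float:
        """Pearson correlation of paired replicate well medians."""
        return replicate_correlation(self.model.wells)

    def summary(self) -> str:
        tc = self.constants["targeting"]
        f = self.frame
        lines = [
            "LD targeting screen - robust Z scoring",
            "=" * 46,
            f"dsRNAs scored:            {len(f)}",
            f"wells:                    {len(self.model.wells)}",
            f"targeting median:         {tc.median:.6f}",
            f"targeting MAD:            {tc.mad:.6f} (scale {tc.scale})",
        ]
        if "hit_call" in f.columns:
            n_dec = int((f["hit_call"] == "decrease").sum())
            n_inc = int((f["hit_call"] == "increase").sum())
            lines += [
                f"hit cutoff |Z| >:         {self.cutoffs.get('z')}",
                f"decrease hits:            {n_dec}",
                f"increase hits:            {n_inc}",
                f"flagged cell death:       {int(f['flag_cell_death'].sum())}",
                f"flagged small LDs:        {int(f['flag_small_ld'].sum())}",
                f"flagged excluded class:   {int(f['flag_excluded_category'].sum())}",
            ]
        try:
            lines.append(f"replicate correlation R:  {self.replicate_correlation():.4f}")
        except ValueError:
            pass
        return "\n".join(lines)


def replicate_correlation(wells: pd.DataFrame, library_only: bool = False) -> float:
    """Pearson r of replicate-1 vs replicate-2 per-well medians.

    ``library_only`` drops control wells, whose fixed offsets otherwise
    inflate the correlation.
    """
    scored = wells[wells["dsrna_id"].notna() & np.isfinite(wells["x_i"])]
    if library_only:
        scored = scored[scored["role"] == "library"]
    pivot = scored.pivot_table(index=["plate", "well"], columns="replicate",
                               values="x_i", aggfunc="first")
    if pivot.shape[1] < 2:
        raise ValueError("need two replicates for a correlation")
    pairs = pivot.iloc[:, :2].dropna()
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete replicate pairs")
    r, _ = stats.pearsonr(pairs.iloc[:, 0], pairs.iloc[:, 1])
    return float(r)


def score_screen(wells: pd.DataFrame, constants: ScreenConstants | None = None,
                 **kwargs) -> ScreenResults:
    """Functional wrapper: build the model and fit in one call."""
    return TargetingScreenModel(wells).fit(constants=constants, **kwargs)


def call_hits(results: ScreenResults, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :meth:`ScreenResults.call_hits`."""
    return results.call_hits(**kwargs)
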