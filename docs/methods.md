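# Methods

## The readout and the scoring model

The screen's per-cell readout is the LD targeting ratio: the mean
protein-channel intensity inside the LD mask of a cell divided by the
mean outside the LD mask but within the cell mask, after
autofluorescence correction.  Cells with no assigned LD pixels (or a
nonpositive outside mean) have no ratio; they count toward the well's
cell total but not its median.  The well readout X_i is the standard
median (mean of the two central order statistics for even counts) of
the defined ratios pooled across the well's fields.

Per dsRNA, replicate well medians are averaged before scoring.  The
combination rule is a package choice; replicate concordance is reported
separately as the Pearson correlation of paired replicate medians, so
no information is hidden by the averaging.

Robust Z-scores standardize a readout by the median and the scaled
median absolute deviation, Z = (x − median) / (1.4826·MAD).  Under
normality 1.4826·MAD is a consistent estimate of the standard
deviation (checked at n = 10⁵ to within 2% in the tests), so |Z| > 2.5
on a null screen fires at the Gaussian rate 2·(1 − Φ(2.5)) ≈ 1.24%.
Cutoffs are strict inequalities.  Three exclusion filters demote a
call to `none` while retaining the Z-score: cell death (cell-count
robust Z < −2.5), extremely small LDs (relative-LD-area robust Z
< −2.5; the numeric threshold is a package choice and configurable —
what "extremely small" means quantitatively is genuinely open), and
membership in an excluded housekeeping gene set supplied by the caller.
When a gene has several dsRNAs, the gene-level call is the dsRNA with
the largest |Z|.

Scoring constants (median, MAD) are by default estimated from the
library wells of the run being scored, pooled over replicates, controls
excluded; per-replicate estimation is available.  The published
genome-wide screen's constants (median 2.147287, MAD 0.113917) are
packaged as `PAPER_SCREEN_CONSTANTS` for scoring on that scale.  A
degenerate targeting spread (MAD = 0) is an error; a degenerate
*secondary* metric (e.g. constant cell counts) merely disables that
filter (Z = NaN), since a spread-free metric cannot flag anything.

## The synthetic-data generator

Two layers generate test data with known truth.

**Field level.**  Cells are perturbed disks (low-order Fourier radial
perturbation) with an interior nuclear disk; LDs are small disks placed
fully inside one cell, away from the nucleus, with a 2-px clearance
between droplets so they remain resolvable puncta at the simulated
resolution.  The protein channel carries a per-cell cytoplasmic level
(±15% cell-to-cell brightness jitter) plus rim-weighted LD signal.
Because Gaussian PSF blur is linear, the LD amplitudes are obtained by
solving a small per-field linear system such that the ground-truth-mask
targeting ratio equals the requested true ratio *exactly after blur*
(including signal bleed between neighbouring cells); Poisson shot noise
(on scaled counts), Gaussian read noise, and an additive
autofluorescence constant are applied afterwards.  With blur and noise
disabled the mask-measured ratio equals the requested ratio to ~1e-7
relative error; at default noise it is recovered within a few percent.
Wells designated as autofluorescence controls carry cells but no
labelled protein, so their protein-channel mean is exactly the quantity
the plate-level correction subtracts.

Defaults (units): field 512×512 px at 0.065 µm/px (configurable; the
test suite and the acceptance script use 192×192 px fields with 5 cells
of radius 26 px, nuclei 8 px, LDs 3–5 px — a desk-scale choice stated
here once); cytoplasmic protein 400 counts, nucleus stain 3000, LD
stain 3000, camera background 100, autofluorescence 150, PSF σ = 1 px,
Poisson scale 0.05 (shot-noise SD = √(counts/0.05)), read noise SD 20
counts.  Seeds fully determine output; per-field sub-seeds derive from
a BLAKE2 hash of (purpose, master seed, plate, well, field), so no
global RNG state is shared.

**Well level.**  Rendering every field of a multi-plate screen is
pointless for testing the scoring stage, so `simulate_screen_wells`
draws per-well medians directly: X_i = true ratio + gene-level offset
(SD `gene_sd`, drawn once per dsRNA and shared by replicates) +
well-level noise (SD `well_sd`); cell counts are Poisson around 800 ×
the planted multiplier.  The defaults gene_sd = 0.148, well_sd = 0.082
were chosen to reproduce the published screen's dispersion analytically:
total per-replicate robust SD √(0.148² + 0.082²) = 0.169 (the screen's
1.4826 × 0.113917) and expected replicate correlation
0.148²/(0.148² + 0.082²) = 0.765.  Control wells get well noise only;
positive-control effects are fixed at 0.6× (coatomer/Arf-like) and
1.5× (seipin-like) of baseline 2.15.

What the generator does *not* emulate: optical aberrations, bleaching,
stage drift, cell crowding/overlap beyond first-come pixel ownership,
out-of-focus light, or heavy-tailed per-cell effect distributions.
Passing tests therefore demonstrate correctness of the measurement and
scoring machinery under a controlled image-formation model, not
segmentation robustness on real micrographs.

## Segmentation

Per-pixel features are a deterministic filter bank: raw intensity,
Gaussian blurs at σ ∈ {1, 2, 4, 8}, gradient magnitude and Laplacian at
σ ∈ {1, 2}, and a difference of Gaussians (σ 1 − 8).  One random forest
per compartment (100 trees, fixed seed, class-balanced subsampling of
at most 5000 annotated pixels per class per image, min_samples_leaf = 2)
is trained from annotated images — by convention 0 = unlabelled,
1 = background, 2 = foreground, so sparse scribbles work.  A stratified
20% pixel hold-out provides the reported accuracy.  Nuclei and cells
are classified from the nuclear-stain channel (which also carries a dim
cell-body level), LDs from the LD-stain channel; the probability
threshold defaults to 0.5.

Nuclei and LDs are 8-connected components with minimum areas of 50 and
4 px respectively (at 0.065 µm/px; configurable).  Cells are a
watershed partition of the cell foreground seeded by nucleus labels,
flooding an inverted smoothed cell-probability surface (inverted
distance transform when no probabilities exist), 4-connected flooding;
cell labels equal their seed nucleus labels, and foreground unreachable
from any seed stays background.  LD objects are assigned to the cell
with the largest intersection area; ties go to the smaller cell label;
LDs touching no cell are excluded downstream.

## Confocal metrics and thresholds

The confocal targeting-ratio variant Otsu-thresholds the LD-stain
values inside a manually drawn cell outline (mask 1), dilates the LD
mask by one pixel — one binary dilation with a 3×3 square element,
configurable to a cross — to include LD surfaces (mask 2), and takes
mean(protein | mask 2) / mean(protein | mask 1 − mask 2).  An optional
nuclear mask is removed from mask 1 first (for nucleus-partitioned
proteins such as CCT1).  The screen-scale ratio deliberately uses the
*undilated* LD mask: the two procedures are specified differently at
their sources, and a flag harmonizes them if desired.  Area-near-LD
fractions threshold the marker channel by Otsu and the LD channel by
Huang, dilate the LD mask by one pixel and report the overlapping
marker-area fraction.

Otsu and Huang thresholds are computed on 256-bin histograms of in-ROI
values (bin edges from the in-ROI min/max); foreground is strictly
above the threshold.  Huang's method minimizes total fuzzy entropy with
membership u(g) = 1/(1 + |g − μ_side|/C), C the grey-level range; it is
implemented here and cross-checked against ITK's filter in the tests.
Constant regions are an error for automatic thresholds.

## 3D spatial association

Volumes are preprocessed with a size-3 median filter and large-scale
Gaussian background subtraction (the named preprocessing steps have no
published radii; these are package choices), thresholded (Otsu, Huang
or manual), and labelled with 26-connectivity; only objects strictly
larger than 30 voxels are kept.  An object's boundary voxels are those
with at least one background neighbour under 26-connectivity (volume-
edge voxels included).  The closest distance between two objects is the
minimum Euclidean distance between boundary-voxel centres, scaled by
the anisotropic voxel size (0.3 µm z, 0.065 µm xy by default); a
voxel-space mode exists for parity testing, since whether the original
measurements were anisotropy-scaled is unknown.  Overlapping voxel sets
have distance zero by definition, and an ERES is "associated" with LDs
exactly when its nearest-LD distance is zero; boundary adjacency
without overlap is one voxel, not zero, unless the
`adjacency_counts_as_zero` flag is set.  The association fraction is
associated ERES over all ERES; with no ERES it is undefined (NaN), not
zero.  Distance queries use a k-d tree and agree with exhaustive
all-pairs search to machine precision.

## Numerical and design notes

- Coordinates are 0-based (z, )y, x with pixel centres on integer
  coordinates; images are float32 in a 16-bit count range and are
  written as 16-bit TIFF.
- Ratio-undefined cells are counted in `cell_count` but excluded from
  X_i: the cell-death filter needs total cells, the ratio needs LD
  pixels.
- Cells touching the field border are kept (no published border
  policy); the simulator rarely places them at the tested densities.
- The 3D simulator places each ERES along +x of its own LD, so planted
  boundary distances are exact on the voxel grid (fractional requests
  round to the nearest voxel, within half a voxel); distance-0 requests
  share at least one voxel.
- `derive_seed` hashes to 31-bit integers, so any externally supplied
  master seed maps into a safe seed range.

## Known limitations

Segmentation quality figures (IoU ≥ 0.95 observed on synthetic fields)
say nothing about real micrographs, where texture, debris and contact
between cells dominate errors.  The watershed gives one cell per
nucleus, so multinucleate or unstained cells are mis-segmented.  The
small-LD exclusion threshold is an operational choice, not a published
constant.  Published headline numbers that depend on the original
~1.2 million screen images (genome-wide hit counts, specific gene
Z-scores) are out of reach of desk-scale simulation and are not claimed
by any test; the packaged constants only reproduce fixed points of the
scoring formula.
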