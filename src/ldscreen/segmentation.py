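"""Pixel-classifier segmentation of nuclei, cells and lipid droplets.

The screen's segmentation stage: three random-forest pixel classifiers
(one per compartment) trained on annotated images, nucleus-seeded
watershed to partition the cell foreground into per-cell regions, and
area-of-intersection assignment of LD objects to cells.

Annotation convention: label images use 0 = unlabelled, 1 = background,
2 = foreground; unlabelled pixels are ignored during training, so
sparse scribbles work as well as dense masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, segmentation
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "PixelClassifierModel",
    "extract_features",
    "FEATURE_SIGMAS",
    "train_pixel_classifier",
    "classify_pixels",
    "segment_nuclei",
    "segment_cells",
    "segment_lds",
    "assign_lds_to_cells",
]

FEATURE_SIGMAS = (1.0, 2.0, 4.0, 8.0)

COMPARTMENTS = ("nucleus", "cell", "LD")


def extract_features(image: np.ndarray, sigmas=FEATURE_SIGMAS) -> np.ndarray:
    """Per-pixel filter-bank features, shape (H, W, F).

    Raw intensity, Gaussian blurs at each scale, gradient magnitude and
    Laplacian at the two finest scales, and difference-of-Gaussians
    between the extreme scales.  Purely deterministic.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2D image")
    feats = [img]
    blurred = {s: ndi.gaussian_filter(img, s, mode="reflect") for s in sigmas}
    feats.extend(blurred[s] for s in sigmas)
    for s in sigmas[:2]:
        feats.append(ndi.gaussian_gradient_magnitude(img, s, mode="reflect"))
        feats.append(ndi.gaussian_laplace(img, s, mode="reflect"))
    feats.append(blurred[sigmas[0]] - blurred[sigmas[-1]])
    return np.stack(feats, axis=-1).astype(np.float32)


@dataclass
class PixelClassifierModel:
    """A trained per-pixel random forest for one compartment."""

    compartment: str
    sigmas: tuple
    forest: RandomForestClassifier
    n_train_images: int
    seed: int
    holdout_accuracy: float = float("nan")

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Foreground probability map in [0, 1]."""
        feats = extract_features(image, self.sigmas)
        flat = feats.reshape(-1, feats.shape[-1])
        proba = self.forest.predict_proba(flat)
        fg_col = list(self.forest.classes_).index(2)
        return proba[:, fg_col].reshape(image.shape)


def train_pixel_classifier(
    annotated_images,
    compartment: str,
    seed: int = 0,
    n_estimators: int = 100,
    max_pixels_per_class: int = 5000,
    sigmas=FEATURE_SIGMAS,
    holdout_fraction: float = 0.2,
) -> PixelClassifierModel:
    """Train a random-forest pixel classifier from annotated images.

    ``annotated_images`` is a list of (channel image, label image)
    pairs.  Pixels of each class are subsampled to at most
    ``max_pixels_per_class`` per image (class-balanced); a held-out
    split provides the reported pixel accuracy.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"compartment must be one of {COMPARTMENTS}")
    annotated = list(annotated_images)
    if not annotated:
        raise ValueError("at least one annotated image required")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for img, labels in annotated:
        img = np.asarray(img)
        labels = np.asarray(labels)
        if img.shape != labels.shape:
            raise ValueError("annotation shape does not match image shape")
        feats = extract_features(img, sigmas)
        for cls in (1, 2):
            idx = np.flatnonzero(labels.ravel() == cls)
            if idx.size > max_pixels_per_class:
                idx = rng.choice(idx, max_pixels_per_class, replace=False)
            X_parts.append(feats.reshape(-1, feats.shape[-1])[idx])
            y_parts.append(np.full(idx.size, cls, np.int8))
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if np.unique(y).size < 2:
        raise ValueError("annotations must contain both background and foreground")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1,
        min_samples_leaf=2, class_weight="balanced")
    forest.fit(X_tr, y_tr)
    acc = float(forest.score(X_te, y_te))
    return PixelClassifierModel(compartment=compartment, sigmas=tuple(sigmas),
                                forest=forest, n_train_images=len(annotated),
                                seed=seed, holdout_accuracy=acc)


def classify_pixels(model: PixelClassifierModel, image: np.ndarray,
                    prob_threshold: float = 0.5) -> np.ndarray:
    """Boolean foreground mask from a trained classifier."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    return model.predict_proba(image) >= prob_threshold


def _labelled_components(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    labels = measure.label(np.asarray(mask, bool), connectivity=2)
    if min_area_px > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        sizes[0] = min_area_px  # keep background
        labels[(sizes < min_area_px)[labels]] = 0
    relabelled, _, _ = segmentation.relabel_sequential(labels)
    return relabelled.astype(np.uint16)


def segment_nuclei(nuclei_foreground: np.ndarray, min_area_px: int = 50) -> np.ndarray:
    """8-connected components of the nucleus foreground, small ones removed."""
    return _labelled_components(nuclei_foreground, min_area_px)


def segment_lds(ld_foreground: np.ndarray, min_area_px: int = 4) -> np.ndarray:
    """8-connected components of the LD foreground, small ones removed."""
    return _labelled_components(ld_foreground, min_area_px)


def segment_cells(
    cell_foreground: np.ndarray,
    nuclei: np.ndarray,
    cell_probability: np.ndarray | None = None,
    smoothing_sigma: float = 2.0,
) -> np.ndarray:
    """Nucleus-seeded watershed partition of the cell foreground.

    The elevation surface is the inverted (smoothed) cell-probability
    map when available, else the inverted distance transform of the
    foreground.  Cell labels equal their seed nucleus labels; foreground
    unreachable from any seed stays background.
    """
    fg = np.asarray(cell_foreground, bool) | (nuclei > 0)
    if nuclei.max() == 0:
        warnings.warn("no nuclei seeds; returning empty cell mask", stacklevel=2)
        return np.zeros_like(fg, dtype=np.uint16)
    if cell_probability is not None:
        elevation = -ndi.gaussian_filter(np.asarray(cell_probability, float),
                                         smoothing_sigma)
    else:
        elevation = -ndi.distance_transform_edt(fg)
    labels = segmentation.watershed(elevation, markers=np.asarray(nuclei),
                                    mask=fg, connectivity=1)
    return labels.astype(np.uint16)


def assign_lds_to_cells(lds: np.ndarray, cells: np.ndarray) -> dict[int, int]:
    """Assign each LD object to the cell it overlaps most.

    LDs with no cell overlap are left out of the mapping (excluded
    downstream); ties go to the smaller cell label.
    """
    lds = np.asarray(lds)
    cells = np.asarray(cells)
    if lds.shape != cells.shape:
        raise ValueError("LD and cell masks must have the same shape")
    sel = lds > 0
    if not sel.any():
        return {}
    pair_counts: dict[int, dict[int, int]] = {}
    ld_vals = lds[sel].ravel()
    cell_vals = cells[sel].ravel()
    # joint histogram over (ld, cell) pairs
    max_cell = int(cell_vals.max(initial=0))
    codes = ld_vals.astype(np.int64) * (max_cell + 1) + cell_vals.astype(np.int64)
    uniq, counts = np.unique(codes, return_counts=True)
    for code, n in zip(uniq, counts):
        ld, cell = divmod(int(code), max_cell + 1)
        if cell == 0:
            continue
        pair_counts.setdefault(ld, {})[cell] = int(n)
    assignment = {}
    for ld, by_cell in pair_counts.items():
        best = max(by_cell.items(), key=lambda kv: (kv[1], -kv[0]))
        assignment[ld] = best[0]
    return assignment
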