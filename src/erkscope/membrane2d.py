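"""Cell-surface EGF-488 binding quantification from max projections.

Surface-bound ligand appears as small puncta scattered over the membrane.
Because rounded tissues on compliant substrata do not fit in one z-slice,
z-stacks are first collapsed by maximum-intensity projection; the 2D
image is then background-corrected (rolling ball) and blurred, puncta are
detected by intensity + size thresholding, and each detected object is
assigned to a cell of an externally produced segmentation mask so the
readout is total EGF-positive area per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, restoration

from .puncta3d import (
    _CONNECTIVITY_2D,
    PunctaObject,
    PunctaSet,
    ZStackImage,
    threshold_intensity,
)

__all__ = [
    "CellMask",
    "MembraneBindingResult",
    "ConditionSummary",
    "max_project",
    "preprocess",
    "detect_puncta_2d",
    "per_cell_area",
    "compare_conditions",
]

DEFAULT_BALL_RADIUS = 25
DEFAULT_GAUSSIAN_SIGMA = 1.0
DEFAULT_MIN_AREA = 2
DEFAULT_MAX_AREA = 100


@dataclass
class CellMask:
    """2D labelled segmentation image: 0 = background, k = cell k."""

    labels: np.ndarray
    provenance: str = "external"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"cell mask must be 2D, got {self.labels.ndim}D")
        if (self.labels < 0).any():
            raise ValueError("cell mask labels must be non-negative")

    @property
    def cell_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def area_of(self, cell_id: int) -> int:
        return int(np.count_nonzero(self.labels == cell_id))


@dataclass
class MembraneBindingResult:
    """Per-cell EGF-positive puncta area for one condition."""

    per_cell_area: dict[int, float]
    n_cells: int
    condition: str = ""
    thresholds: dict[str, float] = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def areas(self) -> np.ndarray:
        return np.array([self.per_cell_area[k] for k in sorted(self.per_cell_area)], dtype=float)


@dataclass
class ConditionSummary:
    """Distribution summaries per condition and pairwise fold-changes."""

    stats: dict[str, dict[str, float]]
    fold_changes: dict[tuple[str, str], float]


def max_project(stack: ZStackImage | np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along z: ``out[y, x] = max_z v[z, y, x]``."""
    arr = stack.voxels if isinstance(stack, ZStackImage) else np.asarray(stack)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError(f"max projection needs a 3D stack with >=1 slice, got {arr.shape}")
    return arr.max(axis=0)


def preprocess(
    image: np.ndarray,
    rolling_ball_radius: float = DEFAULT_BALL_RADIUS,
    gaussian_sigma: float = DEFAULT_GAUSSIAN_SIGMA,
    background_method: str = "rolling_ball",
) -> np.ndarray:
    """Rolling-ball background subtraction followed by Gaussian smoothing.

    The rolling-ball background estimate (radius in pixels) is subtracted
    and negatives clamped to zero; the result is then blurred with a
    Gaussian of ``gaussian_sigma`` (0 skips the blur).  The operation
    order is fixed: background first, blur second.
    ``background_method="opening"`` swaps in grayscale morphological
    opening with a disk footprint as an alternative estimator.
    """
    if not rolling_ball_radius > 0:
        raise ValueError(f"rolling_ball_radius must be positive, got {rolling_ball_radius}")
    if gaussian_sigma < 0:
        raise ValueError(f"gaussian_sigma must be >= 0, got {gaussian_sigma}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got {img.ndim}D")
    if background_method == "rolling_ball":
        background = restoration.rolling_ball(img, radius=rolling_ball_radius)
    elif background_method == "opening":
        footprint = morphology.disk(int(round(rolling_ball_radius)))
        background = ndimage.grey_opening(img, footprint=footprint)
    else:
        raise ValueError(f"unknown background_method {background_method!r}")
    out = np.clip(img - background, 0.0, None)
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=gaussian_sigma)
    return out


def detect_puncta_2d(
    image: np.ndarray,
    method: str = "otsu",
    value: float | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    max_area: int = DEFAULT_MAX_AREA,
    connectivity: int = 8,
) -> PunctaSet:
    """Detect EGF-positive objects by intensity + size thresholding.

    Thresholding as in :func:`erkscope.puncta3d.threshold_intensity`,
    labelling with 2D connectivity 4 or 8 (default 8, consistent with the
    3D 26-neighbourhood), and inclusive area bounds in pixels.
    """
    if not 0 < min_area <= max_area:
        raise ValueError(f"need 0 < min_area <= max_area, got ({min_area}, {max_area})")
    if connectivity not in _CONNECTIVITY_2D:
        raise ValueError(f"2D connectivity must be one of {sorted(_CONNECTIVITY_2D)}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got {img.ndim}D")
    mask, thr = threshold_intensity(img, method=method, value=value)
    labels = measure.label(mask, connectivity=_CONNECTIVITY_2D[connectivity])
    objects = []
    keep_ids = []
    for p in measure.regionprops(labels):
        if min_area <= p.area <= max_area:
            objects.append(PunctaObject(id=int(p.label), voxel_count=int(p.area),
                                        centroid=tuple(float(c) for c in p.centroid)))
            keep_ids.append(int(p.label))
    labels = np.where(np.isin(labels, keep_ids), labels, 0)
    return PunctaSet(objects=objects, labels=labels,
                     thresholds={"intensity": thr, "min_area": float(min_area),
                                 "max_area": float(max_area)})


def per_cell_area(
    puncta: PunctaSet,
    mask: CellMask,
    assignment: str = "centroid",
    max_distance: float = 10.0,
) -> MembraneBindingResult:
    """Total detected puncta area per segmented cell.

    Each object is assigned to exactly one cell.  ``assignment="centroid"``
    (default) uses the cell containing the object's centroid pixel;
    objects whose centroid falls on background are assigned to the
    nearest cell if it lies within ``max_distance`` pixels, else dropped
    and counted in ``n_dropped`` (membrane puncta in max projections
    frequently straddle label boundaries, hence the fallback).
    ``assignment="majority"`` uses the cell with the largest pixel
    overlap instead.  Cells without puncta appear with area 0.
    """
    if assignment not in ("centroid", "majority"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    if mask.labels.shape != puncta.labels.shape:
        raise ValueError(f"shape mismatch: mask {mask.labels.shape} vs puncta {puncta.labels.shape}")
    labels = mask.labels
    areas: dict[int, float] = {k: 0.0 for k in mask.cell_ids}
    # nearest-cell lookup for background pixels
    bg = labels == 0
    if bg.any():
        dist, (iy, ix) = ndimage.distance_transform_edt(bg, return_indices=True)
    else:
        dist = np.zeros(labels.shape)
        iy, ix = np.indices(labels.shape)
    dropped = 0
    for obj in puncta.objects:
        if assignment == "majority":
            cell_labels = labels[puncta.labels == obj.id]
            cell_labels = cell_labels[cell_labels > 0]
            if len(cell_labels):
                k = int(np.bincount(cell_labels).argmax())
                obj.cell_id = k
                areas[k] += obj.voxel_count
                continue
        cy, cx = (int(round(c)) for c in obj.centroid[-2:])
        cy = min(max(cy, 0), labels.shape[0] - 1)
        cx = min(max(cx, 0), labels.shape[1] - 1)
        k = int(labels[cy, cx])
        if k == 0:
            if dist[cy, cx] <= max_distance:
                k = int(labels[iy[cy, cx], ix[cy, cx]])
        if k == 0:
            dropped += 1
            continue
        obj.cell_id = k
        areas[k] += obj.voxel_count
    return MembraneBindingResult(
        per_cell_area=areas,
        n_cells=len(areas),
        thresholds=dict(puncta.thresholds),
        n_dropped=dropped,
    )


def compare_conditions(results: list[MembraneBindingResult]) -> ConditionSummary:
    """Summarize per-cell area distributions across conditions.

    Reports mean, SD, quartiles (linear interpolation between order
    statistics), median, min and max per condition — mirroring the
    box-whisker convention of 25th-75th percentile boxes with min/max
    whiskers — plus pairwise fold-changes of means.
    """
    if len(results) < 2:
        raise ValueError("need at least two conditions to compare")
    stats: dict[str, dict[str, float]] = {}
    for res in results:
        if res.n_cells == 0:
            raise ValueError(f"condition {res.condition!r} has no cells")
        a = res.areas
        stats[res.condition] = {
            "n_cells": float(len(a)),
            "mean": float(a.mean()),
            "sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
            "q25": float(np.quantile(a, 0.25)),
            "median": float(np.quantile(a, 0.5)),
            "q75": float(np.quantile(a, 0.75)),
            "min": float(a.min()),
            "max": float(a.max()),
        }
    folds: dict[tuple[str, str], float] = {}
    conds = [r.condition for r in results]
    for a in conds:
        for b in conds:
            if a != b and stats[b]["mean"] != 0:
                folds[(a, b)] = stats[a]["mean"] / stats[b]["mean"]
    return ConditionSummary(stats=stats, fold_changes=folds)
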