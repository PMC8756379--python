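"""EGF-488 / EGFR internalization quantification from 3D z-stacks.

Pipeline: per-slice Gaussian background subtraction, intensity
thresholding, 3D connected-component labelling, size filtering, optional
double-positive filtering against a second channel, and per-nucleus
volume normalization.  Internalized ligand-receptor complexes appear as
small bright puncta positive in both the EGF-488 and EGFR channels; the
readout is total punctum volume per nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "ZStackImage",
    "PunctaObject",
    "PunctaSet",
    "InternalizationResult",
    "subtract_background_gaussian",
    "threshold_intensity",
    "label_objects_3d",
    "filter_by_size",
    "filter_double_positive",
    "quantify_internalization",
    "count_nuclei",
]

#: Defaults for the internalization pipeline; the original analysis
#: constants are not published, so these are declared, logged choices.
DEFAULT_SIGMA_PX = 3.0
DEFAULT_MIN_SIZE = 2
DEFAULT_MAX_SIZE = 200

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # voxel neighbourhood -> skimage rank
_CONNECTIVITY_2D = {4: 1, 8: 2}


@dataclass
class ZStackImage:
    """A single-channel 3D (z, y, x) voxel array with optional calibration."""

    voxels: np.ndarray
    channel_name: str = ""
    voxel_size: tuple[float, float, float] | None = None  # (z, y, x), physical units

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError(f"z-stack must be 3D with >=1 slice, got shape {self.voxels.shape}")
        if np.issubdtype(self.voxels.dtype, np.floating) and (self.voxels < 0).any():
            raise ValueError("negative intensities in z-stack")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class PunctaObject:
    id: int
    voxel_count: int
    centroid: tuple[float, ...]
    flags: dict[str, bool] = field(default_factory=dict)
    overlap_fraction: float | None = None
    cell_id: int | None = None


@dataclass
class PunctaSet:
    """Labelled detected objects plus the label image they live in."""

    objects: list[PunctaObject]
    labels: np.ndarray  # labelled image, same shape as the source mask
    source_channels: tuple[str, ...] = ()
    thresholds: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.objects)

    @property
    def total_size(self) -> int:
        return int(sum(o.voxel_count for o in self.objects))

    def ids(self) -> set[int]:
        return {o.id for o in self.objects}


@dataclass
class InternalizationResult:
    total_volume: float
    n_nuclei: int
    normalized_volume: float
    condition: str = ""


def subtract_background_gaussian(stack: ZStackImage, sigma_px: float = DEFAULT_SIGMA_PX) -> ZStackImage:
    """Per-slice Gaussian background subtraction.

    Each z-slice is independently blurred with a Gaussian of ``sigma_px``
    and the blurred image subtracted from the raw slice; negative values
    are clamped to zero (negative intensities are non-physical and would
    destabilize Otsu thresholding downstream).  Slices never mix.
    """
    if not sigma_px > 0:
        raise ValueError(f"sigma_px must be positive, got {sigma_px}")
    raw = stack.voxels.astype(float)
    blurred = ndimage.gaussian_filter(raw, sigma=(0.0, sigma_px, sigma_px))
    out = np.clip(raw - blurred, 0.0, None)
    return ZStackImage(out, channel_name=stack.channel_name, voxel_size=stack.voxel_size)


def threshold_intensity(
    image: ZStackImage | np.ndarray,
    method: str = "otsu",
    value: float | None = None,
) -> tuple[np.ndarray, float]:
    """Threshold an image to a boolean positive-pixel mask.

    ``method`` is ``fixed`` (``value`` in AU), ``quantile`` (``value`` a
    fraction in (0, 1)) or ``otsu`` (``value`` ignored).  Returns the
    mask (strictly-above comparison) together with the threshold actually
    applied, which callers record in provenance.
    """
    arr = image.voxels if isinstance(image, ZStackImage) else np.asarray(image)
    arr = arr.astype(float)
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding needs a value")
        thr = float(value)
    elif method == "quantile":
        if value is None or not 0.0 < value < 1.0:
            raise ValueError(f"quantile must be in (0, 1), got {value}")
        thr = float(np.quantile(arr, value))
    elif method == "otsu":
        if arr.min() == arr.max():
            raise ValueError("otsu thresholding undefined on a constant image")
        thr = float(filters.threshold_otsu(arr))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return arr > thr, thr


def label_objects_3d(mask: np.ndarray, connectivity: int = 26) -> PunctaSet:
    """Connected-component labelling of a 3D boolean mask.

    ``connectivity`` is the voxel neighbourhood: 6 (faces only), 18 or 26
    (faces, edges and corners; default, merging the diagonal voxel
    contacts a single bright spot produces across slices).  Physical
    anisotropy is ignored — connectivity is lattice-based.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"expected 3D mask, got {mask.ndim}D")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"3D connectivity must be one of {sorted(_CONNECTIVITY)}")
    labels = measure.label(mask, connectivity=_CONNECTIVITY[connectivity])
    objects = [
        PunctaObject(id=int(p.label), voxel_count=int(p.area),
                     centroid=tuple(float(c) for c in p.centroid))
        for p in measure.regionprops(labels)
    ]
    return PunctaSet(objects=objects, labels=labels)


def _subset(puncta: PunctaSet, keep: list[PunctaObject]) -> PunctaSet:
    kept_ids = {o.id for o in keep}
    labels = np.where(np.isin(puncta.labels, list(kept_ids)), puncta.labels, 0)
    return PunctaSet(objects=keep, labels=labels,
                     source_channels=puncta.source_channels,
                     thresholds=dict(puncta.thresholds))


def filter_by_size(puncta: PunctaSet, min_size: int, max_size: int) -> PunctaSet:
    """Retain objects with ``min_size <= voxel_count <= max_size`` (inclusive).

    The lower bound removes single-voxel noise; the upper bound removes
    structures larger than individual puncta.
    """
    if not 0 < min_size <= max_size:
        raise ValueError(f"need 0 < min_size <= max_size, got ({min_size}, {max_size})")
    keep = [o for o in puncta.objects if min_size <= o.voxel_count <= max_size]
    out = _subset(puncta, keep)
    out.thresholds.update(min_size=float(min_size), max_size=float(max_size))
    return out


def filter_double_positive(
    puncta_a: PunctaSet,
    mask_b: np.ndarray,
    min_overlap: float = 0.0,
) -> PunctaSet:
    """Retain channel-A objects that are also positive in channel B.

    With the default ``min_overlap=0`` an object is kept if *any* of its
    voxels lies in ``mask_b`` (the per-voxel "doubly positive" reading);
    a positive ``min_overlap`` requires at least that fraction of the
    object's voxels to overlap.  The overlap fraction is recorded on
    every retained object, and the output is always a subset of the
    input.
    """
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_b.shape != puncta_a.labels.shape:
        raise ValueError(f"shape mismatch: {mask_b.shape} vs {puncta_a.labels.shape}")
    keep: list[PunctaObject] = []
    for obj in puncta_a.objects:
        overlap = int(np.count_nonzero(mask_b[puncta_a.labels == obj.id]))
        frac = overlap / obj.voxel_count
        retained = (overlap > 0) if min_overlap <= 0 else (frac >= min_overlap)
        if retained:
            obj.overlap_fraction = frac
            obj.flags["double_positive"] = True
            keep.append(obj)
    out = _subset(puncta_a, keep)
    out.thresholds.update(min_overlap=float(min_overlap))
    return out


def quantify_internalization(puncta: PunctaSet, n_nuclei: int, condition: str = "") -> InternalizationResult:
    """Total punctum volume normalized to the number of nuclei present."""
    if n_nuclei < 1:
        raise ValueError(f"n_nuclei must be >= 1, got {n_nuclei}")
    total = float(puncta.total_size)
    return InternalizationResult(
        total_volume=total,
        n_nuclei=int(n_nuclei),
        normalized_volume=total / n_nuclei,
        condition=condition,
    )


def count_nuclei(
    hoechst: ZStackImage | None,
    explicit_count: int | None = None,
    min_size_px: int = 20,
) -> int:
    """Count nuclei from a Hoechst-like channel.

    A user-supplied ``explicit_count`` always overrides.  Otherwise the
    channel is max-projected, Otsu-thresholded, 2D-labelled
    (8-connectivity) and size-filtered.  A blank channel yields 0 with a
    warning, since normalization then requires an explicit count.
    """
    if explicit_count is not None:
        return int(explicit_count)
    if hoechst is None:
        raise ValueError("either a nuclei channel or an explicit count is required")
    proj = hoechst.voxels.max(axis=0).astype(float)
    if proj.min() == proj.max():
        warnings.warn("blank nuclei channel: returning 0; supply an explicit "
                      "count for normalization", stacklevel=2)
        return 0
    mask = proj > filters.threshold_otsu(proj)
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(sizes >= min_size_px))
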