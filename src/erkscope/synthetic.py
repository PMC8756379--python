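"""Ground-truthed synthetic data emulating stiffness-dependent Erk signaling.

Cells cultured on soft substrata show low, flat Erk activity; on
intermediate and stiff substrata activity becomes pulsatile or constantly
elevated, and acute EGF stimulation produces transient or sustained step
responses.  This module generates three kinds of synthetic inputs with
exact ground truth so every analysis stage of the package can be verified
without raw microscopy data:

1. C/N-ratio trajectories in five regimes (``flat``, ``pulsatile``,
   ``constant_on``, ``step_transient``, ``step_sustained``),
2. 3D two-signal-channel z-stacks (EGF-488-like and EGFR-like) plus a
   Hoechst-like nuclei channel, containing non-overlapping bright puncta
   with known positions, voxel counts and channel co-positivity,
3. 2D max-projection-style membrane scenes with abutting cells (a full
   label tessellation), per-cell puncta budgets, and an optional
   exclusion zone around cell-cell contacts.

Everything is deterministic for a fixed config + seed.  The generators
deliberately omit optical PSF modelling, photobleaching and cell motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .trajectories import Trajectory, cn_at_time

__all__ = [
    "TrajectoryGenConfig",
    "ImageGenConfig",
    "ObjectRecord",
    "GroundTruth",
    "GeometryError",
    "generate_trajectories",
    "generate_zstack",
    "generate_membrane_scene",
    "TRAJECTORY_PRESETS",
]

REGIMES = ("flat", "pulsatile", "constant_on", "step_transient", "step_sustained")


class GeometryError(ValueError):
    """Scene geometry infeasible (objects cannot be placed without overlap)."""


@dataclass(frozen=True)
class TrajectoryGenConfig:
    """Configuration of the trajectory generator.

    Attributes
    ----------
    n_cells, n_frames:
        Number of cells and frames per cell.
    frame_interval_min:
        Acquisition interval in minutes (time-lapse imaging is typically
        run at 1-3 min/frame; default 1).
    baseline_cn:
        Resting C/N ratio (dimensionless, > 0).
    regime:
        One of ``flat | pulsatile | constant_on | step_transient |
        step_sustained``.
    pulse_rate_per_hr:
        Rate of the homogeneous pulse point process (pulsatile regime).
    pulse_amplitude:
        Additive peak height of each pulse above baseline.
    pulse_width_frames:
        Half-width of the symmetric triangular pulse in frames; pulses
        are thinned to a minimum inter-pulse gap of twice this value so
        ground-truth pulses stay resolvable.
    stim_frame:
        Frame index of the stimulus for the step regimes.
    response_peak:
        Additive response height (step regimes and ``constant_on``).
    decay_halflife_min:
        Exponential return half-life of the transient step response.
    noise_cv:
        Coefficient of variation of multiplicative lognormal noise
        applied to the clean C/N signal (the C/N ratio is a ratio of
        positive intensities, so noise is multiplicative by nature).
    seed:
        Seed of the generator; identical config + seed gives identical
        output.
    """

    n_cells: int = 50
    n_frames: int = 120
    frame_interval_min: float = 1.0
    baseline_cn: float = 1.0
    regime: str = "pulsatile"
    pulse_rate_per_hr: float = 4.0
    pulse_amplitude: float = 0.5
    pulse_width_frames: int = 3
    stim_frame: int | None = None
    response_peak: float = 1.0
    decay_halflife_min: float = 15.0
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frame_interval_min", "baseline_cn", "pulse_rate_per_hr",
                     "pulse_amplitude", "response_peak", "decay_halflife_min",
                     "noise_cv"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.baseline_cn <= 0:
            raise ValueError("baseline_cn must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.pulse_width_frames < 1:
            raise ValueError("pulse_width_frames must be >= 1")
        if self.n_frames < 2 or self.n_cells < 0:
            raise ValueError("need n_frames >= 2 and n_cells >= 0")
        if self.regime.startswith("step"):
            sf = self.stim_frame
            if sf is None or not (0 <= sf < self.n_frames):
                raise ValueError(
                    f"stim_frame must lie in [0, {self.n_frames}) for step regimes, got {sf}"
                )


@dataclass(frozen=True)
class ImageGenConfig:
    """Configuration of the 3D z-stack and 2D membrane-scene generators.

    ``puncta_per_cell`` is an exact per-cell count when
    ``count_mode="exact"`` (default) or the mean of a Poisson draw when
    ``count_mode="poisson"``.  Puncta never overlap (centres separated by
    more than twice their radius) so the ground-truth object count always
    equals the generated count.  ``contact_exclusion`` suppresses puncta
    near cell-cell boundaries, emulating ligand exclusion from cell-cell
    contacts on compliant substrata.
    """

    shape_zyx: tuple[int, int, int] = (16, 256, 256)
    n_cells: int = 4
    n_nuclei: int | None = None  # default: one per cell
    puncta_per_cell: float = 5.0
    puncta_radius_px: int = 2
    puncta_intensity: float = 3000.0
    background_level: float = 0.0
    background_gradient: float = 0.0
    double_positive_fraction: float = 0.5
    contact_exclusion: bool = False
    exclusion_distance_px: float = 6.0
    cell_radius_px: int = 40
    nucleus_radius_px: int = 5
    nucleus_intensity: float = 4000.0
    membrane_intensity: float = 150.0
    count_mode: str = "exact"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape_zyx) != 3 or any(s < 1 for s in self.shape_zyx):
            raise ValueError(f"bad shape_zyx {self.shape_zyx}")
        if not 0.0 <= self.double_positive_fraction <= 1.0:
            raise ValueError("double_positive_fraction must be in [0, 1]")
        if self.puncta_radius_px < 1 or self.puncta_per_cell < 0:
            raise ValueError("puncta_radius_px >= 1 and puncta_per_cell >= 0 required")
        if min(self.puncta_intensity, self.background_level,
               self.nucleus_intensity, self.membrane_intensity) < 0:
            raise ValueError("intensities must be non-negative")
        if self.count_mode not in ("exact", "poisson"):
            raise ValueError(f"count_mode must be 'exact' or 'poisson', got {self.count_mode!r}")

    @property
    def n_nuclei_effective(self) -> int:
        return self.n_cells if self.n_nuclei is None else self.n_nuclei


@dataclass
class ObjectRecord:
    """Ground truth for one generated punctum."""

    object_id: int
    centroid: tuple[float, ...]  # (z, y, x) or (y, x)
    size_px: int  # voxels in 3D, pixels in 2D
    cell_id: int
    egf_positive: bool = True
    egfr_positive: bool = False


@dataclass
class GroundTruth:
    """Exact ground truth accompanying a synthetic dataset.

    Trajectory runs fill ``pulse_frames`` / ``pulse_times`` / ``auc``;
    image runs fill ``objects`` / ``per_cell_area`` / ``n_nuclei``.
    """

    pulse_frames: dict[str, np.ndarray] = field(default_factory=dict)
    pulse_times: dict[str, np.ndarray] = field(default_factory=dict)
    auc: dict[str, dict[str, float]] = field(default_factory=dict)
    objects: list[ObjectRecord] = field(default_factory=list)
    per_cell_area: dict[int, float] = field(default_factory=dict)
    n_nuclei: int | None = None


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def draw_pulse_frames(
    rng: np.random.Generator,
    n_frames: int,
    frame_interval_min: float,
    rate_per_hr: float,
    min_gap_frames: int,
    margin_frames: int = 0,
) -> np.ndarray:
    """Pulse frames of a homogeneous point process thinned by dead time.

    Events are drawn as a Poisson process at ``rate_per_hr`` over the
    acquisition span, rounded to frame indices, and thinned left to right
    so consecutive kept events are at least ``min_gap_frames`` apart.
    Events within ``margin_frames`` of either series end are rejected so
    every ground-truth pulse peak is an interior frame and stays
    detectable as a local maximum.
    """
    duration_min = n_frames * frame_interval_min
    n_events = rng.poisson(rate_per_hr * duration_min / 60.0)
    times = np.sort(rng.uniform(0.0, duration_min, size=n_events))
    frames = np.minimum(np.round(times / frame_interval_min).astype(int), n_frames - 1)
    kept: list[int] = []
    for f in frames:
        if f < margin_frames or f > n_frames - 1 - margin_frames:
            continue
        if not kept or f - kept[-1] >= min_gap_frames:
            kept.append(int(f))
    return np.asarray(kept, dtype=int)


def _triangular_bumps(n_frames: int, centers: np.ndarray, amplitude: float,
                      half_width: int) -> np.ndarray:
    out = np.zeros(n_frames)
    idx = np.arange(n_frames)
    for c in centers:
        out += amplitude * np.clip(1.0 - np.abs(idx - c) / half_width, 0.0, None)
    return out


def clean_signal(config: TrajectoryGenConfig, pulse_frames: np.ndarray) -> np.ndarray:
    """Noise-free C/N signal for one cell given its pulse frames."""
    n, dt = config.n_frames, config.frame_interval_min
    sig = np.full(n, config.baseline_cn)
    if config.regime == "pulsatile":
        sig += _triangular_bumps(n, pulse_frames, config.pulse_amplitude,
                                 config.pulse_width_frames)
    elif config.regime == "constant_on":
        sig += config.response_peak
    elif config.regime in ("step_transient", "step_sustained"):
        k = np.arange(n) - config.stim_frame
        resp = np.where(k >= 0, config.response_peak, 0.0)
        if config.regime == "step_transient":
            resp = np.where(
                k >= 0,
                config.response_peak * np.exp2(-k * dt / config.decay_halflife_min),
                0.0,
            )
        sig = sig + resp
    return sig


def generate_trajectories(
    config: TrajectoryGenConfig,
) -> tuple[list[Trajectory], GroundTruth]:
    """Generate per-cell C/N trajectories with exact ground truth.

    Returns the trajectories (unsmoothed, as a measurement pipeline would
    produce them) and a :class:`GroundTruth` holding true pulse frames /
    times per cell and, for step regimes, the true early/late
    post-stimulus AUC of the clean signal under the package's baseline
    convention (windowed mean at the stimulus time).
    """
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log1p(config.noise_cv ** 2))
    trajectories: list[Trajectory] = []
    gt = GroundTruth()
    times = np.arange(config.n_frames) * config.frame_interval_min
    for i in range(config.n_cells):
        cell = f"cell{i:04d}"
        if config.regime == "pulsatile":
            pulses = draw_pulse_frames(
                rng, config.n_frames, config.frame_interval_min,
                config.pulse_rate_per_hr, 2 * config.pulse_width_frames,
                margin_frames=config.pulse_width_frames,
            )
        else:
            pulses = np.array([], dtype=int)
        sig = clean_signal(config, pulses)
        if config.noise_cv > 0:
            noise = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                                  size=config.n_frames)
            cn = sig * noise
        else:
            cn = sig.copy()
        trajectories.append(Trajectory(cell, times.copy(), cn, smoothed=False))
        gt.pulse_frames[cell] = pulses
        gt.pulse_times[cell] = pulses * config.frame_interval_min
        if config.regime in ("step_transient", "step_sustained"):
            clean = Trajectory(cell, times.copy(), sig, smoothed=False)
            stim_time = config.stim_frame * config.frame_interval_min
            baseline = cn_at_time(clean, stim_time)
            rel = times - stim_time
            early = (rel > 0) & (rel <= 60.0)
            late = (rel > 60.0)
            gt.auc[cell] = {
                "early": float((sig[early] - baseline).sum()),
                "late": float((sig[late] - baseline).sum()) if late.any() else 0.0,
            }
    return trajectories, gt


#: Qualitative stiffness presets.  The source regimes are qualitative
#: observations (soft: low flat activity; intermediate: sparse pulses;
#: stiff: frequent pulses / constant activity); no quantitative per-regime
#: distributions exist, so these bundles are documented emulations, not
#: reproductions.
TRAJECTORY_PRESETS: dict[str, TrajectoryGenConfig] = {
    "soft": TrajectoryGenConfig(regime="flat", baseline_cn=0.7, noise_cv=0.05),
    "intermediate": TrajectoryGenConfig(regime="pulsatile", baseline_cn=1.0,
                                        pulse_rate_per_hr=2.0, pulse_amplitude=0.5,
                                        noise_cv=0.05),
    "stiff": TrajectoryGenConfig(regime="pulsatile", baseline_cn=1.3,
                                 pulse_rate_per_hr=5.0, pulse_amplitude=0.6,
                                 noise_cv=0.05),
}


# ---------------------------------------------------------------------------
# shared placement helpers
# ---------------------------------------------------------------------------

_MAX_TRIES = 20_000


def _place_points_min_dist(
    rng: np.random.Generator,
    n: int,
    low: np.ndarray,
    high: np.ndarray,
    min_dist: float,
    accept=None,
) -> np.ndarray:
    """Rejection-sample ``n`` integer points with pairwise min distance."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        if tries > _MAX_TRIES:
            raise GeometryError(
                f"could not place {n} objects with min distance {min_dist} "
                f"in box {low}..{high} after {_MAX_TRIES} tries"
            )
        tries += 1
        cand = np.array([rng.integers(lo, hi + 1) for lo, hi in zip(low, high)])
        if accept is not None and not accept(cand):
            continue
        if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
            pts.append(cand)
    return np.array(pts, dtype=int).reshape(n, len(low))


def _ball_offsets(radius: int, ndim: int) -> np.ndarray:
    """Integer offsets of a rasterized ball/disk: ||d||^2 <= radius^2."""
    r = int(radius)
    grids = np.meshgrid(*([np.arange(-r, r + 1)] * ndim), indexing="ij")
    d2 = sum(g * g for g in grids)
    mask = d2 <= r * r
    return np.stack([g[mask] for g in grids], axis=1)


def _poisson_background(rng: np.random.Generator, shape: tuple[int, ...],
                        level: float, gradient: float) -> np.ndarray:
    """Background field: level + linear gradient along x, Poisson noise."""
    x = np.arange(shape[-1], dtype=float)
    lam = np.broadcast_to(level + gradient * x, shape)
    if lam.max() <= 0:
        return np.zeros(shape)
    return rng.poisson(np.clip(lam, 0.0, None)).astype(float)


def _per_cell_counts(rng: np.random.Generator, cfg: ImageGenConfig) -> np.ndarray:
    if cfg.count_mode == "exact":
        return np.full(cfg.n_cells, int(round(cfg.puncta_per_cell)), dtype=int)
    return rng.poisson(cfg.puncta_per_cell, size=cfg.n_cells)


def _split_double_positive(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    """Boolean co-positivity flags with an exact count round(frac * n)."""
    flags = np.zeros(n, dtype=bool)
    n_dp = int(round(frac * n))
    if n_dp:
        flags[rng.permutation(n)[:n_dp]] = True
    return flags


# ---------------------------------------------------------------------------
# 3D z-stacks
# ---------------------------------------------------------------------------

def generate_zstack(config: ImageGenConfig):
    """Generate a two-signal-channel z-stack plus nuclei channel and mask.

    Returns ``(channels, mask, ground_truth)`` where ``channels`` maps
    ``{"egf", "egfr", "nuclei"}`` to :class:`~erkscope.puncta3d.ZStackImage`
    objects (axis order z, y, x), ``mask`` is a 2D
    :class:`~erkscope.membrane2d.CellMask` of non-overlapping disk cells,
    and the ground truth records every punctum's centroid, rasterized
    voxel count, owning cell and channel co-positivity, plus per-cell
    totals and the nucleus count.

    Puncta are spheres of ``puncta_radius_px`` placed fully inside their
    cell's footprint with centre separation > 2 x radius (plus a margin)
    so connected-component labelling recovers each punctum individually.
    The EGFR-like channel carries a diffuse low-intensity membrane ring
    per cell plus the co-positive subset of puncta; the background of the
    signal channels is ``background_level`` plus a linear x-gradient with
    Poisson counting noise.
    """
    from .membrane2d import CellMask
    from .puncta3d import ZStackImage

    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape_zyx
    r_cell = config.cell_radius_px
    r = config.puncta_radius_px

    # --- cells: non-overlapping disks in the (y, x) plane
    if config.n_cells > 0:
        margin = r_cell + 1
        if 2 * margin >= min(ny, nx):
            raise GeometryError(f"image {ny}x{nx} too small for cell radius {r_cell}")
        centers = _place_points_min_dist(
            rng, config.n_cells,
            low=np.array([margin, margin]), high=np.array([ny - margin - 1, nx - margin - 1]),
            min_dist=2 * r_cell + 2,
        )
    else:
        centers = np.zeros((0, 2), dtype=int)

    labels = np.zeros((ny, nx), dtype=np.uint16)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for k, (cy, cx) in enumerate(centers, start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r_cell * r_cell] = k

    egf = _poisson_background(rng, config.shape_zyx, config.background_level,
                              config.background_gradient)
    egfr = _poisson_background(rng, config.shape_zyx, config.background_level,
                               config.background_gradient)
    nuclei = np.zeros(config.shape_zyx)

    # --- diffuse EGFR membrane ring at each cell boundary, all slices
    if config.membrane_intensity > 0 and len(centers):
        ring = np.zeros((ny, nx), dtype=bool)
        for cy, cx in centers:
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            ring |= (d2 <= r_cell * r_cell) & (d2 >= (r_cell - 2) ** 2)
        egfr += config.membrane_intensity * ring[None, :, :]

    # --- nuclei: spheres at the first n_nuclei cell centres (mid-plane)
    n_nuc = config.n_nuclei_effective
    rn = config.nucleus_radius_px
    zmid = nz // 2
    nuc_offsets = _ball_offsets(rn, 3)
    if n_nuc > len(centers):
        raise GeometryError(f"cannot place {n_nuc} nuclei in {len(centers)} cells")
    for cy, cx in centers[:n_nuc]:
        vox = nuc_offsets + np.array([zmid, cy, cx])
        ok = ((vox >= 0) & (vox < np.array(config.shape_zyx))).all(axis=1)
        vox = vox[ok]
        nuclei[vox[:, 0], vox[:, 1], vox[:, 2]] += config.nucleus_intensity

    # --- puncta: spheres inside cells, well separated in 3D
    counts = _per_cell_counts(rng, config)
    offsets = _ball_offsets(r, 3)
    sphere_voxels = len(offsets)
    all_centers: list[np.ndarray] = []
    owner: list[int] = []
    if nz < 2 * (r + 1) + 1 and counts.sum() > 0:
        raise GeometryError(f"stack depth {nz} too small for puncta radius {r}")
    for k, (cy, cx) in enumerate(centers, start=1):
        budget = int(counts[k - 1])
        placed = 0
        tries = 0
        while placed < budget:
            if tries > _MAX_TRIES:
                raise GeometryError(f"could not place {budget} puncta in cell {k}")
            tries += 1
            z = rng.integers(r + 1, nz - r - 1)
            ang = rng.uniform(0, 2 * np.pi)
            rad = (r_cell - r - 2) * math.sqrt(rng.uniform())
            y = int(round(cy + rad * math.sin(ang)))
            x = int(round(cx + rad * math.cos(ang)))
            cand = np.array([z, y, x])
            if all(np.linalg.norm(cand - p) >= 2 * r + 3 for p in all_centers):
                all_centers.append(cand)
                owner.append(k)
                placed += 1

    gt = GroundTruth(n_nuclei=n_nuc)
    gt.per_cell_area = {k: 0.0 for k in range(1, config.n_cells + 1)}
    dp = _split_double_positive(rng, len(all_centers), config.double_positive_fraction)
    for oid, (c, cell_k) in enumerate(zip(all_centers, owner), start=1):
        vox = offsets + c
        egf[vox[:, 0], vox[:, 1], vox[:, 2]] += config.puncta_intensity
        if dp[oid - 1]:
            egfr[vox[:, 0], vox[:, 1], vox[:, 2]] += config.puncta_intensity
        gt.objects.append(ObjectRecord(
            object_id=oid, centroid=tuple(float(v) for v in c),
            size_px=sphere_voxels, cell_id=int(cell_k),
            egf_positive=True, egfr_positive=bool(dp[oid - 1]),
        ))
        gt.per_cell_area[int(cell_k)] += sphere_voxels

    def _as_stack(arr: np.ndarray, name: str) -> ZStackImage:
        return ZStackImage(np.clip(arr, 0, 65535).astype(np.uint16), channel_name=name)

    channels = {
        "egf": _as_stack(egf, "egf"),
        "egfr": _as_stack(egfr, "egfr"),
        "nuclei": _as_stack(nuclei, "nuclei"),
    }
    return channels, CellMask(labels, provenance="synthetic"), gt


# ---------------------------------------------------------------------------
# 2D membrane scenes
# ---------------------------------------------------------------------------

def cell_boundary_pixels(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels where two different *cell* labels abut.

    A pixel belongs to the inter-cell boundary if any 4-neighbour carries
    a different non-zero label.
    """
    b = np.zeros(labels.shape, dtype=bool)
    for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(labels, sh, axis=ax)
        edge = (labels != nb) & (labels > 0) & (nb > 0)
        # roll wraps around; wrap edges cannot be true boundaries between
        # physically abutting cells only if labels differ there by chance —
        # mask the wrapped border row/column.
        if ax == 0:
            edge[0 if sh == 1 else -1, :] = False
        else:
            edge[:, 0 if sh == 1 else -1] = False
        b |= edge
    return b


def generate_membrane_scene(config: ImageGenConfig):
    """Generate a 2D membrane-binding scene with abutting cells.

    Cells form a full Voronoi tessellation of the field (every pixel
    belongs to a cell), mimicking a confluent epithelium whose cell-cell
    contacts are shared label boundaries.  Puncta are disks of
    ``puncta_radius_px`` placed inside cells; with ``contact_exclusion``
    no punctum centre lies within ``exclusion_distance_px`` of an
    inter-cell boundary pixel (one extra pixel of margin is enforced so
    detected centroids stay robustly outside the zone).

    Returns ``(channels, mask, ground_truth)`` with ``channels`` mapping
    ``{"egf"}`` to a 2D float array.
    """
    from .membrane2d import CellMask

    rng = np.random.default_rng(config.seed)
    _, ny, nx = config.shape_zyx
    n = config.n_cells
    if n < 1:
        raise GeometryError("membrane scene needs at least one cell")
    # Voronoi seeds on a jittered grid: cells stay evenly sized (no sliver
    # cells) for every seed, while boundaries remain irregular
    rows = int(math.ceil(math.sqrt(n)))
    cols = int(math.ceil(n / rows))
    pitch_y, pitch_x = ny / rows, nx / cols
    cells_ij = [(i, j) for i in range(rows) for j in range(cols)][:n]
    seeds = np.array([
        [
            int((i + 0.5) * pitch_y + rng.uniform(-0.25, 0.25) * pitch_y),
            int((j + 0.5) * pitch_x + rng.uniform(-0.25, 0.25) * pitch_x),
        ]
        for i, j in cells_ij
    ])
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy[None] - seeds[:, 0, None, None]) ** 2 + (xx[None] - seeds[:, 1, None, None]) ** 2
    labels = (np.argmin(d2, axis=0) + 1).astype(np.uint16)

    boundary = cell_boundary_pixels(labels)
    # distance from every pixel to the nearest inter-cell boundary pixel
    dist_to_boundary = ndimage.distance_transform_edt(~boundary)

    r = config.puncta_radius_px
    disk = _ball_offsets(r, 2)
    disk_area = len(disk)
    min_clearance = float(r + 1)
    if config.contact_exclusion:
        min_clearance = max(min_clearance, config.exclusion_distance_px + 1.0)

    counts = _per_cell_counts(rng, config)
    img = _poisson_background(rng, (ny, nx), config.background_level,
                              config.background_gradient)

    gt = GroundTruth(n_nuclei=n)
    gt.per_cell_area = {k: 0.0 for k in range(1, n + 1)}
    all_centers: list[np.ndarray] = []
    for k in range(1, n + 1):
        budget = int(counts[k - 1])
        cell_pix = np.argwhere(
            (labels == k)
            & (dist_to_boundary >= min_clearance)
            & (yy >= r + 1) & (yy < ny - r - 1)
            & (xx >= r + 1) & (xx < nx - r - 1)
        )
        if budget and len(cell_pix) == 0:
            raise GeometryError(f"cell {k}: no admissible pixels for puncta")
        # greedy pass over a shuffled list of admissible pixels: deterministic
        # for a fixed seed and robust where pure rejection sampling stalls
        placed = 0
        for idx in rng.permutation(len(cell_pix)):
            if placed == budget:
                break
            cand = cell_pix[idx]
            if all(np.linalg.norm(cand - p) >= 2 * r + 3 for p in all_centers):
                all_centers.append(cand)
                pix = disk + cand
                img[pix[:, 0], pix[:, 1]] += config.puncta_intensity
                gt.objects.append(ObjectRecord(
                    object_id=len(all_centers),
                    centroid=tuple(float(v) for v in cand),
                    size_px=disk_area, cell_id=k,
                ))
                gt.per_cell_area[k] += disk_area
                placed += 1
        if placed < budget:
            raise GeometryError(f"could not place {budget} puncta in cell {k}")

    channels = {"egf": np.clip(img, 0, 65535).astype(np.uint16)}
    return channels, CellMask(labels, provenance="synthetic"), gt


def with_seed(config, seed: int):
    """Return a copy of a generator config with a different seed."""
    return replace(config, seed=seed)
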