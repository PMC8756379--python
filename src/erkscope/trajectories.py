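"""Erk-KTR trajectory quantification.

The kinase translocation reporter (KTR) leaves the nucleus when Erk is
active, so per-cell Erk activity is read out as the ratio of mean
cytoplasmic to mean nuclear reporter intensity (the C/N ratio) after
background subtraction.  This module derives every downstream statistic
from such trajectories:

* 3-frame moving-average smoothing,
* pulse detection by a scale-free 20 %-relative-increase rule,
* baseline-subtracted area under the curve (AUC) over post-stimulus
  windows,
* fixed-time-point readouts (windowed means +/- 10 min),
* peak responses after a stimulus, and
* on / pulsing / off classification of single cells.

All functions operate on small dataclass containers holding NumPy arrays;
times are minutes, intensities arbitrary units, and the C/N ratio is
dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityTimeSeries",
    "Trajectory",
    "PulseCallResult",
    "TrajectoryFeatures",
    "PopulationSummary",
    "compute_cn",
    "smooth",
    "detect_pulses",
    "auc",
    "cn_at_time",
    "peak_response",
    "compute_features",
    "classify",
    "summarize_population",
]

#: Default relative-increase threshold for pulse calling (20 %).
DEFAULT_PULSE_THRESHOLD = 0.20

#: Half-width (minutes) of the window used for fixed-time-point readouts.
FIXED_POINT_HALF_WINDOW_MIN = 10.0


class TrajectoryError(ValueError):
    """Raised when a trajectory violates the container contract."""


@dataclass
class IntensityTimeSeries:
    """Raw per-cell intensity measurements over time.

    Parameters
    ----------
    cell_id:
        Identifier of the measured cell.
    times:
        Acquisition times in minutes, strictly increasing with uniform
        spacing.
    nuclear_mean, cytoplasmic_mean:
        Mean gray values of the nuclear and cytoplasmic KTR regions (AU).
    background:
        Background intensity measured in regions without cells; a scalar
        or a per-frame array (AU).
    """

    cell_id: str
    times: np.ndarray
    nuclear_mean: np.ndarray
    cytoplasmic_mean: np.ndarray
    background: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nuclear_mean = np.asarray(self.nuclear_mean, dtype=float)
        self.cytoplasmic_mean = np.asarray(self.cytoplasmic_mean, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise TrajectoryError(f"cell {self.cell_id}: empty time axis")
        if not (len(self.times) == len(self.nuclear_mean) == len(self.cytoplasmic_mean)):
            raise TrajectoryError(f"cell {self.cell_id}: ragged series")
        dt = np.diff(self.times)
        if len(dt) and (dt <= 0).any():
            raise TrajectoryError(f"cell {self.cell_id}: times not strictly increasing")
        if len(dt) > 1 and not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise TrajectoryError(f"cell {self.cell_id}: non-uniform frame interval")

    @property
    def background_per_frame(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.background, dtype=float), self.times.shape)


@dataclass
class Trajectory:
    """A single cell's C/N-ratio time series."""

    cell_id: str
    times: np.ndarray
    cn: np.ndarray
    smoothed: bool = False
    #: frame indices of the source series dropped as invalid by compute_cn
    excluded_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cn = np.asarray(self.cn, dtype=float)
        if len(self.times) != len(self.cn):
            raise TrajectoryError(f"cell {self.cell_id}: times/cn length mismatch")
        if len(self.cn) and not (self.cn > 0).all():
            raise TrajectoryError(f"cell {self.cell_id}: non-positive C/N ratio")

    def __len__(self) -> int:
        return len(self.cn)

    @property
    def frame_interval(self) -> float:
        if len(self.times) < 2:
            raise TrajectoryError(f"cell {self.cell_id}: interval undefined for <2 frames")
        return float(self.times[1] - self.times[0])


@dataclass
class PulseCallResult:
    """Pulses detected on one trajectory."""

    cell_id: str
    pulse_indices: np.ndarray
    pulse_times: np.ndarray
    prominence: np.ndarray
    threshold: float

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_indices)


@dataclass
class TrajectoryFeatures:
    """Scalar summaries of one trajectory."""

    cell_id: str
    mean_cn: float
    n_pulses: int
    auc_early: float | None = None
    auc_late: float | None = None
    cn_at: dict[float, float] = field(default_factory=dict)
    peak_response: float | None = None
    class_label: str | None = None
    condition: str | None = None


@dataclass
class PopulationSummary:
    """Per-condition population statistics (heatmap-level bookkeeping)."""

    n_cells: dict[str, int]
    class_fractions: dict[str, dict[str, float]]
    pulse_histogram: dict[str, dict[int, int]]
    mean_cn_mean: dict[str, float]
    mean_cn_sd: dict[str, float]
    fold_changes: dict[tuple[str, str], float]


def compute_cn(series: IntensityTimeSeries) -> Trajectory:
    """Compute the background-subtracted C/N ratio trajectory.

    ``cn[t] = (cytoplasmic_mean[t] - background[t]) /
    (nuclear_mean[t] - background[t])``.  Frames whose numerator or
    denominator is non-positive are excluded and recorded in
    ``Trajectory.excluded_frames``.

    Raises
    ------
    TrajectoryError
        If every frame is invalid.
    """
    bg = series.background_per_frame
    num = series.cytoplasmic_mean - bg
    den = series.nuclear_mean - bg
    valid = (den > 0) & (num > 0)
    if not valid.any():
        raise TrajectoryError(f"cell {series.cell_id}: all frames invalid after background subtraction")
    excluded = np.flatnonzero(~valid)
    if len(excluded):
        warnings.warn(
            f"cell {series.cell_id}: excluded {len(excluded)} invalid frame(s)",
            stacklevel=2,
        )
    return Trajectory(
        cell_id=series.cell_id,
        times=series.times[valid],
        cn=num[valid] / den[valid],
        smoothed=False,
        excluded_frames=excluded,
    )


def smooth(traj: Trajectory) -> Trajectory:
    """3-frame moving-average smoothing.

    Each interior frame is replaced by the mean of itself and its two
    neighbours; the first and last frames are averaged over the two
    available frames.  Requires at least three frames.
    """
    n = len(traj)
    if n < 3:
        raise TrajectoryError(f"cell {traj.cell_id}: smoothing needs >=3 frames, got {n}")
    cn = traj.cn
    out = np.empty_like(cn)
    out[1:-1] = (cn[:-2] + cn[1:-1] + cn[2:]) / 3.0
    out[0] = (cn[0] + cn[1]) / 2.0
    out[-1] = (cn[-2] + cn[-1]) / 2.0
    return Trajectory(traj.cell_id, traj.times.copy(), out, smoothed=True,
                      excluded_frames=traj.excluded_frames)


def _plateau_peaks(cn: np.ndarray) -> list[int]:
    """Indices of strict local maxima; a flat-topped plateau is represented
    by its first frame.  Endpoints are never peaks (they count as troughs)."""
    n = len(cn)
    peaks: list[int] = []
    i = 1
    while i < n - 1:
        if cn[i] > cn[i - 1]:
            j = i
            while j + 1 < n and cn[j + 1] == cn[i]:
                j += 1
            if j + 1 < n and cn[j + 1] < cn[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return peaks


def detect_pulses(
    traj: Trajectory,
    threshold: float = DEFAULT_PULSE_THRESHOLD,
    mode: str = "smaller",
) -> PulseCallResult:
    """Call Erk-activity pulses with the relative-increase rule.

    A candidate pulse is a strict local maximum of the (smoothed) C/N
    trajectory.  Its flanking trough values ``mL`` and ``mR`` are the
    minima of the trajectory between the candidate and the neighbouring
    candidate peaks (or the series endpoints, which count as troughs).
    With the default ``mode="smaller"`` the candidate at index ``i`` is
    called a pulse iff

        ``cn[i] >= (1 + threshold) * min(mL, mR)``

    i.e. the peak exceeds the smaller flanking trough by at least
    ``threshold`` (default 20 %).  ``mode="larger"`` requires the same
    margin over the *larger* flanking trough instead (a stricter call).
    The reported prominence is the governing relative increase
    ``cn[i] / trough - 1``.  The rule is scale-free: multiplying the
    trajectory by any positive constant leaves the calls unchanged.

    Parameters
    ----------
    traj:
        Input trajectory; the convention of this package (following the
        original analysis order) is to smooth first.
    threshold:
        Relative increase required; must be positive.
    mode:
        ``"smaller"`` (default) or ``"larger"`` flanking-trough reference.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if mode not in ("smaller", "larger"):
        raise ValueError(f"unknown mode {mode!r}")
    if not traj.smoothed and len(traj) >= 3:
        warnings.warn(
            f"cell {traj.cell_id}: pulse detection on an unsmoothed trajectory",
            stacklevel=2,
        )
    cn = traj.cn
    peaks = _plateau_peaks(cn)
    idx: list[int] = []
    prom: list[float] = []
    bounds = [0] + peaks + [len(cn) - 1]
    for k, p in enumerate(peaks):
        # flanking troughs: minimum between this peak and its neighbours
        m_left = float(cn[bounds[k]: p + 1].min())
        m_right = float(cn[p: bounds[k + 2] + 1].min())
        ref = min(m_left, m_right) if mode == "smaller" else max(m_left, m_right)
        if cn[p] >= (1.0 + threshold) * ref:
            idx.append(p)
            prom.append(float(cn[p] / ref - 1.0))
    indices = np.asarray(idx, dtype=int)
    return PulseCallResult(
        cell_id=traj.cell_id,
        pulse_indices=indices,
        pulse_times=traj.times[indices] if len(indices) else np.array([], dtype=float),
        prominence=np.asarray(prom, dtype=float),
        threshold=float(threshold),
    )


def cn_at_time(traj: Trajectory, t: float) -> float:
    """Windowed-mean C/N readout at a fixed time point.

    Returns the mean of the C/N ratio over all frames within 10 minutes
    of ``t``, clipped to the span of the series.
    """
    span = (traj.times[0], traj.times[-1])
    if not (span[0] <= t <= span[1]):
        raise ValueError(f"time {t} min outside trajectory span {span}")
    sel = np.abs(traj.times - t) <= FIXED_POINT_HALF_WINDOW_MIN
    return float(traj.cn[sel].mean())


def auc(
    traj: Trajectory,
    stim_time: float,
    window: tuple[float, float] = (0.0, 60.0),
    baseline: float | None = None,
    time_weighted: bool = False,
) -> float:
    """Baseline-subtracted area under the curve after a stimulus.

    The baseline defaults to the windowed-mean C/N at ``stim_time``
    (see :func:`cn_at_time`).  The AUC is the plain sum of
    ``cn - baseline`` over frames whose stimulus-relative time lies in
    ``(window[0], window[1]]`` — a frame-sum with units of
    (dimensionless C/N) x frames.  ``time_weighted=True`` multiplies by
    the frame interval instead (units: C/N x minutes).

    Default windows used throughout the package: early ``(0, 60]`` min
    and late ``(60, end]`` min after the stimulus.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"empty AUC window {window}")
    if baseline is None:
        baseline = cn_at_time(traj, stim_time)
    rel = traj.times - stim_time
    sel = (rel > lo) & (rel <= hi)
    if not sel.any():
        raise ValueError(f"no frames in window {window} after stim at {stim_time} min")
    total = float((traj.cn[sel] - baseline).sum())
    if time_weighted:
        total *= traj.frame_interval
    return total


def peak_response(traj: Trajectory, stim_time: float, search_window_min: float = 30.0) -> float:
    """Maximum C/N ratio in ``(stim_time, stim_time + search_window_min]``."""
    rel = traj.times - stim_time
    sel = (rel > 0) & (rel <= search_window_min)
    if not sel.any():
        raise ValueError(f"no frames within {search_window_min} min after stim at {stim_time} min")
    return float(traj.cn[sel].max())


def classify(features: TrajectoryFeatures, on_threshold: float | None = None) -> str:
    """Assign a cell to the on / pulsing / off dynamic class.

    A cell with at least two detected pulses is *pulsing* regardless of
    its mean activity.  Otherwise it is *on* if its time-averaged C/N
    ratio is at least ``on_threshold`` and *off* below it.
    ``on_threshold`` is deliberately mandatory (there is no canonical
    value); omitting it for a non-pulsing cell raises.
    """
    if features.n_pulses >= 2:
        return "pulsing"
    if on_threshold is None:
        raise ValueError(
            f"cell {features.cell_id}: on_threshold is required to classify a "
            "cell with fewer than two pulses"
        )
    return "on" if features.mean_cn >= on_threshold else "off"


def compute_features(
    traj: Trajectory,
    pulses: PulseCallResult | None = None,
    stim_time: float | None = None,
    early_window: tuple[float, float] = (0.0, 60.0),
    late_window: tuple[float, float] | None = None,
    cn_times: tuple[float, ...] = (),
    on_threshold: float | None = None,
    peak_search_min: float = 30.0,
    condition: str | None = None,
) -> TrajectoryFeatures:
    """Bundle the standard per-cell readouts into a feature record.

    AUC / peak readouts are computed only when ``stim_time`` is given;
    the class label only when ``on_threshold`` is given or the cell is
    pulsing.
    """
    if pulses is None:
        pulses = detect_pulses(traj)
    feats = TrajectoryFeatures(
        cell_id=traj.cell_id,
        mean_cn=float(traj.cn.mean()),
        n_pulses=pulses.n_pulses,
        condition=condition,
    )
    if stim_time is not None:
        if late_window is None:
            late_window = (60.0, float(traj.times[-1] - stim_time))
        baseline = cn_at_time(traj, stim_time)
        feats.auc_early = auc(traj, stim_time, early_window, baseline=baseline)
        if late_window[1] > late_window[0]:
            feats.auc_late = auc(traj, stim_time, late_window, baseline=baseline)
        feats.peak_response = peak_response(traj, stim_time, peak_search_min)
    for t in cn_times:
        feats.cn_at[float(t)] = cn_at_time(traj, float(t))
    if on_threshold is not None or feats.n_pulses >= 2:
        feats.class_label = classify(feats, on_threshold)
    return feats


def summarize_population(
    features: list[TrajectoryFeatures] | dict[str, list[TrajectoryFeatures]],
) -> PopulationSummary:
    """Population-level bookkeeping across one or more conditions.

    Accepts either a flat feature list (treated as a single unnamed
    condition) or a mapping ``condition -> features``.  Class fractions
    within each condition sum to one; fold-changes of mean C/N are
    reported for every ordered condition pair.
    """
    if isinstance(features, dict):
        groups = features
    else:
        groups = {"all": list(features)}
    for cond, feats in groups.items():
        if not feats:
            raise ValueError(f"condition {cond!r} has no cells")

    n_cells: dict[str, int] = {}
    fractions: dict[str, dict[str, float]] = {}
    hist: dict[str, dict[int, int]] = {}
    mu: dict[str, float] = {}
    sd: dict[str, float] = {}
    for cond, feats in groups.items():
        n = len(feats)
        n_cells[cond] = n
        counts = {"on": 0, "pulsing": 0, "off": 0}
        h: dict[int, int] = {}
        for f in feats:
            if f.class_label is None:
                raise ValueError(f"cell {f.cell_id}: unclassified feature record")
            counts[f.class_label] += 1
            h[f.n_pulses] = h.get(f.n_pulses, 0) + 1
        fractions[cond] = {k: v / n for k, v in counts.items()}
        hist[cond] = dict(sorted(h.items()))
        vals = np.array([f.mean_cn for f in feats], dtype=float)
        mu[cond] = float(vals.mean())
        sd[cond] = float(vals.std(ddof=1)) if n > 1 else 0.0

    folds: dict[tuple[str, str], float] = {}
    conds = list(groups)
    for a in conds:
        for b in conds:
            if a != b:
                folds[(a, b)] = mu[a] / mu[b]
    return PopulationSummary(
        n_cells=n_cells,
        class_fractions=fractions,
        pulse_histogram=hist,
        mean_cn_mean=mu,
        mean_cn_sd=sd,
        fold_changes=folds,
    )
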