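"""TIFF and tabular I/O plus provenance records.

TIFF stacks are read and written with ``tifffile`` as multi-page files
(one page per z-slice or time frame), 16-bit unsigned; label masks as
16-bit label TIFFs.  Tabular data is plain CSV with a fixed column order
and '.' decimal separator so runs are diffable across tools.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .membrane2d import CellMask
from .puncta3d import ZStackImage
from .trajectories import IntensityTimeSeries, TrajectoryFeatures

__all__ = [
    "DataError",
    "ProvenanceRecord",
    "read_stack",
    "write_stack",
    "read_cell_mask",
    "write_cell_mask",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_features_csv",
    "write_heatmap_csv",
    "sha256_of",
]

TIMESERIES_COLUMNS = ["cell_id", "time_min", "nuclear_mean", "cytoplasmic_mean", "background"]
FEATURE_COLUMNS = ["condition", "cell_id", "mean_cn", "n_pulses", "auc_early",
                   "auc_late", "peak_response", "class_label"]


class DataError(ValueError):
    """Raised for unreadable or inconsistent input data."""


@dataclass
class ProvenanceRecord:
    """What a run did: version, config, inputs and applied thresholds.

    Every numeric decision made during a run — including data-derived
    ones such as Otsu threshold values — is recorded under ``applied``.
    """

    tool_version: str
    config_hash: str
    timestamp: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)
    applied: dict[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def sha256_of(obj) -> str:
    """SHA-256 of a file path's bytes or of a canonical-JSON-serializable object."""
    if isinstance(obj, (str, Path)) and Path(obj).is_file():
        return hashlib.sha256(Path(obj).read_bytes()).hexdigest()
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, axis_spec: str = "z", n_channels: int = 1):
    """Read a TIFF into one or more :class:`ZStackImage` objects.

    ``axis_spec`` declares the page ordering: ``"z"`` or ``"t"`` for a
    single-channel stack (pages are slices/frames), ``"cz"`` for
    channel-interleaved pages (page order c0z0, c1z0, ..., with
    ``n_channels`` channels).  A 2D TIFF becomes a 1-slice stack.  The
    round trip ``read_stack(write_stack(x))`` is bit-exact.
    """
    path = Path(path)
    if not path.is_file():
        raise DataError(f"no such TIFF: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile detail
        raise DataError(f"unreadable TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise DataError(f"{path}: expected 2D or 3D TIFF, got shape {arr.shape}")
    if axis_spec in ("z", "t"):
        if n_channels != 1:
            raise DataError(f"axis_spec {axis_spec!r} implies a single channel")
        return ZStackImage(arr, channel_name=path.stem)
    if axis_spec == "cz":
        if n_channels < 1 or arr.shape[0] % n_channels != 0:
            raise DataError(
                f"{path}: {arr.shape[0]} pages not divisible by {n_channels} channels"
            )
        return [
            ZStackImage(arr[c::n_channels], channel_name=f"{path.stem}_c{c}")
            for c in range(n_channels)
        ]
    raise DataError(f"unknown axis_spec {axis_spec!r} (use 'z', 't' or 'cz')")


def write_stack(path: str | Path, stack: ZStackImage | np.ndarray) -> Path:
    """Write a stack as a multi-page 16-bit unsigned TIFF."""
    arr = stack.voxels if isinstance(stack, ZStackImage) else np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.dtype != np.uint16:
        if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
            raise DataError("stack values outside uint16 range; rescale before writing")
        arr = arr.astype(np.uint16)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def read_cell_mask(path: str | Path) -> CellMask:
    """Read a 2D integer label TIFF (CellPose-compatible)."""
    path = Path(path)
    if not path.is_file():
        raise DataError(f"no such mask TIFF: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise DataError(f"{path}: cell mask must be 2D, got shape {arr.shape}")
    return CellMask(arr.astype(np.int64), provenance=str(path))


def write_cell_mask(path: str | Path, mask: CellMask) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    return path


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_timeseries_csv(path: str | Path) -> list[IntensityTimeSeries]:
    """Read per-cell intensity time series from a long-format CSV.

    Expected columns: ``cell_id, time_min, nuclear_mean, cytoplasmic_mean,
    background``.
    """
    path = Path(path)
    if not path.is_file():
        raise DataError(f"no such CSV: {path}")
    df = pd.read_csv(path)
    missing = set(TIMESERIES_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        out.append(IntensityTimeSeries(
            cell_id=str(cell_id),
            times=grp["time_min"].to_numpy(float),
            nuclear_mean=grp["nuclear_mean"].to_numpy(float),
            cytoplasmic_mean=grp["cytoplasmic_mean"].to_numpy(float),
            background=grp["background"].to_numpy(float),
        ))
    if not out:
        raise DataError(f"{path}: no cells found")
    return out


def write_timeseries_csv(path: str | Path, series: list[IntensityTimeSeries]) -> Path:
    rows = []
    for s in series:
        bg = s.background_per_frame
        for i in range(len(s.times)):
            rows.append((s.cell_id, s.times[i], s.nuclear_mean[i],
                         s.cytoplasmic_mean[i], bg[i]))
    df = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_features_csv(path: str | Path, features: list[TrajectoryFeatures]) -> Path:
    rows = [
        {
            "condition": f.condition or "",
            "cell_id": f.cell_id,
            "mean_cn": f.mean_cn,
            "n_pulses": f.n_pulses,
            "auc_early": f.auc_early if f.auc_early is not None else "",
            "auc_late": f.auc_late if f.auc_late is not None else "",
            "peak_response": f.peak_response if f.peak_response is not None else "",
            "class_label": f.class_label or "",
        }
        for f in features
    ]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_heatmap_csv(path: str | Path, trajectories, order_by: str = "mean") -> Path:
    """Write a cells x frames C/N matrix CSV, rows ordered for heatmaps.

    Rows (cells) are ordered by descending time-averaged C/N, the layout
    used for stacked single-cell activity heatmaps.
    """
    trajs = sorted(trajectories, key=lambda t: -float(np.mean(t.cn)))
    times = trajs[0].times
    data = {t.cell_id: t.cn for t in trajs}
    df = pd.DataFrame.from_dict(data, orient="index",
                                columns=[f"t{tm:g}" for tm in times])
    df.index.name = "cell_id"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path)
    return path
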