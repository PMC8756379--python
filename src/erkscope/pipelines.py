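"""End-to-end pipelines chaining the analysis stages.

Each pipeline executes its stages in the fixed scientific order
(smoothing before pulse detection; projection before preprocessing;
background subtraction before thresholding), writes deterministic CSV
payloads plus a provenance JSON, and funnels all randomness through one
top-level seed.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, membrane2d, puncta3d, synthetic, trajectories as tj

__all__ = ["ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


_KNOWN_KEYS: dict[str, set[str]] = {
    "simulate": {"pipeline", "out_dir", "seed", "kind", "preset", "n_cells",
                 "n_frames", "regime", "stim_frame", "noise_cv", "condition",
                 "puncta_per_cell", "n_cells_image", "shape_zyx",
                 "contact_exclusion", "double_positive_fraction"},
    "ktr": {"pipeline", "out_dir", "seed", "input_csv", "threshold", "mode",
            "stim_time", "early_window", "late_window", "on_threshold",
            "cn_times", "condition"},
    "puncta3d": {"pipeline", "out_dir", "seed", "egf_tiff", "egfr_tiff",
                 "nuclei_tiff", "sigma", "threshold_method", "threshold_value",
                 "min_size", "max_size", "min_overlap", "n_nuclei", "condition"},
    "membrane": {"pipeline", "out_dir", "seed", "egf_tiff", "mask_tiff",
                 "ball_radius", "gaussian_sigma", "threshold_method",
                 "threshold_value", "min_area", "max_area", "assignment",
                 "max_distance", "condition"},
}


def _validate(config: dict) -> str:
    pipeline = config.get("pipeline")
    if pipeline not in _KNOWN_KEYS:
        raise ConfigError(f"unknown pipeline {pipeline!r}; choose from {sorted(_KNOWN_KEYS)}")
    unknown = set(config) - _KNOWN_KEYS[pipeline]
    if unknown:
        raise ConfigError(f"unknown config keys for {pipeline}: {sorted(unknown)}")
    if "out_dir" not in config:
        raise ConfigError("out_dir is required")
    return pipeline


def run_pipeline(config: dict) -> io.ProvenanceRecord:
    """Run one pipeline from a flat config dict.

    ``config["pipeline"]`` selects ``simulate | ktr | puncta3d | membrane``.
    Unknown keys are rejected.  Returns the provenance record, which is
    also written as ``provenance.json`` in the output directory; result
    CSV payloads are bitwise-deterministic for identical config + inputs.
    """
    pipeline = _validate(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = io.ProvenanceRecord(
        tool_version=__version__,
        config_hash=io.sha256_of({k: v for k, v in config.items() if k != "out_dir"}),
    )
    prov.applied["pipeline"] = pipeline
    for key, val in sorted(config.items()):
        if key not in ("pipeline", "out_dir"):
            prov.applied[f"config.{key}"] = str(val)
    runner = {"simulate": _run_simulate, "ktr": _run_ktr,
              "puncta3d": _run_puncta3d, "membrane": _run_membrane}[pipeline]
    runner(config, out_dir, prov)
    prov.write(out_dir / "provenance.json")
    return prov


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def _run_simulate(config: dict, out_dir: Path, prov: io.ProvenanceRecord) -> None:
    kind = config.get("kind", "trajectories")
    seed = int(config.get("seed", 0))
    if kind == "trajectories":
        preset = config.get("preset")
        if preset is not None:
            if preset not in synthetic.TRAJECTORY_PRESETS:
                raise ConfigError(f"unknown preset {preset!r}")
            gen_cfg = synthetic.TRAJECTORY_PRESETS[preset]
        else:
            gen_cfg = synthetic.TrajectoryGenConfig()
        overrides = {k: config[k] for k in
                     ("n_cells", "n_frames", "regime", "stim_frame", "noise_cv")
                     if k in config}
        gen_cfg = replace(gen_cfg, seed=seed, **overrides)
        trajs, gt = synthetic.generate_trajectories(gen_cfg)
        # emit as a measurement-style intensity CSV (nuclear fixed at 1000 AU)
        series = [
            tj.IntensityTimeSeries(
                cell_id=t.cell_id, times=t.times,
                nuclear_mean=np.full(len(t), 1000.0),
                cytoplasmic_mean=t.cn * 1000.0,
                background=0.0,
            )
            for t in trajs
        ]
        io.write_timeseries_csv(out_dir / "timeseries.csv", series)
        rows = [
            {"cell_id": cid, "pulse_frame": int(f), "pulse_time_min": float(tm)}
            for cid in sorted(gt.pulse_frames)
            for f, tm in zip(gt.pulse_frames[cid], gt.pulse_times[cid])
        ]
        pd.DataFrame(rows, columns=["cell_id", "pulse_frame", "pulse_time_min"]).to_csv(
            out_dir / "ground_truth_pulses.csv", index=False)
        prov.applied["generator.regime"] = gen_cfg.regime
        prov.applied["generator.seed"] = seed
    elif kind in ("zstack", "membrane"):
        img_cfg = synthetic.ImageGenConfig(
            seed=seed,
            n_cells=int(config.get("n_cells_image", 4)),
            puncta_per_cell=float(config.get("puncta_per_cell", 5.0)),
            shape_zyx=tuple(config.get("shape_zyx", (16, 256, 256))),
            contact_exclusion=bool(config.get("contact_exclusion", False)),
            double_positive_fraction=float(config.get("double_positive_fraction", 0.5)),
        )
        if kind == "zstack":
            channels, mask, gt = synthetic.generate_zstack(img_cfg)
            for name, stack in channels.items():
                io.write_stack(out_dir / f"{name}.tif", stack)
        else:
            channels, mask, gt = synthetic.generate_membrane_scene(img_cfg)
            io.write_stack(out_dir / "egf.tif", channels["egf"][None])
        io.write_cell_mask(out_dir / "mask.tif", mask)
        rows = [
            {"object_id": o.object_id, "cell_id": o.cell_id, "size_px": o.size_px,
             "centroid": ";".join(f"{c:g}" for c in o.centroid),
             "egf_positive": o.egf_positive, "egfr_positive": o.egfr_positive}
            for o in gt.objects
        ]
        pd.DataFrame(rows, columns=["object_id", "cell_id", "size_px", "centroid",
                                    "egf_positive", "egfr_positive"]).to_csv(
            out_dir / "ground_truth_objects.csv", index=False)
        prov.applied["generator.seed"] = seed
    else:
        raise ConfigError(f"unknown simulate kind {kind!r}")


# ---------------------------------------------------------------------------
# ktr
# ---------------------------------------------------------------------------

def _run_ktr(config: dict, out_dir: Path, prov: io.ProvenanceRecord) -> None:
    if "input_csv" not in config:
        raise ConfigError("ktr pipeline needs input_csv")
    path = config["input_csv"]
    series = io.read_timeseries_csv(path)
    prov.input_checksums[str(path)] = io.sha256_of(path)
    threshold = float(config.get("threshold", tj.DEFAULT_PULSE_THRESHOLD))
    mode = config.get("mode", "smaller")
    stim_time = config.get("stim_time")
    on_threshold = config.get("on_threshold")
    early = tuple(config.get("early_window", (0.0, 60.0)))
    late = tuple(config["late_window"]) if "late_window" in config else None
    condition = config.get("condition", "")

    feats, smoothed_trajs = [], []
    for s in series:
        traj = tj.smooth(tj.compute_cn(s))
        smoothed_trajs.append(traj)
        pulses = tj.detect_pulses(traj, threshold=threshold, mode=mode)
        feats.append(tj.compute_features(
            traj, pulses=pulses,
            stim_time=float(stim_time) if stim_time is not None else None,
            early_window=early, late_window=late,
            cn_times=tuple(config.get("cn_times", ())),
            on_threshold=float(on_threshold) if on_threshold is not None else None,
            condition=condition,
        ))
    io.write_features_csv(out_dir / "features.csv", feats)
    io.write_heatmap_csv(out_dir / "heatmap.csv", smoothed_trajs)
    prov.applied["pulse.threshold"] = threshold
    prov.applied["pulse.mode"] = mode
    if on_threshold is not None:
        prov.applied["classify.on_threshold"] = float(on_threshold)
        summary = tj.summarize_population({condition or "all": feats})
        rows = [
            {"condition": cond, "n_cells": summary.n_cells[cond],
             "frac_on": summary.class_fractions[cond]["on"],
             "frac_pulsing": summary.class_fractions[cond]["pulsing"],
             "frac_off": summary.class_fractions[cond]["off"],
             "mean_cn_mean": summary.mean_cn_mean[cond],
             "mean_cn_sd": summary.mean_cn_sd[cond]}
            for cond in summary.n_cells
        ]
        pd.DataFrame(rows).to_csv(out_dir / "population.csv", index=False)


# ---------------------------------------------------------------------------
# puncta3d
# ---------------------------------------------------------------------------

def _run_puncta3d(config: dict, out_dir: Path, prov: io.ProvenanceRecord) -> None:
    if "egf_tiff" not in config:
        raise ConfigError("puncta3d pipeline needs egf_tiff")
    sigma = float(config.get("sigma", puncta3d.DEFAULT_SIGMA_PX))
    method = config.get("threshold_method", "otsu")
    value = config.get("threshold_value")
    min_size = int(config.get("min_size", puncta3d.DEFAULT_MIN_SIZE))
    max_size = int(config.get("max_size", puncta3d.DEFAULT_MAX_SIZE))

    egf = io.read_stack(config["egf_tiff"])
    prov.input_checksums[str(config["egf_tiff"])] = io.sha256_of(config["egf_tiff"])
    sub = puncta3d.subtract_background_gaussian(egf, sigma)
    mask, thr = puncta3d.threshold_intensity(sub, method=method, value=value)
    prov.applied["egf.threshold"] = thr
    puncta = puncta3d.label_objects_3d(mask)
    puncta = puncta3d.filter_by_size(puncta, min_size, max_size)

    if "egfr_tiff" in config:
        egfr = io.read_stack(config["egfr_tiff"])
        prov.input_checksums[str(config["egfr_tiff"])] = io.sha256_of(config["egfr_tiff"])
        sub_b = puncta3d.subtract_background_gaussian(egfr, sigma)
        mask_b, thr_b = puncta3d.threshold_intensity(sub_b, method=method, value=value)
        prov.applied["egfr.threshold"] = thr_b
        puncta = puncta3d.filter_double_positive(
            puncta, mask_b, min_overlap=float(config.get("min_overlap", 0.0)))

    n_nuclei = config.get("n_nuclei")
    hoechst = io.read_stack(config["nuclei_tiff"]) if "nuclei_tiff" in config else None
    n = puncta3d.count_nuclei(hoechst, explicit_count=n_nuclei)
    if n < 1:
        raise io.DataError("no nuclei counted; pass n_nuclei explicitly")
    result = puncta3d.quantify_internalization(puncta, n,
                                               condition=config.get("condition", ""))
    prov.applied["n_nuclei"] = n

    rows = [
        {"object_id": o.id, "voxel_count": o.voxel_count,
         "centroid_z": o.centroid[0], "centroid_y": o.centroid[1],
         "centroid_x": o.centroid[2],
         "double_positive": o.flags.get("double_positive", False)}
        for o in puncta.objects
    ]
    pd.DataFrame(rows, columns=["object_id", "voxel_count", "centroid_z",
                                "centroid_y", "centroid_x", "double_positive"]).to_csv(
        out_dir / "puncta.csv", index=False)
    pd.DataFrame([{
        "condition": result.condition, "total_volume": result.total_volume,
        "n_nuclei": result.n_nuclei, "normalized_volume": result.normalized_volume,
    }]).to_csv(out_dir / "internalization.csv", index=False)


# ---------------------------------------------------------------------------
# membrane
# ---------------------------------------------------------------------------

def _run_membrane(config: dict, out_dir: Path, prov: io.ProvenanceRecord) -> None:
    for key in ("egf_tiff", "mask_tiff"):
        if key not in config:
            raise ConfigError(f"membrane pipeline needs {key}")
    stack = io.read_stack(config["egf_tiff"])
    mask = io.read_cell_mask(config["mask_tiff"])
    for key in ("egf_tiff", "mask_tiff"):
        prov.input_checksums[str(config[key])] = io.sha256_of(config[key])

    proj = membrane2d.max_project(stack)
    pre = membrane2d.preprocess(
        proj,
        rolling_ball_radius=float(config.get("ball_radius", membrane2d.DEFAULT_BALL_RADIUS)),
        gaussian_sigma=float(config.get("gaussian_sigma", membrane2d.DEFAULT_GAUSSIAN_SIGMA)),
    )
    puncta = membrane2d.detect_puncta_2d(
        pre,
        method=config.get("threshold_method", "otsu"),
        value=config.get("threshold_value"),
        min_area=int(config.get("min_area", membrane2d.DEFAULT_MIN_AREA)),
        max_area=int(config.get("max_area", membrane2d.DEFAULT_MAX_AREA)),
    )
    prov.applied["egf.threshold"] = puncta.thresholds["intensity"]
    result = membrane2d.per_cell_area(
        puncta, mask,
        assignment=config.get("assignment", "centroid"),
        max_distance=float(config.get("max_distance", 10.0)),
    )
    result.condition = config.get("condition", "")
    prov.applied["n_dropped_objects"] = result.n_dropped

    rows = [
        {"condition": result.condition, "cell_id": k,
         "puncta_area_px2": result.per_cell_area[k], "cell_area_px2": mask.area_of(k)}
        for k in sorted(result.per_cell_area)
    ]
    pd.DataFrame(rows, columns=["condition", "cell_id", "puncta_area_px2",
                                "cell_area_px2"]).to_csv(
        out_dir / "per_cell_area.csv", index=False)
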