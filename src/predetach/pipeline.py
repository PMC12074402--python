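"""End-to-end pipeline: ingest frames, QC, detect, track, analyse, report.

Artifacts are written stage by stage under the configured output
directory; a stage whose artifact already exists is skipped, so a run is
resumable and deleting an intermediate reproduces it identically (all
stages are deterministic given the inputs, config and seed).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import detections, events, imaging, kinematics

log = logging.getLogger("predetach")

FRAME_PATTERNS = ("*.png", "*.tif", "*.tiff")

DEFAULT_CONFIG: dict = {
    "io": {"input_dir": None, "output_dir": None, "table_path": None,
           "ground_truth": None},
    "seed": 0,
    "imaging_qc": {
        "blur_threshold": imaging.DEFAULT_BLUR_THRESHOLD,
        "unsharp_amount": 1.0,
        "unsharp_radius": 2.0,
        "noise_trigger": imaging.DEFAULT_NOISE_TRIGGER,
        "median_kernel": 3,
        "clahe_clip": 2.0,
        "clahe_grid": [8, 8],
        "contrast_skip": imaging.DEFAULT_CONTRAST_SKIP,
        "morph_radius": 1,
    },
    "detector": {"min_area": 30.0},
    "association": {"gate": detections.DEFAULT_GATE,
                    "persistence_gap": detections.DEFAULT_PERSISTENCE_GAP},
    "events": {
        "detach_displacement_threshold": 87.5,
        "reappearance_horizon": 10,
        "tube_distance_threshold": 90.0,
        "tube_stability_window": 10,
        "tube_stability_tolerance": 2.0,
        "calm_threshold": kinematics.DEFAULT_CALM_THRESHOLD,
        "min_calm_length": kinematics.DEFAULT_MIN_LENGTH,
        "oscillation_window": kinematics.DEFAULT_OSC_WINDOW,
    },
    "metrics": {"iou_threshold": 0.5},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML file <- overrides (flag > file > default)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            _deep_update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def qc_config(cfg: dict) -> imaging.QCConfig:
    q = cfg["imaging_qc"]
    return imaging.QCConfig(
        blur_threshold=q["blur_threshold"], unsharp_amount=q["unsharp_amount"],
        unsharp_radius=q["unsharp_radius"], noise_trigger=q["noise_trigger"],
        median_kernel=q["median_kernel"], clahe_clip=q["clahe_clip"],
        clahe_grid=tuple(q["clahe_grid"]), contrast_skip=q["contrast_skip"],
        morph_radius=q["morph_radius"])


def detector_config(cfg: dict) -> events.DetectorConfig:
    return events.DetectorConfig(**cfg["events"])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def ingest_frames(input_dir) -> list[Path]:
    """List frame files (PNG/TIFF) in lexicographic order."""
    input_dir = Path(input_dir) if input_dir is not None else None
    if input_dir is None or not input_dir.is_dir():
        raise PipelineError(f"ingestion: input directory not found: {input_dir}")
    paths: list[Path] = []
    for pat in FRAME_PATTERNS:
        paths.extend(input_dir.glob(pat))
    paths = sorted(set(paths))
    if not paths:
        raise PipelineError(f"ingestion: no frames matching {FRAME_PATTERNS} "
                            f"in {input_dir}")
    return paths


def preprocess_stage(frame_paths: list[Path], out_dir: Path, cfg: dict) -> Path:
    """QC every frame; writes preprocessed PNGs plus a quality table."""
    pre_dir = out_dir / "preprocessed"
    quality_path = out_dir / "quality.csv"
    if quality_path.exists() and pre_dir.is_dir() and \
            len(list(pre_dir.glob("*.png"))) == len(frame_paths):
        log.info("preprocess: artifact exists, skipping")
        return pre_dir
    pre_dir.mkdir(parents=True, exist_ok=True)
    config = qc_config(cfg)
    rows = []
    for i, path in enumerate(frame_paths):
        frame = np.asarray(iio.imread(path))[..., :3]
        out, report = imaging.preprocess(frame, config)
        iio.imwrite(pre_dir / f"frame_{i:05d}.png", out)
        rows.append({
            "frame_index": i,
            "laplacian_variance_L": report.laplacian_variance_L,
            "is_blurred": report.is_blurred,
            "extreme_fraction_max": max(report.extreme_pixel_fraction),
            "contrast_score": report.contrast_score,
            "applied_steps": "|".join(report.applied_steps),
        })
    pd.DataFrame(rows).to_csv(quality_path, index=False)
    log.info("preprocess: %d frames", len(rows))
    return pre_dir


def detect_stage(pre_dir: Path, out_dir: Path, cfg: dict) -> Path:
    """Detect and track objects; writes the detection table."""
    table_path = out_dir / "detections.csv"
    if table_path.exists():
        log.info("detect: artifact exists, skipping")
        return table_path
    frame_paths = sorted(pre_dir.glob("*.png"))
    per_frame = []
    for i, path in enumerate(frame_paths):
        frame = np.asarray(iio.imread(path))[..., :3]
        per_frame.append(detections.detect_objects(
            frame, min_area=cfg["detector"]["min_area"], frame_index=i))
    table = detections.associate_ids(
        per_frame, gate=cfg["association"]["gate"],
        persistence_gap=cfg["association"]["persistence_gap"])
    detections.write_table(table, table_path)
    log.info("detect: %d records over %d frames", len(table), len(frame_paths))
    return table_path


def analyze_stage(table_path: Path, out_dir: Path, cfg: dict,
                  n_frames: int | None = None) -> dict:
    """Kinematic series, interval labels and the event report."""
    table = detections.read_table(table_path)
    trajs = detections.trajectories_from_table(table, n_frames=n_frames)
    config = detector_config(cfg)
    reports, summary = events.build_event_report(trajs, config)

    series_dir = out_dir / "series"
    series_dir.mkdir(parents=True, exist_ok=True)
    interval_rows = []
    for obj_id in sorted(trajs):
        traj = trajs[obj_id]
        df = pd.DataFrame({"diagonal": kinematics.diagonal_series(traj)})
        df["displacement"] = kinematics.displacement_series(traj)
        df["oscillation_score"] = kinematics.oscillation_series(
            traj, config.oscillation_window)
        df.to_csv(series_dir / f"object_{obj_id}.csv")
        score = kinematics.oscillation_series(traj, config.oscillation_window)
        for iv in kinematics.segment_intervals(score, config.calm_threshold,
                                               config.min_calm_length,
                                               object_id=obj_id):
            interval_rows.append({"object_id": obj_id, "kind": iv.kind,
                                  "start": iv.start, "end": iv.end})
    pd.DataFrame(interval_rows).to_csv(out_dir / "intervals.csv", index=False)

    report_rows = events.reports_to_frame(reports)
    report_rows.to_csv(out_dir / "report.csv", index=False)
    payload = {
        "summary": summary,
        "events": [{
            "object_id": r.object_id,
            "object_class": r.object_class,
            "status": r.status,
            "detachment_frame": r.detachment_frame,
            "pre_detachment_frame": r.pre_detachment_frame,
            "tube_cell_distance_at_event": r.tube_cell_distance_at_event,
            "is_suspect": r.is_suspect,
        } for r in reports],
    }
    with open(out_dir / "report.yaml", "w") as fh:
        yaml.safe_dump(_to_plain(payload), fh, sort_keys=False)
    log.info("analyze: %d objects, suspect=%s, detached=%s",
             summary["n_objects"], summary["suspect_id"], summary["detached_ids"])
    return {"reports": reports, "summary": summary, "trajectories": trajs}


def evaluate_stage(table_path: Path, ground_truth_path, out_dir: Path,
                   cfg: dict) -> dict | None:
    """Score tracked detections against a ground-truth table (IoU matching)."""
    from . import metrics as m

    if ground_truth_path is None:
        return None
    pred = detections.read_table(table_path)
    gt = detections.read_table(ground_truth_path)

    def by_class(df, scored):
        out: dict[str, list] = {}
        for _, r in df.iterrows():
            cls = "tube" if str(r["object_name"]).startswith("tube") else "cell"
            box = (r["x"], r["y"], r["width"], r["height"])
            item = (int(r["frame_index"]), box, 1.0) if scored \
                else (int(r["frame_index"]), box)
            out.setdefault(cls, []).append(item)
        return out

    preds, gts = by_class(pred, True), by_class(gt, False)
    thr = cfg["metrics"]["iou_threshold"]
    aps = {cls: m.average_precision(preds.get(cls, []), gts.get(cls, []), thr)
           for cls in sorted(set(preds) | set(gts))}
    result = {
        "ap_per_class": aps,
        "map": m.mean_ap(aps),
        "map_range": m.map_range(preds, gts),
    }
    with open(out_dir / "metrics.yaml", "w") as fh:
        yaml.safe_dump(_to_plain(result), fh, sort_keys=False)
    log.info("evaluate: mAP@%.2f=%.3f", thr, result["map"])
    return result


def plot_series(trajectories, reports, out_dir, config=None) -> dict:
    """Per-object motion plots plus a 2-D trajectory plot.

    Returns the created file paths and the event markers drawn, keyed by
    object id.  With no trajectories, nothing is drawn.
    """
    out_dir = Path(out_dir)
    if not trajectories:
        log.warning("plot: empty table, no plots produced")
        return {"files": [], "markers": {}}
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = events.DetectorConfig()
    by_id = {r.object_id: r for r in reports} if reports else {}
    files, markers = [], {}
    for obj_id in sorted(trajectories):
        traj = trajectories[obj_id]
        fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
        diag = kinematics.diagonal_series(traj)
        disp = kinematics.displacement_series(traj)
        axes[0].plot(diag.index, diag.values, lw=1)
        axes[0].set_ylabel("diagonal (px)")
        axes[1].plot(disp.index, disp.values, lw=1, color="tab:orange")
        axes[1].set_ylabel("displacement (px/frame)")
        axes[1].set_xlabel("frame")
        report = by_id.get(obj_id)
        drawn = {}
        if report is not None:
            if report.detachment_frame is not None:
                for ax in axes:
                    ax.axvline(report.detachment_frame, color="red", ls="--", lw=1)
                drawn["detachment"] = report.detachment_frame
            if report.pre_detachment_frame is not None:
                for ax in axes:
                    ax.axvline(report.pre_detachment_frame, color="green",
                               ls=":", lw=1)
                drawn["pre_detachment"] = report.pre_detachment_frame
        markers[obj_id] = drawn
        fig.suptitle(f"{traj.object_class} {obj_id}")
        path = out_dir / f"series_object_{obj_id}.png"
        fig.savefig(path, dpi=90)
        plt.close(fig)
        files.append(path)

    fig, ax = plt.subplots(figsize=(6, 6))
    for obj_id in sorted(trajectories):
        traj = trajectories[obj_id]
        ax.plot(traj.centers[:, 0], traj.centers[:, 1], lw=1,
                label=f"{traj.object_class} {obj_id}")
    ax.invert_yaxis()  # image coordinates
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.legend(fontsize=7)
    path = out_dir / "trajectories_2d.png"
    fig.savefig(path, dpi=90)
    plt.close(fig)
    files.append(path)
    return {"files": files, "markers": markers}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, make_plots: bool = True) -> dict:
    """Run every stage in order; returns the in-memory analysis artifacts."""
    cfg = _deep_update(default_config(), config)
    out_dir = Path(cfg["io"]["output_dir"] or "predetach_out")
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("run: config hash %s, seed %s", _config_hash(cfg), cfg["seed"])

    frame_paths = ingest_frames(cfg["io"]["input_dir"])
    pre_dir = preprocess_stage(frame_paths, out_dir, cfg)
    table_path = detect_stage(pre_dir, out_dir, cfg)
    analysis = analyze_stage(table_path, out_dir, cfg,
                             n_frames=len(frame_paths))
    metrics_result = evaluate_stage(table_path, cfg["io"].get("ground_truth"),
                                    out_dir, cfg)
    plots = None
    if make_plots:
        plots = plot_series(analysis["trajectories"], analysis["reports"],
                            out_dir / "plots", detector_config(cfg))
    return {**analysis, "metrics": metrics_result, "plots": plots,
            "output_dir": out_dir, "table_path": table_path}


def _to_plain(obj):
    """Recursively convert numpy scalars for YAML serialisation."""
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
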