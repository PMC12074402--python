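"""Per-frame object tables: CSV contract, reference detector, id association.

The canonical on-disk artifact of the whole pipeline is a flat table with
one row per (frame, object): frame index, stable object id, class-tagged
name, bounding box (left, top, width, height) and its centre, all in
pixels.  Any external segmentation model can feed the analysis stages by
exporting this schema; a simple intensity-based detector is provided so
synthetic scenes run end to end without a trained model.

Coordinate convention: 0-based pixel indices, bbox given as
(left, top, width, height); centres are ``left + width/2`` and may be
half-integers.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2lab
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .kinematics import CELL, TUBE, Trajectory

COLUMNS = [
    "frame_index", "object_id", "object_name",
    "x", "y", "width", "height", "x_center", "y_center",
]

#: aspect ratio above which the most elongated component is classed as the tube
TUBE_ASPECT_RATIO = 2.5
#: default association gate (px); chosen below the detachment band (85-90 px)
#: so a detachment jump breaks the track rather than being smoothed over
DEFAULT_GATE = 50.0
#: frames a track may go unseen before it is closed
DEFAULT_PERSISTENCE_GAP = 5
#: minimum foreground/background lightness separation for a detection pass
MIN_SEPARATION = 40.0


class SchemaError(ValueError):
    """A detection table violates the CSV contract."""


# ---------------------------------------------------------------------------
# table contract
# ---------------------------------------------------------------------------

def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a detection table.

    Returns a copy sorted by (frame_index, object_id) with canonical
    dtypes.  Raises :class:`SchemaError` naming the offending column/row.
    """
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = table.loc[:, COLUMNS].copy()
    for col in ("frame_index", "object_id", "x", "y", "width", "height",
                "x_center", "y_center"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or numeric.isna().any():
            row = int(df.index[numeric.isna()][0])
            raise SchemaError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = numeric
    df["frame_index"] = df["frame_index"].astype(int)
    df["object_id"] = df["object_id"].astype(int)
    if (df["frame_index"] < 0).any():
        row = int(df.index[df["frame_index"] < 0][0])
        raise SchemaError(f"negative frame_index at row {row}")
    bad_size = (df["width"] <= 0) | (df["height"] <= 0)
    if bad_size.any():
        row = int(df.index[bad_size][0])
        raise SchemaError(f"non-positive bbox size at row {row}")
    for axis in ("x", "y"):
        expect = df[axis] + df[f"{'width' if axis == 'x' else 'height'}"] / 2
        off = ~np.isclose(expect, df[f"{axis}_center"], atol=1e-6)
        if off.any():
            row = int(df.index[off][0])
            raise SchemaError(f"{axis}_center inconsistent with bbox at row {row}")
    dup = df.duplicated(subset=["frame_index", "object_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise SchemaError(f"duplicate (frame_index, object_id) at row {row}")
    return df.sort_values(["frame_index", "object_id"], kind="stable").reset_index(drop=True)


def read_table(path) -> pd.DataFrame:
    """Read and validate a detection table from CSV."""
    return validate_table(pd.read_csv(path))


def write_table(table: pd.DataFrame, path) -> None:
    """Validate and write a detection table as UTF-8 comma CSV.

    Floats are written with shortest-repr formatting, so a write/read
    round trip reproduces every field exactly.
    """
    validate_table(table).to_csv(path, index=False)


def empty_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        COLUMNS, [int, int, str, float, float, float, float, float, float])})
    return df


def records_to_table(records: Iterable[Mapping]) -> pd.DataFrame:
    rows = list(records)
    if not rows:
        return empty_table()
    return validate_table(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# trajectories <-> tables
# ---------------------------------------------------------------------------

def table_from_trajectories(trajectories: Mapping[int, Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into the detection-table schema (one row per
    present object-frame)."""
    rows = []
    for obj_id in sorted(trajectories):
        traj = trajectories[obj_id]
        for f, (cx, cy), (w, h) in zip(traj.frames, traj.centers, traj.bboxes):
            rows.append({
                "frame_index": int(f), "object_id": int(obj_id),
                "object_name": f"{traj.object_class}{obj_id}",
                "x": cx - w / 2, "y": cy - h / 2,
                "width": w, "height": h, "x_center": cx, "y_center": cy,
            })
    return records_to_table(rows)


def trajectories_from_table(table: pd.DataFrame,
                            n_frames: int | None = None) -> dict[int, Trajectory]:
    """Group a detection table into per-object trajectories.

    The object class is recovered from the ``object_name`` prefix
    ("tube..." or "cell...").
    """
    df = validate_table(table)
    if n_frames is None:
        n_frames = int(df["frame_index"].max()) + 1 if len(df) else 0
    out: dict[int, Trajectory] = {}
    for obj_id, grp in df.groupby("object_id", sort=True):
        name = str(grp["object_name"].iloc[0])
        cls = TUBE if name.startswith(TUBE) else CELL
        out[int(obj_id)] = Trajectory(
            object_id=int(obj_id),
            object_class=cls,
            frames=grp["frame_index"].to_numpy(),
            centers=grp[["x_center", "y_center"]].to_numpy(),
            bboxes=grp[["width", "height"]].to_numpy(),
            n_frames=n_frames,
        )
    return out


# ---------------------------------------------------------------------------
# reference detector
# ---------------------------------------------------------------------------

def detect_objects(frame: np.ndarray, min_area: float = 30.0,
                   frame_index: int = 0) -> list[dict]:
    """Intensity-based reference detector for rendered scenes.

    Otsu-thresholds the Lab lightness channel, labels connected
    components, and keeps components of at least ``min_area`` px**2.  The
    single most elongated component is classed as the tube when its
    bounding-box aspect ratio exceeds :data:`TUBE_ASPECT_RATIO`; all other
    components are cells.  Object ids are left unassigned (-1).

    Touching objects merge into one component — a known limitation of
    connectivity-based detection; the tracker and event rules operate on
    whatever the detector reports.
    """
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise TypeError("expected an RGB frame (H, W, 3)")
    L = rgb2lab(frame.astype(np.float64) / 255.0)[..., 0] * 2.55
    if np.ptp(L) < 1e-9:
        return []
    # background dominates the area, so its level is the median; Otsu alone
    # can split inside the background texture when objects are small
    background = float(np.median(L))
    thr = max(threshold_otsu(L), background + MIN_SEPARATION / 2)
    mask = L > thr
    if not mask.any() or mask.all():
        return []
    lab = label(mask)
    records = []
    for region in regionprops(lab):
        if region.area < min_area:
            continue
        if L[tuple(region.coords.T)].mean() - background < MIN_SEPARATION:
            continue
        minr, minc, maxr, maxc = region.bbox
        w, h = float(maxc - minc), float(maxr - minr)
        records.append({
            "frame_index": int(frame_index), "object_id": -1,
            "object_name": CELL,
            "x": float(minc), "y": float(minr), "width": w, "height": h,
            "x_center": minc + w / 2, "y_center": minr + h / 2,
            "_aspect": max(w, h) / min(w, h),
        })
    if records:
        best = max(range(len(records)), key=lambda i: records[i]["_aspect"])
        if records[best]["_aspect"] > TUBE_ASPECT_RATIO:
            records[best]["object_name"] = TUBE
    for r in records:
        del r["_aspect"]
    return records


# ---------------------------------------------------------------------------
# id association
# ---------------------------------------------------------------------------

def associate_ids(per_frame: Sequence[Sequence[Mapping]] | pd.DataFrame,
                  gate: float = DEFAULT_GATE,
                  persistence_gap: int = DEFAULT_PERSISTENCE_GAP) -> pd.DataFrame:
    """Assign stable object ids across frames by greedy nearest-centroid
    matching.

    A detection joins the open track whose last centroid is nearest,
    provided the distance is within ``gate`` px; candidate pairs are
    taken in order of ascending distance (ties: smallest track id).
    Unmatched detections start new tracks; tracks unseen for more than
    ``persistence_gap`` frames are closed and their ids never reused.

    ``per_frame`` is either a list of per-frame record lists (ids
    ignored) or a detection table whose rows are grouped by frame.
    """
    if isinstance(per_frame, pd.DataFrame):
        df = per_frame
        frames = sorted(df["frame_index"].unique())
        per_frame = [df[df["frame_index"] == f].to_dict("records") for f in frames]

    tracks: dict[int, dict] = {}  # id -> {center, last_frame, class}
    next_id = 0
    out_rows = []
    for dets in per_frame:
        dets = list(dets)
        if not dets:
            continue
        frame = int(dets[0]["frame_index"])
        open_ids = [tid for tid, t in tracks.items()
                    if frame - t["last_frame"] <= persistence_gap]
        # candidate (distance, track_id, det_idx) pairs within the gate
        pairs = []
        for tid in open_ids:
            tc = tracks[tid]["center"]
            for di, d in enumerate(dets):
                dist = float(np.hypot(d["x_center"] - tc[0], d["y_center"] - tc[1]))
                if dist <= gate:
                    pairs.append((dist, tid, di))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        assigned: dict[int, int] = {}
        for dist, tid, di in pairs:
            if tid in used_tracks or di in assigned:
                continue
            used_tracks.add(tid)
            assigned[di] = tid
        for di, d in enumerate(dets):
            if di in assigned:
                tid = assigned[di]
            else:
                tid = next_id
                next_id += 1
                name = str(d.get("object_name", CELL))
                cls = TUBE if name.startswith(TUBE) else CELL
                tracks[tid] = {"center": None, "last_frame": frame, "class": cls}
            tracks[tid]["center"] = (float(d["x_center"]), float(d["y_center"]))
            tracks[tid]["last_frame"] = frame
            row = {k: v for k, v in d.items() if k in COLUMNS}
            row["object_id"] = tid
            row["object_name"] = f"{tracks[tid]['class']}{tid}"
            out_rows.append(row)
    return records_to_table(out_rows)
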