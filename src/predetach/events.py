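"""Kinematic detachment and pre-detachment event rules.

A cell counts as **detached** at the first frame where its centroid
steps by more than the displacement threshold (default 87.5 px, the
midpoint of the empirical 85-90 px band; strict inequality) between two
consecutive frames *and* it does not reappear near its pre-jump position
within the reappearance horizon.  A track that simply ends, with no
observed jump, is classed **lost** — a tracker failure must not
masquerade as biology.  Because the tracker's association gate sits
below the detachment band, a genuine jump usually breaks the track; an
optional reassociation pass therefore matches a dying track to a track
born the next frame at super-threshold distance and reconstructs the
jump across the break.

The **pre-detachment** moment is the earliest frame at which three
conditions hold simultaneously: the tube has held a stable position over
the stability window, the tube-cell distance is inside the proximity
threshold (default 90 px), and the cell's oscillation envelope has risen
past the onset threshold right after a calm plateau ended.  That
conjunction operationalises the observation that the tube settles, draws
close, and the still-adherent cell starts oscillating under suction just
before it lets go.

All detectors are pure functions of trajectories plus configuration; a
replay is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinematics import (
    CELL,
    TUBE,
    DEFAULT_CALM_THRESHOLD,
    DEFAULT_MIN_LENGTH,
    DEFAULT_OSC_WINDOW,
    IntervalLabel,
    Trajectory,
    displacement_series,
    oscillation_series,
    segment_intervals,
    velocity_variability,
)


class ConfigurationError(ValueError):
    """The scene or configuration violates a detector precondition."""


@dataclass
class DetectorConfig:
    """Thresholds of the event detectors (pixels / frames)."""

    detach_displacement_threshold: float = 87.5  # px, band [85, 90]
    reappearance_horizon: int = 10  # frames
    tube_distance_threshold: float = 90.0  # px
    tube_stability_window: int = 10  # frames
    tube_stability_tolerance: float = 2.0  # px/frame
    calm_threshold: float = DEFAULT_CALM_THRESHOLD  # px/frame
    min_calm_length: int = DEFAULT_MIN_LENGTH  # frames
    oscillation_window: int = DEFAULT_OSC_WINDOW  # frames
    oscillation_onset_threshold: float | None = None  # px; default 3x calm

    def __post_init__(self) -> None:
        if self.oscillation_onset_threshold is None:
            self.oscillation_onset_threshold = 3.0 * self.calm_threshold
        for name in ("detach_displacement_threshold", "reappearance_horizon",
                     "tube_distance_threshold", "tube_stability_window",
                     "tube_stability_tolerance", "calm_threshold",
                     "min_calm_length", "oscillation_window",
                     "oscillation_onset_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class DetachmentResult:
    status: str | None  # "detached", "lost", or None
    frame: int | None = None
    evidence: dict = field(default_factory=dict)


@dataclass
class EventReport:
    object_id: int
    object_class: str
    status: str  # "detached", "lost", or "tracked"
    detachment_frame: int | None = None
    pre_detachment_frame: int | None = None
    tube_cell_distance_at_event: float | None = None
    is_suspect: bool = False
    evidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# detachment
# ---------------------------------------------------------------------------

def _non_reappearance(traj: Trajectory, origin: np.ndarray, start: int,
                      horizon: int, threshold: float,
                      fragment: Trajectory | None = None) -> bool:
    """True iff the object stays absent or > threshold from ``origin``
    over the ``horizon`` frames following ``start``."""
    end = min(start + horizon, traj.n_frames - 1)
    for u in range(start + 1, end + 1):
        pos = None
        if traj.is_present(u):
            pos = traj.center_at(u)
        elif fragment is not None and fragment.is_present(u):
            pos = fragment.center_at(u)
        if pos is not None and np.linalg.norm(pos - origin) <= threshold:
            return False
    return True


def detect_detachment(traj: Trajectory, config: DetectorConfig | None = None,
                      candidates: Iterable[Trajectory] = ()) -> DetachmentResult:
    """Find the kinematic detachment frame of one trajectory, if any.

    First scans the trajectory's own displacement series for a
    super-threshold step with no reattachment within the horizon.  If
    instead the track ends early with no jump, ``candidates`` (other
    tracks of the same scene) are searched for a fragment born on the
    very next frame at super-threshold distance — the signature of a
    detachment jump that broke the tracker's association gate.  A track
    that ends early with neither explanation is reported as lost.
    """
    if config is None:
        config = DetectorConfig()
    thr = config.detach_displacement_threshold
    disp = displacement_series(traj)
    for frame, d in disp.items():
        if d > thr:
            origin = traj.center_at(frame - 1)
            if _non_reappearance(traj, origin, int(frame),
                                 config.reappearance_horizon, thr):
                return DetachmentResult(
                    "detached", int(frame),
                    {"displacement": float(d), "origin": tuple(origin)})
    if len(traj.frames) == 0:
        return DetachmentResult(None)
    last = int(traj.frames[-1])
    if last >= traj.n_frames - 1:
        return DetachmentResult(None)
    # track ended early: look for a jump fragment across the association break
    origin = traj.center_at(last)
    born = [c for c in candidates
            if c.object_id != traj.object_id and len(c.frames)
            and int(c.frames[0]) == last + 1]
    for cand in sorted(born, key=lambda c: c.object_id):
        d = float(np.linalg.norm(cand.center_at(last + 1) - origin))
        if d > thr and _non_reappearance(traj, origin, last + 1,
                                         config.reappearance_horizon, thr,
                                         fragment=cand):
            return DetachmentResult(
                "detached", last + 1,
                {"displacement": d, "origin": tuple(origin),
                 "fragment_id": cand.object_id})
    return DetachmentResult("lost", last + 1, {"last_seen": last})


# ---------------------------------------------------------------------------
# tube context
# ---------------------------------------------------------------------------

def tube_cell_distance(traj_cell: Trajectory, traj_tube: Trajectory,
                       frame: int) -> float:
    """Euclidean centre distance (px) between cell and tube at a frame."""
    if not (traj_cell.is_present(frame) and traj_tube.is_present(frame)):
        raise ValueError(f"both objects must be present at frame {frame}")
    return float(np.linalg.norm(traj_cell.center_at(frame) - traj_tube.center_at(frame)))


def tube_is_stable(traj_tube: Trajectory, frame: int, window: int = 10,
                   tolerance: float = 2.0) -> bool:
    """True iff every tube displacement over the ``window`` frame pairs
    ending at ``frame`` is <= tolerance.  Insufficient history (including
    absence anywhere in the window) is conservatively unstable."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if frame - window < 0:
        return False
    for u in range(frame - window + 1, frame + 1):
        if not (traj_tube.is_present(u) and traj_tube.is_present(u - 1)):
            return False
        step = np.linalg.norm(traj_tube.center_at(u) - traj_tube.center_at(u - 1))
        if step > tolerance:
            return False
    return True


# ---------------------------------------------------------------------------
# pre-detachment
# ---------------------------------------------------------------------------

def detect_pre_detachment(traj_cell: Trajectory, traj_tube: Trajectory,
                          intervals: Sequence[IntervalLabel],
                          config: DetectorConfig | None = None,
                          search_end: int | None = None) -> DetachmentResult:
    """Earliest frame satisfying tube stability AND proximity AND
    oscillation onset after a calm plateau; ``search_end`` (exclusive)
    bounds the search, e.g. at the detachment frame."""
    if config is None:
        config = DetectorConfig()
    score = oscillation_series(traj_cell, config.oscillation_window, "position")
    calm_ends = [iv.end for iv in intervals if iv.kind == "calm"]
    window = config.tube_stability_window
    for frame, s in score.items():
        t = int(frame)
        if search_end is not None and t >= search_end:
            break
        if s < config.oscillation_onset_threshold:
            continue
        if not any(t - window < e <= t for e in calm_ends):
            continue
        if not tube_is_stable(traj_tube, t, window, config.tube_stability_tolerance):
            continue
        if not (traj_cell.is_present(t) and traj_tube.is_present(t)):
            continue
        dist = tube_cell_distance(traj_cell, traj_tube, t)
        if dist >= config.tube_distance_threshold:
            continue
        return DetachmentResult(
            "pre-detachment", t,
            {"oscillation_score": float(s), "tube_distance": dist,
             "tube_stable": True})
    return DetachmentResult(None)


# ---------------------------------------------------------------------------
# scene report
# ---------------------------------------------------------------------------

def build_event_report(trajectories: Mapping[int, Trajectory] | Iterable[Trajectory],
                       config: DetectorConfig | None = None
                       ) -> tuple[list[EventReport], dict]:
    """Run both detectors for every cell of a scene.

    Requires exactly one tube trajectory.  Jump fragments consumed by the
    reassociation pass are excluded from their own report.  The velocity
    -variability suspect is flagged; whenever both events are reported
    for an object, pre-detachment strictly precedes detachment (the
    pre-detachment search is bounded by the detachment frame).
    """
    if config is None:
        config = DetectorConfig()
    if isinstance(trajectories, Mapping):
        trajs = [trajectories[k] for k in sorted(trajectories)]
    else:
        trajs = sorted(trajectories, key=lambda t: t.object_id)
    tubes = [t for t in trajs if t.object_class == TUBE]
    if len(tubes) != 1:
        raise ConfigurationError(
            f"exactly one tube trajectory required, found {len(tubes)}")
    tube = tubes[0]
    cells = [t for t in trajs if t.object_class != TUBE]

    suspect_id = None
    if trajs:
        var = velocity_variability(trajs)
        flagged = var[var["suspect"]]
        if len(flagged):
            suspect_id = int(flagged["object_id"].iloc[0])

    consumed: set[int] = set()
    reports: list[EventReport] = []
    for cell in cells:
        detach = detect_detachment(cell, config, candidates=cells)
        if detach.status == "detached" and "fragment_id" in detach.evidence:
            consumed.add(int(detach.evidence["fragment_id"]))
        score = oscillation_series(cell, config.oscillation_window, "position")
        intervals = segment_intervals(score, config.calm_threshold,
                                      config.min_calm_length,
                                      object_id=cell.object_id)
        pre = detect_pre_detachment(
            cell, tube, intervals, config,
            search_end=detach.frame if detach.status == "detached" else None)
        dist = None
        ref_frame = pre.frame if pre.frame is not None else (
            detach.frame - 1 if detach.status == "detached" else None)
        if ref_frame is not None and cell.is_present(ref_frame) \
                and tube.is_present(ref_frame):
            dist = tube_cell_distance(cell, tube, ref_frame)
        reports.append(EventReport(
            object_id=cell.object_id,
            object_class=cell.object_class,
            status=detach.status or "tracked",
            detachment_frame=detach.frame if detach.status == "detached" else None,
            pre_detachment_frame=pre.frame,
            tube_cell_distance_at_event=dist,
            is_suspect=cell.object_id == suspect_id,
            evidence={
                "detachment": detach.evidence,
                "pre_detachment": pre.evidence,
                "intervals": [(iv.kind, iv.start, iv.end) for iv in intervals],
            },
        ))
    reports = [r for r in reports if r.object_id not in consumed]
    summary = {
        "n_objects": len(trajs),
        "tube_id": tube.object_id,
        "suspect_id": suspect_id,
        "detached_ids": [r.object_id for r in reports if r.status == "detached"],
        "fragment_ids": sorted(consumed),
    }
    return reports, summary


def reports_to_frame(reports: Sequence[EventReport]) -> pd.DataFrame:
    """Flatten event reports to one row per object (for CSV export)."""
    rows = []
    for r in reports:
        rows.append({
            "object_id": r.object_id,
            "object_class": r.object_class,
            "status": r.status,
            "detachment_frame": r.detachment_frame,
            "pre_detachment_frame": r.pre_detachment_frame,
            "tube_cell_distance_at_event": r.tube_cell_distance_at_event,
            "is_suspect": r.is_suspect,
        })
    return pd.DataFrame(rows)
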