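"""Trajectory kinematics for micromanipulation video analysis.

Turns per-frame detection tables into the time series used to judge the
state of each object during an extraction attempt:

* **diagonal distance** — Euclidean length ``sqrt(w**2 + h**2)`` of the
  bounding box, a proxy for object size/deformation (suction dilates the
  target cell's box before it lets go);
* **displacement** — Euclidean norm of the centroid step between
  consecutive frames (pixels per frame, i.e. the object's speed);
* **oscillation score** — a rolling-max envelope of the absolute
  frame-to-frame differences, which turns raw jitter into a
  threshold-friendly activity signal;
* **calm / oscillation intervals** — a partition of the observed frame
  range into quiet plateaus and bursts of movement.

All spatial quantities are in pixels; time is in frame units (one frame =
one image of the sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

TUBE = "tube"
CELL = "cell"

#: default threshold (px/frame) below which motion counts as calm
DEFAULT_CALM_THRESHOLD = 2.0
#: default minimum run length (frames) for an interval to stand on its own
DEFAULT_MIN_LENGTH = 5
#: default rolling window (frames) for the oscillation envelope
DEFAULT_OSC_WINDOW = 5


@dataclass
class Trajectory:
    """Per-object time series of centroid and bounding box.

    ``frames`` holds the (strictly increasing) frame indices at which the
    object was observed; absence is encoded by missing indices, never by
    placeholder rows.
    """

    object_id: int
    object_class: str  # "tube" or "cell"
    frames: np.ndarray  # (n,) int
    centers: np.ndarray  # (n, 2) float, [x_center, y_center] px
    bboxes: np.ndarray  # (n, 2) float, [width, height] px
    n_frames: int  # total length of the sequence

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.bboxes = np.asarray(self.bboxes, dtype=float).reshape(-1, 2)
        if not (len(self.frames) == len(self.centers) == len(self.bboxes)):
            raise ValueError("frames, centers and bboxes must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if len(self.frames) and self.frames[-1] >= self.n_frames:
            raise ValueError("frame index beyond n_frames")
        if np.any(self.bboxes <= 0):
            raise ValueError("bounding-box width/height must be positive")
        self._index = {int(f): i for i, f in enumerate(self.frames)}

    # -- presence ---------------------------------------------------------
    @property
    def present(self) -> np.ndarray:
        """Boolean presence mask over the full [0, n_frames) range."""
        mask = np.zeros(self.n_frames, dtype=bool)
        mask[self.frames] = True
        return mask

    def is_present(self, frame: int) -> bool:
        return int(frame) in self._index

    def center_at(self, frame: int) -> np.ndarray:
        return self.centers[self._index[int(frame)]]

    def bbox_at(self, frame: int) -> np.ndarray:
        return self.bboxes[self._index[int(frame)]]


@dataclass(frozen=True)
class IntervalLabel:
    """A maximal calm or oscillation run, as the half-open span [start, end)."""

    kind: Literal["calm", "oscillation"]
    start: int
    end: int
    object_id: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# series
# ---------------------------------------------------------------------------

def diagonal_series(traj: Trajectory) -> pd.Series:
    """Bounding-box diagonal ``sqrt(w**2 + h**2)`` (px), indexed by frame."""
    diag = np.hypot(traj.bboxes[:, 0], traj.bboxes[:, 1])
    return pd.Series(diag, index=pd.Index(traj.frames, name="frame"), name="diagonal")


def displacement_series(traj: Trajectory) -> pd.Series:
    """Centroid step length between consecutive present frames (px/frame).

    Indexed by the *later* frame of each pair.  Pairs spanning an absence
    gap yield no value (absence is an event, not a zero).
    """
    if len(traj.frames) < 2:
        return pd.Series(dtype=float, name="displacement",
                         index=pd.Index([], dtype=int, name="frame"))
    steps = np.linalg.norm(np.diff(traj.centers, axis=0), axis=1)
    consecutive = np.diff(traj.frames) == 1
    return pd.Series(
        steps[consecutive],
        index=pd.Index(traj.frames[1:][consecutive], name="frame"),
        name="displacement",
    )


def diagonal_delta_series(traj: Trajectory) -> pd.Series:
    """Absolute diagonal change between consecutive present frames (px)."""
    if len(traj.frames) < 2:
        return pd.Series(dtype=float, name="diagonal_delta",
                         index=pd.Index([], dtype=int, name="frame"))
    diag = np.hypot(traj.bboxes[:, 0], traj.bboxes[:, 1])
    deltas = np.abs(np.diff(diag))
    consecutive = np.diff(traj.frames) == 1
    return pd.Series(
        deltas[consecutive],
        index=pd.Index(traj.frames[1:][consecutive], name="frame"),
        name="diagonal_delta",
    )


def oscillation_series(
    traj: Trajectory,
    window: int = DEFAULT_OSC_WINDOW,
    mode: Literal["position", "diagonal"] = "position",
) -> pd.Series:
    """Rolling-max envelope of absolute frame-to-frame differences.

    ``mode="position"`` uses the displacement series, ``mode="diagonal"``
    the absolute diagonal change.  With ``window=1`` the score equals the
    instantaneous difference.  The rolling window runs over the observed
    pair sequence (absence gaps are skipped, not zero-filled).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if mode == "position":
        base = displacement_series(traj)
    elif mode == "diagonal":
        base = diagonal_delta_series(traj)
    else:
        raise ValueError(f"unknown oscillation mode {mode!r}")
    score = base.rolling(window, min_periods=1).max()
    score.name = "oscillation_score"
    return score


# ---------------------------------------------------------------------------
# interval segmentation
# ---------------------------------------------------------------------------

def segment_intervals(
    score,
    calm_threshold: float = DEFAULT_CALM_THRESHOLD,
    min_length: int = DEFAULT_MIN_LENGTH,
    start_frame: int | None = None,
    object_id: int | None = None,
) -> list[IntervalLabel]:
    """Partition a motion-score series into calm and oscillation intervals.

    Frames with ``score < calm_threshold`` are calm, the rest oscillation.
    Maximal runs shorter than ``min_length`` are merged into the longer of
    their neighbouring runs (ties merge into the preceding run), so short
    blips do not fragment a plateau.  The returned half-open spans are
    disjoint, sorted, and exactly cover the observed range.

    ``score`` may be a pandas Series (its index supplies the start frame)
    or a plain sequence with ``start_frame``.
    """
    if calm_threshold <= 0:
        raise ValueError("calm_threshold must be > 0")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if isinstance(score, pd.Series):
        if start_frame is None:
            start_frame = int(score.index[0]) if len(score) else 0
        values = score.to_numpy(dtype=float)
    else:
        values = np.asarray(score, dtype=float)
        if start_frame is None:
            start_frame = 0
    n = len(values)
    if n == 0:
        return []

    # maximal runs of the raw labelling
    osc = values >= calm_threshold
    runs: list[list] = []  # [kind, start, end) in local coordinates
    run_start = 0
    for i in range(1, n + 1):
        if i == n or osc[i] != osc[run_start]:
            runs.append([("oscillation" if osc[run_start] else "calm"), run_start, i])
            run_start = i

    runs = _merge_short_runs(runs, min_length)

    return [
        IntervalLabel(kind=k, start=start_frame + s, end=start_frame + e,
                      object_id=object_id)
        for k, s, e in runs
    ]


def _merge_short_runs(runs: list[list], min_length: int) -> list[list]:
    """Repeatedly absorb the shortest sub-minimum run into its longer neighbour."""
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [e - s for _, s, e in runs]
        short = [i for i, ln in enumerate(lengths) if ln < min_length]
        if not short:
            break
        # deterministic choice: shortest run first, leftmost on ties
        i = min(short, key=lambda j: (lengths[j], j))
        left = lengths[i - 1] if i > 0 else -1
        right = lengths[i + 1] if i + 1 < len(runs) else -1
        # merge into the longer neighbour; ties (and equal) go to the preceding run
        target = i - 1 if left >= right else i + 1
        kind = runs[target][0]
        lo = min(runs[i][1], runs[target][1])
        hi = max(runs[i][2], runs[target][2])
        a, b = sorted((i, target))
        runs[a:b + 1] = [[kind, lo, hi]]
        # coalesce neighbours that now share a kind
        j = 1
        while j < len(runs):
            if runs[j][0] == runs[j - 1][0]:
                runs[j - 1][2] = runs[j][2]
                del runs[j]
            else:
                j += 1
    return runs


# ---------------------------------------------------------------------------
# per-object variability summary
# ---------------------------------------------------------------------------

def velocity_variability(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    """Rank objects by how erratically they move.

    For each object the standard deviation, maximum and range of its
    displacement series are computed; rows are sorted by std descending
    (ties broken by object id ascending).  The top-ranked *non-tube* object
    is flagged as the suspect — the cell whose erratic velocity marks it as
    the one reacting to suction.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("at least one trajectory is required")
    rows = []
    for traj in trajectories:
        disp = displacement_series(traj).to_numpy()
        if disp.size:
            std, mx, rng = float(np.std(disp)), float(np.max(disp)), float(np.ptp(disp))
        else:
            std = mx = rng = 0.0
        rows.append(
            {"object_id": traj.object_id, "object_class": traj.object_class,
             "std": std, "max": mx, "range": rng}
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["std", "object_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["suspect"] = False
    non_tube = df.index[df["object_class"] != TUBE]
    if len(non_tube):
        df.loc[non_tube[0], "suspect"] = True
    return df


def suspect_object(trajectories: Iterable[Trajectory]) -> int | None:
    """Id of the most erratically moving non-tube object, if any."""
    df = velocity_variability(trajectories)
    flagged = df[df["suspect"]]
    return int(flagged["object_id"].iloc[0]) if len(flagged) else None
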