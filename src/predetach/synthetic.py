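"""Ground-truthed synthetic extraction scenes.

Emulates the statistical structure of a recorded micropipette extraction
sequence: a tube that drifts into position and then holds still, several
near-static adherent cells, and one target cell that sits through calm
plateaus, oscillates with growing amplitude once suction engages, dilates
under aspiration, and finally exhibits a single large displacement jump
followed by disappearance from the field of view.  Photometric
degradations (Gaussian blur, salt-and-pepper impulses, contrast
compression) emulate the acquisition defects the imaging-QC stage is
built to correct.

Every stochastic draw derives from one scenario seed through named
sub-streams (trajectories, rendering, degradations — in that order), so a
(spec, seed) pair reproduces trajectories and frames bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .kinematics import CELL, TUBE, Trajectory

# RNG sub-stream labels, combined with the scenario seed
_STREAM_TRAJECTORIES = 0
_STREAM_RENDER = 1
_STREAM_DEGRADE = 2

#: oscillation carrier frequency (cycles/frame); incommensurate with the
#: frame grid so bursts sweep through their full amplitude
_OSC_FREQ = 0.171
#: uniform half-width of the per-frame phase noise (radians)
_OSC_PHASE_NOISE = 0.3

# rendering intensities (8-bit); background low, objects high, so the
# lightness separation comfortably exceeds the 50-grey-level contract
_BACKGROUND_LEVEL = 45.0
_BACKGROUND_AMPLITUDE = 8.0
_CELL_LEVEL = np.array([225.0, 235.0, 225.0])
_TUBE_LEVEL = np.array([230.0, 230.0, 238.0])


class ScenarioError(ValueError):
    """A scenario specification is internally inconsistent."""


@dataclass
class ObjectSpec:
    """Scripted behaviour of one object over the scenario.

    Intervals are half-open ``[start, end)`` frame ranges.  ``drifts``
    translate the base centre linearly by (dx, dy) px over a span (used
    for the tube's approach and repositioning); ``oscillation_bursts``
    superimpose a zero-mean sinusoid of the given amplitude along a
    random direction; ``suction_dilation`` grows the bounding-box
    diagonal by the given amount over a span.  When ``detachment_frame``
    is set the centroid jumps by ``jump_magnitude`` at that frame and the
    object is absent from every later frame.
    """

    object_id: int
    object_class: str = CELL  # "tube" or "cell"
    base_center: tuple[float, float] = (0.0, 0.0)  # (x, y) px
    base_bbox: tuple[float, float] = (20.0, 16.0)  # (w, h) px
    calm_intervals: list[tuple[int, int]] = field(default_factory=list)
    oscillation_bursts: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    drifts: list[tuple[tuple[int, int], tuple[float, float]]] = field(default_factory=list)
    suction_dilation: tuple[tuple[int, int], float] | None = None
    detachment_frame: int | None = None
    jump_magnitude: float | None = None
    jump_direction: tuple[float, float] | None = None  # unit-ish vector; random if None


@dataclass
class ScenarioSpec:
    n_frames: int
    frame_size: tuple[int, int]  # (height, width) px
    objects: list[ObjectSpec]
    seed: int = 0
    calm_jitter: float = 0.5  # max per-frame displacement during calm (px)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ScenarioError("n_frames must be >= 2")
        if self.frame_size[0] < 64 or self.frame_size[1] < 64:
            raise ScenarioError("frame_size must be at least 64x64")
        ids = [o.object_id for o in self.objects]
        if len(set(ids)) != len(ids):
            raise ScenarioError("object ids must be unique")
        tubes = [o for o in self.objects if o.object_class == TUBE]
        if self.objects and len(tubes) != 1:
            raise ScenarioError("exactly one object must have class 'tube'")
        for obj in self.objects:
            self._validate_object(obj)

    def _validate_object(self, obj: ObjectSpec) -> None:
        if obj.object_class not in (TUBE, CELL):
            raise ScenarioError(f"object {obj.object_id}: unknown class {obj.object_class!r}")
        if obj.base_bbox[0] <= 0 or obj.base_bbox[1] <= 0:
            raise ScenarioError(f"object {obj.object_id}: bbox must be positive")
        active: list[tuple[int, int, str]] = []
        for s, e in obj.calm_intervals:
            self._check_span(obj, s, e)
        for (s, e), amp in obj.oscillation_bursts:
            self._check_span(obj, s, e)
            if amp < 0:
                raise ScenarioError(f"object {obj.object_id}: negative burst amplitude")
            active.append((s, e, "oscillation burst"))
        for (s, e), _ in obj.drifts:
            self._check_span(obj, s, e)
            active.append((s, e, "drift"))
        if obj.suction_dilation is not None:
            (s, e), growth = obj.suction_dilation
            self._check_span(obj, s, e)
            if growth < 0:
                raise ScenarioError(f"object {obj.object_id}: negative dilation growth")
        # calm intervals must not overlap scripted motion: contradictory
        for cs, ce in obj.calm_intervals:
            for s, e, what in active:
                if cs < e and s < ce:
                    raise ScenarioError(
                        f"object {obj.object_id}: calm interval [{cs},{ce}) "
                        f"overlaps {what} [{s},{e})")
        if (obj.detachment_frame is None) != (obj.jump_magnitude is None):
            raise ScenarioError(
                f"object {obj.object_id}: detachment_frame and jump_magnitude "
                "must be set together")
        if obj.detachment_frame is not None:
            if not (0 < obj.detachment_frame < self.n_frames):
                raise ScenarioError(f"object {obj.object_id}: detachment_frame out of range")
            if obj.jump_magnitude <= 0:
                raise ScenarioError(f"object {obj.object_id}: jump_magnitude must be > 0")

    def _check_span(self, obj: ObjectSpec, s: int, e: int) -> None:
        if not (0 <= s < e <= self.n_frames):
            raise ScenarioError(
                f"object {obj.object_id}: interval [{s},{e}) outside [0,{self.n_frames})")


@dataclass
class DegradationSpec:
    blur_sigma: float = 0.0  # Gaussian std (px); 0 disables
    noise_fraction: float = 0.0  # fraction of pixels replaced by extremes
    contrast_scale: float = 1.0  # multiplicative L-range compression

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ScenarioError("blur_sigma must be >= 0")
        if not 0 <= self.noise_fraction <= 1:
            raise ScenarioError("noise_fraction must be in [0, 1]")
        if self.contrast_scale <= 0:
            raise ScenarioError("contrast_scale must be > 0")


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def generate_trajectories(spec: ScenarioSpec) -> dict[int, Trajectory]:
    """Generate ground-truth trajectories for every object in the scenario.

    Deterministic given (spec, seed).  During calm stretches per-frame
    displacement never exceeds ``spec.calm_jitter``; a detachment frame
    carries a centroid step of exactly ``jump_magnitude``.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, _STREAM_TRAJECTORIES])
    n = spec.n_frames
    out: dict[int, Trajectory] = {}
    tube_spec = next((o for o in spec.objects if o.object_class == TUBE), None)
    for obj in sorted(spec.objects, key=lambda o: o.object_id):
        # sub-pixel jitter: per-axis bound a gives per-frame displacement
        # <= 2*a*sqrt(2); choose a so that equals calm_jitter
        a = spec.calm_jitter / (2.0 * np.sqrt(2.0))
        offsets = rng.uniform(-a, a, size=(n, 2))
        base = np.tile(np.asarray(obj.base_center, dtype=float), (n, 1))
        for (s, e), (dx, dy) in obj.drifts:
            ramp = np.linspace(0.0, 1.0, e - s, endpoint=True)
            base[s:e] += np.outer(ramp, [dx, dy])
            base[e:] += [dx, dy]
        for (s, e), amp in obj.oscillation_bursts:
            t = np.arange(e - s)
            phase0 = rng.uniform(0, 2 * np.pi)
            pnoise = rng.uniform(-_OSC_PHASE_NOISE, _OSC_PHASE_NOISE, size=e - s)
            theta = rng.uniform(0, 2 * np.pi)
            wave = amp * np.sin(2 * np.pi * _OSC_FREQ * t + phase0 + pnoise)
            base[s:e] += np.outer(wave, [np.cos(theta), np.sin(theta)])
        pos = base + offsets

        w = np.full(n, float(obj.base_bbox[0]))
        h = np.full(n, float(obj.base_bbox[1]))
        if obj.suction_dilation is not None:
            (s, e), growth = obj.suction_dilation
            d0 = float(np.hypot(w[0], h[0]))
            ramp = np.linspace(0.0, 1.0, e - s, endpoint=True)
            factor = (d0 + growth * ramp) / d0
            w[s:e] *= factor
            h[s:e] *= factor
            w[e:] *= factor[-1] if len(factor) else 1.0
            h[e:] *= factor[-1] if len(factor) else 1.0

        last = n - 1
        if obj.detachment_frame is not None:
            df = obj.detachment_frame
            if obj.jump_direction is not None:
                direction = np.asarray(obj.jump_direction, dtype=float)
            elif tube_spec is not None and obj is not tube_spec:
                # jump directed away from the aspiration axis keeps the
                # displaced centroid inside the rendered field of view
                direction = pos[df - 1] - np.asarray(tube_spec.base_center, float)
            else:
                angle = rng.uniform(0, 2 * np.pi)
                direction = np.array([np.cos(angle), np.sin(angle)])
            norm = np.linalg.norm(direction)
            if norm == 0:
                direction = np.array([1.0, 0.0])
                norm = 1.0
            pos[df] = pos[df - 1] + obj.jump_magnitude * direction / norm
            last = df

        frames = np.arange(0, last + 1)
        out[obj.object_id] = Trajectory(
            object_id=obj.object_id,
            object_class=obj.object_class,
            frames=frames,
            centers=pos[: last + 1],
            bboxes=np.column_stack([w[: last + 1], h[: last + 1]]),
            n_frames=n,
        )
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_frames(trajectories: dict[int, Trajectory], spec: ScenarioSpec) -> np.ndarray:
    """Render trajectories as an (n_frames, H, W, 3) uint8 frame stack.

    Each present object is drawn as a filled high-contrast blob — an
    ellipse for cells, an elongated rectangle for the tube — over a
    static low-amplitude smooth texture, so the reference detector can
    recover every object.
    """
    H, W = spec.frame_size
    for obj in spec.objects:
        if obj.base_bbox[0] > W or obj.base_bbox[1] > H:
            raise ScenarioError(f"object {obj.object_id} larger than the frame")
    rng = np.random.default_rng([spec.seed, _STREAM_RENDER])
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(H, W)), sigma=6.0)
    ptp = np.ptp(texture)
    if ptp > 0:
        texture = (texture - texture.min()) / ptp - 0.5
    background = _BACKGROUND_LEVEL + _BACKGROUND_AMPLITUDE * texture
    background = np.clip(background, 0, 255)

    stack = np.empty((spec.n_frames, H, W, 3), dtype=np.uint8)
    base_frame = np.repeat(background[:, :, None], 3, axis=2)
    for f in range(spec.n_frames):
        img = base_frame.copy()
        for obj_id in sorted(trajectories):
            traj = trajectories[obj_id]
            if not traj.is_present(f):
                continue
            cx, cy = traj.center_at(f)
            w, h = traj.bbox_at(f)
            if traj.object_class == TUBE:
                r0 = int(round(cy - h / 2))
                r1 = int(round(cy + h / 2))
                c0 = int(round(cx - w / 2))
                c1 = int(round(cx + w / 2))
                r0, r1 = max(r0, 0), min(r1, H)
                c0, c1 = max(c0, 0), min(c1, W)
                if r1 > r0 and c1 > c0:
                    img[r0:r1, c0:c1] = _TUBE_LEVEL
            else:
                rr, cc = draw_ellipse(cy, cx, h / 2, w / 2, shape=(H, W))
                img[rr, cc] = _CELL_LEVEL
        stack[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return stack


# ---------------------------------------------------------------------------
# photometric degradation
# ---------------------------------------------------------------------------

def degrade(frames: np.ndarray, deg: DegradationSpec, seed: int) -> np.ndarray:
    """Apply photometric degradations to a frame stack.

    Order: Gaussian blur, contrast compression, impulse noise — noise
    last so that exactly ``round(noise_fraction * n_pixels)`` pixels per
    frame end at the extreme values 0 or 255.  Steps with neutral
    parameters are skipped, so the neutral spec is the identity.
    Deterministic given (deg, seed).
    """
    rng = np.random.default_rng([seed, _STREAM_DEGRADE])
    out = frames.copy()
    n, H, W, _ = out.shape
    for f in range(n):
        img = out[f].astype(np.float64)
        if deg.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, sigma=(deg.blur_sigma, deg.blur_sigma, 0))
        if deg.contrast_scale != 1.0:
            # compress each channel about its mean; equivalent to an
            # L-range compression for the near-achromatic scenes rendered here
            mean = img.mean(axis=(0, 1), keepdims=True)
            img = mean + (img - mean) * deg.contrast_scale
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        if deg.noise_fraction > 0:
            k = int(round(deg.noise_fraction * H * W))
            idx = rng.choice(H * W, size=k, replace=False)
            values = rng.integers(0, 2, size=k) * 255
            flat = img.reshape(-1, 3)
            flat[idx] = values[:, None]
            img = flat.reshape(H, W, 3)
        out[f] = img
    return out


# ---------------------------------------------------------------------------
# canonical scenario and scene IO
# ---------------------------------------------------------------------------

def canonical_scenario(seed: int = 0, n_frames: int = 120,
                       detachment_frame: int = 60, onset: int = 52,
                       jump_magnitude: float = 120.0,
                       burst_amplitude: float = 12.0) -> ScenarioSpec:
    """The reference extraction scenario used throughout the test-bench.

    A tube drifts into position over the first 40 frames (per-frame speed
    above the stability tolerance) and then holds still within jitter; the
    target cell sits calm until ``onset``, oscillates with the given
    amplitude until ``detachment_frame``, then jumps by
    ``jump_magnitude`` px away from the tube and disappears.  Two
    bystander cells stay calm throughout.  Tube–target distance ends
    around 70 px, inside the 90 px proximity threshold.
    """
    if not (0 < onset < detachment_frame < n_frames):
        raise ScenarioError("need 0 < onset < detachment_frame < n_frames")
    tube = ObjectSpec(
        object_id=0, object_class=TUBE,
        base_center=(40.0, 60.0), base_bbox=(70.0, 14.0),
        drifts=[((0, 40), (90.0, 60.0))],  # ends at (130, 120), ~2.7 px/frame
    )
    target = ObjectSpec(
        object_id=1, object_class=CELL,
        base_center=(200.0, 120.0), base_bbox=(22.0, 18.0),
        calm_intervals=[(0, onset)],
        oscillation_bursts=[((onset, detachment_frame), burst_amplitude)],
        suction_dilation=((onset, detachment_frame), 6.0),
        detachment_frame=detachment_frame,
        jump_magnitude=jump_magnitude,
    )
    bystander_a = ObjectSpec(object_id=2, object_class=CELL,
                             base_center=(80.0, 200.0), base_bbox=(20.0, 16.0))
    bystander_b = ObjectSpec(object_id=3, object_class=CELL,
                             base_center=(310.0, 210.0), base_bbox=(18.0, 20.0))
    return ScenarioSpec(
        n_frames=n_frames, frame_size=(256, 384),
        objects=[tube, target, bystander_a, bystander_b], seed=seed,
    )


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["objects"] = [dataclasses.asdict(o) for o in spec.objects]
    return d


def scenario_from_dict(d: dict) -> ScenarioSpec:
    objects = []
    for o in d.get("objects", []):
        o = dict(o)
        if o.get("suction_dilation") is not None:
            (s, e), g = o["suction_dilation"]
            o["suction_dilation"] = ((int(s), int(e)), float(g))
        o["calm_intervals"] = [tuple(map(int, iv)) for iv in o.get("calm_intervals", [])]
        o["oscillation_bursts"] = [
            ((int(s), int(e)), float(a)) for (s, e), a in o.get("oscillation_bursts", [])]
        o["drifts"] = [((int(s), int(e)), (float(dx), float(dy)))
                       for (s, e), (dx, dy) in o.get("drifts", [])]
        if o.get("base_center") is not None:
            o["base_center"] = tuple(map(float, o["base_center"]))
        if o.get("base_bbox") is not None:
            o["base_bbox"] = tuple(map(float, o["base_bbox"]))
        if o.get("jump_direction") is not None:
            o["jump_direction"] = tuple(map(float, o["jump_direction"]))
        objects.append(ObjectSpec(**o))
    return ScenarioSpec(
        n_frames=int(d["n_frames"]),
        frame_size=tuple(map(int, d["frame_size"])),
        objects=objects,
        seed=int(d.get("seed", 0)),
        calm_jitter=float(d.get("calm_jitter", 0.5)),
    )


def load_scenario(path) -> ScenarioSpec:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def save_scenario(spec: ScenarioSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(spec), fh, sort_keys=False)


def write_scene(out_dir, spec: ScenarioSpec,
                degradation: DegradationSpec | None = None) -> dict:
    """Simulate a scene to disk: frames, ground-truth table, scenario YAML.

    Frames are written as zero-padded ``frame_%05d.png``; ground truth
    follows the detection-table CSV contract.  Returns the artifact paths.
    """
    from .detections import table_from_trajectories, write_table

    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    trajectories = generate_trajectories(spec)
    stack = render_frames(trajectories, spec)
    if degradation is not None:
        stack = degrade(stack, degradation, spec.seed)
    for f in range(spec.n_frames):
        iio.imwrite(frames_dir / f"frame_{f:05d}.png", stack[f])
    gt_path = out_dir / "ground_truth.csv"
    write_table(table_from_trajectories(trajectories), gt_path)
    scen_path = out_dir / "scenario.yaml"
    save_scenario(spec, scen_path)
    return {"frames_dir": frames_dir, "ground_truth": gt_path, "scenario": scen_path}
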