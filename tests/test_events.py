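"""Detachment and pre-detachment event rules."""

import numpy as np
import pytest

from predetach import events, kinematics, synthetic
from predetach.events import ConfigurationError, DetectorConfig
from predetach.kinematics import Trajectory


def traj(centers, frames=None, n_frames=None, object_id=1,
         object_class="cell"):
    centers = np.asarray(centers, dtype=float)
    if frames is None:
        frames = np.arange(len(centers))
    if n_frames is None:
        n_frames = int(np.max(frames)) + 1 if len(frames) else 1
    return Trajectory(object_id=object_id, object_class=object_class,
                      frames=frames, centers=centers,
                      bboxes=np.tile([10.0, 8.0], (len(centers), 1)),
                      n_frames=n_frames)


def jump_trajectory(jump, at=60, n_frames=100, absent_after=True):
    centers = [(100.0, 100.0)] * at + [(100.0 + jump, 100.0)]
    if not absent_after:
        centers += [(100.0 + jump, 100.0)] * (n_frames - at - 1)
    return traj(centers, n_frames=n_frames)


class TestDetectDetachment:
    def test_static_trajectory_not_detached(self):
        res = events.detect_detachment(traj([(5.0, 5.0)] * 50))
        assert res.status is None

    def test_jump_then_absence_detected(self):
        res = events.detect_detachment(jump_trajectory(120.0))
        assert (res.status, res.frame) == ("detached", 60)

    def test_reattachment_cancels_detachment(self):
        centers = [(100.0, 100.0)] * 60 + [(200.0, 100.0), (190.0, 100.0),
                   (150.0, 100.0), (105.0, 100.0)] + [(100.0, 100.0)] * 36
        res = events.detect_detachment(traj(centers))
        assert res.status is None

    def test_vanishing_without_jump_is_lost(self):
        res = events.detect_detachment(traj([(5.0, 5.0)] * 40, n_frames=100))
        assert res.status == "lost"

    def test_jump_recovered_across_tracker_break(self):
        # the track dies at 59 and a 1-frame fragment is born at 60, 120 px away
        dying = traj([(100.0, 100.0)] * 60, n_frames=100, object_id=1)
        fragment = traj([(220.0, 100.0)], frames=[60], n_frames=100, object_id=7)
        res = events.detect_detachment(dying, candidates=[fragment])
        assert (res.status, res.frame) == ("detached", 60)
        assert res.evidence["fragment_id"] == 7

    def test_threshold_band_is_strict(self):
        assert events.detect_detachment(
            jump_trajectory(84.0),
            DetectorConfig(detach_displacement_threshold=85.0)).status != "detached"
        assert events.detect_detachment(
            jump_trajectory(91.0),
            DetectorConfig(detach_displacement_threshold=90.0)).status == "detached"

    def test_raising_threshold_only_removes_detections(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            jump = rng.uniform(60, 150)
            t = jump_trajectory(jump)
            detected = []
            for thr in (85.0, 87.5, 90.0, 120.0):
                cfg = DetectorConfig(detach_displacement_threshold=thr)
                detected.append(events.detect_detachment(t, cfg).status == "detached")
            # once a detection disappears at some threshold it never returns
            assert detected == sorted(detected, reverse=True)

    def test_generator_scenario_recovered(self, canonical_trajectories):
        res = events.detect_detachment(canonical_trajectories[1])
        assert (res.status, res.frame) == ("detached", 60)


class TestTubeContext:
    def test_coincident_centers_distance_zero(self):
        a = traj([(10.0, 10.0)], object_id=1)
        b = traj([(10.0, 10.0)], object_id=0, object_class="tube")
        assert events.tube_cell_distance(a, b, 0) == 0.0

    def test_6_8_10_distance(self):
        a = traj([(0.0, 0.0)], object_id=1)
        b = traj([(60.0, 80.0)], object_id=0, object_class="tube")
        assert events.tube_cell_distance(a, b, 0) == 100.0

    def test_absent_frame_raises(self):
        a = traj([(0.0, 0.0)], object_id=1, n_frames=5)
        b = traj([(1.0, 1.0)] * 5, object_id=0, object_class="tube")
        with pytest.raises(ValueError):
            events.tube_cell_distance(a, b, 3)

    def test_static_tube_is_stable(self):
        tube = traj([(50.0, 50.0)] * 30, object_id=0, object_class="tube")
        assert events.tube_is_stable(tube, 15, window=10, tolerance=2.0)

    def test_adjusting_tube_is_unstable(self):
        centers = [(50.0 + 5.0 * i, 50.0) for i in range(30)]
        tube = traj(centers, object_id=0, object_class="tube")
        assert not events.tube_is_stable(tube, 20, window=10, tolerance=2.0)

    def test_first_stable_frame_after_adjustments(self):
        centers = [(50.0 + 5.0 * min(i, 40), 50.0) for i in range(80)]
        tube = traj(centers, object_id=0, object_class="tube")
        stable_frames = [f for f in range(80)
                         if events.tube_is_stable(tube, f, 10, 2.0)]
        assert stable_frames[0] == 50

    def test_insufficient_history_is_unstable(self):
        tube = traj([(50.0, 50.0)] * 30, object_id=0, object_class="tube")
        assert not events.tube_is_stable(tube, 5, window=10, tolerance=2.0)


class TestDetectPreDetachment:
    def intervals_for(self, cell, cfg):
        score = kinematics.oscillation_series(cell, cfg.oscillation_window)
        return kinematics.segment_intervals(score, cfg.calm_threshold,
                                            cfg.min_calm_length,
                                            object_id=cell.object_id)

    def test_fully_calm_scene_has_no_event(self):
        cfg = DetectorConfig()
        cell = traj([(150.0, 100.0)] * 80, object_id=1)
        tube = traj([(100.0, 100.0)] * 80, object_id=0, object_class="tube")
        res = events.detect_pre_detachment(cell, tube,
                                           self.intervals_for(cell, cfg), cfg)
        assert res.status is None

    def test_canonical_scenario_in_onset_window(self, canonical_trajectories):
        cfg = DetectorConfig()
        cell, tube = canonical_trajectories[1], canonical_trajectories[0]
        res = events.detect_pre_detachment(cell, tube,
                                           self.intervals_for(cell, cfg), cfg,
                                           search_end=60)
        assert res.status == "pre-detachment"
        assert 52 <= res.frame < 60
        assert res.evidence["tube_distance"] < 90.0

    def test_no_event_while_tube_moves(self, canonical_spec):
        spec = synthetic.canonical_scenario(seed=1, n_frames=80,
                                            detachment_frame=60, onset=52)
        # tube keeps adjusting (~2.5 px/frame) until frame 58: stability
        # is never established before the detachment at 60
        spec.objects[0].drifts = [((0, 58), (120.0, 80.0))]
        trajs = synthetic.generate_trajectories(spec)
        cfg = DetectorConfig()
        cell, tube = trajs[1], trajs[0]
        res = events.detect_pre_detachment(cell, tube,
                                           self.intervals_for(cell, cfg), cfg,
                                           search_end=60)
        assert res.status is None


class TestBuildEventReport:
    def test_canonical_scene_report(self, canonical_trajectories):
        reports, summary = events.build_event_report(canonical_trajectories)
        by_id = {r.object_id: r for r in reports}
        target = by_id[1]
        assert target.status == "detached"
        assert target.detachment_frame == 60
        assert target.pre_detachment_frame is not None
        assert target.pre_detachment_frame < target.detachment_frame
        assert target.is_suspect
        assert summary["detached_ids"] == [1]

    def test_calm_scene_keeps_suspect_but_no_events(self):
        tube = traj([(50.0, 50.0)] * 40, object_id=0, object_class="tube")
        cells = [traj([(150.0 + 60 * i, 150.0)] * 40, object_id=i + 1)
                 for i in range(2)]
        reports, summary = events.build_event_report([tube] + cells)
        assert all(r.detachment_frame is None for r in reports)
        assert all(r.pre_detachment_frame is None for r in reports)
        assert summary["suspect_id"] is not None

    def test_exactly_one_detachment_among_two_cells(self, canonical_spec):
        trajs = synthetic.generate_trajectories(canonical_spec)
        reports, _ = events.build_event_report(trajs)
        detached = [r for r in reports if r.status == "detached"]
        assert len(detached) == 1 and detached[0].object_id == 1

    def test_zero_or_two_tubes_rejected(self):
        cell = traj([(10.0, 10.0)] * 5, object_id=1)
        with pytest.raises(ConfigurationError):
            events.build_event_report([cell])
        t0 = traj([(10.0, 10.0)] * 5, object_id=0, object_class="tube")
        t2 = traj([(90.0, 90.0)] * 5, object_id=2, object_class="tube")
        with pytest.raises(ConfigurationError):
            events.build_event_report([t0, t2, cell])

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            DetectorConfig(tube_distance_threshold=-1.0)
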