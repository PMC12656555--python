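import dataclasses

import numpy as np
import pytest

from flocyt import SimConfig, simulate
from flocyt.cli_io import benchmark_tracker_config
from flocyt.evaluation import evaluate
from flocyt.kalman import kf_init
from flocyt.tracker import (
    FloCyTracker,
    Track,
    TrackerConfig,
    channel_centers,
    initial_velocity,
    local_velocity,
    step,
    track_per_channel,
    track_sequence,
)

from conftest import two_lane_detections


def make_track(track_id, position, velocity, age=2):
    return Track(track_id=track_id, state=kf_init(position, velocity), age=age)


class TestInitialVelocity:
    def test_alpha_zero_uses_global_only(self):
        assert np.allclose(initial_velocity(None, (100, 0), 0.0), (100, 0))

    def test_blend(self):
        assert np.allclose(initial_velocity((200, 0), (100, 0), 0.7), (170, 0))

    def test_alpha_one_is_local_only(self):
        assert np.allclose(initial_velocity((200, 5), (-999, 7), 1.0), (200, 5))

    def test_missing_local_with_nonzero_alpha_rejected(self):
        with pytest.raises(ValueError):
            initial_velocity(None, (100, 0), 0.7)


class TestLocalVelocity:
    def test_componentwise_median(self):
        tracks = [
            make_track(0, (0, 0), (100, 0)),
            make_track(1, (0, 0), (120, 2)),
            make_track(2, (0, 0), (80, -2)),
        ]
        assert np.allclose(local_velocity(tracks), (100, 0))

    def test_single_track(self):
        assert np.allclose(local_velocity([make_track(0, (0, 0), (90, 1))]), (90, 1))

    def test_young_tracks_excluded(self):
        assert local_velocity([make_track(0, (0, 0), (90, 1), age=1)]) is None
        assert local_velocity([]) is None


class TestStep:
    def test_match_inside_gate(self):
        tracks = [make_track(0, (100, 100), (100, 0))]
        tracks, res = step(tracks, [(205.0, 101.0)], 1, TrackerConfig(), (100, 0))
        assert res.assignments == [(0, 0)]
        assert res.new_track_ids == [] and res.deleted_track_ids == []
        assert tracks[0].missed_frames == 0

    def test_empty_frame_all_tracks_miss(self):
        tracks = [make_track(0, (100, 100), (100, 0))]
        tracks, res = step(tracks, [], 1, TrackerConfig(), (100, 0))
        assert res.assignments == []
        assert tracks[0].missed_frames == 1

    def test_predicted_roi_exit_deletes_unmatched_track(self):
        cfg = TrackerConfig(roi=(0, 0, 1920, 1080))
        tracks = [make_track(0, (1900.0, 100.0), (100, 0))]
        tracks, res = step(tracks, [], 1, cfg, (100, 0))
        assert res.deleted_track_ids == [0]
        assert tracks == []

    def test_matched_track_survives_at_roi_edge(self):
        cfg = TrackerConfig(roi=(0, 0, 1920, 1080))
        tracks = [make_track(0, (1850.0, 100.0), (100, 0))]
        tracks, res = step(tracks, [(1910.0, 100.0)], 1, cfg, (100, 0))
        assert res.assignments == [(0, 0)]
        assert res.deleted_track_ids == []

    def test_out_of_roi_detection_spawns_no_track(self):
        cfg = TrackerConfig(roi=(0, 0, 1000, 1000))
        tracks, res = step([], [(1500.0, 100.0), (500.0, 100.0)], 0, cfg, (100, 0))
        assert len(res.new_track_ids) == 1

    def test_stale_track_deleted_after_max_missed(self):
        cfg = TrackerConfig(max_missed_frames=2)
        tracks = [make_track(0, (100.0, 100.0), (0, 0))]
        for f in range(1, 4):
            tracks, res = step(tracks, [], f, cfg, (0, 0))
        assert res.deleted_track_ids == [0]


def test_two_parallel_lanes_never_cross_matched():
    frames = two_lane_detections(n_frames=50, lateral_gap=120.0)
    cfg = TrackerConfig()
    traj = track_sequence(frames, cfg)
    rep_ids = traj.ids
    assert len(rep_ids) == 2
    # each hypothesis id keeps a constant y (lane) throughout
    for i in rep_ids:
        ys = traj.records[traj.records["id"] == i]["y"].unique()
        assert len(ys) == 1


def test_track_sequence_requires_two_frames():
    with pytest.raises(ValueError):
        track_sequence([np.zeros((0, 2))])


def test_tracks_persist_through_an_empty_frame():
    frames = two_lane_detections(n_frames=20)
    frames[10] = np.zeros((0, 2))
    traj = track_sequence(frames, TrackerConfig())
    assert len(traj.ids) == 2  # no new identities after the dropout
    for i in traj.ids:
        f = traj.records[traj.records["id"] == i]["frame"].to_numpy()
        assert set(f) == set(range(20)) - {10}


def test_noiseless_small_simulation_one_id_per_cell(small_sim_config, tracker_config):
    cfg = dataclasses.replace(small_sim_config, sigma_x=0.0, sigma_y=0.0, stop_fraction=0.0)
    res = simulate(cfg)
    traj = track_sequence(res.detections, tracker_config)
    # ID conservation: at least one hypothesis per ground-truth cell,
    # and equality when nothing perturbs the motion
    assert len(traj.ids) >= len(res.ground_truth.ids)
    report = evaluate(res.ground_truth, traj, 1.0)
    assert report.fp == 0 and report.fn == 0
    assert report.mt_percent == 100.0


def test_no_duplicate_assignments_on_random_run(small_sim_config, tracker_config):
    res = simulate(small_sim_config)
    from flocyt.flow_init import pooled_estimate

    v_g = pooled_estimate(res.detections, tracker_config.flow_init).v_g
    tracker = FloCyTracker(tracker_config, v_g)
    for f, dets in enumerate(res.detections):
        r = tracker.step(dets, f)
        det_idx = [j for _, j in r.assignments]
        track_ids = [i for i, _ in r.assignments]
        assert len(det_idx) == len(set(det_idx))
        assert len(track_ids) == len(set(track_ids))
        # deletion correctness: no surviving unmatched track is outside the ROI
        for t in tracker.tracks:
            if t.missed_frames > 0 and tracker_config.roi is not None:
                assert 0 <= t.predicted_position[0] <= tracker_config.roi[2]


def test_track_ids_never_reused(small_sim_config, tracker_config):
    res = simulate(small_sim_config)
    traj = track_sequence(res.detections, tracker_config)
    births = traj.records.groupby("id")["frame"].min()
    assert births.index.is_unique


def test_idsw_nondecreasing_with_flow_noise():
    """Centroid noise can only make identity preservation harder: total
    switches over a fixed seed set grow with sigma_x."""
    totals = []
    for sigma in (0.0, 5.0, 15.0):
        total = 0
        for seed in (0, 1, 2):
            cfg = dataclasses.replace(
                SimConfig.from_preset("K", seed=seed, n_frames=150),
                sigma_x=sigma,
                stop_fraction=0.0,
            )
            res = simulate(cfg)
            traj = track_sequence(res.detections, benchmark_tracker_config(cfg))
            total += evaluate(res.ground_truth, traj, 1.0).idsw
        totals.append(total)
    assert totals == sorted(totals)


class TestPerChannel:
    def test_channel_centers_near_true_lane_centers(self, small_sim_config, tracker_config):
        res = simulate(small_sim_config)
        centers = channel_centers(res.detections, tracker_config)
        pitch = small_sim_config.channel_pitch
        true_centers = (np.arange(15) + 0.5) * pitch
        assert len(centers) == 15
        assert np.all(np.abs(centers - true_centers) < pitch / 2)

    def test_single_channel_equals_plain_tracking(self):
        frames = two_lane_detections(n_frames=30)
        cfg = TrackerConfig(n_channels=1)
        assert track_per_channel(frames, cfg) == track_sequence(frames, cfg)

    def test_ids_disjoint_across_channels(self, small_sim_config, tracker_config):
        res = simulate(small_sim_config)
        traj = track_per_channel(res.detections, tracker_config)
        assert traj.records.groupby("id")["y"].apply(
            lambda y: y.max() - y.min()
        ).max() < small_sim_config.channel_pitch  # no id spans two lanes

    def test_too_few_detections_for_clustering(self):
        frames = two_lane_detections(n_frames=5)  # 10 detections in total
        cfg = TrackerConfig(n_channels=15)
        with pytest.raises(ValueError, match="channels"):
            track_per_channel(frames, cfg)

    def test_per_channel_metrics_match_plain_on_clean_lanes(
        self, small_sim_config, tracker_config
    ):
        res = simulate(small_sim_config)
        plain = evaluate(res.ground_truth, track_sequence(res.detections, tracker_config), 1.0)
        per = evaluate(
            res.ground_truth, track_per_channel(res.detections, tracker_config), 1.0
        )
        assert per.mt_percent == 100.0
        assert abs(per.idf1 - plain.idf1) < 0.05


def test_alpha_activation_switches_seed_velocity():
    cfg = TrackerConfig(alpha=1.0, alpha_activation_tracks=2)
    tracker = FloCyTracker(cfg, (100.0, 0.0))
    # two established tracks moving at 200 px/frame
    tracker.tracks = [
        make_track(0, (500.0, 100.0), (200.0, 0.0), age=3),
        make_track(1, (500.0, 400.0), (200.0, 0.0), age=3),
    ]
    dets = [(700.0, 100.0), (700.0, 400.0), (100.0, 700.0)]
    tracker.step(dets, 5)
    newborn = tracker.tracks[-1]
    assert np.allclose(newborn.state.velocity, (200.0, 0.0))  # alpha=1: local median
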