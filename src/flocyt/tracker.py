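"""Per-frame tracking loop: predict, gate, associate, update, create, delete.

The tracker maintains a set of Kalman-filtered tracks over a stream of
per-frame centroid detections.  Each frame it (1) predicts every track one
frame ahead, (2) builds the anisotropic gated cost matrix between predicted
positions and detections, (3) solves the assignment, (4) corrects matched
tracks and resets their miss counters, (5) increments miss counters of
unmatched tracks, (6) deletes tracks that have been missing too long or
whose predicted position has left the region of interest along the flow
axis, and (7) births a track for every unmatched detection inside the ROI.

New tracks are seeded with a staged initial velocity
``v0 = alpha * v_l + (1 - alpha) * v_g``: before enough tracks exist, only
the bulk-flow estimate ``v_g`` (displacement-histogram mode) is available
and ``alpha = 0``; once the active-track count reaches a threshold, the
component-wise median ``v_l`` of current track velocities takes most of the
weight, letting initialisation adapt to temporal flow variation.

A per-channel variant clusters detections into horizontal channel bands
with 1D K-Means on y and runs an independent tracker per band, which
suppresses cross-channel association in multi-lane chips.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .association import GatingParams, assign, build_cost_matrix
from .flow_init import FlowInitConfig, pooled_estimate
from .kalman import KalmanConfig, KalmanState, kf_init, kf_predict, kf_update
from .trajectories import TrajectorySet

__all__ = [
    "Track",
    "TrackerConfig",
    "FrameResult",
    "FloCyTracker",
    "initial_velocity",
    "local_velocity",
    "step",
    "track_sequence",
    "track_per_channel",
]

logger = logging.getLogger(__name__)


@dataclass
class Track:
    """One tracked identity: filter state, lifecycle counters and history."""

    track_id: int
    state: KalmanState
    missed_frames: int = 0
    age: int = 0
    history: list = field(default_factory=list)  # (frame, x, y) of matched frames
    predicted_position: np.ndarray | None = None


@dataclass(frozen=True)
class TrackerConfig:
    """All tunables of the tracking loop.

    alpha
        Blend weight of the local median velocity against the global
        bulk-flow estimate when seeding new tracks, in [0, 1].
    alpha_activation_tracks
        Number of active tracks required before ``alpha`` switches from 0
        to its configured value.
    max_missed_frames
        A track unmatched for more than this many consecutive frames is
        deleted.
    roi
        ``(x_min, y_min, x_max, y_max)`` in pixels, or None for unbounded.
        Detections outside spawn no tracks; a track whose predicted
        flow-axis position leaves the ROI with no match is deleted.
    flow_direction
        "+x" for left-to-right flow, "-x" for right-to-left.
    refresh_v_g
        If True, re-estimate the bulk velocity every ``n_frame_pairs``
        frames over a sliding window instead of fixing it after
        initialisation.
    """

    gating: GatingParams = field(default_factory=GatingParams)
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    flow_init: FlowInitConfig = field(default_factory=FlowInitConfig)
    alpha: float = 0.7
    alpha_activation_tracks: int = 10
    max_missed_frames: int = 3
    roi: tuple[float, float, float, float] | None = None
    n_channels: int = 1
    flow_direction: str = "+x"
    refresh_v_g: bool = False
    channel_cluster_frames: int | None = None  # None: pool the whole sequence

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha!r}")
        if self.max_missed_frames < 1:
            raise ValueError("max_missed_frames must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.flow_direction not in ("+x", "-x"):
            raise ValueError("flow_direction must be '+x' or '-x'")

    @property
    def flow_sign(self) -> int:
        return 1 if self.flow_direction == "+x" else -1


@dataclass(frozen=True)
class FrameResult:
    """What happened in one tracking step."""

    frame: int
    assignments: list  # (track_id, detection_index)
    new_track_ids: list
    deleted_track_ids: list


def initial_velocity(v_local, v_global, alpha_effective: float) -> np.ndarray:
    """Staged seed velocity ``alpha * v_l + (1 - alpha) * v_g`` for new tracks."""
    v_g = np.asarray(v_global, dtype=float)
    if v_local is None:
        if alpha_effective != 0.0:
            raise ValueError("alpha_effective must be 0 when v_local is absent")
        return v_g
    v_l = np.asarray(v_local, dtype=float)
    return alpha_effective * v_l + (1.0 - alpha_effective) * v_g


def local_velocity(tracks) -> np.ndarray | None:
    """Component-wise median of Kalman velocities of tracks with age >= 2."""
    vels = [t.state.velocity for t in tracks if t.age >= 2]
    if not vels:
        return None
    return np.median(np.asarray(vels), axis=0)


def _in_roi(point, roi) -> bool:
    if roi is None:
        return True
    x_min, y_min, x_max, y_max = roi
    return (x_min <= point[0] <= x_max) and (y_min <= point[1] <= y_max)


def _exits_roi_flow_axis(x: float, roi) -> bool:
    if roi is None:
        return False
    x_min, _, x_max, _ = roi
    return x < x_min or x > x_max


class FloCyTracker:
    """Stateful tracker: feed frames with :meth:`step`, read trajectories at the end.

    ``v_global`` must be set (e.g. from :func:`flocyt.flow_init.pooled_estimate`)
    before the first step.
    """

    def __init__(self, config: TrackerConfig, v_global, id_start: int = 0):
        self.config = config
        self.v_global = np.asarray(v_global, dtype=float)
        self.tracks: list[Track] = []
        self._next_id = id_start
        self._archive: list[Track] = []  # deleted tracks, for trajectory export

    def step(self, detections, frame: int) -> FrameResult:
        cfg = self.config
        dets = np.asarray(detections, dtype=float).reshape(-1, 2)

        # staged alpha: rely on the bulk-flow estimate until enough tracks exist
        v_l = local_velocity(self.tracks)
        alpha_eff = (
            cfg.alpha
            if v_l is not None and len(self.tracks) >= cfg.alpha_activation_tracks
            else 0.0
        )
        v0 = initial_velocity(v_l if alpha_eff > 0 else None, self.v_global, alpha_eff)

        # (1) predict
        for t in self.tracks:
            t.state = kf_predict(t.state)
            t.predicted_position = t.state.position.copy()

        # (2)-(3) gate and associate
        predicted = np.array([t.predicted_position for t in self.tracks]).reshape(-1, 2)
        cost = build_cost_matrix(predicted, dets, cfg.gating, cfg.flow_sign)
        matches, unmatched_tracks, unmatched_dets = assign(cost)

        # (4) correct matched tracks
        assignments = []
        for i, j in matches:
            t = self.tracks[i]
            t.state = kf_update(t.state, dets[j])
            t.missed_frames = 0
            t.history.append((frame, float(dets[j, 0]), float(dets[j, 1])))
            assignments.append((t.track_id, j))

        # (5) miss counters
        for i in unmatched_tracks:
            self.tracks[i].missed_frames += 1

        # (6) lifecycle: stale tracks and predicted ROI exits (unmatched only —
        # a track that matched a detection inside the ROI survives)
        unmatched_set = set(unmatched_tracks)
        deleted_ids = []
        survivors = []
        for i, t in enumerate(self.tracks):
            stale = t.missed_frames > cfg.max_missed_frames
            exited = i in unmatched_set and _exits_roi_flow_axis(
                t.predicted_position[0], cfg.roi
            )
            if stale or exited:
                deleted_ids.append(t.track_id)
                self._archive.append(t)
            else:
                survivors.append(t)
        self.tracks = survivors

        # (7) births: unmatched detections inside the ROI
        new_ids = []
        for j in unmatched_dets:
            if not _in_roi(dets[j], cfg.roi):
                continue
            track = Track(
                track_id=self._next_id,
                state=kf_init(dets[j], v0, cfg.kalman),
                history=[(frame, float(dets[j, 0]), float(dets[j, 1]))],
            )
            self._next_id += 1
            new_ids.append(track.track_id)
            self.tracks.append(track)

        for t in self.tracks:
            t.age += 1

        logger.debug(
            "frame=%d n_tracks=%d n_matches=%d n_births=%d n_deaths=%d",
            frame,
            len(self.tracks),
            len(assignments),
            len(new_ids),
            len(deleted_ids),
        )
        return FrameResult(
            frame=frame,
            assignments=assignments,
            new_track_ids=new_ids,
            deleted_track_ids=deleted_ids,
        )

    def trajectories(self) -> TrajectorySet:
        """All matched (frame, id, x, y) records of every track ever created."""
        rows = []
        for t in self._archive + self.tracks:
            rows.extend((f, t.track_id, x, y) for f, x, y in t.history)
        return TrajectorySet(
            pd.DataFrame(rows, columns=["frame", "id", "x", "y"])
            if rows
            else pd.DataFrame(columns=["frame", "id", "x", "y"])
        )


def step(tracks, detections, frame, config, v_global, id_start=0):
    """Functional single-step wrapper: returns ``(tracks', FrameResult)``."""
    tracker = FloCyTracker(config, v_global, id_start=id_start)
    tracker.tracks = list(tracks)
    result = tracker.step(detections, frame)
    return tracker.tracks, result


def _run(detections_by_frame, config: TrackerConfig, v_global, id_start=0):
    tracker = FloCyTracker(config, v_global, id_start=id_start)
    window = config.flow_init.n_frame_pairs
    for frame, dets in enumerate(detections_by_frame):
        if (
            config.refresh_v_g
            and frame > 0
            and frame % window == 0
        ):
            recent = detections_by_frame[max(0, frame - window) : frame + 1]
            try:
                tracker.v_global = np.asarray(
                    pooled_estimate(recent, config.flow_init).v_g
                )
            except ValueError:
                pass  # too sparse to re-estimate; keep the previous value
        tracker.step(dets, frame)
    return tracker


def _initial_v_g(detections_by_frame, config: TrackerConfig):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(pooled_estimate(detections_by_frame, config.flow_init).v_g)


def track_sequence(detections_by_frame, config: TrackerConfig | None = None) -> TrajectorySet:
    """Track a whole detection sequence and return the hypothesis trajectories.

    The bulk-flow velocity is estimated from the first ``n_frame_pairs``
    consecutive frame pairs, then the per-frame loop runs from frame 0.
    """
    config = config or TrackerConfig()
    if len(detections_by_frame) < 2:
        raise ValueError("track_sequence requires at least 2 frames")
    v_g = _initial_v_g(detections_by_frame, config)
    return _run(detections_by_frame, config, v_g).trajectories()


def track_per_channel(
    detections_by_frame, config: TrackerConfig | None = None
) -> TrajectorySet:
    """Cluster detections into channel bands and track each band independently.

    1D K-Means (k = ``n_channels``) on the y coordinates of the detections in
    the first ``channel_cluster_frames`` frames defines the bands; every
    detection in the sequence is then routed to the nearest band centre.
    Track ids are disjoint across channels.
    """
    config = config or TrackerConfig()
    if len(detections_by_frame) < 2:
        raise ValueError("track_per_channel requires at least 2 frames")
    k = config.n_channels
    if k == 1:
        return track_sequence(detections_by_frame, config)

    frames = [np.asarray(f, dtype=float).reshape(-1, 2) for f in detections_by_frame]
    centers = _cluster_band_centers(frames, config)

    v_g_global = _initial_v_g(detections_by_frame, config)
    id_start = 0
    all_records = []
    for c in range(k):
        per_channel = []
        for f in frames:
            if f.shape[0] == 0:
                per_channel.append(f)
                continue
            nearest = np.argmin(np.abs(f[:, 1:2] - centers[None, :]), axis=1)
            per_channel.append(f[nearest == c])
        try:
            v_g = _initial_v_g(per_channel, config)
        except ValueError:
            v_g = v_g_global  # channel too sparse for its own estimate
        tracker = _run(per_channel, config, v_g, id_start=id_start)
        traj = tracker.trajectories()
        id_start = tracker._next_id
        all_records.append(traj.records)

    merged = pd.concat(all_records, ignore_index=True)
    return TrajectorySet(merged)


def _cluster_band_centers(frames, config: TrackerConfig) -> np.ndarray:
    """1D K-Means channel-band centres from pooled detection y coordinates.

    By default the whole sequence is pooled (tracking is offline and flow
    start-up is sparse — a short window can miss lanes entirely); setting
    ``channel_cluster_frames`` restricts clustering to an initial window,
    which is then still extended until it holds at least 10 detections per
    channel.  Fewer pooled detections than channels is an error: plain
    tracking should be used instead.
    """
    k = config.n_channels
    min_points = 10 * k
    window = config.channel_cluster_frames
    pooled = []
    n = 0
    for i, f in enumerate(frames):
        if window is not None and i >= window and n >= min_points:
            break
        if f.shape[0]:
            pooled.append(f[:, 1])
            n += f.shape[0]
    if n < k:
        raise ValueError(
            f"only {n} detections in the clustering window for {k} channels; "
            "use plain track_sequence instead"
        )
    pooled_y = np.concatenate(pooled).reshape(-1, 1)
    km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(pooled_y)
    return np.sort(km.cluster_centers_.ravel())


def channel_centers(detections_by_frame, config: TrackerConfig) -> np.ndarray:
    """Sorted K-Means band centres used by :func:`track_per_channel` (for QC)."""
    frames = [np.asarray(f, dtype=float).reshape(-1, 2) for f in detections_by_frame]
    return _cluster_band_centers(frames, config)
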