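"""CLEAR-MOT scoring of hypothesis trajectories against ground truth.

Implements the four metrics most informative when detections are exact
(ground-truth centroids used as detections, so classical detection misses
and false positives vanish):

* MOTA  — multiple-object tracking accuracy, ``1 - (FN + FP + IDSW) / n_gt``;
* IDSW  — identity switches: frames where a ground-truth object's matched
  hypothesis id differs from its most recent previous match;
* IDF1  — identification F1 under the optimal global one-to-one pairing of
  ground-truth and hypothesis identities;
* MT    — mostly tracked: percentage of ground-truth identities matched in
  at least 80% of their frames (inclusive threshold).

Per-frame correspondence follows the CLEAR convention: existing
object-hypothesis pairings persist while both are present and within the
match radius, and the residual pairs are matched by minimum total distance
(Hungarian).  Distances are Euclidean on centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .trajectories import TrajectorySet

__all__ = [
    "MotReport",
    "frame_correspondence",
    "compute_mota",
    "compute_idf1",
    "compute_mt",
    "evaluate",
]

MT_THRESHOLD = 0.8


@dataclass(frozen=True)
class MotReport:
    """Summary of one tracker-vs-ground-truth comparison."""

    mota: float
    idf1: float
    idsw: int
    mt_percent: float
    fp: int
    fn: int
    n_gt: int

    def to_dict(self) -> dict:
        return {
            "mota": self.mota,
            "idf1": self.idf1,
            "idsw": self.idsw,
            "mt_percent": self.mt_percent,
            "fp": self.fp,
            "fn": self.fn,
            "n_gt": self.n_gt,
        }


def _min_cost_matching(dist: np.ndarray, radius: float):
    """Hungarian matching restricted to pairs within the radius."""
    if dist.size == 0:
        return []
    feasible = dist <= radius
    if not feasible.any():
        return []
    sentinel = (radius + 1.0) * (min(dist.shape) + 1)
    padded = np.where(feasible, dist, sentinel)
    rows, cols = linear_sum_assignment(padded)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]


def frame_correspondence(gt_ids, gt_xy, hyp_ids, hyp_xy, match_radius, previous=None):
    """Match one frame's ground truth to hypotheses.

    ``previous`` maps gt id -> hyp id from the last frame each gt was
    matched; such pairings are kept whenever both parties are present and
    still within ``match_radius`` (identity persistence), even if a
    different hypothesis is marginally closer.  Residual pairs are matched
    by minimal total distance.  Returns ``(matches, fp, fn)`` with matches a
    gt id -> hyp id dict.
    """
    previous = previous or {}
    gt_ids = list(gt_ids)
    hyp_ids = list(hyp_ids)
    gt_xy = np.asarray(gt_xy, dtype=float).reshape(-1, 2)
    hyp_xy = np.asarray(hyp_xy, dtype=float).reshape(-1, 2)
    hyp_index = {h: k for k, h in enumerate(hyp_ids)}

    matches: dict = {}
    free_gt, free_hyp = [], set(range(len(hyp_ids)))
    for gi, g in enumerate(gt_ids):
        h = previous.get(g)
        k = hyp_index.get(h)
        if (
            k is not None
            and k in free_hyp
            and np.linalg.norm(gt_xy[gi] - hyp_xy[k]) <= match_radius
        ):
            matches[g] = h
            free_hyp.discard(k)
        else:
            free_gt.append(gi)

    free_hyp = sorted(free_hyp)
    if free_gt and free_hyp:
        dist = cdist(gt_xy[free_gt], hyp_xy[free_hyp])
        for i, j in _min_cost_matching(dist, match_radius):
            matches[gt_ids[free_gt[i]]] = hyp_ids[free_hyp[j]]

    fp = len(hyp_ids) - len(matches)
    fn = len(gt_ids) - len(matches)
    return matches, fp, fn


def _frames_index(traj: TrajectorySet) -> dict:
    out = {}
    for frame, sub in traj.by_frame():
        out[int(frame)] = (sub["id"].to_numpy(), sub[["x", "y"]].to_numpy())
    return out


def _clear_pass(gt: TrajectorySet, hyp: TrajectorySet, match_radius: float):
    """Single CLEAR sweep: totals of FP/FN/IDSW and per-gt matched-frame counts."""
    gt_by_frame = _frames_index(gt)
    hyp_by_frame = _frames_index(hyp)
    frames = sorted(set(gt_by_frame) | set(hyp_by_frame))

    fp = fn = idsw = 0
    last_match: dict = {}  # gt id -> most recent matched hyp id
    matched_frames: dict = {}  # gt id -> count
    previous: dict = {}  # carries the live correspondence frame to frame
    for frame in frames:
        g_ids, g_xy = gt_by_frame.get(frame, (np.empty(0, int), np.empty((0, 2))))
        h_ids, h_xy = hyp_by_frame.get(frame, (np.empty(0, int), np.empty((0, 2))))
        matches, f_fp, f_fn = frame_correspondence(
            g_ids, g_xy, h_ids, h_xy, match_radius, previous
        )
        fp += f_fp
        fn += f_fn
        for g, h in matches.items():
            if g in last_match and last_match[g] != h:
                idsw += 1
            last_match[g] = h
            matched_frames[g] = matched_frames.get(g, 0) + 1
        previous = dict(previous)
        previous.update(matches)
    return fp, fn, idsw, matched_frames


def _require_gt(gt: TrajectorySet) -> int:
    n_gt = len(gt)
    if n_gt == 0:
        raise ValueError("ground truth has no records; metrics are undefined")
    return n_gt


def compute_mota(gt: TrajectorySet, hyp: TrajectorySet, match_radius: float = 1.0):
    """Returns ``(mota, idsw, fp, fn)``."""
    n_gt = _require_gt(gt)
    fp, fn, idsw, _ = _clear_pass(gt, hyp, match_radius)
    mota = 1.0 - (fn + fp + idsw) / n_gt
    return mota, idsw, fp, fn


def compute_idf1(gt: TrajectorySet, hyp: TrajectorySet, match_radius: float = 1.0):
    """Identification F1 under the optimal global identity pairing.

    For every (gt id, hyp id) pair, count frames where both are present
    within the match radius; the one-to-one identity assignment maximizing
    total co-located frames gives IDTP, and
    ``IDF1 = 2 IDTP / (n_gt + n_hyp)``.
    """
    n_gt = _require_gt(gt)
    n_hyp = len(hyp)
    gt_ids = list(gt.ids)
    hyp_ids = list(hyp.ids)
    if not hyp_ids:
        return 0.0
    g_pos = {g: i for i, g in enumerate(gt_ids)}
    h_pos = {h: j for j, h in enumerate(hyp_ids)}

    overlap = np.zeros((len(gt_ids), len(hyp_ids)))
    hyp_by_frame = _frames_index(hyp)
    for frame, sub in gt.by_frame():
        h = hyp_by_frame.get(int(frame))
        if h is None:
            continue
        h_ids, h_xy = h
        g_ids = sub["id"].to_numpy()
        g_xy = sub[["x", "y"]].to_numpy()
        within = cdist(g_xy, h_xy) <= match_radius
        gi, hj = np.nonzero(within)
        for a, b in zip(gi, hj):
            overlap[g_pos[g_ids[a]], h_pos[h_ids[b]]] += 1

    rows, cols = linear_sum_assignment(-overlap)
    idtp = overlap[rows, cols].sum()
    return float(2.0 * idtp / (n_gt + n_hyp))


def compute_mt(gt: TrajectorySet, hyp: TrajectorySet, match_radius: float = 1.0):
    """Percentage of gt identities matched in >= 80% of their frames."""
    _require_gt(gt)
    _, _, _, matched_frames = _clear_pass(gt, hyp, match_radius)
    lifetimes = gt.records.groupby("id").size()
    mostly = sum(
        1
        for g, life in lifetimes.items()
        if matched_frames.get(g, 0) / life >= MT_THRESHOLD
    )
    return 100.0 * mostly / len(lifetimes)


def evaluate(gt: TrajectorySet, hyp: TrajectorySet, match_radius: float = 1.0) -> MotReport:
    """All four metrics in one report."""
    n_gt = _require_gt(gt)
    fp, fn, idsw, matched_frames = _clear_pass(gt, hyp, match_radius)
    mota = 1.0 - (fn + fp + idsw) / n_gt
    idf1 = compute_idf1(gt, hyp, match_radius)
    lifetimes = gt.records.groupby("id").size()
    mostly = sum(
        1
        for g, life in lifetimes.items()
        if matched_frames.get(g, 0) / life >= MT_THRESHOLD
    )
    mt_percent = 100.0 * mostly / len(lifetimes)
    return MotReport(
        mota=float(mota),
        idf1=float(idf1),
        idsw=int(idsw),
        mt_percent=float(mt_percent),
        fp=int(fp),
        fn=int(fn),
        n_gt=int(n_gt),
    )
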