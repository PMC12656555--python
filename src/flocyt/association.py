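"""Anisotropic gated cost matrix and Hungarian data association.

Candidate track–detection pairs are restricted to a search region elongated
along the flow axis (the image x axis): a pair is feasible when the
flow-axis displacement lies in ``[-s_bk, s_fr]`` and the orthogonal
displacement magnitude is at most ``s_ort``.  Feasible pairs carry their
Euclidean distance as cost; infeasible pairs are excluded from assignment
entirely.  The minimum-cost maximal matching is solved with the Hungarian
algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "GatingParams",
    "CostMatrix",
    "displacements",
    "gate",
    "build_cost_matrix",
    "assign",
]


@dataclass(frozen=True)
class GatingParams:
    """Anisotropic gate half-widths, all in pixels.

    ``s_fr`` bounds the forward (downstream) displacement, ``s_bk`` the
    backward displacement, and ``s_ort`` the orthogonal displacement.  For
    channel flow the gate should be elongated along the flow axis
    (``s_fr >= s_ort``); the converse is permitted but warned about.
    """

    s_fr: float = 600.0
    s_bk: float = 200.0
    s_ort: float = 100.0

    def __post_init__(self) -> None:
        for name in ("s_fr", "s_bk", "s_ort"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value!r}")
        if self.s_fr < self.s_ort:
            warnings.warn(
                "s_fr < s_ort: the gate is not elongated along the flow axis",
                stacklevel=2,
            )


@dataclass
class CostMatrix:
    """Gated assignment costs between N_p predictions and N_d detections.

    ``values`` holds the Euclidean distance where the pair is feasible and
    ``+inf`` otherwise; ``feasible_mask`` is the corresponding binary mask.
    """

    values: np.ndarray
    feasible_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def displacements(prediction, detection, flow_sign: int = 1):
    """Flow-parallel and orthogonal displacement of a detection from a prediction.

    ``flow_sign`` is +1 for left-to-right flow and -1 for right-to-left; it
    flips the sign of the parallel component so that "forward" always means
    downstream.
    """
    p = np.asarray(prediction, dtype=float)
    d = np.asarray(detection, dtype=float)
    return flow_sign * (d[..., 0] - p[..., 0]), d[..., 1] - p[..., 1]


def gate(delta_par, delta_ort, gating: GatingParams):
    """1 where the displacement falls inside the closed anisotropic gate, else 0."""
    delta_par = np.asarray(delta_par, dtype=float)
    delta_ort = np.asarray(delta_ort, dtype=float)
    ok = (
        (delta_par >= -gating.s_bk)
        & (delta_par <= gating.s_fr)
        & (np.abs(delta_ort) <= gating.s_ort)
    )
    return ok.astype(int)


def build_cost_matrix(
    predictions, detections, gating: GatingParams, flow_sign: int = 1
) -> CostMatrix:
    """Gated Euclidean cost matrix between predicted and detected positions."""
    p = np.asarray(predictions, dtype=float).reshape(-1, 2)
    d = np.asarray(detections, dtype=float).reshape(-1, 2)
    n_p, n_d = p.shape[0], d.shape[0]
    if n_p == 0 or n_d == 0:
        empty = np.zeros((n_p, n_d))
        return CostMatrix(values=empty, feasible_mask=empty.astype(int))
    delta_par, delta_ort = displacements(p[:, None, :], d[None, :, :], flow_sign)
    mask = gate(delta_par, delta_ort, gating)
    dist = np.hypot(d[None, :, 0] - p[:, None, 0], d[None, :, 1] - p[:, None, 1])
    values = np.where(mask == 1, dist, np.inf)
    return CostMatrix(values=values, feasible_mask=mask)


def assign(cost: CostMatrix):
    """Minimum-cost maximal matching over the feasible pairs.

    Returns ``(matches, unmatched_tracks, unmatched_detections)`` where
    matches is a list of ``(track_index, detection_index)`` pairs.  The
    Hungarian solver cannot take infinite costs, so infeasible entries are
    replaced by a finite sentinel larger than the total cost of any feasible
    matching; sentinel pairs in the solution are discarded afterwards, which
    also guarantees the number of feasible matches is maximal.
    """
    values = cost.values
    n_p, n_d = values.shape
    if n_p == 0 or n_d == 0 or not np.any(cost.feasible_mask):
        return [], list(range(n_p)), list(range(n_d))

    finite = values[np.isfinite(values)]
    sentinel = (finite.max() + 1.0) * (min(n_p, n_d) + 1)
    padded = np.where(np.isfinite(values), values, sentinel)
    rows, cols = linear_sum_assignment(padded)
    matches = [(int(i), int(j)) for i, j in zip(rows, cols) if np.isfinite(values[i, j])]
    matched_rows = {i for i, _ in matches}
    matched_cols = {j for _, j in matches}
    unmatched_tracks = [i for i in range(n_p) if i not in matched_rows]
    unmatched_detections = [j for j in range(n_d) if j not in matched_cols]
    return matches, unmatched_tracks, unmatched_detections
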