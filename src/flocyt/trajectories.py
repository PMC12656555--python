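"""Trajectory container shared by the tracker, simulator and evaluator.

A :class:`TrajectorySet` is a table of ``(frame, id, x, y)`` records — one
row per object per frame — the common currency for ground truth, tracker
output and CSV I/O.  ``(frame, id)`` pairs are unique.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["TrajectorySet"]

_COLUMNS = ["frame", "id", "x", "y"]


class TrajectorySet:
    """A set of point trajectories keyed by ``(frame, id)``.

    Backed by a pandas DataFrame with columns ``frame`` (int), ``id`` (int),
    ``x``, ``y`` (float pixels), sorted by frame then id.
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"missing column: {', '.join(missing)}")
        df = records[_COLUMNS].copy()
        df["frame"] = df["frame"].astype(int)
        df["id"] = df["id"].astype(int)
        df[["x", "y"]] = df[["x", "y"]].astype(float)
        if df.duplicated(subset=["frame", "id"]).any():
            raise ValueError("duplicate (frame, id) record")
        self.records = df.sort_values(["frame", "id"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_rows(cls, rows) -> "TrajectorySet":
        """Build from an iterable of (frame, id, x, y) tuples."""
        return cls(pd.DataFrame(list(rows), columns=_COLUMNS))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrajectorySet):
            return NotImplemented
        return self.records.equals(other.records)

    @property
    def ids(self) -> np.ndarray:
        return np.sort(self.records["id"].unique())

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.records["frame"].unique())

    def at_frame(self, frame: int) -> pd.DataFrame:
        return self.records[self.records["frame"] == frame]

    def by_frame(self):
        """Iterate ``(frame, sub-table)`` in frame order."""
        return self.records.groupby("frame", sort=True)

    def lifetime(self, obj_id: int) -> int:
        """Number of frames the object appears in."""
        return int((self.records["id"] == obj_id).sum())
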