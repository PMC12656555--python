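"""Synthetic capillary-flow dataset generator with known ground truth.

Elliptical "cells" traverse a multi-lane channel field of view from left to
right.  Each cell carries a constant base velocity drawn from a truncated
normal on ``[v_min, v_max]`` (flow heterogeneity); a global cosine
modulation ``m(t) = 1 + A cos(2 pi t / N)`` emulates the slow temporal
decay/variation of capillary-driven flow; a random subset of cells
undergoes a stop-and-go event (linear deceleration, a stationary hold,
linear re-acceleration) emulating transient obstructions; and zero-mean
Gaussian noise perturbs the per-frame displacements, standing in for
centroid-detection uncertainty.

Per-frame displacements of cell i:

    dx_i(t) = m(t) * vx_i(t) + eta_x(t),   eta_x ~ N(0, sigma_x^2)
    dy_i(t) = vy_i(t) + eta_y(t),          eta_y ~ N(0, sigma_y^2)

Lateral motion is clamped to the cell's channel band (geometric
confinement).  The generator records centroid position, frame number, cell
id and mean ellipse radius for every frame a cell is inside the field of
view — the ground truth, which doubles as the detection stream when
benchmarking trackers without a detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .trajectories import TrajectorySet

__all__ = [
    "SimConfig",
    "SimResult",
    "PRESETS",
    "modulation",
    "step_cell",
    "simulate",
    "render_frame",
]

#: Benchmark dataset grid: (v_min, v_max, total cells, throughput cells/s).
#: A-F sample higher base velocities, G-L lower; within each velocity band
#: the second configuration doubles-to-triples the cell density.
PRESETS: dict[str, tuple[float, float, int, float]] = {
    "A": (100, 500, 2000, 40),
    "B": (100, 500, 3000, 60),
    "C": (200, 300, 3000, 60),
    "D": (200, 300, 5000, 100),
    "E": (300, 400, 3000, 60),
    "F": (300, 400, 5000, 100),
    "G": (50, 100, 2000, 40),
    "H": (50, 100, 3000, 60),
    "I": (50, 150, 2000, 40),
    "J": (50, 150, 3000, 60),
    "K": (50, 300, 2000, 40),
    "L": (50, 300, 3000, 60),
}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults reproduce the benchmark geometry."""

    v_min: float = 50.0
    v_max: float = 300.0
    n_cells_total: int = 2000
    throughput: float = 40.0  # cells/s entering the FOV
    n_frames: int = 1500
    frame_size: tuple[int, int] = (1080, 1920)  # (height, width) pixels
    n_channels: int = 15
    sigma_x: float = 5.0
    sigma_y: float = 0.5
    stop_fraction: float = 0.05
    modulation_amplitude: float = 0.15
    fps: float = 30.0
    radius_range: tuple[float, float] = (8.0, 12.0)
    max_lateral_speed: float = 0.5  # |vy| bound, px/frame
    stop_decel_frames: int = 5
    stop_hold_range: tuple[int, int] = (5, 20)
    stop_accel_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.v_min <= self.v_max:
            raise ValueError("require 0 < v_min <= v_max")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.stop_fraction <= 1:
            raise ValueError("stop_fraction must be in [0, 1]")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SimConfig":
        v_min, v_max, n_cells, throughput = PRESETS[name.upper()]
        return cls(
            v_min=v_min,
            v_max=v_max,
            n_cells_total=n_cells,
            throughput=throughput,
            **overrides,
        )

    @property
    def channel_pitch(self) -> float:
        return self.frame_size[0] / self.n_channels


def modulation(t, N, amplitude: float = 0.15):
    """Global temporal flow modulation ``1 + A cos(2 pi t / N)``."""
    return 1.0 + amplitude * np.cos(2.0 * np.pi * np.asarray(t, dtype=float) / N)


@dataclass
class _Cell:
    cell_id: int
    channel: int
    x: float
    y: float
    base_vx: float
    vy: float
    radius: float
    spawn_frame: int
    stop_at: int | None = None  # frames after spawn when deceleration begins
    hold_frames: int = 0


def _velocity_factor(cell: _Cell, t: int, config: SimConfig) -> float:
    """Stop-and-go profile: 1 before the event, ramp down, hold at 0, ramp up."""
    if cell.stop_at is None:
        return 1.0
    rel = (t - cell.spawn_frame) - cell.stop_at
    if rel < 0:
        return 1.0
    d, h, a = config.stop_decel_frames, cell.hold_frames, config.stop_accel_frames
    if rel < d:
        return 1.0 - (rel + 1) / d
    if rel < d + h:
        return 0.0
    if rel < d + h + a:
        return (rel - d - h + 1) / a
    return 1.0


def _channel_band(cell_channel: int, radius: float, config: SimConfig):
    pitch = config.channel_pitch
    lo = cell_channel * pitch + radius + 1.0
    hi = (cell_channel + 1) * pitch - radius - 1.0
    if hi < lo:  # degenerate narrow channel: pin to the centre line
        mid = (cell_channel + 0.5) * pitch
        return mid, mid
    return lo, hi


def step_cell(cell: _Cell, t: int, config: SimConfig, rng: np.random.Generator) -> _Cell:
    """Advance one cell by one frame in place and return it."""
    m = modulation(t, config.n_frames, config.modulation_amplitude)
    vx = cell.base_vx * _velocity_factor(cell, t, config)
    # scale standard normals so the stream consumption — hence the sampled
    # cells — is identical across noise levels at a fixed seed
    eta_x = config.sigma_x * rng.standard_normal()
    eta_y = config.sigma_y * rng.standard_normal()
    cell.x += m * vx + eta_x
    lo, hi = _channel_band(cell.channel, cell.radius, config)
    cell.y = float(np.clip(cell.y + cell.vy + eta_y, lo, hi))
    return cell


@dataclass
class SimResult:
    """Ground truth plus the detection stream derived from it."""

    ground_truth: TrajectorySet
    detections: list  # per-frame (n, 2) arrays of (x, y)
    table: pd.DataFrame  # frame, id, x, y, radius
    config: SimConfig = field(repr=False, default=None)


def _spawn_cell(cell_id: int, frame: int, config: SimConfig, rng) -> _Cell:
    mean = 0.5 * (config.v_min + config.v_max)
    sd = (config.v_max - config.v_min) / 6.0
    if sd > 0:
        a, b = (config.v_min - mean) / sd, (config.v_max - mean) / sd
        base_vx = float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    else:
        base_vx = mean
    channel = int(rng.integers(config.n_channels))
    radius = float(rng.uniform(*config.radius_range))
    lo, hi = _channel_band(channel, radius, config)
    cell = _Cell(
        cell_id=cell_id,
        channel=channel,
        x=float(rng.uniform(0.0, base_vx)),
        y=float(rng.uniform(lo, hi)),
        base_vx=base_vx,
        vy=float(rng.uniform(-config.max_lateral_speed, config.max_lateral_speed)),
        radius=radius,
        spawn_frame=frame,
    )
    if rng.random() < config.stop_fraction:
        transit = max(4, int(config.frame_size[1] / base_vx))
        cell.stop_at = int(rng.integers(2, max(3, transit)))
        cell.hold_frames = int(rng.integers(*config.stop_hold_range))
    return cell


def _check_throughput(config: SimConfig) -> None:
    mean_v = 0.5 * (config.v_min + config.v_max)
    per_lane_rate = config.throughput / config.fps / config.n_channels
    mean_gap = mean_v / per_lane_rate if per_lane_rate > 0 else np.inf
    min_gap = 4.0 * config.radius_range[1]
    if mean_gap < min_gap:
        achievable = config.throughput * mean_gap / min_gap
        warnings.warn(
            f"throughput {config.throughput} cells/s exceeds channel geometry; "
            f"mean in-lane spacing {mean_gap:.0f} px < {min_gap:.0f} px "
            f"(roughly {achievable:.0f} cells/s achievable)",
            stacklevel=3,
        )


def simulate(config: SimConfig | None = None) -> SimResult:
    """Run the generator and return ground truth plus per-frame detections.

    Cells arrive at the left edge as a Poisson process with rate
    ``throughput / fps`` per frame (thinned once the configured total number
    of cells has been initialized), in uniformly random channels, and are
    recorded every frame until their centroid passes the right edge.
    Deterministic for a fixed config (including the seed).
    """
    config = config or SimConfig()
    _check_throughput(config)
    rng = np.random.default_rng(config.seed)
    width = config.frame_size[1]
    rate = config.throughput / config.fps

    active: list[_Cell] = []
    spawned = 0
    rows = []
    detections = []
    for t in range(config.n_frames):
        n_new = int(rng.poisson(rate))
        n_new = min(n_new, config.n_cells_total - spawned)
        for _ in range(n_new):
            active.append(_spawn_cell(spawned, t, config, rng))
            spawned += 1

        frame_pts = []
        still_active = []
        for cell in active:
            if t > cell.spawn_frame:
                step_cell(cell, t, config, rng)
            if cell.x < width:
                rows.append((t, cell.cell_id, cell.x, cell.y, cell.radius))
                frame_pts.append((cell.x, cell.y))
                still_active.append(cell)
        active = still_active
        detections.append(np.asarray(frame_pts, dtype=float).reshape(-1, 2))

    table = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "radius"])
    gt = TrajectorySet(table[["frame", "id", "x", "y"]])
    return SimResult(ground_truth=gt, detections=detections, table=table, config=config)


def render_frame(records, frame_size, n_channels: int = 15) -> np.ndarray:
    """Rasterize one frame: dark elliptical cells on a light background with
    horizontal channel-wall lines.  ``records`` is an iterable of
    ``(x, y, radius)``; purely cosmetic — tracking never consumes images.
    """
    height, width = frame_size
    img = np.full((height, width), 220, dtype=np.uint8)
    pitch = height / n_channels
    for c in range(n_channels + 1):
        row = min(height - 1, int(round(c * pitch)))
        img[row, :] = 40
    for x, y, radius in records:
        rx, ry = 1.2 * radius, 0.8 * radius
        x0, x1 = int(np.floor(x - rx)), int(np.ceil(x + rx)) + 1
        y0, y1 = int(np.floor(y - ry)), int(np.ceil(y + ry)) + 1
        x0, x1 = max(0, x0), min(width, x1)
        y0, y1 = max(0, y0), min(height, y1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)[None, :]
        ys = np.arange(y0, y1)[:, None]
        mask = ((xs - x) / rx) ** 2 + ((ys - y) / ry) ** 2 <= 1.0
        img[y0:y1, x0:x1][mask] = 40
    return img
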