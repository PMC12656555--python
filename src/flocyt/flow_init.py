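"""Maximum-likelihood bulk-flow velocity from displacement histograms.

Objects entrained in laminar channel flow share a dominant velocity.  It is
estimated without any track information by forming *all* cross-frame
centroid displacements between consecutive frames (a full m x n cross
product, not matched pairs), binning them into a 2D histogram, smoothing
with a Gaussian kernel, and taking the centre of the modal bin.  True
bulk motion piles coincident counts into one bin while the spurious
cross-pair displacements scatter, so the mode is the maximum-likelihood
bulk velocity.  Smoothing the *histogram* rather than kernel-density
estimating the raw vectors keeps the cost bounded by the histogram size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "FlowInitConfig",
    "FlowEstimate",
    "pairwise_displacements",
    "estimate_global_velocity",
    "pooled_estimate",
]


@dataclass(frozen=True)
class FlowInitConfig:
    """Histogram geometry and smoothing for the bulk-velocity estimator.

    kernel_sigma
        Gaussian smoothing width in *bins*.  Larger values give smoother,
        more robust density surfaces when few displacement vectors are
        available; smaller values preserve finer motion structure.
    n_frame_pairs
        Number of consecutive frame pairs pooled before binning.
    bin_width
        Histogram bin size in pixels.
    displacement_bounds_x, displacement_bounds_y
        Per-axis (min, max) extent of the histogram in pixels.  Defaults
        bracket the benchmark association gates so any associable motion
        falls inside the histogram.
    """

    kernel_sigma: float = 10.0
    n_frame_pairs: int = 15
    bin_width: float = 5.0
    displacement_bounds_x: tuple[float, float] = (-300.0, 700.0)
    displacement_bounds_y: tuple[float, float] = (-150.0, 150.0)

    def __post_init__(self) -> None:
        if not self.kernel_sigma > 0:
            raise ValueError(f"kernel_sigma must be > 0, got {self.kernel_sigma!r}")
        if self.n_frame_pairs < 1:
            raise ValueError(f"n_frame_pairs must be >= 1, got {self.n_frame_pairs!r}")
        if not self.bin_width > 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width!r}")
        for name in ("displacement_bounds_x", "displacement_bounds_y"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing (min, max) pair")


@dataclass(frozen=True)
class FlowEstimate:
    """Bulk-flow velocity estimate.

    v_g is the velocity vector in pixels/frame, ``support`` the number of
    displacement vectors pooled, and ``histogram_peak_density`` the smoothed
    density at the selected bin.
    """

    v_g: tuple[float, float]
    support: int
    histogram_peak_density: float


def pairwise_displacements(frame_a, frame_b) -> np.ndarray:
    """All m x n displacement vectors from centroids in frame_a to frame_b."""
    a = np.asarray(frame_a, dtype=float).reshape(-1, 2)
    b = np.asarray(frame_b, dtype=float).reshape(-1, 2)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((0, 2))
    return (b[None, :, :] - a[:, None, :]).reshape(-1, 2)


def _guard_bins(config: FlowInitConfig) -> int:
    """Bins of guard band appended on each side before smoothing, so that a
    peak anywhere inside the configured bounds is at least 3 kernel widths
    from the smoothing boundary (zero-padded smoothing would otherwise
    attenuate near-edge peaks and bias the argmax)."""
    return int(np.ceil(3.0 * config.kernel_sigma))


def _bin_edges(config: FlowInitConfig):
    pad = _guard_bins(config) * config.bin_width

    def edges(lo, hi):
        n = max(1, int(np.ceil((hi - lo) / config.bin_width)))
        g = _guard_bins(config)
        return (lo - pad) + config.bin_width * np.arange(n + 2 * g + 1)

    return edges(*config.displacement_bounds_x), edges(*config.displacement_bounds_y)


def _histogram(displacements_arr: np.ndarray, config: FlowInitConfig):
    ex, ey = _bin_edges(config)
    hist, _, _ = np.histogram2d(
        displacements_arr[:, 0], displacements_arr[:, 1], bins=(ex, ey)
    )
    return hist, ex, ey


def _smooth_and_pick(hist: np.ndarray, ex, ey, config: FlowInitConfig):
    """Gaussian-smooth the binned counts (guard bands included), crop back
    to the configured bounds and return (peak centre, peak density).

    Ties in the smoothed density resolve to the lowest flow-axis bin, then
    the lowest orthogonal bin (row-major argmax), for determinism.
    """
    g = _guard_bins(config)
    smoothed = gaussian_filter(hist, sigma=config.kernel_sigma, mode="constant")
    core = smoothed[g:-g, g:-g]
    ex_core, ey_core = ex[g:-g], ey[g:-g]
    flat = int(np.argmax(core))
    ix, iy = np.unravel_index(flat, core.shape)
    cx = 0.5 * (ex_core[ix] + ex_core[ix + 1])
    cy = 0.5 * (ey_core[iy] + ey_core[iy + 1])
    return (float(cx), float(cy)), float(core[ix, iy])


def estimate_global_velocity(
    displacements_arr, config: FlowInitConfig | None = None
) -> FlowEstimate:
    """Modal bin centre of the smoothed 2D displacement histogram."""
    config = config or FlowInitConfig()
    arr = np.asarray(displacements_arr, dtype=float).reshape(-1, 2)
    (lox, hix), (loy, hiy) = config.displacement_bounds_x, config.displacement_bounds_y
    inside = (
        (arr[:, 0] >= lox) & (arr[:, 0] < hix) & (arr[:, 1] >= loy) & (arr[:, 1] < hiy)
    )
    if not np.any(inside):
        raise ValueError(
            "no displacement falls inside displacement_bounds; "
            "bounds and detections are inconsistent"
        )
    hist, ex, ey = _histogram(arr, config)  # guard bands take the near-misses
    v_g, peak = _smooth_and_pick(hist, ex, ey, config)
    return FlowEstimate(v_g=v_g, support=int(inside.sum()), histogram_peak_density=peak)


def pooled_estimate(frames, config: FlowInitConfig | None = None) -> FlowEstimate:
    """Bulk velocity pooled over the first ``n_frame_pairs`` consecutive frame pairs.

    Frame pairs where either frame has no detections are skipped; if fewer
    pairs are available than requested, the available ones are used with a
    warning.
    """
    config = config or FlowInitConfig()
    frames = [np.asarray(f, dtype=float).reshape(-1, 2) for f in frames]
    if sum(1 for f in frames if f.shape[0] > 0) < 2:
        raise ValueError("pooled_estimate requires at least 2 non-empty frames")
    n_pairs_available = len(frames) - 1
    n_pairs = min(config.n_frame_pairs, n_pairs_available)
    if n_pairs < config.n_frame_pairs:
        warnings.warn(
            f"only {n_pairs} frame pairs available "
            f"(requested {config.n_frame_pairs}); using all of them",
            stacklevel=2,
        )
    pooled = []
    for a, b in zip(frames[:n_pairs], frames[1 : n_pairs + 1]):
        if a.shape[0] == 0 or b.shape[0] == 0:
            continue
        pooled.append(pairwise_displacements(a, b))
    if not pooled:
        raise ValueError("no frame pair with detections on both sides")
    return estimate_global_velocity(np.concatenate(pooled), config)
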