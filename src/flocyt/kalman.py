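"""Linear constant-velocity Kalman filtering of a single cell centroid.

Each cell is modelled with a 4-dimensional state ``[x, y, vx, vy]`` —
centroid position (pixels) and velocity (pixels/frame) — propagated under a
constant-velocity transition with one frame per time step.  Process noise
follows a white-acceleration model: unresolved accelerations (flow
instabilities, cell–cell interactions) enter as random velocity kicks whose
effect on position and velocity is correlated in the standard way.

Measurements are centroid detections ``[x, y]``; the observation model is a
direct position readout with isotropic Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KalmanConfig", "KalmanState", "kf_init", "kf_predict", "kf_update"]

# state transition: position advances by velocity x 1 frame
_F = np.array(
    [
        [1.0, 0.0, 1.0, 0.0],
        [0.0, 1.0, 0.0, 1.0],
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
# observation: position only
_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])


@dataclass(frozen=True)
class KalmanConfig:
    """Noise and initialisation scales for the centroid filter.

    Parameters
    ----------
    process_noise_scale : float
        White-acceleration intensity (px^2/frame^4).  Sets how quickly the
        filter forgets its velocity estimate, trading ramp-following
        against noise smoothing.  The default corresponds to an
        acceleration scale of 25 px/frame^2: the smallest headroom that
        still follows the decelerations cells undergo when transiently
        obstructed in fast capillary flow (up to ~100 px/frame^2 ramps stay
        within the backward gate), chosen low because a more reactive
        filter tracks detection noise and loses identities when slow cells
        pass within a noise-width of each other.
    measurement_noise_scale : float
        Variance of the centroid detection noise per axis (px^2).
    initial_position_var : float
        Prior position variance per axis (px^2) at track creation.
    initial_velocity_var : float
        Prior velocity variance per axis ((px/frame)^2).  Kept large by
        default so early detections dominate the (approximate) seed velocity.
    """

    process_noise_scale: float = 625.0
    measurement_noise_scale: float = 100.0
    initial_position_var: float = 100.0
    initial_velocity_var: float = 10000.0

    def __post_init__(self) -> None:
        for name in (
            "process_noise_scale",
            "measurement_noise_scale",
            "initial_position_var",
            "initial_velocity_var",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value!r}")

    @property
    def Q(self) -> np.ndarray:
        """Process-noise covariance from the white-acceleration model (dt=1)."""
        q = self.process_noise_scale
        return q * np.array(
            [
                [0.25, 0.0, 0.5, 0.0],
                [0.0, 0.25, 0.0, 0.5],
                [0.5, 0.0, 1.0, 0.0],
                [0.0, 0.5, 0.0, 1.0],
            ]
        )

    @property
    def R(self) -> np.ndarray:
        return self.measurement_noise_scale * np.eye(2)


@dataclass
class KalmanState:
    """Filter state: mean vector ``[x, y, vx, vy]`` and 4x4 covariance."""

    mean: np.ndarray
    covariance: np.ndarray
    config: KalmanConfig = field(default_factory=KalmanConfig)

    @property
    def position(self) -> np.ndarray:
        return self.mean[:2]

    @property
    def velocity(self) -> np.ndarray:
        return self.mean[2:]


def _check_finite_2vector(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.shape != (2,):
        raise ValueError(f"{name} must be a 2-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return arr


def kf_init(position, velocity, config: KalmanConfig | None = None) -> KalmanState:
    """Create a filter state for a newly born track.

    The mean is set directly from the detection position and the seed
    velocity (typically the blended global/local flow estimate); the
    covariance is diagonal from the config priors.
    """
    config = config or KalmanConfig()
    pos = _check_finite_2vector(position, "position")
    vel = _check_finite_2vector(velocity, "velocity")
    mean = np.concatenate([pos, vel])
    cov = np.diag(
        [
            config.initial_position_var,
            config.initial_position_var,
            config.initial_velocity_var,
            config.initial_velocity_var,
        ]
    ).astype(float)
    return KalmanState(mean=mean, covariance=cov, config=config)


def kf_predict(state: KalmanState) -> KalmanState:
    """Advance the state one frame under constant velocity.

    Position moves by the current velocity estimate; velocity is unchanged.
    The covariance is propagated through the transition and inflated by the
    process noise.
    """
    mean = _F @ state.mean
    cov = _F @ state.covariance @ _F.T + state.config.Q
    cov = 0.5 * (cov + cov.T)
    return KalmanState(mean=mean, covariance=cov, config=state.config)


def kf_update(state: KalmanState, detection) -> KalmanState:
    """Condition the predicted state on an associated detection."""
    z = _check_finite_2vector(detection, "detection")
    P = state.covariance
    S = _H @ P @ _H.T + state.config.R
    K = P @ _H.T @ np.linalg.solve(S.T, np.eye(2)).T  # P H^T S^-1
    innovation = z - _H @ state.mean
    mean = state.mean + K @ innovation
    # Joseph form keeps the posterior covariance symmetric PSD
    A = np.eye(4) - K @ _H
    cov = A @ P @ A.T + K @ state.config.R @ K.T
    cov = 0.5 * (cov + cov.T)
    return KalmanState(mean=mean, covariance=cov, config=state.config)
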