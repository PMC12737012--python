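"""Heading-aware Extended Kalman Filter for a single swimming cell.

State is ``(x, y, v, theta)``: pixel position, scalar speed (px/frame)
and heading angle (radians, wrapped to (-pi, pi]).  The motion model is
the unicycle-style map

    x <- x + v dt cos(theta)
    y <- y + v dt sin(theta)
    v <- v
    theta <- theta

linearized each step through its analytic Jacobian.  Coupling the
position update to the heading lets the predicted trajectory follow
curvilinear swimming paths instead of extrapolating along fixed
Cartesian axes, which is what makes prediction across detection
dropouts accurate enough for identity reassignment.

Only position is observed (the detection centroid); speed and heading
are estimated indirectly.  After each measurement update the (v, theta)
pair is renormalized to the canonical representation (v >= 0, theta the
direction of the velocity vector), which leaves the velocity vector
itself unchanged.

A reduced ``velocity_only`` mode removes the heading from the estimated
state ([x, y, v] ablation variant): theta receives no process noise and
no Jacobian coupling, and is instead carried forward from the
displacement direction of successive filtered positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EKFState",
    "EKFNoiseConfig",
    "ekf_init",
    "ekf_predict",
    "ekf_update",
    "ekf_velocity",
    "ekf_loss",
    "motion_jacobian",
    "wrap_angle",
]

_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])


def wrap_angle(theta: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    wrapped = math.remainder(theta, 2.0 * math.pi)
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass
class EKFNoiseConfig:
    """Noise and initialization parameters of the filter.

    ``sigma_q`` / ``sigma_r`` are the assumed process and measurement
    noise standard deviations; ``q_scale`` (alpha) and ``r_scale``
    (beta) are the unitless multipliers swept in sensitivity analyses
    (alpha = beta = 1 is the default operating point).  Q = alpha *
    sigma_q^2 * I4; R = beta * sigma_r^2 * I2 (the measurement is
    2-dimensional, so R is 2x2).  ``dt`` is the time step in frames.
    """

    sigma_q: float = 1.0
    sigma_r: float = 1.0
    q_scale: float = 1.0
    r_scale: float = 1.0
    dt: float = 1.0
    heading_epsilon: float = 1e-4
    init_pos_var: float = 10.0
    init_vel_var: float = 25.0
    init_theta_var: float = float(np.pi**2)
    state_mode: str = "heading"  # "heading" | "velocity_only"

    def __post_init__(self) -> None:
        for name in ("sigma_q", "sigma_r", "q_scale", "r_scale", "dt",
                     "heading_epsilon", "init_pos_var", "init_vel_var",
                     "init_theta_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.state_mode not in ("heading", "velocity_only"):
            raise ValueError(f"unknown state_mode {self.state_mode!r}")

    def process_noise(self) -> np.ndarray:
        Q = self.q_scale * self.sigma_q**2 * np.eye(4)
        if self.state_mode == "velocity_only":
            Q[3, 3] = 0.0  # heading is not an estimated state
        return Q

    def measurement_noise(self) -> np.ndarray:
        return self.r_scale * self.sigma_r**2 * np.eye(2)


@dataclass
class EKFState:
    """Filter state for one identity: mean (x, y, v, theta) and 4x4 P."""

    x: float
    y: float
    v: float
    theta: float
    P: np.ndarray
    last_frame: int = 0

    def mean(self) -> np.ndarray:
        return np.array([self.x, self.y, self.v, self.theta])

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)

    def copy(self) -> "EKFState":
        return EKFState(self.x, self.y, self.v, self.theta, self.P.copy(), self.last_frame)


def ekf_init(z: tuple[float, float], cfg: EKFNoiseConfig, frame: int = 0) -> EKFState:
    """Start a filter at a first observation.

    Speed and heading are unobservable from a single detection, so they
    start at zero with large configured variances and converge over the
    next few updates.
    """
    x, y = float(z[0]), float(z[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite initial position {z!r}")
    P = np.diag([cfg.init_pos_var, cfg.init_pos_var, cfg.init_vel_var, cfg.init_theta_var])
    if cfg.state_mode == "velocity_only":
        P[3, 3] = 0.0
    return EKFState(x, y, v=0.0, theta=0.0, P=P, last_frame=frame)


def motion_jacobian(s: EKFState, dt: float, state_mode: str = "heading") -> np.ndarray:
    """Analytic Jacobian of the motion map at the current state."""
    c, si = math.cos(s.theta), math.sin(s.theta)
    F = np.array(
        [
            [1.0, 0.0, dt * c, -s.v * dt * si],
            [0.0, 1.0, dt * si, s.v * dt * c],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    if state_mode == "velocity_only":
        F[0, 3] = 0.0
        F[1, 3] = 0.0
    return F


def ekf_predict(s: EKFState, cfg: EKFNoiseConfig) -> EKFState:
    """One prediction step: propagate mean and covariance by one dt."""
    dt = cfg.dt
    F = motion_jacobian(s, dt, cfg.state_mode)
    x = s.x + s.v * dt * math.cos(s.theta)
    y = s.y + s.v * dt * math.sin(s.theta)
    P = F @ s.P @ F.T + cfg.process_noise()
    return EKFState(x, y, s.v, s.theta, P, s.last_frame)


def ekf_update(s: EKFState, z: tuple[float, float], cfg: EKFNoiseConfig) -> EKFState:
    """Measurement update with a detection centroid.

    Standard EKF correction with the position-selection observation
    matrix, followed by canonicalization of (v, theta) whenever the
    velocity vector is above ``heading_epsilon`` in magnitude, and
    re-symmetrization of P.
    """
    zx, zy = float(z[0]), float(z[1])
    if not (math.isfinite(zx) and math.isfinite(zy)):
        raise ValueError(f"non-finite measurement {z!r}")

    R = cfg.measurement_noise()
    S = _H @ s.P @ _H.T + R
    try:
        K = np.linalg.solve(S.T, (s.P @ _H.T).T).T
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError("singular innovation covariance") from exc
    if not np.all(np.isfinite(K)):
        raise ArithmeticError("non-finite Kalman gain")

    innov = np.array([zx - s.x, zy - s.y])
    mean = s.mean() + K @ innov
    P = (np.eye(4) - K @ _H) @ s.P
    P = (P + P.T) / 2.0

    x, y, v, theta = mean
    prev_x, prev_y = s.x, s.y

    if cfg.state_mode == "velocity_only":
        # Heading is carried, not filtered: take the direction of the
        # displacement of the filtered position over this step.
        dx, dy = x - prev_x, y - prev_y
        if math.hypot(dx, dy) > cfg.heading_epsilon:
            theta = math.atan2(dy, dx)
        else:
            theta = s.theta
        v = abs(v)
    else:
        vx, vy = v * math.cos(theta), v * math.sin(theta)
        if math.hypot(vx, vy) > cfg.heading_epsilon:
            theta = math.atan2(vy, vx)
            v = abs(v)

    return EKFState(float(x), float(y), float(v), wrap_angle(float(theta)), P, s.last_frame)


def ekf_velocity(s: EKFState) -> tuple[float, float]:
    """Cartesian velocity (vx, vy) implied by the polar (v, theta) state."""
    return (s.v * math.cos(s.theta), s.v * math.sin(s.theta))


def ekf_loss(s: EKFState, z: tuple[float, float]) -> float:
    """Euclidean distance (px) between the state's position and z."""
    return math.hypot(float(z[0]) - s.x, float(z[1]) - s.y)
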