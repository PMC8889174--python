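"""Trial measures and model-evaluation metrics.

The primary response measure of a trial is *final heading*: the
circular-mean heading over the last 2 s, reported in right-positive
degrees from the forward direction.  Left-turn trials are collapsed by
sign flip so that left and right responses pool.  Model fits are scored
by heading/speed RMSE and mean position error between two trajectories
on a common time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, stats

from .conventions import heading_to_display_deg
from .optics import wrap_angle
from .simulator import Trajectory

__all__ = [
    "TrialMeasures",
    "lowpass",
    "lowpass_trajectory",
    "final_heading",
    "collapse_left_right",
    "rmse_series",
    "heading_rmse",
    "speed_rmse",
    "mean_position_error",
    "fit_line_and_x_intercept",
    "polarization",
    "trial_measures",
]

FINAL_WINDOW = 2.0


@dataclass(frozen=True)
class TrialMeasures:
    """Response measures extracted from one trial trajectory."""

    final_heading: float  # degrees, right-positive from forward
    heading_deg: np.ndarray
    speed: np.ndarray
    times: np.ndarray


def lowpass(series, cutoff_hz: float, dt: float, order: int = 4):
    """Zero-phase Butterworth low-pass of a uniformly sampled series.

    Filters along the first axis (so an (N, 2) position series works
    directly); heading and speed should be derived afterwards by
    differentiating the filtered positions.
    """
    series = np.asarray(series, dtype=float)
    nyquist = 0.5 / dt
    if not 0 < cutoff_hz < nyquist:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    sos = signal.butter(order, cutoff_hz / nyquist, output="sos")
    padlen = 6 * (order + 1)
    if series.shape[0] <= padlen:
        raise ValueError("series shorter than the filter warm-up")
    return signal.sosfiltfilt(sos, series, axis=0, padlen=padlen)


def lowpass_trajectory(traj: Trajectory, cutoff_hz: float = 1.0) -> Trajectory:
    """Filter a trajectory's positions and re-derive heading and speed."""
    pos = lowpass(traj.positions, cutoff_hz, traj.dt)
    vel = np.gradient(pos, traj.dt, axis=0)
    return Trajectory(
        times=traj.times,
        x=pos[:, 0],
        y=pos[:, 1],
        heading=np.arctan2(vel[:, 1], vel[:, 0]),
        speed=np.hypot(vel[:, 0], vel[:, 1]),
        agent_id=traj.agent_id,
    )


def _circular_mean_deg(deg) -> float:
    rad = np.radians(np.asarray(deg, dtype=float))
    return math.degrees(
        math.atan2(float(np.mean(np.sin(rad))), float(np.mean(np.cos(rad))))
    )


def final_heading(traj: Trajectory, window: float = FINAL_WINDOW) -> float:
    """Circular-mean display heading (degrees) over the trial's last ``window`` s."""
    if traj.duration < window - 1e-9:
        raise ValueError(f"trajectory shorter than the {window} s window")
    mask = traj.times >= traj.times[-1] - window - 1e-9
    return _circular_mean_deg(heading_to_display_deg(traj.heading[mask]))


def collapse_left_right(measures: TrialMeasures, direction: str) -> TrialMeasures:
    """Pool left and right trials by negating headings on left trials."""
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    if direction == "right":
        return measures
    return replace(
        measures,
        final_heading=-measures.final_heading,
        heading_deg=-measures.heading_deg,
    )


def _common_grid(a: Trajectory, b: Trajectory):
    if len(a) != len(b) or not np.allclose(a.times, b.times, atol=1e-9):
        raise ValueError("trajectories are not on a common time grid")


def rmse_series(a, b) -> float:
    """Root-mean-squared difference of two equally sampled series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series length mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def heading_rmse(a: Trajectory, b: Trajectory) -> float:
    """Heading RMSE in degrees, using the circular (wrapped) difference."""
    _common_grid(a, b)
    diff = np.degrees(wrap_angle(a.heading - b.heading))
    return float(np.sqrt(np.mean(np.asarray(diff) ** 2)))


def speed_rmse(a: Trajectory, b: Trajectory) -> float:
    _common_grid(a, b)
    return rmse_series(a.speed, b.speed)


def mean_position_error(a: Trajectory, b: Trajectory) -> float:
    """Mean Euclidean distance between two position series (metres)."""
    _common_grid(a, b)
    return float(np.mean(np.hypot(a.x - b.x, a.y - b.y)))


def fit_line_and_x_intercept(x, y):
    """OLS fit ``y = slope*x + intercept`` plus its x-axis crossing.

    Returns ``(slope, intercept, r, x0)``; ``x0`` is NaN for a flat line.
    Used to extrapolate the interaction range from final-heading-vs-
    distance data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points")
    res = stats.linregress(x, y)
    slope, intercept, r = res.slope, res.intercept, res.rvalue
    x0 = math.nan if slope == 0 else -intercept / slope
    return float(slope), float(intercept), float(r), float(x0)


def polarization(states) -> float:
    """Magnitude of the mean heading unit vector; 1 = fully aligned."""
    headings = np.array(
        [s.heading if hasattr(s, "heading") else float(s) for s in states]
    )
    if headings.size == 0:
        raise ValueError("need at least one agent")
    return float(
        np.hypot(np.mean(np.cos(headings)), np.mean(np.sin(headings)))
    )


def trial_measures(
    traj: Trajectory,
    direction: str = "right",
    window: float = FINAL_WINDOW,
) -> TrialMeasures:
    """Extract (collapsed) response measures from a trial trajectory."""
    m = TrialMeasures(
        final_heading=final_heading(traj, window),
        heading_deg=np.asarray(heading_to_display_deg(traj.heading)),
        speed=traj.speed.copy(),
        times=traj.times.copy(),
    )
    return collapse_left_right(m, direction)
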