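"""First-person optical variables of a neighbouring pedestrian.

A focal walker receives, for each neighbour, a small set of optical
variables: the eccentricity ``beta`` of the neighbour relative to the
walker's heading, the angular velocity ``psi_dot`` of the line of sight,
and the rate of expansion ``theta_dot`` of the visual angle subtended by
the neighbour's body.  These are the inputs to the control laws in
:mod:`crowdvis.control`.

Conventions
-----------
* World frame: positions in metres, headings stored as standard
  counterclockwise (CCW) angles in radians from the +x axis; a walker's
  velocity is ``speed * (cos(heading), sin(heading))``.
* Optical frame: eccentricity ``beta`` and angular velocity ``psi_dot``
  are *positive to the observer's right* (clockwise seen from above).
  The conversion between the two conventions happens here and only here.
* Bodies are discs of diameter ``w``; the full subtended angle is
  ``theta = 2*arctan(w / (2 d))``, clamped to pi once the discs overlap
  (``d <= w/2``) so that simulations survive interpenetration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AgentState",
    "BodyModel",
    "OpticalState",
    "wrap_angle",
    "relative_geometry",
    "visual_angle",
    "angular_velocity",
    "expansion_rate",
    "relative_expansion",
    "optical_state",
]

logger = logging.getLogger(__name__)


def wrap_angle(a):
    """Wrap an angle (scalar or array) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + math.pi) % (2.0 * math.pi) - math.pi)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass
class AgentState:
    """Kinematic state of one pedestrian at an instant.

    ``heading`` is CCW radians from +x; ``speed`` is non-negative by
    default (a signed-speed mode exists in the simulator config).
    """

    position: np.ndarray
    heading: float
    speed: float
    heading_rate: float = 0.0
    speed_rate: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (2,):
            raise ValueError("position must be a 2-vector")
        if not np.isfinite(self.position).all():
            raise ValueError("position must be finite")
        for name in ("heading", "speed", "heading_rate", "speed_rate"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, v)
        self.heading = wrap_angle(self.heading)

    @property
    def velocity(self) -> np.ndarray:
        return self.speed * np.array(
            [math.cos(self.heading), math.sin(self.heading)]
        )

    def copy(self) -> "AgentState":
        return replace(self, position=self.position.copy())


@dataclass(frozen=True)
class BodyModel:
    """A pedestrian body approximated as a disc of diameter ``w`` metres."""

    diameter: float = 0.4

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValueError("body diameter must be positive")


@dataclass(frozen=True)
class OpticalState:
    """What one neighbour looks like from a focal agent.

    ``bearing`` is the world-frame CCW direction of the line of sight;
    ``eccentricity`` and ``angular_velocity`` use the right-positive
    optical convention.  ``visibility`` is filled in by
    :mod:`crowdvis.visibility` (1.0 until occlusion is applied).
    """

    distance: float
    bearing: float
    eccentricity: float
    visual_angle: float
    angular_velocity: float
    expansion_rate: float
    range_rate: float = 0.0
    visibility: float = 1.0


def _check_distinct(p: AgentState, n: AgentState) -> np.ndarray:
    rel = n.position - p.position
    if float(rel @ rel) == 0.0:
        raise ValueError(
            "degenerate geometry: focal agent and neighbour share a position"
        )
    return rel


def relative_geometry(p: AgentState, n: AgentState):
    """Distance, bearing, eccentricity and range rate of ``n`` seen from ``p``.

    Returns ``(d, psi, beta, d_dot)`` where ``psi`` is the world-frame CCW
    bearing, ``beta`` is the eccentricity (positive when ``n`` is to
    ``p``'s right) and ``d_dot`` is the component of relative velocity
    along the line of sight (positive = receding).
    """
    rel = _check_distinct(p, n)
    d = float(np.hypot(rel[0], rel[1]))
    psi = math.atan2(rel[1], rel[0])
    # CCW heading minus CCW bearing = clockwise offset = right-positive.
    beta = wrap_angle(p.heading - psi)
    v_rel = n.velocity - p.velocity
    d_dot = float(v_rel @ rel) / d
    return d, psi, beta, d_dot


def visual_angle(w: float, d: float) -> float:
    """Full angle subtended by a frontal extent ``w`` at distance ``d``.

    ``theta = 2*arctan(w / (2 d))``, which stays defined (and below pi)
    even when bodies interpenetrate (``d < w/2``); overlap is logged
    rather than raised so simulations survive it.
    """
    if not w > 0:
        raise ValueError("body diameter must be positive")
    if not d > 0:
        raise ValueError("distance must be positive")
    if d < w / 2.0:
        logger.warning("bodies overlap (d=%.3f < w/2=%.3f)", d, w / 2.0)
    return 2.0 * math.atan2(w, 2.0 * d)


def angular_velocity(p: AgentState, n: AgentState) -> float:
    """Signed rate of change of the line of sight, positive rightward.

    Computed from the transverse component of the relative velocity of
    the neighbour's body centre: ``psi_dot = v_perp / d``.
    """
    rel = _check_distinct(p, n)
    d2 = float(rel @ rel)
    v_rel = n.velocity - p.velocity
    # 2-D cross product rel x v_rel is CCW-positive; negate for
    # right-positive optical convention.
    return -float(rel[0] * v_rel[1] - rel[1] * v_rel[0]) / d2


def expansion_rate(w: float, d: float, d_dot: float) -> float:
    """Time derivative of the visual angle; positive for approach.

    ``d/dt [2 atan(w/2d)] = -w * d_dot / (d**2 + w**2/4)``.
    """
    if not w > 0:
        raise ValueError("body diameter must be positive")
    if not d > 0:
        raise ValueError("distance must be positive")
    return -w * d_dot / (d * d + w * w / 4.0)


def relative_expansion(theta_dot: float, theta: float) -> float:
    """Size-normalized expansion ``theta_dot / theta`` (1/s)."""
    if not theta > 0:
        raise ValueError("visual angle must be positive")
    return theta_dot / theta


def optical_state(p: AgentState, n: AgentState, body: BodyModel) -> OpticalState:
    """Bundle all optical variables of neighbour ``n`` as seen by ``p``."""
    d, psi, beta, d_dot = relative_geometry(p, n)
    return OpticalState(
        distance=d,
        bearing=psi,
        eccentricity=beta,
        visual_angle=visual_angle(body.diameter, d),
        angular_velocity=angular_velocity(p, n),
        expansion_rate=expansion_rate(body.diameter, d, d_dot),
        range_rate=d_dot,
    )


# ---------------------------------------------------------------------------
# Vectorized core used by the simulator (one focal agent vs. many
# neighbours described by raw arrays).  Kept free of dataclass overhead.
# ---------------------------------------------------------------------------

def optical_arrays(position, heading, velocity, nbr_positions, nbr_velocities, w):
    """Optical variables of many neighbours at once.

    Parameters are raw arrays: ``nbr_positions`` (n, 2) and
    ``nbr_velocities`` (n, 2).  Returns a dict of 1-D arrays
    ``d, psi, beta, theta, psi_dot, theta_dot, d_dot`` in the same
    conventions as the scalar functions.
    """
    rel = np.asarray(nbr_positions, dtype=float) - np.asarray(position, dtype=float)
    d2 = np.einsum("ij,ij->i", rel, rel)
    if np.any(d2 == 0.0):
        raise ValueError("degenerate geometry: coincident agent positions")
    d = np.sqrt(d2)
    psi = np.arctan2(rel[:, 1], rel[:, 0])
    beta = wrap_angle(heading - psi)
    v_rel = np.asarray(nbr_velocities, dtype=float) - np.asarray(velocity, dtype=float)
    d_dot = np.einsum("ij,ij->i", v_rel, rel) / d
    psi_dot = -(rel[:, 0] * v_rel[:, 1] - rel[:, 1] * v_rel[:, 0]) / d2
    theta = 2.0 * np.arctan2(w, 2.0 * d)
    theta_dot = -w * d_dot / (d2 + w * w / 4.0)
    return {
        "d": d,
        "psi": psi,
        "beta": np.atleast_1d(beta),
        "theta": theta,
        "psi_dot": psi_dot,
        "theta_dot": theta_dot,
        "d_dot": d_dot,
    }
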