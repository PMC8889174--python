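"""Behavioural control laws: visual model and omniscient baseline.

Visual model
------------
A walker nulls the optical motion of each neighbour.  For neighbour *i*
at eccentricity ``beta_i`` (right-positive) with angular velocity
``psi_dot_i`` (right-positive) and expansion rate ``theta_dot_i``::

    heading:  phi_ddot = -c1 * cos(beta_i) * psi_dot_i + c2 * sin(beta_i) * theta_dot_i
    speed:    r_ddot   = -c3 * sin(beta_i) * psi_dot_i - c4 * cos(beta_i) * theta_dot_i

The eccentricity terms act as a filter: dead ahead, heading responds
only to angular velocity and speed only to expansion; at 90 deg the
roles swap.  The returned ``phi_ddot`` is a CCW-positive (leftward)
heading acceleration in the world convention of :mod:`crowdvis.optics`:
a neighbour drifting leftward in the view (negative ``psi_dot``) makes
the walker accelerate its heading leftward.

Multiple neighbours are combined by the visibility-weighted average
``(1/n) * sum_i v_i * law_i`` over the ``n`` neighbours inside the field
of view with thresholded visibility ``v_i > 0``.  With nobody visible
the walker simply coasts.

Omniscient baseline
-------------------
A damped relaxation of heading and speed toward the distance-weighted
circular-mean heading and mean speed of neighbours within the field of
view, with weights ``exp(-d / lambda)`` truncated at a cutoff radius
(default 4 m).  An optional gradual long-range term
``b * exp(-d / lambda2)`` (not truncated) extends the decay for
far-crowd conditions.  The relaxation gains are documented stand-ins,
exposed in :class:`OmniscientParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optics import AgentState, BodyModel, optical_arrays, wrap_angle
from .visibility import VisibilityConfig, visibility_weights_arrays

__all__ = [
    "VisualParams",
    "OmniscientParams",
    "heading_accel_single",
    "speed_accel_single",
    "visual_model_step",
    "omniscient_model_step",
]


@dataclass(frozen=True)
class VisualParams:
    """Gains of the visual control laws (fitted constants, held fixed).

    ``use_relative_expansion`` substitutes the size-normalized
    ``theta_dot / theta`` for ``theta_dot`` in both laws.

    ``heading_damping`` is the turning-rate damping applied at the
    neighbourhood level (``-b * phi_dot`` added to the averaged heading
    acceleration whenever at least one neighbour is visible).  The
    per-neighbour laws alone form a marginally stable oscillator in
    heading; a rate-damping term of this kind appears throughout the
    steering-dynamics literature and is required for the smooth,
    distance-graded responses seen in the experiments.  Set it to zero
    to recover the bare averaged laws.
    """

    c1: float = 14.38
    c2: float = 59.71
    c3: float = 0.18
    c4: float = 0.72
    use_relative_expansion: bool = False
    heading_damping: float = 15.0

    def __post_init__(self):
        if min(self.c1, self.c2, self.c3, self.c4) <= 0:
            raise ValueError("control gains must be positive")
        if self.heading_damping < 0:
            raise ValueError("heading damping must be non-negative")


@dataclass(frozen=True)
class OmniscientParams:
    """Tunables of the omniscient baseline.

    ``heading_gain``/``speed_gain`` set the stiffness of the relaxation,
    ``heading_damping`` damps the turning rate, ``decay_length`` and
    ``cutoff`` shape the distance weighting.  ``gradual_weight`` /
    ``gradual_length`` add the optional long-range exponential term.

    The relaxation gains are stand-ins calibrated so the baseline
    reproduces the visual model's responses on the two-row perturbation
    grid (where the two models behave nearly identically); they are not
    fitted constants.
    """

    heading_gain: float = 1.0
    speed_gain: float = 0.2
    heading_damping: float = 3.0
    decay_length: float = 1.3
    cutoff: float = 4.0
    gradual_weight: float = 0.0
    gradual_length: float = 10.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff radius must be positive")
        if self.decay_length <= 0 or self.gradual_length <= 0:
            raise ValueError("decay lengths must be positive")
        if self.gradual_weight < 0:
            raise ValueError("weights must be non-negative")

    def weight(self, d):
        """Distance weight: truncated exponential plus optional gradual term."""
        d = np.asarray(d, dtype=float)
        w = np.exp(-d / self.decay_length) * (d <= self.cutoff)
        if self.gradual_weight > 0:
            w = w + self.gradual_weight * np.exp(-d / self.gradual_length)
        return w


def heading_accel_single(beta, psi_dot, theta_dot, params: VisualParams | None = None):
    """Heading acceleration from a single neighbour's optical motion."""
    p = params or VisualParams()
    return -p.c1 * np.cos(beta) * psi_dot + p.c2 * np.sin(beta) * theta_dot


def speed_accel_single(beta, psi_dot, theta_dot, params: VisualParams | None = None):
    """Speed (radial) acceleration from a single neighbour's optical motion."""
    p = params or VisualParams()
    return -p.c3 * np.sin(beta) * psi_dot - p.c4 * np.cos(beta) * theta_dot


def visual_model_step(
    p: AgentState,
    neighbours,
    body: BodyModel | None = None,
    params: VisualParams | None = None,
    vis_cfg: VisibilityConfig | None = None,
):
    """One evaluation of the visual model for focal agent ``p``.

    Computes the optical state of every neighbour, keeps those inside
    the field of view with thresholded visibility above zero, and
    returns the visibility-weighted average ``(phi_ddot, r_ddot)``.
    Returns ``(0.0, 0.0)`` when no neighbour is visible.
    """
    body = body or BodyModel()
    neighbours = list(neighbours)
    if not neighbours:
        return 0.0, 0.0
    positions = np.array([n.position for n in neighbours])
    velocities = np.array([n.velocity for n in neighbours])
    return visual_model_accels(
        p.position, p.heading, p.velocity, positions, velocities,
        body, params or VisualParams(), vis_cfg or VisibilityConfig(),
        heading_rate=p.heading_rate,
    )


def visual_model_accels(position, heading, velocity, nbr_positions,
                        nbr_velocities, body, params, vis_cfg,
                        heading_rate=0.0):
    """Array-native core of :func:`visual_model_step`."""
    opt = optical_arrays(
        position, heading, velocity, nbr_positions, nbr_velocities, body.diameter
    )
    _, weights = visibility_weights_arrays(
        opt["d"], opt["beta"], opt["theta"], vis_cfg
    )
    visible = weights > 0.0
    n = int(visible.sum())
    if n == 0:
        return 0.0, 0.0
    beta = opt["beta"][visible]
    psi_dot = opt["psi_dot"][visible]
    expansion = opt["theta_dot"][visible]
    if params.use_relative_expansion:
        expansion = expansion / opt["theta"][visible]
    w = weights[visible]
    phi_ddot = float(np.sum(w * heading_accel_single(beta, psi_dot, expansion, params)) / n)
    phi_ddot -= params.heading_damping * heading_rate
    r_ddot = float(np.sum(w * speed_accel_single(beta, psi_dot, expansion, params)) / n)
    return phi_ddot, r_ddot


def omniscient_model_step(
    p: AgentState,
    neighbours,
    params: OmniscientParams | None = None,
    fov: float = math.pi,
):
    """One evaluation of the omniscient baseline for focal agent ``p``.

    Relaxes heading toward the distance-weighted circular mean of
    neighbour headings (via the sine of the heading difference, with
    rate damping) and speed toward the weighted mean neighbour speed.
    Neighbours outside the field of view or with zero distance weight
    contribute nothing; with none left, returns ``(0.0, 0.0)``.
    """
    params = params or OmniscientParams()
    neighbours = list(neighbours)
    if not neighbours:
        return 0.0, 0.0
    positions = np.array([n.position for n in neighbours])
    headings = np.array([n.heading for n in neighbours])
    speeds = np.array([n.speed for n in neighbours])
    return omniscient_model_accels(
        p.position, p.heading, p.speed, p.heading_rate,
        positions, headings, speeds, params, fov,
    )


def omniscient_model_accels(position, heading, speed, heading_rate,
                            nbr_positions, nbr_headings, nbr_speeds,
                            params, fov):
    """Array-native core of :func:`omniscient_model_step`."""
    rel = np.asarray(nbr_positions, dtype=float) - np.asarray(position, dtype=float)
    d = np.hypot(rel[:, 0], rel[:, 1])
    psi = np.arctan2(rel[:, 1], rel[:, 0])
    beta = np.atleast_1d(wrap_angle(heading - psi))
    w = params.weight(d)
    w = np.where(np.abs(beta) <= fov / 2.0 + 1e-12, w, 0.0)
    total = float(w.sum())
    if total <= 0.0:
        return 0.0, 0.0
    mean_heading = math.atan2(
        float(np.sum(w * np.sin(nbr_headings))),
        float(np.sum(w * np.cos(nbr_headings))),
    )
    mean_speed = float(np.sum(w * nbr_speeds)) / total
    phi_ddot = (
        params.heading_gain * math.sin(mean_heading - heading)
        - params.heading_damping * heading_rate
    )
    r_ddot = params.speed_gain * (mean_speed - speed)
    return float(phi_ddot), float(r_ddot)
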