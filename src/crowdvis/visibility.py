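"""Occlusion geometry: how much of each neighbour can actually be seen.

Each neighbour's body subtends an angular interval on the focal walker's
view circle.  Nearer bodies occlude farther ones; a neighbour's
*visibility* ``v`` is the fraction of its subtended interval left
uncovered by the union of all strictly nearer bodies.  Visibilities
below a threshold ``v_t`` are zeroed, so a far neighbour in a dense
crowd simply drops out of the neighbourhood.

Two independent routes compute ``v``: an exact interval-union sweep
(:func:`visibility_fraction`) and a ray-sampling oracle
(:func:`ray_cast_visibility`) used to validate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .optics import OpticalState, wrap_angle

__all__ = [
    "AngularInterval",
    "VisibilityConfig",
    "in_fov",
    "visibility_fraction",
    "ray_cast_visibility",
    "apply_threshold",
    "visibility_weights_arrays",
    "opacity_range",
]

#: sentinel returned by :func:`opacity_range` when the crowd never
#: becomes opaque (the farthest neighbour is still visible).
NO_OPACITY = math.inf

#: distance tie tolerance (m): bodies this close in range do not
#: occlude one another
DIST_TIE_TOL = 1e-9


@dataclass(frozen=True)
class AngularInterval:
    """One body's subtended extent ``[centre - half_width, centre + half_width]``.

    Angles live on the circle; ``half_width`` never exceeds pi/2 because
    the subtense of a disc of diameter w is at most pi (clamped).
    """

    centre: float
    half_width: float

    def __post_init__(self):
        if not (0.0 < self.half_width <= math.pi / 2.0 + 1e-12):
            raise ValueError("half_width must lie in (0, pi/2]")

    @property
    def width(self) -> float:
        return 2.0 * self.half_width


@dataclass(frozen=True)
class VisibilityConfig:
    """Occlusion threshold and field-of-view filter.

    ``fov`` is the total field-of-view angle centred on the heading
    direction; pi (180 deg) is the default walking field of view and
    pi/2 (90 deg) replicates a head-mounted display.
    """

    v_t: float = 0.15
    fov: float = math.pi

    def __post_init__(self):
        if not (0.0 <= self.v_t < 1.0):
            raise ValueError("v_t must lie in [0, 1)")
        if not (0.0 < self.fov <= 2.0 * math.pi):
            raise ValueError("fov must lie in (0, 2*pi]")


def in_fov(beta, fov: float):
    """True iff eccentricity ``beta`` lies within the field of view (inclusive)."""
    return np.abs(np.asarray(beta)) <= fov / 2.0 + 1e-12


def _uncovered_measure(lo: float, hi: float, occluders: np.ndarray) -> float:
    """Length of [lo, hi] not covered by the union of occluder intervals.

    ``occluders`` is an (n, 2) array of [start, end] pairs on the real
    line (already unwrapped relative to the target centre).
    """
    if hi <= lo:
        return 0.0
    if occluders.size == 0:
        return hi - lo
    a = np.clip(occluders[:, 0], lo, hi)
    b = np.clip(occluders[:, 1], lo, hi)
    keep = b > a
    if not keep.any():
        return hi - lo
    a, b = a[keep], b[keep]
    order = np.argsort(a)
    a, b = a[order], b[order]
    covered = 0.0
    cur_a, cur_b = a[0], b[0]
    for k in range(1, len(a)):
        if a[k] > cur_b:
            covered += cur_b - cur_a
            cur_a, cur_b = a[k], b[k]
        else:
            cur_b = max(cur_b, b[k])
    covered += cur_b - cur_a
    return (hi - lo) - covered


def _occluder_bounds(target_centre: float, centres, half_widths) -> np.ndarray:
    """Occluder intervals unwrapped to the target's local angular frame."""
    centres = np.atleast_1d(np.asarray(centres, dtype=float))
    half_widths = np.atleast_1d(np.asarray(half_widths, dtype=float))
    rel = wrap_angle(centres - target_centre)
    rel = np.atleast_1d(rel)
    return np.column_stack([rel - half_widths, rel + half_widths])


def visibility_fraction(
    target: OpticalState,
    occluders: Iterable[OpticalState],
    fov: float | None = None,
) -> float:
    """Fraction of ``target``'s subtended interval left uncovered.

    ``occluders`` must be strictly nearer than the target (equidistant
    bodies do not occlude one another); farther entries are ignored.
    When ``fov`` is given the target's interval is first clipped to the
    field of view, but the denominator stays the full subtense: a body
    half out of view is half as visible.  Occluders outside the FOV
    still occlude.
    """
    theta = target.visual_angle
    if not theta > 0:
        raise ValueError("target subtends an empty interval")
    # strictly nearer, with a float tolerance so equidistant bodies
    # (e.g. on a common arc) never occlude each other
    occ = [o for o in occluders if o.distance < target.distance - DIST_TIE_TOL]
    half = theta / 2.0
    lo, hi = -half, half
    if fov is not None and fov < 2.0 * math.pi:
        # FOV expressed in the target's local frame (centred on its
        # eccentricity); safe on the real line since |beta| <= pi.
        lo = max(lo, -fov / 2.0 - target.eccentricity)
        hi = min(hi, fov / 2.0 - target.eccentricity)
        if hi <= lo:
            return 0.0
    if not occ:
        return (hi - lo) / theta
    bounds = _occluder_bounds(
        target.eccentricity,
        [o.eccentricity for o in occ],
        [o.visual_angle / 2.0 for o in occ],
    )
    return _uncovered_measure(lo, hi, bounds) / theta


def ray_cast_visibility(
    target: OpticalState,
    occluders: Iterable[OpticalState],
    n_rays: int = 10_000,
    fov: float | None = None,
) -> float:
    """Independent visibility estimate by sampling rays across the target.

    Rays are cast at a regular grid of directions spanning the target's
    subtended interval; a ray is blocked when it falls inside a strictly
    nearer body's subtense (or outside the field of view).  Converges to
    the interval measure at rate O(1/n_rays).
    """
    if n_rays < 1000:
        raise ValueError("n_rays must be at least 1000")
    theta = target.visual_angle
    half = theta / 2.0
    # midpoint grid over the target interval, in local coordinates
    alphas = (np.arange(n_rays) + 0.5) / n_rays * theta - half
    visible = np.ones(n_rays, dtype=bool)
    if fov is not None and fov < 2.0 * math.pi:
        world = alphas + target.eccentricity
        visible &= np.abs(world) <= fov / 2.0
    for o in occluders:
        if o.distance >= target.distance - DIST_TIE_TOL:
            continue
        rel = wrap_angle(o.eccentricity - target.eccentricity)
        visible &= np.abs(alphas - rel) > o.visual_angle / 2.0
    return float(visible.sum()) / n_rays


def apply_threshold(v: float, v_t: float) -> float:
    """Zero out sub-threshold visibility; the boundary value is kept."""
    if not (0.0 <= v <= 1.0 + 1e-12):
        raise ValueError("visibility must lie in [0, 1]")
    return 0.0 if v < v_t else v


def visibility_weights_arrays(d, beta, theta, cfg: VisibilityConfig):
    """Thresholded visibility weights for a batch of neighbours.

    Array-native counterpart of :func:`visibility_fraction` +
    :func:`apply_threshold` used by the simulator: ``d``, ``beta``,
    ``theta`` are 1-D arrays over neighbours.  Returns ``(v, weights)``.
    A neighbour is a candidate iff its centre bearing is inside the FOV;
    its interval is clipped to the FOV; every strictly nearer neighbour
    occludes regardless of FOV.
    """
    d = np.asarray(d, dtype=float)
    beta = np.asarray(beta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = d.shape[0]
    v = np.zeros(n)
    clip = cfg.fov < 2.0 * math.pi
    half_fov = cfg.fov / 2.0
    candidate = in_fov(beta, cfg.fov)
    half = theta / 2.0
    for i in range(n):
        if not candidate[i]:
            continue
        lo, hi = -half[i], half[i]
        if clip:
            lo = max(lo, -half_fov - beta[i])
            hi = min(hi, half_fov - beta[i])
            if hi <= lo:
                continue
        nearer = d < d[i] - DIST_TIE_TOL
        if nearer.any():
            rel = np.atleast_1d(wrap_angle(beta[nearer] - beta[i]))
            bounds = np.column_stack([rel - half[nearer], rel + half[nearer]])
            v[i] = _uncovered_measure(lo, hi, bounds) / theta[i]
        else:
            v[i] = (hi - lo) / theta[i]
    weights = np.where(v < cfg.v_t, 0.0, v)
    return v, weights


def opacity_range(crowd, focal, cfg: VisibilityConfig, body=None) -> float:
    """Smallest radius beyond which the crowd is completely opaque.

    Returns the smallest ``R`` such that every neighbour farther than
    ``R`` has thresholded visibility zero from ``focal``; this is the
    distance of the farthest still-visible neighbour.  If the farthest
    neighbour of all is itself visible the crowd never becomes opaque
    and :data:`NO_OPACITY` (+inf) is returned.
    """
    from .optics import BodyModel, optical_arrays

    if body is None:
        body = BodyModel()
    crowd = list(crowd)
    if len(crowd) < 2:
        return NO_OPACITY
    positions = np.array([a.position for a in crowd])
    velocities = np.array([a.velocity for a in crowd])
    opt = optical_arrays(
        focal.position, focal.heading, focal.velocity,
        positions, velocities, body.diameter,
    )
    _, weights = visibility_weights_arrays(opt["d"], opt["beta"], opt["theta"], cfg)
    visible = weights > 0.0
    d = opt["d"]
    if visible[np.argmax(d)]:
        return NO_OPACITY
    if not visible.any():
        return 0.0
    return float(d[visible].max())
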