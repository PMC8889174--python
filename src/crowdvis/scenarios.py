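"""Virtual-crowd layouts, perturbation schedules and synthetic swarms.

The trial scenarios mirror the perturbation experiments: a focal walker
starts at the origin facing forward (+y), a crowd of scripted virtual
neighbours walks forward at 1.0 m/s, and after 5 s the heading (or
speed) of a subset of neighbours is perturbed.  The trial lasts 12 s.

Three layouts are provided:

* a single fully-visible row (arc) at 1.8-8 m, crowd size 2/4/8, all
  neighbours perturbed together;
* three rows of four (12 neighbours) spaced 2 m apart with the near row
  at 2/4/6 m, one row perturbed — far rows are dynamically occluded;
* a two-row layout (5 near at 1.5 m, 7 far at 3.5 m) where 0-12
  neighbours, predominantly in one row, are perturbed in heading or
  speed.

A seeded correlated-walk generator emits synthetic "swarm" segments for
replay tests, so no recorded data set is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conventions import FORWARD
from .optics import AgentState, wrap_angle
from .simulator import DEFAULT_DT, NeighbourScript, Trajectory

__all__ = [
    "ScriptedWalker",
    "Scenario",
    "build_exp1",
    "build_exp2",
    "build_rio",
    "build_initial_arcs",
    "generate_dense_crowd",
    "generate_synthetic_swarm",
    "EXP1_DISTANCES",
    "EXP1_SIZES",
    "EXP2_NEAR_DISTANCES",
    "EXP2_ROWS",
    "ARC_ECCENTRICITIES_DEG",
]

EXP1_DISTANCES = (1.8, 3.0, 4.0, 6.0, 8.0)
EXP1_SIZES = (2, 4, 8)
EXP2_NEAR_DISTANCES = (2.0, 4.0, 6.0)
EXP2_ROWS = ("near", "middle", "far")
ARC_ECCENTRICITIES_DEG = (6.0, -6.0, 19.0, -19.0, 32.0, -32.0, 45.0, -45.0)

HEADING_PERTURBATION_DEG = 10.0
SPEED_PERTURBATION = 0.3
PERTURBATION_TIME = 5.0
TRIAL_DURATION = 12.0
CROWD_SPEED = 1.0


def _direction_sign(direction) -> int:
    """+1 for a rightward perturbation, -1 for leftward."""
    if direction in (1, +1, "right", "r", "+"):
        return 1
    if direction in (-1, "left", "l", "-"):
        return -1
    raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")


@dataclass(frozen=True)
class ScriptedWalker:
    """One virtual neighbour: start position plus perturbation spec.

    ``heading_delta`` is the internal (CCW) heading change in radians;
    ``speed_delta`` in m/s.  Both ramp linearly over ``ramp`` seconds
    starting at the scenario's perturbation time.
    """

    position: tuple[float, float]
    base_speed: float = CROWD_SPEED
    heading_delta: float = 0.0
    speed_delta: float = 0.0

    @property
    def perturbed(self) -> bool:
        return self.heading_delta != 0.0 or self.speed_delta != 0.0


@dataclass
class Scenario:
    """Crowd layout + perturbation schedule + trial timing."""

    walkers: list[ScriptedWalker]
    focal: AgentState
    perturbation_time: float = PERTURBATION_TIME
    duration: float = TRIAL_DURATION
    ramp: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.perturbation_time < self.duration:
            raise ValueError("perturbation must occur before the trial ends")

    @property
    def n_neighbours(self) -> int:
        return len(self.walkers)

    def script(self, dt: float = DEFAULT_DT) -> NeighbourScript:
        """Sample the scripted neighbour kinematics on a uniform grid.

        Headings/speeds follow the analytic ramp profile; positions are
        accumulated with the same semi-implicit rule as the simulator.
        """
        n_steps = int(round(self.duration / dt))
        times = np.arange(n_steps + 1) * dt
        n = len(self.walkers)
        ramp = max(self.ramp, 1e-9)
        frac = np.clip((times - self.perturbation_time) / ramp, 0.0, 1.0)
        headings = np.empty((n_steps + 1, n))
        speeds = np.empty((n_steps + 1, n))
        positions = np.empty((n_steps + 1, n, 2))
        for i, wk in enumerate(self.walkers):
            headings[:, i] = wrap_angle(FORWARD + frac * wk.heading_delta)
            speeds[:, i] = wk.base_speed + frac * wk.speed_delta
            positions[0, i] = wk.position
        step_vec = (
            speeds[1:, :, None]
            * np.stack([np.cos(headings[1:]), np.sin(headings[1:])], axis=-1)
        )
        positions[1:] = positions[0] + np.cumsum(step_vec * dt, axis=0)
        return NeighbourScript(times, positions, headings, speeds)

    def neighbour_trajectories(self, dt: float = DEFAULT_DT) -> list[Trajectory]:
        return self.script(dt).to_trajectories()


def _focal_state(speed: float = CROWD_SPEED) -> AgentState:
    return AgentState(np.zeros(2), FORWARD, speed)


def _ecc_to_position(distance: float, ecc_deg: float) -> tuple[float, float]:
    """Position at a given range and right-positive eccentricity from origin."""
    ang = FORWARD - math.radians(ecc_deg)
    return (distance * math.cos(ang), distance * math.sin(ang))


def build_initial_arcs(
    radius: float,
    n: int,
    eccentricities_deg=ARC_ECCENTRICITIES_DEG,
    jitter: float = 0.0,
    seed: int | None = None,
    min_separation: float = 0.4,
    max_tries: int = 200,
) -> np.ndarray:
    """Positions on an arc about the focal start, innermost slots first.

    With ``jitter > 0`` each position is displaced uniformly within a
    disc of that radius (seeded), re-drawn until all pairwise
    separations stay at or above ``min_separation``.
    """
    if radius <= 0:
        raise ValueError("arc radius must be positive")
    if n > len(eccentricities_deg):
        raise ValueError("not enough eccentricity slots")
    base = np.array([_ecc_to_position(radius, e) for e in eccentricities_deg[:n]])
    if jitter <= 0:
        return base
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        ang = rng.uniform(0, 2 * math.pi, n)
        rad = jitter * np.sqrt(rng.uniform(0, 1, n))
        pts = base + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        diffs = pts[:, None] - pts[None, :]
        dd = np.hypot(diffs[..., 0], diffs[..., 1])
        np.fill_diagonal(dd, np.inf)
        if dd.min() >= min_separation:
            return pts
    raise RuntimeError("could not satisfy minimum separation; reduce jitter")


def build_exp1(
    crowd_size: int,
    distance: float,
    direction="right",
    focal_speed: float = CROWD_SPEED,
    jitter: float = 0.0,
    seed: int | None = None,
    ramp: float = 0.5,
) -> Scenario:
    """Single fully-visible row at one distance; everyone turns together."""
    if crowd_size not in EXP1_SIZES:
        raise ValueError(f"crowd_size must be one of {EXP1_SIZES}")
    if distance not in EXP1_DISTANCES:
        raise ValueError(f"distance must be one of {EXP1_DISTANCES}")
    sign = _direction_sign(direction)
    delta = -sign * math.radians(HEADING_PERTURBATION_DEG)  # internal CCW
    pts = build_initial_arcs(distance, crowd_size, jitter=jitter, seed=seed)
    walkers = [ScriptedWalker(tuple(p), heading_delta=delta) for p in pts]
    return Scenario(
        walkers=walkers,
        focal=_focal_state(focal_speed),
        ramp=ramp,
        metadata={
            "experiment": "exp1",
            "crowd_size": crowd_size,
            "distance": distance,
            "direction": "right" if sign > 0 else "left",
        },
    )


def build_exp2(
    near_row_distance: float,
    perturbed_row: str,
    direction="right",
    focal_speed: float = CROWD_SPEED,
    seed: int = 0,
    jitter: float = 0.3,
    row_spacing: float = 2.0,
    column_ecc_deg=(-24.0, -8.0, 8.0, 24.0),
    ramp: float = 0.5,
) -> Scenario:
    """Three rows of four, 2 m apart; exactly one row turns.

    Columns sit at fixed eccentricity slots from the focal start (so
    farther rows start roughly behind nearer ones and get dynamically
    occluded), with seeded positional jitter bounded so the row
    ordering is preserved.
    """
    if near_row_distance not in EXP2_NEAR_DISTANCES:
        raise ValueError(f"near_row_distance must be one of {EXP2_NEAR_DISTANCES}")
    if perturbed_row not in EXP2_ROWS:
        raise ValueError(f"perturbed_row must be one of {EXP2_ROWS}")
    if not 0 <= jitter < row_spacing / 2.0:
        raise ValueError("jitter must be smaller than half the row spacing")
    sign = _direction_sign(direction)
    delta = -sign * math.radians(HEADING_PERTURBATION_DEG)
    rng = np.random.default_rng(seed)
    walkers = []
    for r, row_name in enumerate(EXP2_ROWS):
        y = near_row_distance + r * row_spacing
        dx = rng.uniform(-jitter, jitter, 4)
        dy = rng.uniform(-jitter, jitter, 4)
        turn = delta if row_name == perturbed_row else 0.0
        for j, ecc in enumerate(column_ecc_deg):
            x = y * math.tan(math.radians(ecc))
            walkers.append(
                ScriptedWalker(
                    (float(x + dx[j]), float(y + dy[j])),
                    heading_delta=turn,
                )
            )
    return Scenario(
        walkers=walkers,
        focal=_focal_state(focal_speed),
        ramp=ramp,
        metadata={
            "experiment": "exp2",
            "near_row_distance": near_row_distance,
            "perturbed_row": perturbed_row,
            "direction": "right" if sign > 0 else "left",
        },
    )


RIO_NEAR_Y = 1.5
RIO_FAR_Y = 3.5
RIO_NEAR_X = tuple(float(x) for x in range(-2, 3))
RIO_FAR_X = tuple(float(x) for x in range(-3, 4))


def build_rio(
    perturbed_count: int,
    row: str = "near",
    mode: str = "heading",
    direction="right",
    focal_speed: float = CROWD_SPEED,
    seed: int = 0,
    ramp: float = 0.5,
) -> Scenario:
    """Two-row layout: 5 near (1.5 m) + 7 far (3.5 m); a subset is perturbed.

    The perturbed subset sits predominantly in the chosen row (seeded
    draw); overflow spills into the other row, centre-most first.
    ``mode`` selects a +-10 deg heading turn or a +-0.3 m/s speed change.
    """
    if not 0 <= perturbed_count <= 12:
        raise ValueError("perturbed_count must be between 0 and 12")
    if row not in ("near", "far"):
        raise ValueError("row must be 'near' or 'far'")
    if mode not in ("heading", "speed"):
        raise ValueError("mode must be 'heading' or 'speed'")
    sign = _direction_sign(direction)
    positions = [(x, RIO_NEAR_Y) for x in RIO_NEAR_X] + [
        (x, RIO_FAR_Y) for x in RIO_FAR_X
    ]
    near_idx = list(range(5))
    far_idx = list(range(5, 12))
    primary, secondary = (near_idx, far_idx) if row == "near" else (far_idx, near_idx)
    rng = np.random.default_rng(seed)
    primary = list(rng.permutation(primary))
    # overflow fills the other row centre-most (nearest to the focal) first
    secondary = sorted(secondary, key=lambda i: abs(positions[i][0]))
    targets = set((primary + secondary)[:perturbed_count])
    heading_delta = -sign * math.radians(HEADING_PERTURBATION_DEG)
    speed_delta = sign * SPEED_PERTURBATION
    walkers = []
    for i, pos in enumerate(positions):
        if i in targets:
            if mode == "heading":
                walkers.append(ScriptedWalker(pos, heading_delta=heading_delta))
            else:
                walkers.append(ScriptedWalker(pos, speed_delta=speed_delta))
        else:
            walkers.append(ScriptedWalker(pos))
    return Scenario(
        walkers=walkers,
        focal=_focal_state(focal_speed),
        ramp=ramp,
        metadata={
            "experiment": "rio",
            "perturbed_count": perturbed_count,
            "row": row,
            "mode": mode,
            "direction": "right" if sign > 0 else "left",
        },
    )


def generate_dense_crowd(
    n_agents: int = 200,
    spacing: float | None = None,
    spacing_range: tuple[float, float] = (1.0, 2.0),
    seed: int | None = None,
    speed: float = CROWD_SPEED,
) -> list[AgentState]:
    """Static dense crowd on a jittered grid, all facing forward.

    The grid pitch (``spacing``) is drawn per crowd from
    ``spacing_range`` unless given explicitly; positional jitter is
    bounded so every nearest-neighbour distance stays inside the range
    (the boundary pitches therefore get no jitter).  Used to study
    crowd opacity; take the focal agent nearest the centroid.
    """
    if n_agents < 2:
        raise ValueError("need at least 2 agents")
    rng = np.random.default_rng(seed)
    low, high = spacing_range
    pitch = rng.uniform(low, high) if spacing is None else float(spacing)
    if not low <= pitch <= high:
        raise ValueError("spacing outside spacing_range")
    # each point moves by at most j, so lateral neighbour distances stay
    # within pitch +- 2j; cap j against both range bounds
    jitter = min((pitch - low) / 2.0, (high - pitch) / 2.0)
    side = int(math.ceil(math.sqrt(n_agents)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:n_agents] * pitch
    pts = pts - pts.mean(axis=0)
    if jitter > 0:
        pts = pts + rng.uniform(-jitter / math.sqrt(2), jitter / math.sqrt(2),
                                pts.shape)
    return [AgentState(p, FORWARD, speed) for p in pts]


def generate_synthetic_swarm(
    n_agents: int,
    duration: float = 10.0,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    area: tuple[float, float] = (14.0, 20.0),
    base_speed: float = 1.2,
    veer_std: float = 0.5,
    veer_timescale: float = 5.0,
    agent_heading_std: float = 0.1,
    agent_heading_timescale: float = 1.5,
    speed_std: float = 0.1,
    speed_timescale: float = 2.0,
    spacing: float = 1.5,
    gait_amplitude: float = 0.0,
    gait_frequency: float = 1.8,
    tracker_noise: float = 0.0,
) -> list[Trajectory]:
    """Seeded correlated-walk swarm emulating recorded group segments.

    A common slowly-varying group heading (Ornstein-Uhlenbeck, standard
    deviation ``veer_std`` rad, time constant ``veer_timescale`` s)
    drives every agent; each agent adds its own faster heading and speed
    noise.  Optional gait-frequency lateral oscillation and white
    tracker noise perturb the reported positions only.  Setting all
    noise scales to zero gives parallel straight walkers.
    """
    if n_agents < 2:
        raise ValueError("need at least 2 agents")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    def ou(std, tau, shape):
        """Stationary Ornstein-Uhlenbeck paths sampled at dt."""
        out = np.empty((n_steps + 1,) + shape)
        if std <= 0:
            out[:] = 0.0
            return out
        a = math.exp(-dt / tau)
        innov = std * math.sqrt(max(1.0 - a * a, 0.0))
        out[0] = rng.normal(0.0, std, shape)
        noise = rng.normal(0.0, 1.0, (n_steps,) + shape)
        for k in range(n_steps):
            out[k + 1] = a * out[k] + innov * noise[k]
        return out

    group_heading = FORWARD + ou(veer_std, veer_timescale, ())
    headings = group_heading[:, None] + ou(
        agent_heading_std, agent_heading_timescale, (n_agents,)
    )
    speeds = np.clip(
        base_speed + ou(speed_std, speed_timescale, (n_agents,)), 0.0, None
    )
    # initial grid centred in the area, jittered
    cols = int(math.ceil(math.sqrt(n_agents)))
    rows = int(math.ceil(n_agents / cols))
    gx, gy = np.meshgrid(np.arange(cols), np.arange(rows))
    grid = np.column_stack([gx.ravel(), gy.ravel()])[:n_agents] * spacing
    grid = grid - grid.mean(axis=0)
    grid = grid + rng.uniform(-0.25 * spacing, 0.25 * spacing, grid.shape)
    half = np.array(area) / 2.0
    grid = np.clip(grid, -half + 0.5, half - 0.5)

    positions = np.empty((n_steps + 1, n_agents, 2))
    positions[0] = grid
    steps = (
        speeds[1:, :, None]
        * np.stack([np.cos(headings[1:]), np.sin(headings[1:])], axis=-1)
        * dt
    )
    positions[1:] = grid + np.cumsum(steps, axis=0)

    reported = positions.copy()
    if gait_amplitude > 0:
        phase = rng.uniform(0, 2 * math.pi, n_agents)
        osc = gait_amplitude * np.sin(
            2 * math.pi * gait_frequency * times[:, None] + phase
        )
        normal = np.stack(
            [-np.sin(headings), np.cos(headings)], axis=-1
        )  # lateral sway
        reported = reported + osc[..., None] * normal
    if tracker_noise > 0:
        reported = reported + rng.normal(0.0, tracker_noise, reported.shape)

    return [
        Trajectory(
            times=times,
            x=reported[:, i, 0],
            y=reported[:, i, 1],
            heading=wrap_angle(headings[:, i]),
            speed=speeds[:, i],
            agent_id=f"swarm{i}",
        )
        for i in range(n_agents)
    ]
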