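"""Time integration of walker dynamics.

Supports three modes of use: single-focal-agent trials against scripted
virtual neighbours (:func:`simulate_trial`), replay of recorded or
synthetic group trajectories with a simulated focal walker
(:func:`simulate_swarm_replay`), and fully coupled multi-agent
simulation where every agent runs the model simultaneously
(:func:`multi_agent_simulate`).

The default integrator is fixed-step semi-implicit Euler at the 60 Hz
experimental clock; a classic RK4 stepper is available for convergence
checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .control import (
    OmniscientParams,
    VisualParams,
    omniscient_model_accels,
    visual_model_accels,
)
from .optics import AgentState, BodyModel, wrap_angle
from .visibility import VisibilityConfig

__all__ = [
    "Trajectory",
    "SimConfig",
    "integrate_step",
    "simulate_trial",
    "simulate_swarm_replay",
    "multi_agent_simulate",
]

logger = logging.getLogger(__name__)

DEFAULT_DT = 1.0 / 60.0


@dataclass
class Trajectory:
    """Time-indexed kinematic series for one agent on a uniform grid."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray  # CCW radians from +x, wrapped
    speed: np.ndarray
    heading_rate: np.ndarray | None = None
    speed_rate: np.ndarray | None = None
    agent_id: str = "agent"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name in ("x", "y", "heading", "speed"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} length must match times")
            setattr(self, name, arr)
        for name in ("heading_rate", "speed_rate"):
            arr = getattr(self, name)
            if arr is None:
                arr = np.zeros_like(self.times)
            setattr(self, name, np.asarray(arr, dtype=float))
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if steps.min() <= 0:
                raise ValueError("times must be strictly increasing")
            # tolerance accommodates decimal-formatted time columns
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise ValueError("times must form a uniform grid")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("trajectory has no time step")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def state_at(self, k: int) -> AgentState:
        return AgentState(
            position=np.array([self.x[k], self.y[k]]),
            heading=float(self.heading[k]),
            speed=float(self.speed[k]),
            heading_rate=float(self.heading_rate[k]),
            speed_rate=float(self.speed_rate[k]),
        )

    @classmethod
    def from_states(cls, times, states: Sequence[AgentState], agent_id="agent"):
        return cls(
            times=np.asarray(times, dtype=float),
            x=np.array([s.position[0] for s in states]),
            y=np.array([s.position[1] for s in states]),
            heading=np.array([s.heading for s in states]),
            speed=np.array([s.speed for s in states]),
            heading_rate=np.array([s.heading_rate for s in states]),
            speed_rate=np.array([s.speed_rate for s in states]),
            agent_id=agent_id,
        )


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to run a simulation deterministically."""

    dt: float = DEFAULT_DT
    integrator: str = "euler"  # "euler" (semi-implicit) | "rk4"
    model: str = "visual"  # "visual" | "omniscient"
    speed_floor: float = 0.0
    allow_negative_speed: bool = False
    seed: int | None = None
    body: BodyModel = field(default_factory=BodyModel)
    visual: VisualParams = field(default_factory=VisualParams)
    omniscient: OmniscientParams = field(default_factory=OmniscientParams)
    vis: VisibilityConfig = field(default_factory=VisibilityConfig)

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.integrator not in ("euler", "rk4"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.model not in ("visual", "omniscient"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def floor(self) -> float:
        return -math.inf if self.allow_negative_speed else self.speed_floor


def integrate_step(
    state: AgentState, phi_ddot: float, r_ddot: float, dt: float,
    speed_floor: float = 0.0,
) -> AgentState:
    """Advance one agent by ``dt`` under the given accelerations.

    Semi-implicit Euler: rates first, then heading, then position from
    the updated speed and heading.  Heading is wrapped and speed clamped
    at the floor.
    """
    if not (math.isfinite(phi_ddot) and math.isfinite(r_ddot)):
        raise FloatingPointError(
            f"non-finite accelerations ({phi_ddot}, {r_ddot}) at "
            f"position {state.position}"
        )
    heading_rate = state.heading_rate + phi_ddot * dt
    speed = state.speed + r_ddot * dt
    if speed < speed_floor:
        speed = speed_floor
    heading = wrap_angle(state.heading + heading_rate * dt)
    position = state.position + speed * dt * np.array(
        [math.cos(heading), math.sin(heading)]
    )
    new = AgentState(
        position=position,
        heading=heading,
        speed=speed,
        heading_rate=heading_rate,
        speed_rate=r_ddot,
    )
    if not np.isfinite(position).all():
        raise FloatingPointError(f"non-finite position after step: {position}")
    return new


def _rk4_step(state: AgentState, accel_fn, dt: float,
              speed_floor: float) -> AgentState:
    """Classic RK4 on (x, y, heading, speed, heading_rate).

    ``accel_fn`` maps an AgentState to (phi_ddot, r_ddot); the neighbour
    snapshot inside it is held over the step.
    """

    def deriv(y):
        x, yy, phi, s, phi_dot = y
        st = AgentState(np.array([x, yy]), phi, max(s, speed_floor), phi_dot)
        phi_ddot, r_ddot = accel_fn(st)
        return np.array(
            [s * math.cos(phi), s * math.sin(phi), phi_dot, r_ddot, phi_ddot]
        ), r_ddot

    y0 = np.array([
        state.position[0], state.position[1], state.heading,
        state.speed, state.heading_rate,
    ])
    k1, _ = deriv(y0)
    k2, _ = deriv(y0 + 0.5 * dt * k1)
    k3, _ = deriv(y0 + 0.5 * dt * k2)
    k4, r_last = deriv(y0 + dt * k3)
    y = y0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return AgentState(
        position=y[:2],
        heading=wrap_angle(y[2]),
        speed=max(y[3], speed_floor),
        heading_rate=y[4],
        speed_rate=r_last,
    )


def _model_accel_fn(cfg: SimConfig) -> Callable:
    """Accel function (state, neighbour snapshot dict) -> (phi_ddot, r_ddot)."""
    if cfg.model == "visual":

        def fn(state, snap):
            return visual_model_accels(
                state.position, state.heading, state.velocity,
                snap["positions"], snap["velocities"],
                cfg.body, cfg.visual, cfg.vis,
                heading_rate=state.heading_rate,
            )

    else:

        def fn(state, snap):
            return omniscient_model_accels(
                state.position, state.heading, state.speed, state.heading_rate,
                snap["positions"], snap["headings"], snap["speeds"],
                cfg.omniscient, cfg.vis.fov,
            )

    return fn


def _advance(state, snap, accel_fn, cfg: SimConfig) -> AgentState:
    if cfg.integrator == "rk4":
        return _rk4_step(state, lambda st: accel_fn(st, snap), cfg.dt, cfg.floor)
    phi_ddot, r_ddot = accel_fn(state, snap)
    return integrate_step(state, phi_ddot, r_ddot, cfg.dt, cfg.floor)


class NeighbourScript:
    """Pre-sampled neighbour kinematics on a uniform grid.

    Arrays are shaped (n_steps, n_agents, ...).  Built from a list of
    :class:`Trajectory` on a common time grid.
    """

    def __init__(self, times, positions, headings, speeds, agent_ids=None):
        self.times = np.asarray(times, dtype=float)
        self.positions = np.asarray(positions, dtype=float)
        self.headings = np.asarray(headings, dtype=float)
        self.speeds = np.asarray(speeds, dtype=float)
        self.agent_ids = agent_ids or [
            f"n{i}" for i in range(self.positions.shape[1])
        ]
        if not np.isfinite(self.positions).all():
            raise ValueError("neighbour script contains gaps (non-finite data); "
                             "enable gap filling to interpolate")

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def snapshot(self, k: int) -> dict:
        h = self.headings[k]
        s = self.speeds[k]
        return {
            "positions": self.positions[k],
            "velocities": (s[:, None] * np.column_stack([np.cos(h), np.sin(h)])),
            "headings": h,
            "speeds": s,
        }

    @classmethod
    def from_trajectories(cls, trajs: Sequence[Trajectory], fill_gaps=False):
        if not trajs:
            raise ValueError("no neighbour trajectories supplied")
        times = trajs[0].times
        for t in trajs[1:]:
            if t.times.shape != times.shape or not np.allclose(
                t.times, times, atol=1e-9
            ):
                raise ValueError("neighbour trajectories must share a time grid")
        pos = np.stack([t.positions for t in trajs], axis=1)
        head = np.stack([t.heading for t in trajs], axis=1)
        speed = np.stack([t.speed for t in trajs], axis=1)
        if fill_gaps:
            for arr in (pos.reshape(len(times), -1), head, speed):
                for j in range(arr.shape[1]):
                    col = arr[:, j]
                    bad = ~np.isfinite(col)
                    if bad.any():
                        good = ~bad
                        if good.sum() < 2:
                            raise ValueError("gap too large to fill")
                        col[bad] = np.interp(
                            times[bad], times[good], col[good]
                        )
        return cls(times, pos, head, speed, [t.agent_id for t in trajs])

    def to_trajectories(self) -> list[Trajectory]:
        out = []
        for i in range(self.n_agents):
            out.append(
                Trajectory(
                    times=self.times,
                    x=self.positions[:, i, 0],
                    y=self.positions[:, i, 1],
                    heading=self.headings[:, i],
                    speed=self.speeds[:, i],
                    agent_id=self.agent_ids[i],
                )
            )
        return out


def _run_focal(script: NeighbourScript, focal: AgentState,
               cfg: SimConfig, agent_id="focal") -> Trajectory:
    accel_fn = _model_accel_fn(cfg)
    n_steps = len(script.times) - 1
    states = [focal.copy()]
    state = focal.copy()
    for k in range(n_steps):
        state = _advance(state, script.snapshot(k), accel_fn, cfg)
        states.append(state)
    return Trajectory.from_states(script.times, states, agent_id=agent_id)


def simulate_trial(scenario, cfg: SimConfig) -> Trajectory:
    """Run the focal agent through one scripted virtual-crowd trial.

    The scenario supplies the neighbour script and the focal initial
    state; the result is deterministic given the scenario and config.
    """
    script = scenario.script(cfg.dt)
    if abs(script.dt - cfg.dt) > 1e-9:
        raise ValueError(
            f"scenario sampled at dt={script.dt} but config requests {cfg.dt}"
        )
    return _run_focal(script, scenario.focal, cfg)


def simulate_swarm_replay(
    neighbour_trajs: Sequence[Trajectory],
    focal_init: AgentState,
    cfg: SimConfig,
    fill_gaps: bool = False,
) -> Trajectory:
    """Drive a simulated focal walker with recorded/synthetic neighbours."""
    script = NeighbourScript.from_trajectories(neighbour_trajs, fill_gaps=fill_gaps)
    if script.times[-1] - script.times[0] < 1.0:
        raise ValueError("replay segment must span at least 1 s")
    return _run_focal(script, focal_init, cfg)


def multi_agent_simulate(
    initial: Sequence[AgentState], cfg: SimConfig, T: float,
) -> list[Trajectory]:
    """Coupled simulation: every agent is simultaneously focal.

    Synchronous update — within a step all agents read the same
    snapshot of the previous states.  Collisions (centre distance below
    half a body diameter) are logged and the optics clamp carries on.
    """
    agents = [a.copy() for a in initial]
    n = len(agents)
    if n < 2:
        raise ValueError("need at least 2 agents")
    accel_fn = _model_accel_fn(cfg)
    n_steps = int(round(T / cfg.dt))
    times = np.arange(n_steps + 1) * cfg.dt
    history: list[list[AgentState]] = [[a.copy() for a in agents]]
    half_w = cfg.body.diameter / 2.0
    others = [np.array([j for j in range(n) if j != i]) for i in range(n)]
    collision_reported = False
    for _k in range(n_steps):
        positions = np.array([a.position for a in agents])
        headings = np.array([a.heading for a in agents])
        speeds = np.array([a.speed for a in agents])
        velocities = speeds[:, None] * np.column_stack(
            [np.cos(headings), np.sin(headings)]
        )
        diffs = positions[:, None, :] - positions[None, :, :]
        dists = np.hypot(diffs[..., 0], diffs[..., 1])
        np.fill_diagonal(dists, np.inf)
        if (dists < half_w).any():
            level = logging.DEBUG if collision_reported else logging.WARNING
            logger.log(level, "agent collision at t=%.2f s (min d=%.3f m)",
                       _k * cfg.dt, float(dists.min()))
            collision_reported = True
        new_agents = []
        for i in range(n):
            idx = others[i]
            snap = {
                "positions": positions[idx],
                "velocities": velocities[idx],
                "headings": headings[idx],
                "speeds": speeds[idx],
            }
            new_agents.append(_advance(agents[i], snap, accel_fn, cfg))
        agents = new_agents
        history.append([a.copy() for a in agents])
    return [
        Trajectory.from_states(
            times, [step[i] for step in history], agent_id=f"agent{i}"
        )
        for i in range(n)
    ]
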