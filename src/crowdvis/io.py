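"""Trajectory table I/O.

Trajectories travel as UTF-8 comma-delimited text with columns
``time_s, agent_id, x_m, y_m, heading_deg, speed_mps`` (one row per
agent per step).  Headings in files use the display convention
(degrees, right-positive from forward); they are converted to internal
radians on read.  Tables missing heading/speed columns are
reconstructed by finite differences of position.  Lines starting with
``#`` are provenance comments and are ignored on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conventions import heading_from_display_deg, heading_to_display_deg
from .simulator import Trajectory

__all__ = ["read_trajectories", "write_trajectories", "provenance_header"]

REQUIRED_COLUMNS = ("time_s", "agent_id", "x_m", "y_m")
OPTIONAL_COLUMNS = ("heading_deg", "speed_mps")


def provenance_header(seed=None, config=None, extra=None) -> str:
    """Comment block recording how an output file was produced."""
    from . import __version__

    payload = {"version": __version__}
    if seed is not None:
        payload["seed"] = seed
    if config is not None:
        text = json.dumps(config, sort_keys=True, default=str)
        payload["config_sha1"] = hashlib.sha1(text.encode()).hexdigest()[:12]
    if extra:
        payload.update(extra)
    lines = [f"# {k}={v}" for k, v in payload.items()]
    return "\n".join(lines) + "\n"


def write_trajectories(path, trajectories, seed=None, config=None) -> None:
    """Write trajectories to a delimited table with a provenance header."""
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": traj.times,
                    "agent_id": traj.agent_id,
                    "x_m": traj.x,
                    "y_m": traj.y,
                    "heading_deg": heading_to_display_deg(traj.heading),
                    "speed_mps": traj.speed,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        table.to_csv(fh, index=False, float_format="%.17g")


def _reconstruct_kinematics(times, x, y):
    """Heading/speed from centred finite differences of position."""
    pos = np.column_stack([x, y])
    dt = float(times[1] - times[0])
    vel = np.gradient(pos, dt, axis=0)
    heading = np.arctan2(vel[:, 1], vel[:, 0])
    speed = np.hypot(vel[:, 0], vel[:, 1])
    # a stationary walker has no defined travel direction; keep zero
    heading[speed < 1e-12] = 0.0
    return heading, speed


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory table, one :class:`Trajectory` per agent id."""
    path = Path(path)
    try:
        table = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trajectory file") from None
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    numeric = [c for c in table.columns if c != "agent_id"]
    table[numeric] = table[numeric].apply(pd.to_numeric, errors="coerce")
    bad = table[numeric].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering (comment lines shift this)
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: malformed row near line {line}")
    out = []
    for agent_id, group in table.groupby("agent_id", sort=False):
        group = group.sort_values("time_s")
        times = group["time_s"].to_numpy(dtype=float)
        if len(times) >= 2:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise ValueError(
                    f"{path}: non-uniform time grid for agent {agent_id!r}"
                )
        x = group["x_m"].to_numpy(dtype=float)
        y = group["y_m"].to_numpy(dtype=float)
        if all(c in group.columns for c in OPTIONAL_COLUMNS):
            heading = heading_from_display_deg(
                group["heading_deg"].to_numpy(dtype=float)
            )
            speed = group["speed_mps"].to_numpy(dtype=float)
        else:
            heading, speed = _reconstruct_kinematics(times, x, y)
        out.append(
            Trajectory(
                times=times, x=x, y=y,
                heading=np.atleast_1d(heading), speed=speed,
                agent_id=str(agent_id),
            )
        )
    if not out:
        raise ValueError(f"{path}: no trajectory rows")
    return out
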