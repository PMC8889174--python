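import math

import numpy as np
import pytest

from crowdvis.optics import AgentState, BodyModel, OpticalState


@pytest.fixture
def body():
    return BodyModel()


@pytest.fixture
def north_walker():
    """Focal agent at the origin heading +y at 1 m/s."""
    return AgentState(np.zeros(2), math.pi / 2, 1.0)


def make_state(x, y, heading=math.pi / 2, speed=1.0, heading_rate=0.0):
    return AgentState(np.array([x, y], dtype=float), heading, speed,
                      heading_rate=heading_rate)


def random_optical_scene(rng, n_occluders=None, w=0.4):
    """A target OpticalState plus a batch of strictly nearer occluders.

    Geometry is generated in polar coordinates around an implicit
    observer; only the fields the visibility engine reads (distance,
    eccentricity, visual angle) are populated.
    """
    if n_occluders is None:
        n_occluders = int(rng.integers(0, 8))
    d_t = rng.uniform(2.0, 8.0)
    beta_t = rng.uniform(-math.pi / 2, math.pi / 2)
    target = OpticalState(
        distance=d_t, bearing=0.0, eccentricity=beta_t,
        visual_angle=2 * math.atan2(w, 2 * d_t),
        angular_velocity=0.0, expansion_rate=0.0,
    )
    occluders = []
    for _ in range(n_occluders):
        d = rng.uniform(0.5, d_t * 0.98)
        beta = beta_t + rng.uniform(-0.6, 0.6)
        occluders.append(
            OpticalState(
                distance=d, bearing=0.0, eccentricity=beta,
                visual_angle=2 * math.atan2(w, 2 * d),
                angular_velocity=0.0, expansion_rate=0.0,
            )
        )
    return target, occluders
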