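import math

import numpy as np
import pytest

from crowdvis.conventions import FORWARD
from crowdvis.metrics import final_heading, heading_rmse
from crowdvis.optics import AgentState
from crowdvis.scenarios import (
    ScriptedWalker,
    Scenario,
    build_exp1,
    generate_synthetic_swarm,
)
from crowdvis.simulator import (
    SimConfig,
    Trajectory,
    integrate_step,
    multi_agent_simulate,
    simulate_swarm_replay,
    simulate_trial,
)

from .conftest import make_state


class TestTrajectory:
    def test_requires_uniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            Trajectory(times=[0.0, 0.1, 0.3], x=[0, 0, 0], y=[0, 0, 0],
                       heading=[0, 0, 0], speed=[1, 1, 1])

    def test_requires_increasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(times=[0.0, 0.0, 0.1], x=[0, 0, 0], y=[0, 0, 0],
                       heading=[0, 0, 0], speed=[1, 1, 1])

    def test_state_round_trip(self):
        states = [make_state(0, i * 0.1, speed=1.2) for i in range(5)]
        traj = Trajectory.from_states(np.arange(5) / 60, states, agent_id="a")
        st = traj.state_at(3)
        assert st.position == pytest.approx(states[3].position)
        assert st.speed == 1.2


class TestIntegrateStep:
    def test_zero_accel_straight_line(self):
        s = make_state(0, 0, heading=FORWARD, speed=1.5)
        for _ in range(10):
            s = integrate_step(s, 0.0, 0.0, 0.1)
        assert s.position == pytest.approx([0.0, 1.5])
        assert s.heading == FORWARD
        assert s.speed == 1.5

    def test_constant_heading_accel_integrates_rate_exactly(self):
        s = make_state(0, 0)
        dt, T = 1 / 60, 2.0
        for _ in range(int(T / dt)):
            s = integrate_step(s, 0.5, 0.0, dt)
        assert s.heading_rate == pytest.approx(0.5 * T, abs=1e-9)

    def test_speed_floor_clamps(self):
        s = make_state(0, 0, speed=0.1)
        s = integrate_step(s, 0.0, -5.0, 0.1, speed_floor=0.0)
        assert s.speed == 0.0

    def test_negative_speed_allowed_when_floor_lifted(self):
        s = make_state(0, 0, speed=0.1)
        s = integrate_step(s, 0.0, -5.0, 0.1, speed_floor=-math.inf)
        assert s.speed == pytest.approx(-0.4)

    def test_non_finite_accel_raises(self):
        with pytest.raises(FloatingPointError):
            integrate_step(make_state(0, 0), math.nan, 0.0, 0.1)

    def test_heading_wraps(self):
        s = make_state(0, 0, heading=3.1)
        s = integrate_step(s, 0.0, 0.0, 0.1)
        assert -math.pi < s.heading <= math.pi


class TestSimulateTrial:
    def test_unperturbed_crowd_fixed_point(self):
        walkers = [ScriptedWalker((x, 2.0)) for x in (-1.5, -0.5, 0.5, 1.5)]
        scn = Scenario(walkers=walkers,
                       focal=AgentState(np.zeros(2), FORWARD, 1.0))
        traj = simulate_trial(scn, SimConfig())
        assert abs(final_heading(traj)) < 0.1

    def test_perturbed_trial_turns_focal(self):
        traj = simulate_trial(build_exp1(4, 1.8, "right"), SimConfig())
        assert final_heading(traj) > 5.0

    def test_nearer_crowd_larger_response(self):
        cfg = SimConfig()
        near = final_heading(simulate_trial(build_exp1(4, 1.8, "right"), cfg))
        far = final_heading(simulate_trial(build_exp1(4, 8.0, "right"), cfg))
        assert near > far

    def test_left_right_mirror_exact(self):
        cfg = SimConfig()
        tr = simulate_trial(build_exp1(4, 3.0, "right"), cfg)
        tl = simulate_trial(build_exp1(4, 3.0, "left"), cfg)
        assert np.max(np.abs((tr.heading - FORWARD) + (tl.heading - FORWARD))) \
            <= 1e-9
        assert np.max(np.abs(tr.x + tl.x)) <= 1e-9
        assert np.max(np.abs(tr.y - tl.y)) <= 1e-9

    def test_determinism(self):
        cfg = SimConfig()
        a = simulate_trial(build_exp1(2, 3.0, "right"), cfg)
        b = simulate_trial(build_exp1(2, 3.0, "right"), cfg)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.heading, b.heading)

    def test_dt_mismatch_rejected(self):
        scn = build_exp1(2, 3.0, "right")
        script = scn.script(1 / 30)

        class Frozen:
            focal = scn.focal

            def script(self, dt):
                return script

        with pytest.raises(ValueError, match="dt"):
            simulate_trial(Frozen(), SimConfig(dt=1 / 60))

    def test_no_nan_in_trajectory(self):
        traj = simulate_trial(build_exp1(8, 1.8, "right"), SimConfig())
        for arr in (traj.x, traj.y, traj.heading, traj.speed):
            assert np.isfinite(arr).all()

    def test_rk4_close_to_euler(self):
        scn = build_exp1(4, 3.0, "right")
        e = simulate_trial(scn, SimConfig(integrator="euler"))
        r = simulate_trial(scn, SimConfig(integrator="rk4"))
        assert abs(e.x[-1] - r.x[-1]) < 0.05
        assert abs(e.y[-1] - r.y[-1]) < 0.05

    def test_rk4_self_convergence(self):
        scn = build_exp1(4, 3.0, "right")
        a = simulate_trial(scn, SimConfig(integrator="rk4", dt=1 / 60))
        b = simulate_trial(scn, SimConfig(integrator="rk4", dt=1 / 120))
        endpoint_shift = math.hypot(a.x[-1] - b.x[-1], a.y[-1] - b.y[-1])
        assert endpoint_shift < 1e-3


class TestSwarmReplay:
    def test_stationary_everything_stays_put(self):
        times = np.arange(0, 121) / 60
        nbrs = [
            Trajectory(times=times, x=np.full_like(times, x),
                       y=np.full_like(times, 2.0),
                       heading=np.full_like(times, FORWARD),
                       speed=np.zeros_like(times), agent_id=f"n{x}")
            for x in (-1.0, 1.0)
        ]
        focal = AgentState(np.zeros(2), FORWARD, 0.0)
        sim = simulate_swarm_replay(nbrs, focal, SimConfig())
        assert np.max(np.hypot(sim.x, sim.y)) < 1e-6

    def test_speed_matching_approach(self):
        nbrs = generate_synthetic_swarm(
            6, duration=8.0, seed=3, veer_std=0.0, agent_heading_std=0.0,
            speed_std=0.0, base_speed=1.3,
        )
        focal = AgentState(np.array([0.0, -3.0]), FORWARD, 1.0)
        sim = simulate_swarm_replay(nbrs, focal, SimConfig())
        ds = np.diff(sim.speed)
        assert np.all(ds[60:] >= -1e-9)  # monotone after 1 s transient
        assert sim.speed[-1] > sim.speed[0]

    def test_short_segment_rejected(self):
        times = np.arange(0, 30) / 60
        nbr = Trajectory(times=times, x=np.zeros_like(times),
                         y=np.full_like(times, 2.0),
                         heading=np.full_like(times, FORWARD),
                         speed=np.ones_like(times))
        with pytest.raises(ValueError, match="1 s"):
            simulate_swarm_replay([nbr], AgentState(np.zeros(2), FORWARD, 1.0),
                                  SimConfig())

    def test_gaps_rejected_unless_filled(self):
        times = np.arange(0, 121) / 60
        y = np.linspace(2, 4, len(times))
        y_gap = y.copy()
        y_gap[40:50] = np.nan
        mk = lambda yy: Trajectory(times=times, x=np.zeros_like(times), y=yy,
                                   heading=np.full_like(times, FORWARD),
                                   speed=np.ones_like(times))
        focal = AgentState(np.array([0.0, 0.0]), FORWARD, 1.0)
        with pytest.raises(ValueError, match="gap"):
            simulate_swarm_replay([mk(y_gap)], focal, SimConfig())
        sim = simulate_swarm_replay([mk(y_gap)], focal, SimConfig(),
                                    fill_gaps=True)
        ref = simulate_swarm_replay([mk(y)], focal, SimConfig())
        assert np.allclose(sim.y, ref.y, atol=1e-9)

    def test_visual_beats_omniscient_under_frequent_occlusion(self):
        # dense synthetic swarms: the hindmost walker is re-simulated
        # by both models and scored against its recorded trajectory
        rv, ro = [], []
        for seed in range(20):
            trajs = generate_synthetic_swarm(
                16, duration=10.0, seed=seed, spacing=1.2,
                veer_std=0.5, agent_heading_std=0.05,
            )
            idx = int(np.argmin([t.y[0] for t in trajs]))
            truth = trajs[idx]
            nbrs = [t for i, t in enumerate(trajs) if i != idx]
            init = truth.state_at(0)
            sv = simulate_swarm_replay(nbrs, init, SimConfig(model="visual"))
            so = simulate_swarm_replay(nbrs, init,
                                       SimConfig(model="omniscient"))
            rv.append(heading_rmse(sv, truth))
            ro.append(heading_rmse(so, truth))
        assert np.mean(rv) < np.mean(ro)


class TestMultiAgent:
    def test_two_aligned_agents_go_straight(self):
        agents = [make_state(-0.5, 0), make_state(0.5, 0)]
        trajs = multi_agent_simulate(agents, SimConfig(), T=2.0)
        for t in trajs:
            assert np.max(np.abs(t.heading - FORWARD)) < 1e-12
            assert np.max(np.abs(t.speed - 1.0)) < 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        agents = [
            make_state(x, y, heading=rng.uniform(-math.pi, math.pi))
            for x, y in rng.uniform(0, 4, (5, 2))
        ]
        cfg = SimConfig()
        fwd = multi_agent_simulate(agents, cfg, T=1.0)
        perm = [2, 0, 4, 1, 3]
        back = multi_agent_simulate([agents[i] for i in perm], cfg, T=1.0)
        for k, i in enumerate(perm):
            assert np.array_equal(fwd[i].x, back[k].x)
            assert np.array_equal(fwd[i].heading, back[k].heading)

    def test_determinism_bit_identical(self):
        agents = [make_state(0, 0, heading=0.3), make_state(1, 1, heading=-0.2)]
        a = multi_agent_simulate(agents, SimConfig(), T=1.0)
        b = multi_agent_simulate(agents, SimConfig(), T=1.0)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x, tb.x)
            assert np.array_equal(ta.heading, tb.heading)

    def test_single_agent_rejected(self):
        with pytest.raises(ValueError):
            multi_agent_simulate([make_state(0, 0)], SimConfig(), T=1.0)

    def test_no_nan_with_collisions(self, caplog):
        # agents head straight at each other; collision is logged and
        # the simulation carries on
        agents = [make_state(0, 0, heading=FORWARD),
                  make_state(0, 1.0, heading=-FORWARD)]
        with caplog.at_level("WARNING"):
            trajs = multi_agent_simulate(agents, SimConfig(), T=3.0)
        for t in trajs:
            assert np.isfinite(t.x).all() and np.isfinite(t.heading).all()


class TestSimConfig:
    def test_invalid_integrator(self):
        with pytest.raises(ValueError):
            SimConfig(integrator="leapfrog")

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            SimConfig(model="psychic")

    def test_signed_speed_mode(self):
        cfg = SimConfig(allow_negative_speed=True)
        assert cfg.floor == -math.inf
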