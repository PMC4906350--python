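import math

import numpy as np
import pytest

from swarmscape import (
    AgentState,
    SwarmConfig,
    ZoneParams,
    order_parameters,
    preset_config,
    simulate,
    step,
)
from swarmscape.couzin_sim import (
    SwarmState,
    repulsion_direction,
    social_direction,
    turn_toward,
    visible_neighbors,
)


def agent(pos, direction):
    d = np.asarray(direction, dtype=float)
    return AgentState(np.asarray(pos, dtype=float), d / np.linalg.norm(d))


class TestZoneParams:
    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            ZoneParams(2.0, 1.0, 14.0)
        with pytest.raises(ValueError):
            ZoneParams(0.0, 1.0, 14.0)

    def test_equal_radii_allowed(self):
        z = ZoneParams(1.0, 1.0, 1.0)
        assert z.max_turn_angle == pytest.approx(0.07)


class TestVisibleNeighbors:
    def test_neighbor_directly_behind_excluded(self):
        focal = agent([0, 0, 0], [1, 0, 0])
        behind = [agent([-2, 0, 0], [1, 0, 0])]
        assert visible_neighbors(focal, behind, 0.0, 5.0, math.pi / 3) == []

    def test_neighbor_directly_ahead_included(self):
        focal = agent([0, 0, 0], [1, 0, 0])
        ahead = [agent([2, 0, 0], [1, 0, 0])]
        assert visible_neighbors(focal, ahead, 0.0, 5.0, math.pi / 3) == [0]

    def test_outside_shell_excluded(self):
        focal = agent([0, 0, 0], [1, 0, 0])
        others = [agent([2, 0, 0], [1, 0, 0])]
        assert visible_neighbors(focal, others, 0.0, 2.0, 0.0) == []  # half-open at r_max
        assert visible_neighbors(focal, others, 2.0, 5.0, 0.0) == [0]  # closed at r_min

    def test_coincident_neighbor_excluded_with_warning(self, caplog):
        focal = agent([0, 0, 0], [1, 0, 0])
        others = [agent([0, 0, 0], [0, 1, 0])]
        with caplog.at_level("WARNING"):
            assert visible_neighbors(focal, others, 0.0, 5.0, 0.0) == []
        assert any("coincident" in r.message for r in caplog.records)

    def test_matches_brute_force_oracle(self, rng):
        """20 random neighbours vs an independent distance/angle loop."""
        focal = agent(rng.normal(size=3), rng.normal(size=3))
        others = [agent(rng.normal(scale=3, size=3), rng.normal(size=3)) for _ in range(20)]
        r_min, r_max, blind = 1.0, 4.0, math.pi / 4
        got = visible_neighbors(focal, others, r_min, r_max, blind)

        expected = []
        for j, o in enumerate(others):
            rel = o.position - focal.position
            dist = math.sqrt(sum(rel**2))
            if dist == 0 or not (r_min <= dist < r_max):
                continue
            cosang = float(rel @ (-focal.direction)) / dist
            if math.acos(max(-1.0, min(1.0, cosang))) > blind:
                expected.append(j)
        assert got == expected


class TestRepulsionDirection:
    def test_single_neighbor_negated_unit(self):
        focal = agent([0, 0, 0], [0, 0, 1])
        out = repulsion_direction(focal, np.array([[1.0, 0, 0]]))
        np.testing.assert_allclose(out, [-1, 0, 0], atol=1e-15)

    def test_symmetric_cancellation_falls_back_to_heading(self):
        focal = agent([0, 0, 0], [0, 0, 1])
        out = repulsion_direction(focal, np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        np.testing.assert_allclose(out, [0, 0, 1])

    def test_matches_summation_oracle(self, rng):
        focal = agent(rng.normal(size=3), rng.normal(size=3))
        nbrs = rng.normal(scale=2, size=(3, 3)) + focal.position
        out = repulsion_direction(focal, nbrs)
        acc = np.zeros(3)
        for p in nbrs:
            rel = p - focal.position
            acc -= rel / np.linalg.norm(rel)
        np.testing.assert_allclose(out, acc / np.linalg.norm(acc), atol=1e-12)


class TestSocialDirection:
    def test_no_neighbors_keeps_heading(self):
        focal = agent([0, 0, 0], [0, 1, 0])
        out = social_direction(focal, np.empty((0, 3)), np.empty((0, 3)))
        np.testing.assert_allclose(out, [0, 1, 0])

    def test_single_attraction_neighbor(self):
        focal = agent([0, 0, 0], [1, 0, 0])
        out = social_direction(focal, np.empty((0, 3)), np.array([[0.0, 2.0, 0.0]]))
        np.testing.assert_allclose(out, [0, 1, 0], atol=1e-15)

    def test_both_zones_match_arithmetic_oracle(self, rng):
        focal = agent([0, 0, 0], [1, 0, 0])
        orient = rng.normal(size=(2, 3))
        orient /= np.linalg.norm(orient, axis=1)[:, None]
        attract = rng.normal(scale=2, size=(2, 3))
        out = social_direction(focal, orient, attract)

        w_o = orient.sum(axis=0) + focal.direction
        w_o = w_o / np.linalg.norm(w_o)
        w_a = np.zeros(3)
        for p in attract:
            w_a += (p - focal.position) / np.linalg.norm(p - focal.position)
        w_a = w_a / np.linalg.norm(w_a)
        combined = (w_o + w_a) / 2.0
        np.testing.assert_allclose(out, combined / np.linalg.norm(combined), atol=1e-12)


class TestTurnToward:
    def test_within_limit_adopts_desired(self):
        d = np.array([1.0, 0, 0])
        w = np.array([math.cos(math.radians(10)), math.sin(math.radians(10)), 0])
        out = turn_toward(d, w, math.radians(30))
        np.testing.assert_allclose(out, w, atol=1e-12)

    def test_identity(self):
        d = np.array([0.0, 0, 1])
        np.testing.assert_allclose(turn_toward(d, d, 0.1), d)

    def test_zero_desired_keeps_heading(self):
        d = np.array([0.0, 1, 0])
        np.testing.assert_allclose(turn_toward(d, np.zeros(3), 0.1), d)

    def test_limited_rotation_matches_rodrigues_oracle(self):
        d = np.array([1.0, 0, 0])
        w = np.array([0.0, 1.0, 0])  # 90 degrees away
        max_angle = math.radians(30)
        out = turn_toward(d, w, max_angle)
        # independent Rodrigues rotation about +z
        c, s = math.cos(max_angle), math.sin(max_angle)
        expected = np.array([c, s, 0.0])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert math.acos(np.clip(out @ d, -1, 1)) == pytest.approx(max_angle, abs=1e-12)
        assert math.acos(np.clip(out @ w, -1, 1)) == pytest.approx(math.radians(60), abs=1e-12)

    def test_antiparallel_uses_deterministic_axis(self):
        d = np.array([1.0, 0, 0])
        out1 = turn_toward(d, -d, 0.3)
        out2 = turn_toward(d, -d, 0.3)
        np.testing.assert_array_equal(out1, out2)
        assert math.acos(np.clip(out1 @ d, -1, 1)) == pytest.approx(0.3, abs=1e-12)


class TestStep:
    def test_facing_repulsive_pair_separates(self):
        # turn limit generous enough to complete the about-face in one step
        zones = ZoneParams(2.0, 2.0, 5.0, blind_halfangle=0.0,
                           max_turn_rate_theta=40.0, speed=1.0, tau=0.1)
        state = SwarmState(
            time=0.0,
            positions=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            directions=np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
        )
        new = step(state, zones)
        d0 = np.linalg.norm(state.positions[1] - state.positions[0])
        d1 = np.linalg.norm(new.positions[1] - new.positions[0])
        assert d1 > d0
        # two-agent arithmetic oracle: each flees directly away from the other
        np.testing.assert_allclose(new.positions[0], [-0.1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(new.positions[1], [1.1, 0, 0], atol=1e-12)

    def test_isolated_agents_move_straight(self):
        zones = ZoneParams(1.0, 1.0, 2.0, speed=3.0, tau=0.1)
        state = SwarmState(
            time=0.0,
            positions=np.array([[0.0, 0, 0], [100.0, 0, 0]]),
            directions=np.array([[0.0, 0, 1], [0.0, 1, 0]]),
        )
        new = step(state, zones)
        np.testing.assert_allclose(new.positions[0], [0, 0, 0.3], atol=1e-12)
        np.testing.assert_allclose(new.positions[1], [100, 0.3, 0], atol=1e-12)
        np.testing.assert_array_equal(new.directions, state.directions)

    def test_noise_requires_rng(self, random_swarm_state):
        zones = ZoneParams(1.0, 2.0, 5.0, noise_sd=0.1)
        with pytest.raises(ValueError):
            step(random_swarm_state, zones, rng=None)

    def test_step_is_deterministic_given_rng_state(self, random_swarm_state):
        zones = ZoneParams(1.0, 2.0, 5.0, noise_sd=0.1)
        a = step(random_swarm_state, zones, np.random.default_rng(5))
        b = step(random_swarm_state, zones, np.random.default_rng(5))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.directions, b.directions)


class TestStepInvariants:
    ZONES = ZoneParams(1.0, 2.5, 6.0, noise_sd=0.0)

    def test_permutation_equivariance(self, random_swarm_state, rng):
        perm = rng.permutation(random_swarm_state.n_agents)
        permuted = SwarmState(
            time=0.0,
            positions=random_swarm_state.positions[perm],
            directions=random_swarm_state.directions[perm],
        )
        out = step(random_swarm_state, self.ZONES)
        out_p = step(permuted, self.ZONES)
        np.testing.assert_allclose(out_p.positions, out.positions[perm], atol=1e-12)
        np.testing.assert_allclose(out_p.directions, out.directions[perm], atol=1e-12)

    def test_unit_norm_displacement_and_turn_limit(self, random_swarm_state):
        zones = ZoneParams(1.0, 2.5, 6.0, noise_sd=0.05)
        rng = np.random.default_rng(0)
        state = random_swarm_state
        for _ in range(50):
            new = step(state, zones, rng)
            np.testing.assert_allclose(
                np.linalg.norm(new.directions, axis=1), 1.0, atol=1e-9
            )
            disp = np.linalg.norm(new.positions - state.positions, axis=1)
            np.testing.assert_allclose(disp, zones.speed * zones.tau, atol=1e-9)
            cosang = np.clip(
                np.einsum("ij,ij->i", new.directions, state.directions), -1, 1
            )
            assert np.all(np.arccos(cosang) <= zones.max_turn_angle + 1e-9)
            state = new


class TestSimulate:
    def test_single_retained_frame(self):
        cfg = SwarmConfig(n_agents=3, zones=ZoneParams(1.0, 2.0, 5.0),
                          n_steps=6, burn_in_steps=5, seed=1)
        traj = simulate(cfg)
        assert traj.n_frames == 1

    def test_zero_speed_positions_constant(self):
        cfg = SwarmConfig(n_agents=4, zones=ZoneParams(1.0, 2.0, 5.0, speed=0.0),
                          n_steps=10, seed=1)
        traj = simulate(cfg)
        assert np.all(traj.positions == traj.positions[0])

    def test_fixed_seed_bit_identical(self):
        cfg = preset_config("torus", n_agents=10, n_steps=50, seed=3)
        a, b = simulate(cfg), simulate(cfg)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.directions, b.directions)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            preset_config("spiral")


class TestOrderParameters:
    def test_identical_directions_full_polarization(self):
        state = SwarmState(0.0, np.random.default_rng(0).normal(size=(6, 3)),
                           np.tile([1.0, 0, 0], (6, 1)))
        pol, _ = order_parameters(state)
        assert pol == pytest.approx(1.0)

    def test_antiparallel_pairs_zero_polarization(self):
        d = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        state = SwarmState(0.0, np.random.default_rng(1).normal(size=(4, 3)), d)
        pol, _ = order_parameters(state)
        assert pol == pytest.approx(0.0, abs=1e-12)

    def test_tangential_ring_full_angular_momentum(self):
        """Hand-constructed ring: agents on a circle, headings tangential."""
        n = 8
        ang = 2 * np.pi * np.arange(n) / n
        pos = np.stack([np.cos(ang), np.sin(ang), np.zeros(n)], axis=1)
        dirs = np.stack([-np.sin(ang), np.cos(ang), np.zeros(n)], axis=1)
        state = SwarmState(0.0, pos, dirs)
        pol, mom = order_parameters(state)
        assert mom == pytest.approx(1.0, abs=1e-12)
        assert pol == pytest.approx(0.0, abs=1e-12)
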