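import math
from dataclasses import replace

import numpy as np
import pytest

from preyflock import default_params
from preyflock.engine import compute_accelerations
from preyflock.forces import (alignment_force, attraction_force,
                              friction_force, prey_force_breakdown,
                              propulsion_force, separation_force,
                              visible_mask)
from preyflock.state import CRUISING, ESCAPE

from conftest import random_world


@pytest.fixture
def p():
    return default_params()


class TestVisibility:
    def test_zero_blind_angle_is_pure_metric_ball(self, p):
        pos = np.zeros(2)
        heading = np.array([1.0, 0.0])
        others = np.array([[1.0, 0.0], [-2.0, 0.0], [0.0, 30.0]])
        mask = visible_mask(pos, heading, others, 5.0, 0.0, p.L)
        assert mask.tolist() == [True, True, False]

    def test_target_directly_behind_is_excluded(self, p):
        mask = visible_mask(np.zeros(2), np.array([1.0, 0.0]),
                            np.array([[-3.0, 0.0]]), 5.0, math.pi / 2, p.L)
        assert not mask[0]

    def test_eight_points_on_circle_rear_quarter_hidden(self, p):
        """theta_b = pi/2 hides exactly the two points in the rear cone."""
        ang = (np.arange(8) + 0.5) * math.pi / 4  # 22.5, 67.5, ..., 337.5 deg
        others = np.column_stack([np.cos(ang), np.sin(ang)]) * 2.0
        mask = visible_mask(np.zeros(2), np.array([1.0, 0.0]), others,
                            5.0, math.pi / 2, p.L)
        # blind cone: strictly within 45 deg of the -x axis
        # -> the points at 157.5 and 202.5 deg; the other six are visible
        expected = [True, True, True, False, False, True, True, True]
        assert mask.tolist() == expected


class TestSeparation:
    def test_zero_force_at_contact_distance(self, p):
        pos = np.array([[0.0, 0.0], [p.r_sep, 0.0]])
        f = separation_force(0, pos, np.full(2, p.r_sep), p.k_n, p.L)
        np.testing.assert_allclose(f, 0.0)

    def test_half_overlap_hand_value(self, p):
        """At distance d_pr/2 the magnitude is k_n * d_pr / 2, away from j."""
        pos = np.array([[0.0, 0.0], [0.5 * p.d_pr, 0.0]])
        f = separation_force(0, pos, np.full(2, p.d_pr), p.k_n, p.L)
        np.testing.assert_allclose(f, [-0.5 * p.k_n * p.d_pr, 0.0], atol=1e-12)

    def test_pairwise_antisymmetry(self, p):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 2.0, (2, 2))
        radii = np.full(2, 1.8)
        f0 = separation_force(0, pos, radii, p.k_n, p.L)
        f1 = separation_force(1, pos, radii, p.k_n, p.L)
        np.testing.assert_allclose(f0, -f1, atol=1e-12)

    def test_coincident_agents_repel_deterministically(self, p):
        pos = np.zeros((2, 2))
        radii = np.full(2, p.d_pr)
        f0 = separation_force(0, pos, radii, p.k_n, p.L)
        f0_again = separation_force(0, pos, radii, p.k_n, p.L)
        f1 = separation_force(1, pos, radii, p.k_n, p.L)
        np.testing.assert_allclose(f0, f0_again)
        np.testing.assert_allclose(f0, -f1)
        assert np.linalg.norm(f0) == pytest.approx(p.k_n * p.d_pr)

    def test_net_separation_force_vanishes_over_closed_system(self, p):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 3.0, (12, 2)) % p.L
        radii = np.full(12, p.d_pr)
        total = sum(separation_force(i, pos, radii, p.k_n, p.L)
                    for i in range(12))
        np.testing.assert_allclose(total, 0.0, atol=1e-10)


class TestPropulsion:
    def test_zero_at_rayleigh_terminal_point(self, p):
        v_star = math.sqrt(p.beta_pr_c / p.gamma)
        f = propulsion_force(np.array([v_star, 0.0]), np.array([1.0, 0.0]),
                             CRUISING, np.zeros(2), p)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_braking_above_terminal(self, p):
        v = np.array([2 * math.sqrt(p.beta_pr_c / p.gamma), 0.0])
        f = propulsion_force(v, np.array([1.0, 0.0]), CRUISING, np.zeros(2), p)
        assert f[0] < 0 and f[1] == 0

    def test_escape_from_rest_pushes_away_from_predator(self, p):
        """Predator due east, prey at rest: force m*beta_e due west."""
        f = propulsion_force(np.zeros(2), np.array([0.0, 1.0]), ESCAPE,
                             np.array([-1.0, 0.0]), p)
        np.testing.assert_allclose(f, [-p.m_pr * p.beta_pr_e, 0.0], atol=1e-12)


class TestAlignment:
    def test_no_neighbours_reduces_to_social_drag(self, p):
        v = np.array([0.3, -0.4])
        f = alignment_force(v, np.empty((0, 2)), np.empty(0), np.empty(0), p)
        np.testing.assert_allclose(f, -p.C_v * p.d_pr * v)

    def test_identical_velocity_single_neighbour(self, p):
        """One equal-mass co-moving neighbour: F = C_v d (phi - 1) v."""
        v = np.array([0.5, 0.2])
        f = alignment_force(v, v[None, :], np.array([2.0]),
                            np.array([p.m_pr]), p)
        phi = p.m_pr / (p.m_pr + p.m_fluid)
        np.testing.assert_allclose(f, p.C_v * p.d_pr * (phi - 1) * v)

    def test_two_neighbours_weighted_mean_hand_value(self, p):
        """Weights W1 = 2*W2 give v_surr = (2/3, 1/3)."""
        # choose distances so the Gaussian weights have ratio 2:1
        r1 = 1.0
        r2 = math.sqrt(r1 ** 2 + 2 * p.w_rms ** 2 * math.log(2.0))
        vn = np.array([[1.0, 0.0], [0.0, 1.0]])
        v = np.zeros(2)
        f = alignment_force(v, vn, np.array([r1, r2]),
                            np.full(2, p.m_pr), p)
        phi = 2 * p.m_pr / (2 * p.m_pr + p.m_fluid)
        expected = p.C_v * p.d_pr * phi * np.array([2 / 3, 1 / 3])
        np.testing.assert_allclose(f, expected, rtol=1e-12)

    def test_noise_rotation_preserves_magnitude(self, p):
        v = np.array([0.5, 0.1])
        f0 = alignment_force(v, np.empty((0, 2)), np.empty(0), np.empty(0), p)
        f1 = alignment_force(v, np.empty((0, 2)), np.empty(0), np.empty(0), p,
                             zeta=0.7)
        assert np.linalg.norm(f0) == pytest.approx(np.linalg.norm(f1))
        assert not np.allclose(f0, f1)


class TestAttraction:
    def test_empty_shell_zero(self, p):
        np.testing.assert_allclose(
            attraction_force(np.zeros(2), np.empty((0, 2)), p), 0.0)

    def test_boundary_magnitude_equals_strength(self, p):
        """A neighbour exactly at r_atr pulls with magnitude upsilon_a."""
        f = attraction_force(np.zeros(2), np.array([[p.r_atr, 0.0]]), p)
        np.testing.assert_allclose(f, [p.upsilon_a, 0.0], atol=1e-15)

    def test_half_range_hand_value(self, p):
        """At r = r_atr/2 the magnitude is upsilon_a * sqrt(3)/2."""
        f = attraction_force(np.zeros(2), np.array([[p.r_atr / 2, 0.0]]), p)
        np.testing.assert_allclose(f, [p.upsilon_a * math.sqrt(3) / 2, 0.0],
                                   rtol=1e-12)


class TestFriction:
    def test_zero_velocity_zero_drag(self):
        np.testing.assert_allclose(friction_force(np.zeros(2), 1.0), 0.0)

    def test_quadratic_scaling(self):
        f1 = friction_force(np.array([0.3, 0.4]), 1.0)
        f2 = friction_force(np.array([0.6, 0.8]), 1.0)
        np.testing.assert_allclose(f2, 4 * f1)

    def test_hand_value(self):
        """v = (3, 4) with rho*c_f*A = 2 gives force -(15, 20)."""
        f = friction_force(np.array([3.0, 4.0]), 0.5 * 2.0)
        np.testing.assert_allclose(f, [-15.0, -20.0])


class TestTotalPreyForce:
    def test_dead_prey_behavioural_block_exactly_zero(self, params, rng):
        w = random_world(params, rng, n_dead=5)
        bd = prey_force_breakdown(w, params)
        dead = w.mu == 0
        assert (bd.propulsion[dead] == 0).all()
        assert (bd.alignment[dead] == 0).all()
        assert (bd.attraction[dead] == 0).all()
        # dead prey still feel drag
        moving_dead = dead & (np.linalg.norm(w.prey_v, axis=1) > 0)
        assert (np.linalg.norm(bd.friction[moving_dead], axis=1) > 0).all()

    def test_isolated_live_cruiser_only_propulsion_drag_and_social_drag(
            self, params, rng):
        w = random_world(params, rng)
        w.prey_x[0] = [5.0, 5.0]  # far from the pack at the domain centre
        w.prey_mode[0] = CRUISING
        bd = prey_force_breakdown(w, params)
        np.testing.assert_allclose(bd.separation[0], 0.0)
        np.testing.assert_allclose(bd.attraction[0], 0.0)
        # the no-neighbour alignment limit is the social drag -C_v d v
        np.testing.assert_allclose(
            bd.alignment[0], -params.C_v * params.d_pr * w.prey_v[0])

    def test_kernel_matches_reference_assembly(self, params, rng):
        """Numba production kernel equals the readable reference path."""
        w = random_world(params, rng, n_dead=4)
        zeta = rng.normal(0, params.sigma_zeta, params.N)
        a_nb = compute_accelerations(w, params, zeta, engine="numba")
        a_np = compute_accelerations(w, params, zeta, engine="numpy")
        np.testing.assert_allclose(a_nb[0], a_np[0], atol=1e-9)
        np.testing.assert_allclose(a_nb[1], a_np[1], atol=1e-9)

    def test_kernel_matches_reference_with_blind_social_off(self, rng):
        params = replace(default_params(), N=30, N_p=2,
                         blind_angle_social=False)
        w = random_world(params, rng, n_dead=2)
        zeta = rng.normal(0, params.sigma_zeta, params.N)
        a_nb = compute_accelerations(w, params, zeta, engine="numba")
        a_np = compute_accelerations(w, params, zeta, engine="numpy")
        np.testing.assert_allclose(a_nb[0], a_np[0], atol=1e-9)
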