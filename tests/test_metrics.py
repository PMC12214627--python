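import math

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import DBSCAN

from preyflock.geometry import pairwise_displacements
from preyflock.metrics import (capture_rate, cluster_prey, dbscan_periodic,
                               default_min_pts, events_to_frame,
                               first_passage_times, group_size_distribution,
                               group_speed, kappa, live_fraction, local_order,
                               pursuit_outcome_stats)
from preyflock.state import PursuitEvent

L = 100.0


class TestLocalOrder:
    def test_identical_headings_give_one(self):
        x = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        v = np.tile([0.3, 0.4], (3, 1))
        assert local_order(v, x, 2.0, L) == pytest.approx(1.0)

    def test_antiparallel_pair_gives_minus_one(self):
        x = np.array([[0, 0], [1, 0]], dtype=float)
        v = np.array([[1.0, 0.0], [-2.0, 0.0]])
        assert local_order(v, x, 2.0, L) == pytest.approx(-1.0)

    def test_four_agents_match_bruteforce_pair_sum(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 3, (4, 2))
        v = rng.normal(0, 1, (4, 2))
        r_alg = 2.0
        acc, n_pairs = 0.0, 0
        for i in range(4):
            for j in range(i + 1, 4):
                d = x[j] - x[i]  # no wrap at this scale
                if np.linalg.norm(d) <= r_alg:
                    acc += (v[i] @ v[j]) / (np.linalg.norm(v[i])
                                            * np.linalg.norm(v[j]))
                    n_pairs += 1
        assert local_order(v, x, r_alg, L) == pytest.approx(acc / n_pairs)

    def test_no_neighbouring_pair_is_undefined(self):
        x = np.array([[0, 0], [50, 50]], dtype=float)
        v = np.ones((2, 2))
        assert math.isnan(local_order(v, x, 1.0, L))

    def test_bounded_in_minus_one_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.uniform(0, 5, (8, 2))
            v = rng.normal(0, 1, (8, 2))
            val = local_order(v, x, 3.0, L)
            assert -1.0 - 1e-12 <= val <= 1.0 + 1e-12


class TestGroupSpeed:
    def test_common_velocity_normalised(self):
        v = np.tile([2.0, 0.0], (5, 1))
        assert group_speed(v, v0=2.0) == pytest.approx(1.0)

    def test_opposite_velocities_cancel(self):
        v = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert group_speed(v, v0=1.0) == pytest.approx(0.0)

    def test_three_member_hand_value(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        expected = np.linalg.norm(v.mean(axis=0))
        assert group_speed(v, v0=1.0) == pytest.approx(expected)


def _periodic_dbscan_reference(x, eps, min_pts, L):
    """Independent oracle: scikit-learn DBSCAN on precomputed torus distances."""
    d = pairwise_displacements(x, x, L)
    dist = np.linalg.norm(d, axis=2)
    return DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(
        dist).labels_


def _same_partition(a, b):
    """Labelings equal up to label permutation (noise must coincide)."""
    a, b = np.asarray(a), np.asarray(b)
    if not ((a == -1) == (b == -1)).all():
        return False
    mapping = {}
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if mapping.setdefault(la, lb) != lb:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestClustering:
    def test_two_blobs_and_noise_match_sklearn(self):
        rng = np.random.default_rng(5)
        blob1 = rng.normal([20, 20], 0.8, (30, 2))
        blob2 = rng.normal([60, 60], 0.8, (25, 2))
        stray = rng.uniform(0, L, (6, 2))
        x = np.vstack([blob1, blob2, stray]) % L
        ours = dbscan_periodic(x, 3.0, 5, L)
        ref = _periodic_dbscan_reference(x, 3.0, 5, L)
        assert _same_partition(ours, ref)

    def test_cluster_across_periodic_boundary_matches_sklearn(self):
        rng = np.random.default_rng(6)
        blob = (rng.normal(0.0, 0.8, (25, 2))) % L  # straddles the corner
        ours = dbscan_periodic(blob, 3.0, 5, L)
        ref = _periodic_dbscan_reference(blob, 3.0, 5, L)
        assert _same_partition(ours, ref)
        assert set(ours) == {0}  # one cluster despite the wrap

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal([30, 30], 1.0, (20, 2)),
                       rng.normal([70, 30], 1.0, (20, 2))])
        perm = rng.permutation(len(x))
        base = dbscan_periodic(x, 3.0, 4, L)
        permuted = dbscan_periodic(x[perm], 3.0, 4, L)
        assert _same_partition(base[perm], permuted)

    def test_all_within_eps_single_cluster_l_c(self):
        x = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]], float)
        res = cluster_prey(x, 2.0, 5, L, N=10)
        assert res.n_clusters == 1 and res.n_noise == 0
        assert res.l_c == pytest.approx(0.5)  # 5 live of initial N=10

    def test_isolated_points_all_noise(self):
        x = np.array([[0, 0], [20, 0], [0, 20], [20, 20]], float)
        res = cluster_prey(x, 2.0, 5, L, N=506)
        assert res.n_clusters == 0 and res.n_noise == 4
        assert res.l_c == 0.0

    def test_default_min_pts_one_percent_floor(self):
        assert default_min_pts(506) == 5
        assert default_min_pts(100) == 1
        assert default_min_pts(5) == 1


class TestGroupSizeDistribution:
    def test_full_cluster_every_realisation_point_mass_at_one(self):
        edges, p = group_size_distribution(
            [np.array([506]), np.array([506])], N=506,
            bins=np.array([0, 0.5, 0.95, 1.0]))
        np.testing.assert_allclose(p, [0, 0, 1])

    def test_hand_built_histogram(self):
        sizes = [np.array([250, 250]), np.array([400, 100])]
        edges, p = group_size_distribution(sizes, N=500,
                                           bins=np.array([0., 0.3, 0.6, 1.0]))
        # phis: 0.5, 0.5, 0.8, 0.2 -> bins (0.3,0.6]: 2, (0,0.3]: 1, (0.6,1]: 1
        np.testing.assert_allclose(p, [0.25, 0.5, 0.25])
        assert p.sum() == pytest.approx(1.0)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            group_size_distribution([], N=10)


class TestLiveFractionAndRate:
    def test_live_fraction_examples(self):
        assert live_fraction(np.ones(10)) == 1.0
        assert live_fraction(np.zeros(10)) == 0.0
        mu = np.zeros(506); mu[:253] = 1
        assert live_fraction(mu) == pytest.approx(0.5)

    def test_constant_series_zero_rate(self):
        tau = np.arange(6.0)
        _, a = capture_rate(tau, np.full(6, 0.7), window=3)
        np.testing.assert_allclose(a, 0.0)

    def test_linear_decay_recovers_slope(self):
        tau = np.arange(6.0)
        n_l = 1.0 - 0.05 * tau
        _, a = capture_rate(tau, n_l, window=3)
        np.testing.assert_allclose(a, 0.05)

    def test_hand_series_with_truncated_edges(self):
        tau = np.arange(6.0)
        n_l = np.array([1.0, 0.9, 0.9, 0.6, 0.6, 0.5])
        slopes = np.array([0.1, 0.0, 0.3, 0.0, 0.1])
        mid, a = capture_rate(tau, n_l, window=3)
        expected = [np.mean(slopes[max(0, k - 1):k + 2]) for k in range(5)]
        np.testing.assert_allclose(a, expected)
        np.testing.assert_allclose(mid, tau[:-1] + 0.5)

    def test_strictly_monotone_series_positive_interior_rate(self):
        rng = np.random.default_rng(3)
        n_l = np.concatenate([[1.0], 1.0 - np.cumsum(rng.uniform(0.01, 0.05, 9))])
        _, a = capture_rate(np.arange(10.0), n_l, window=5)
        assert (a > 0).all()


def _events(spec):
    return [PursuitEvent(0, 1, 0, 0, phi, outcome, "NP")
            for phi, outcome in spec]


class TestPursuitStats:
    def test_all_success_single_bin(self):
        tbl = pursuit_outcome_stats(_events([(1.0, "success")] * 4),
                                    phi_bins=np.array([0.0, 0.5, 1.0]))
        assert tbl.loc["success"].iloc[-1] == pytest.approx(1.0)
        assert tbl.to_numpy().sum() == pytest.approx(1.0)

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            pursuit_outcome_stats([])

    def test_hand_binned_table(self):
        ev = _events([(0.1, "success"), (0.1, "failure"), (0.6, "failure"),
                      (0.6, "failure"), (0.9, "success")])
        tbl = pursuit_outcome_stats(ev, phi_bins=np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(tbl.loc["success"], [0.2, 0.2])
        np.testing.assert_allclose(tbl.loc["failure"], [0.2, 0.4])


class TestKappa:
    def test_first_passage_linear_interpolation(self):
        tau = np.array([0.0, 10.0, 20.0])
        n_d = np.array([0.0, 0.1, 0.3])
        fpt = first_passage_times(tau, n_d, [0.05, 0.1, 0.2, 0.5])
        np.testing.assert_allclose(fpt[:3], [5.0, 10.0, 15.0])
        assert math.isnan(fpt[3])  # level never reached

    def test_identical_ensembles_kappa_one(self):
        fpt = np.array([[10.0, 20.0], [14.0, 30.0]])
        np.testing.assert_allclose(kappa(fpt, fpt), 1.0)

    def test_duo_twice_as_fast_kappa_two(self):
        single = np.array([[10.0, 20.0], [14.0, 30.0]])
        np.testing.assert_allclose(kappa(single, single / 2), 2.0)

    def test_swapped_ensembles_invert_ratio(self):
        a = np.array([[10.0, 24.0]])
        b = np.array([[4.0, 6.0]])
        np.testing.assert_allclose(kappa(a, b) * kappa(b, a), 1.0)

    def test_hand_two_realisation_ensembles(self):
        single = np.array([[12.0, 30.0], [18.0, 40.0]])  # means 15, 35
        duo = np.array([[5.0, 10.0], [5.0, 18.0]])       # means 5, 14
        np.testing.assert_allclose(kappa(single, duo), [3.0, 2.5])


def test_events_to_frame_schema():
    df = events_to_frame(_events([(0.3, "success")]))
    assert isinstance(df, pd.DataFrame)
    assert {"t_start", "t_end", "predator_id", "target_id", "phi",
            "outcome", "strategy_mode"} <= set(df.columns)
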