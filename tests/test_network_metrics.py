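import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from pollnet import (
    InteractionMatrix,
    barber_q,
    compute_metrics,
    h2_prime,
    modularity,
    nodf,
    robustness_pollinators,
    weighted_connectance,
    zone_metrics,
)
from pollnet.network_metrics import _h2_min_fill

from conftest import make_matrix, make_zone


def random_binary(seed, shape=(6, 6)):
    rng = np.random.default_rng(seed)
    B = rng.random(shape) < 0.45
    B[0, 0] = True
    return make_matrix(B.astype(int))


class TestWeightedConnectance:
    def test_single_link(self):
        assert weighted_connectance(make_matrix([[5]])) == pytest.approx(0.5)

    def test_uniform_2x2(self, uniform2):
        assert weighted_connectance(uniform2) == pytest.approx(0.5)

    def test_fixed_3x4_matches_formula_oracle(self):
        counts = [[5, 1, 0, 2], [0, 3, 1, 0], [1, 0, 4, 2]]
        # frozen from oracles.connectance_formula(counts)
        assert weighted_connectance(make_matrix(counts)) == pytest.approx(
            0.29167479924316836, abs=1e-12
        )
        assert weighted_connectance(make_matrix(counts)) == pytest.approx(
            oracles.connectance_formula(counts), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_upper_bound_half(self, seed):
        rng = np.random.default_rng(seed)
        M = make_matrix(rng.integers(0, 6, (4, 7)) + (rng.random((4, 7)) < 0.2))
        assert 0 < weighted_connectance(M.trim()) <= 0.5

    def test_uniform_complete_attains_half(self):
        for P, Q in [(2, 2), (3, 3), (4, 4)]:
            M = make_matrix(np.ones((P, Q), dtype=int))
            assert weighted_connectance(M) == pytest.approx(0.5)


class TestNODF:
    def test_identity_is_zero(self):
        assert nodf(make_matrix(np.eye(3, dtype=int))) == 0.0

    def test_full_triangle_is_100(self, triangular3):
        assert nodf(triangular3) == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        M = random_binary(seed)
        assert nodf(M) == pytest.approx(oracles.nodf_bruteforce(M.binary().tolist()))

    def test_undefined_below_2x2(self):
        with pytest.raises(ValueError, match="NODF undefined"):
            nodf(make_matrix([[3]]))

    def test_permutation_invariance(self):
        M = random_binary(3)
        rng = np.random.default_rng(0)
        perm_r = rng.permutation(M.n_plants)
        perm_c = rng.permutation(M.n_pollinators)
        M2 = InteractionMatrix(
            tuple(M.plant_labels[i] for i in perm_r),
            tuple(M.pollinator_labels[j] for j in perm_c),
            M.counts[np.ix_(perm_r, perm_c)],
        )
        assert nodf(M2) == pytest.approx(nodf(M))

    def test_permutation_matrix_is_zero(self):
        rng = np.random.default_rng(1)
        P = np.eye(5, dtype=int)[rng.permutation(5)]
        assert nodf(make_matrix(P)) == 0.0

    def test_weighted_variant_on_nested_counts(self):
        # strictly nested, strictly decreasing weights -> weighted NODF 100
        M = make_matrix([[3, 2, 1], [2, 1, 0], [1, 0, 0]])
        assert nodf(M, weighted=True) == pytest.approx(100.0)
        assert nodf(M) == pytest.approx(100.0)


class TestH2Prime:
    def test_uniform_is_zero(self, uniform2):
        assert h2_prime(uniform2) == 0.0

    def test_diagonal_is_one(self):
        assert h2_prime(make_matrix([[2, 0], [0, 2]])) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [
            [[3, 1, 0], [1, 2, 1], [0, 1, 3]],
            [[2, 1, 0], [1, 1, 1], [0, 1, 2]],
            [[4, 0, 1], [0, 3, 1], [1, 1, 1]],
            [[2, 2, 0], [1, 0, 2], [0, 2, 1]],
        ],
    )
    def test_matches_exhaustive_enumeration(self, counts):
        counts = np.array(counts)
        assert counts.sum() <= 12
        greedy = _h2_min_fill(counts.sum(axis=1), counts.sum(axis=0))
        enumerated = oracles.h2min_enumerate(
            counts.sum(axis=1).tolist(), counts.sum(axis=0).tolist()
        )
        assert greedy == pytest.approx(enumerated, abs=1e-12)
        assert h2_prime(make_matrix(counts)) == pytest.approx(
            oracles.h2prime_enumerate(counts.tolist()), abs=1e-12
        )

    def test_outer_product_is_zero(self):
        r = np.array([1, 2, 3])
        c = np.array([2, 1, 1])
        assert h2_prime(make_matrix(np.outer(r, c))) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_1x1(self):
        with pytest.raises(ValueError):
            h2_prime(make_matrix([[4]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        M = make_matrix(rng.integers(0, 5, (5, 8))).trim()
        assert 0.0 <= h2_prime(M) <= 1.0


class TestModularity:
    def test_two_block_toy(self):
        M = make_matrix([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]])
        part = modularity(M, seed=0)
        assert part.q == pytest.approx(0.5)
        # partition equals the two blocks (verified optimal by exhaustive search)
        q_ex, _, _ = oracles.modularity_exhaustive(M.counts.tolist())
        assert q_ex == pytest.approx(0.5)
        assert part.row_modules["p0"] == part.row_modules["p1"] == part.col_modules["i0"]
        assert part.row_modules["p2"] == part.row_modules["p3"] == part.col_modules["i2"]
        assert part.row_modules["p0"] != part.row_modules["p2"]

    def test_single_module_q_is_exactly_zero(self):
        rng = np.random.default_rng(4)
        M = make_matrix(rng.integers(0, 5, (4, 6))).trim()
        assert barber_q(M, [0] * M.n_plants, [0] * M.n_pollinators) == 0.0

    @pytest.mark.parametrize("seed", [7, 11, 13])
    def test_matches_exhaustive_on_5x5(self, seed):
        rng = np.random.default_rng(seed)
        M = make_matrix(rng.integers(0, 5, (5, 5))).trim()
        q_ex, _, _ = oracles.modularity_exhaustive(M.counts.tolist())
        assert modularity(M, seed=0, restarts=10).q == pytest.approx(q_ex, abs=1e-9)

    def test_never_below_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            M = make_matrix(rng.integers(0, 4, (5, 5))).trim()
            assert modularity(M, seed=1).q >= 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        M = make_matrix(rng.integers(0, 4, (6, 6))).trim()
        a = modularity(M, seed=5, restarts=10)
        b = modularity(M, seed=5, restarts=10)
        assert a.q == b.q and a.row_modules == b.row_modules

    def test_reported_q_matches_partition(self):
        rng = np.random.default_rng(12)
        M = make_matrix(rng.integers(0, 4, (5, 6))).trim()
        part = modularity(M, seed=0)
        g_r = [part.row_modules[l] for l in M.plant_labels]
        g_c = [part.col_modules[l] for l in M.pollinator_labels]
        assert part.q == pytest.approx(barber_q(M, g_r, g_c), abs=1e-12)


class TestRobustness:
    @pytest.mark.parametrize("P", [1, 2, 4, 6])
    def test_complete_bipartite_closed_form(self, P):
        M = make_matrix(np.ones((P, 3), dtype=int))
        r = robustness_pollinators(M, replicates=3, seed=0)
        assert r == pytest.approx((2 * P - 1) / (2 * P))

    def test_mc_close_to_exhaustive_on_toy(self):
        counts = [[1, 1, 0, 0], [0, 1, 1, 1], [1, 0, 1, 0]]
        M = make_matrix(counts)
        exact = oracles.robustness_exhaustive(counts)
        mc = robustness_pollinators(M, replicates=300, seed=2)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_mc_converges_with_replicates(self):
        rng = np.random.default_rng(0)
        counts = (rng.random((5, 6)) < 0.5).astype(int)
        counts[:, 0] = 1
        M = make_matrix(counts).trim()
        exact = oracles.robustness_exhaustive(M.binary().tolist())
        err_small = abs(robustness_pollinators(M, replicates=20, seed=1) - exact)
        errs_big = [
            abs(robustness_pollinators(M, replicates=2000, seed=s) - exact)
            for s in range(3)
        ]
        assert max(errs_big) < 0.02
        assert np.mean(errs_big) <= err_small + 0.005

    def test_deterministic_orders(self):
        rng = np.random.default_rng(3)
        M = make_matrix((rng.random((5, 5)) < 0.5).astype(int)).trim()
        asc = robustness_pollinators(M, order="degree_ascending")
        desc = robustness_pollinators(M, order="degree_descending")
        assert 0 < asc < 1 and 0 < desc < 1
        assert desc <= asc  # removing hubs first collapses faster


class TestZoneMetrics:
    def test_duplicated_site_mean_equals_site(self):
        counts = [[3, 1, 0], [1, 2, 1], [0, 1, 3]]
        zone = make_zone({"S1": counts, "S2": counts})
        df = zone_metrics(zone, replicates=20, seed=0)
        for col in ("nodf", "h2_prime", "connectance_w"):
            assert df.loc["mean", col] == pytest.approx(df.loc["S1", col])

    def test_mean_is_hand_average(self, gradient_zones):
        coll = gradient_zones["SF"]
        df = zone_metrics(coll, replicates=10, seed=0, restarts=3)
        sites = df.drop(index="mean")
        assert df.loc["mean", "nodf"] == pytest.approx(sites["nodf"].mean())

    def test_site_error_is_labelled(self):
        zone = make_zone({"S1": [[2]], "S2": [[1, 1], [1, 1]]})
        with pytest.raises(ValueError, match="site S1"):
            zone_metrics(zone)

    def test_compute_metrics_ranges(self, gradient_zones):
        M = gradient_zones["PP"].sites[0].matrix
        res = compute_metrics(M, replicates=10, seed=0, restarts=3)
        assert 0 < res.connectance_w <= 0.5
        assert 0 <= res.nodf <= 100
        assert 0 <= res.h2_prime <= 1
        assert -0.5 <= res.modularity_q <= 1
        assert 0 < res.robustness_r < 1
        assert res.n_links <= res.n_plants * res.n_pollinators
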