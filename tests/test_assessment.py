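"""ARI, Chernoff information, KL divergences and the grouping analysis."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from twotruths.assessment import (
    GaussianComponent,
    ari,
    ari_permutation_test,
    best_two_grouping,
    chernoff_h,
    chernoff_information,
    chernoff_ratio_sbm,
    gaussian_kl,
    limit_gmm_params,
    mixture_kl_numeric,
)
from twotruths.sbm import SBMParams


def brute_force_ari(l1, l2):
    """O(n^2) pair-agreement ARI (oracle)."""
    n = len(l1)
    a = b = ab = 0
    for i, j in itertools.combinations(range(n), 2):
        s1 = l1[i] == l1[j]
        s2 = l2[i] == l2[j]
        a += s1
        b += s2
        ab += s1 and s2
    npairs = n * (n - 1) // 2
    expected = a * b / npairs
    max_index = (a + b) / 2
    if max_index == expected:
        return 1.0 if a == b else 0.0
    return (ab - expected) / (max_index - expected)


class TestARI:
    def test_identical_partitions(self, rng):
        labels = rng.integers(0, 4, size=100)
        assert ari(labels, labels) == pytest.approx(1.0)

    def test_crossed_pairs_give_minus_half(self):
        assert ari([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_trivial_vs_singletons_is_zero(self):
        n = 6
        assert ari([0] * n, list(range(n))) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 60))
            l1 = rng.integers(0, rng.integers(1, 6), size=n)
            l2 = rng.integers(0, rng.integers(1, 6), size=n)
            assert ari(l1, l2) == pytest.approx(brute_force_ari(l1, l2), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 80))
            l1 = rng.integers(0, 5, size=n)
            l2 = rng.integers(0, 5, size=n)
            if len(set(l1)) == 1 and len(set(l2)) == 1:
                continue  # degenerate convention differs by design
            assert ari(l1, l2) == pytest.approx(adjusted_rand_score(l1, l2))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_invariant_under_label_permutation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        l1 = rng.integers(0, 4, size=n)
        l2 = rng.integers(0, 4, size=n)
        perm = rng.permutation(4)
        assert ari(l1, l2) == pytest.approx(ari(perm[l1], l2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])


class TestPermutationTest:
    def test_identical_partitions_significant(self, rng):
        labels = rng.integers(0, 4, size=200)
        p = ari_permutation_test(labels, labels.copy(), n_perm=1000, seed=0)
        assert p <= 0.01

    def test_null_calibration(self):
        hits = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            l1 = rng.integers(0, 3, size=60)
            l2 = rng.integers(0, 3, size=60)
            p = ari_permutation_test(l1, l2, n_perm=199, seed=seed + 1)
            hits += p <= 0.05
        assert 0.0 <= hits / reps <= 0.12  # 0.05 plus binomial slack

    def test_p_value_strictly_positive(self, rng):
        l1 = rng.integers(0, 2, size=30)
        l2 = rng.integers(0, 2, size=30)
        p = ari_permutation_test(l1, l2, n_perm=50, seed=0)
        assert 0.0 < p <= 1.0


def _comp(mu, sigma, w=1.0):
    return GaussianComponent(mu=np.asarray(mu, float), sigma=np.asarray(sigma, float), weight=w)


class TestChernoff:
    def test_identical_gaussians_zero_everywhere(self):
        F = _comp([1.0, -2.0], [[2.0, 0.3], [0.3, 1.0]])
        for t in (0.1, 0.5, 0.9):
            assert chernoff_h(t, F, F) == pytest.approx(0.0, abs=1e-12)
        assert chernoff_information(F, F).value == pytest.approx(0.0, abs=1e-10)

    def test_equal_covariance_reduces_to_quadratic(self):
        S = np.array([[1.5, 0.2], [0.2, 0.8]])
        F1 = _comp([0.0, 0.0], S)
        F2 = _comp([1.0, -1.0], S)
        dmu = np.array([1.0, -1.0])
        for t in (0.2, 0.5, 0.7):
            expect = 0.5 * t * (1 - t) * dmu @ np.linalg.solve(S, dmu)
            assert chernoff_h(t, F1, F2) == pytest.approx(expect)

    def test_one_dimensional_variance_contrast(self):
        F1 = _comp([0.0], [[1.0]])
        F2 = _comp([0.0], [[4.0]])
        assert chernoff_h(0.5, F1, F2) == pytest.approx(
            0.5 * np.log(2.5 / 2.0), abs=1e-9
        )
        assert chernoff_h(0.5, F1, F2) == pytest.approx(0.1115718, abs=1e-6)

    def test_equal_covariance_closed_form_supremum(self):
        F1 = _comp([0.0, 0.0], np.eye(2))
        F2 = _comp([2.0, 0.0], np.eye(2))
        res = chernoff_information(F1, F2)
        assert res.value == pytest.approx(0.5, abs=1e-6)  # (1/8)*||dmu||^2
        assert res.t_star == pytest.approx(0.5, abs=1e-4)

    def test_matches_fine_grid_oracle(self, rng):
        for _ in range(5):
            A1 = rng.normal(size=(2, 2))
            A2 = rng.normal(size=(2, 2))
            F1 = _comp(rng.normal(size=2), A1 @ A1.T + 0.5 * np.eye(2))
            F2 = _comp(rng.normal(size=2), A2 @ A2.T + 0.5 * np.eye(2))
            res = chernoff_information(F1, F2)
            ts = np.arange(1e-4, 1.0, 1e-4)
            grid = max(chernoff_h(t, F1, F2) for t in ts)
            assert res.value == pytest.approx(grid, abs=1e-6)
            assert res.value >= grid - 1e-10

    def test_symmetric_in_arguments(self, rng):
        A1 = rng.normal(size=(3, 3))
        A2 = rng.normal(size=(3, 3))
        F1 = _comp(rng.normal(size=3), A1 @ A1.T + np.eye(3))
        F2 = _comp(rng.normal(size=3), A2 @ A2.T + np.eye(3))
        c12 = chernoff_information(F1, F2).value
        c21 = chernoff_information(F2, F1).value
        assert abs(c12 - c21) <= 1e-8

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError):
            _comp([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])


class TestLimitParams:
    def test_affinity_blocks_well_separated(self, small_affinity_params):
        comps = limit_gmm_params(
            small_affinity_params, "ASE", 2, n=2000, n_graphs=2, seed=0
        )
        dmu = comps[0].mu - comps[1].mu
        pooled = 0.5 * (comps[0].sigma + comps[1].sigma)
        maha = np.sqrt(dmu @ np.linalg.solve(pooled, dmu))
        assert maha > 3.0

    def test_indistinguishable_blocks_coincide(self):
        p = SBMParams(pi=[0.5, 0.5], B=[[0.05, 0.05], [0.05, 0.05]])
        comps = limit_gmm_params(p, "ASE", 2, n=1000, n_graphs=2, seed=0)
        sd = np.sqrt(np.trace(comps[0].sigma))
        dist = np.linalg.norm(comps[0].mu - comps[1].mu)
        assert dist < 8 * sd / np.sqrt(1000)

    def test_separation_stable_across_seed_sets(self, small_affinity_params):
        """Self-consistency: rotation-invariant summaries agree between
        independent estimation runs within Monte-Carlo tolerance."""
        seps, norms = [], []
        for seed in (100, 200):
            comps = limit_gmm_params(
                small_affinity_params, "LSE", 2, n=2000, n_graphs=3, seed=seed
            )
            seps.append(np.linalg.norm(comps[0].mu - comps[1].mu))
            norms.append([np.linalg.norm(c.mu) for c in comps])
        assert seps[0] == pytest.approx(seps[1], rel=0.05)
        assert np.allclose(norms[0], norms[1], rtol=0.05)


class TestChernoffRatio:
    def test_affinity_prefers_laplacian(self, small_affinity_params):
        rhos = [
            chernoff_ratio_sbm(
                small_affinity_params, d=2, n=2000, n_graphs=2, seed=s
            ).rho
            for s in (0, 1, 2)
        ]
        assert all(r < 1.0 for r in rhos)

    def test_core_periphery_prefers_adjacency(self, core_periphery_params):
        rhos = [
            chernoff_ratio_sbm(
                core_periphery_params, d=2, n=2000, n_graphs=2, seed=s
            ).rho
            for s in (0, 1, 2)
        ]
        assert all(r > 1.0 for r in rhos)

    def test_min_pairwise_invariant_under_relabeling(self, rng):
        from twotruths.assessment import _min_pairwise_chernoff

        comps = [
            _comp(rng.normal(size=2), np.eye(2) * (1 + k), w=0.25)
            for k in range(4)
        ]
        v1, _ = _min_pairwise_chernoff(comps)
        v2, _ = _min_pairwise_chernoff(comps[::-1])
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_ratio_consistency(self, small_affinity_params):
        res = chernoff_ratio_sbm(
            small_affinity_params, d=2, n=1000, n_graphs=1, seed=0
        )
        assert res.rho == pytest.approx(res.rho_A / res.rho_L)
        assert (res.rho > 1) == (res.rho_A > res.rho_L)


class TestGaussianKL:
    def test_identical_zero(self):
        F = _comp([1.0, 2.0], [[1.0, 0.2], [0.2, 2.0]])
        assert gaussian_kl(F, F) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_one_dimensional(self):
        assert gaussian_kl(_comp([0.0], [[1.0]]), _comp([1.0], [[1.0]])) == (
            pytest.approx(0.5)
        )

    def test_matches_monte_carlo(self, rng):
        A1 = rng.normal(size=(2, 2))
        A2 = rng.normal(size=(2, 2))
        F1 = _comp(rng.normal(size=2), A1 @ A1.T + 0.5 * np.eye(2))
        F2 = _comp(rng.normal(size=2), A2 @ A2.T + 0.5 * np.eye(2))
        closed = gaussian_kl(F1, F2)
        X = rng.multivariate_normal(F1.mu, F1.sigma, size=1_000_000)
        from twotruths.assessment import _mixture_logpdf

        diff = _mixture_logpdf([F1], X) - _mixture_logpdf([F2], X)
        mc, se = diff.mean(), diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(closed - mc) < 3 * se


class TestMixtureKL:
    def test_self_divergence_zero(self):
        P = [_comp([0.0, 0.0], np.eye(2))]
        res = mixture_kl_numeric(P, P, n_samples=20_000, seed=0)
        assert res.value <= 3 * max(res.se, 1e-12)

    def test_single_components_match_closed_form(self, rng):
        F1 = _comp([0.0, 0.0], np.eye(2))
        F2 = _comp([1.0, 0.5], [[2.0, 0.0], [0.0, 1.0]])
        res = mixture_kl_numeric([F1], [F2], n_samples=100_000, seed=1)
        assert abs(res.value - gaussian_kl(F1, F2)) < 3 * res.se

    def test_nonnegative(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            P = [_comp(r.normal(size=2), np.eye(2), w=0.5) for _ in range(2)]
            Q = [_comp(r.normal(size=2), np.eye(2), w=0.5) for _ in range(2)]
            res = mixture_kl_numeric(P, Q, n_samples=10_000, seed=seed)
            assert res.value >= 0.0


class TestBestTwoGrouping:
    def comps_two_pairs(self):
        return [
            _comp([0.0, 0.0], np.eye(2), 0.25),
            _comp([0.1, 0.0], np.eye(2), 0.25),
            _comp([10.0, 0.0], np.eye(2), 0.25),
            _comp([10.1, 0.0], np.eye(2), 0.25),
        ]

    def test_separated_pairs_grouped_together(self):
        res = best_two_grouping(self.comps_two_pairs(), seed=0, n_samples=20_000)
        assert res.best == ((0, 1), (2, 3))

    def test_evaluation_counts(self):
        comps = self.comps_two_pairs()
        ordered = best_two_grouping(comps, mode="ordered-kl", seed=0, n_samples=2_000)
        sym = best_two_grouping(
            comps, mode="symmetrized-kl", seed=0, n_samples=2_000
        )
        assert len(ordered.partitions) == 10
        assert len(sym.partitions) == 7

    def test_matches_high_resolution_oracle(self):
        # square corners, one diagonal pair with inflated variance
        comps = [
            _comp([0.0, 0.0], 9 * np.eye(2), 0.25),
            _comp([10.0, 0.0], np.eye(2), 0.25),
            _comp([0.0, 10.0], np.eye(2), 0.25),
            _comp([10.0, 10.0], 9 * np.eye(2), 0.25),
        ]
        fast = best_two_grouping(comps, seed=3, n_samples=20_000)
        fine = best_two_grouping(comps, seed=4, n_samples=200_000)
        assert fast.best == fine.best

    def test_requires_exactly_four(self):
        with pytest.raises(ValueError):
            best_two_grouping(self.comps_two_pairs()[:3])
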