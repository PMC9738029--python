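import numpy as np
import pytest

from snpsetarch.nsnmf import (
    FactorizationResult, SNPSet, smoothing_matrix, kl_divergence,
    nsnmf_factorize, encode_matrix, extract_snp_sets, run_sweep,
    child_seed, parse_label, sets_to_json, sets_from_json,
)
from snpsetarch.simulate import CohortConfig, PlantedSet, simulate_cohort
from snpsetarch.simulate import score_recovery

from conftest import make_genotypes


def column_gini(W):
    """Mean Gini coefficient of the columns of a nonnegative matrix."""
    out = []
    for j in range(W.shape[1]):
        x = np.sort(W[:, j])
        n = len(x)
        out.append((2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum()))
    return float(np.mean(out))


class TestSmoothing:
    def test_theta_zero_is_identity(self):
        np.testing.assert_array_equal(smoothing_matrix(4, 0.0), np.eye(4))

    def test_theta_one_is_uniform(self):
        S = smoothing_matrix(4, 1.0)
        np.testing.assert_allclose(S, np.full((4, 4), 0.25))

    def test_rows_sum_to_one(self):
        S = smoothing_matrix(5, 0.37)
        np.testing.assert_allclose(S.sum(axis=1), np.ones(5))


class TestFactorize:
    def test_exact_rank2_reconstruction(self, rng):
        W0 = rng.uniform(0.5, 2.0, (30, 2))
        H0 = rng.uniform(0.5, 2.0, (2, 40))
        X = W0 @ H0
        f = nsnmf_factorize(X, k=2, theta=0.0, seed=3, max_iter=5000,
                            tol=1e-12)
        assert f.objective_trace[-1] < 1e-6 * X.sum()

    def test_objective_monotone_non_increasing(self, rng):
        X = rng.uniform(0.0, 3.0, (25, 35))
        for theta in (0.0, 0.5, 0.9):
            f = nsnmf_factorize(X, k=4, theta=theta, seed=1, max_iter=400)
            diffs = np.diff(f.objective_trace)
            assert np.all(diffs <= 1e-9)

    def test_theta_increases_sparsity(self, rng):
        X = rng.uniform(0.5, 3.0, (60, 50))
        f0 = nsnmf_factorize(X, k=4, theta=0.0, seed=7, max_iter=500)
        f9 = nsnmf_factorize(X, k=4, theta=0.9, seed=7, max_iter=500)
        assert column_gini(f9.W) > column_gini(f0.W)

    def test_factors_nonnegative_and_normalized(self, rng):
        X = rng.uniform(0.0, 2.0, (20, 30))
        f = nsnmf_factorize(X, k=3, seed=0, max_iter=200)
        assert np.all(f.W >= 0) and np.all(f.H >= 0)
        np.testing.assert_allclose(f.W.sum(axis=0), np.ones(3), rtol=1e-8)

    def test_zero_rows_get_zero_loadings(self, rng):
        X = rng.uniform(0.5, 2.0, (10, 20))
        X[3] = 0.0
        f = nsnmf_factorize(X, k=2, seed=0, max_iter=100)
        np.testing.assert_allclose(f.W[3], 0.0, atol=1e-12)

    def test_capacity_monotone_divergence(self, rng):
        # divergence at k+1 <= divergence at k (averaged over 5 seeds)
        X = rng.uniform(0.5, 3.0, (30, 40))
        for seed in range(5):
            d = [nsnmf_factorize(X, k=k, theta=0.5, seed=seed,
                                 max_iter=400).objective_trace[-1]
                 for k in (2, 3, 4)]
            assert d[1] <= d[0] * (1 + 1e-6)
            assert d[2] <= d[1] * (1 + 1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="nonnegative"):
            nsnmf_factorize(np.array([[-1.0, 1.0]]), k=2)
        with pytest.raises(ValueError, match="k"):
            nsnmf_factorize(np.ones((4, 4)), k=1)
        with pytest.raises(ValueError, match="theta"):
            nsnmf_factorize(np.ones((4, 4)), k=2, theta=1.5)
        with pytest.raises(ValueError, match="non-finite"):
            nsnmf_factorize(np.array([[np.nan, 1.0]]), k=2)

    def test_frobenius_objective_available(self, rng):
        X = rng.uniform(0.5, 2.0, (15, 20))
        f = nsnmf_factorize(X, k=2, seed=0, max_iter=200,
                            objective="frobenius")
        assert np.all(np.diff(f.objective_trace) <= 1e-9)


class TestEncodeMatrix:
    def test_offset_dosage(self):
        g = make_genotypes([[0, 1, 2]])
        np.testing.assert_array_equal(encode_matrix(g), [[1, 2, 3]])

    def test_risk_dosage_flips_protective(self):
        g = make_genotypes([[0, 1, 2]])
        g.snp_meta["risk_direction"] = ["protective"]
        np.testing.assert_array_equal(
            encode_matrix(g, coding="risk_dosage"), [[3, 2, 1]])

    def test_mode_imputation(self):
        g = make_genotypes([[0, 0, 2]], missing=[[False, True, False]])
        np.testing.assert_array_equal(encode_matrix(g), [[1, 1, 3]])

    def test_unknown_coding(self):
        g = make_genotypes([[0]])
        with pytest.raises(ValueError, match="coding"):
            encode_matrix(g, coding="bogus")


class TestExtractSets:
    def _result(self, W, H, k):
        return FactorizationResult(W=W, H=H, theta=0.5, k=k,
                                   objective_trace=[1.0], seed=0,
                                   converged=True)

    def test_sixty_percent_rule(self, rng):
        W = np.array([[1.0], [0.61], [0.59], [0.0]])
        W = np.hstack([W, W[::-1]])
        H = np.ones((2, 3))
        g = make_genotypes(rng.binomial(2, 0.3, (4, 3)))
        sets = extract_snp_sets(self._result(W, H, 2), g, tau=0.6)
        assert sets[0].snp_ids == g.snp_ids[:2]       # 1.0 and 0.61 pass
        assert sets[1].snp_ids == g.snp_ids[2:][::-1] or \
            set(sets[1].snp_ids) == set(g.snp_ids[2:])

    def test_tau_one_keeps_only_maxima(self, rng):
        W = np.array([[1.0, 0.2], [0.5, 0.9], [0.2, 0.9]])
        H = np.array([[3.0, 1.0], [1.0, 2.0]])
        g = make_genotypes(rng.binomial(2, 0.3, (3, 2)))
        sets = extract_snp_sets(self._result(W, H, 2), g, tau=1.0)
        assert sets[0].snp_ids == [g.snp_ids[0]]
        assert set(sets[1].snp_ids) == set(g.snp_ids[1:])
        assert sets[0].subject_ids == [g.subject_ids[0]]

    def test_row_permutation_invariance(self, rng):
        m, n, k = 20, 15, 3
        W = rng.uniform(0, 1, (m, k))
        H = rng.uniform(0, 1, (k, n))
        g = make_genotypes(rng.binomial(2, 0.3, (m, n)))
        sets = extract_snp_sets(self._result(W, H, k), g)
        perm = rng.permutation(m)
        g_perm = g.subset(snp_idx=perm)
        sets_perm = extract_snp_sets(self._result(W[perm], H, k), g_perm)
        for a, b in zip(sets, sets_perm):
            assert set(a.snp_ids) == set(b.snp_ids)
            assert a.subject_ids == b.subject_ids

    def test_entity_wise_mode_can_drop_factors(self, rng):
        # one dominant factor absorbs every entity's maximum
        W = np.column_stack([np.ones(5), 0.1 * np.ones(5)])
        H = np.vstack([np.ones(4), 0.1 * np.ones(4)])
        g = make_genotypes(rng.binomial(2, 0.3, (5, 4)))
        sets = extract_snp_sets(self._result(W, H, 2), g, mode="entity_wise")
        assert [s.factor_index for s in sets] == [1]

    def test_planted_recovery(self):
        recovered = 0
        for seed in range(10):
            planted = [
                PlantedSet(list(range(0, 12)), list(range(0, 25)), 2, 0.8,
                           "CHD"),
                PlantedSet(list(range(12, 24)), list(range(25, 50)), 2, 0.8,
                           "T2D"),
            ]
            cfg = CohortConfig(n_subjects=120, n_snps_chd=30, n_snps_t2d=30,
                               pattern_counts=(20, 30, 30, 40),
                               planted_sets=planted, maf_range=(0.05, 0.2),
                               missing_rate=0.0, seed=seed)
            g, _, truth = simulate_cohort(cfg)
            f = nsnmf_factorize(encode_matrix(g), k=2, theta=0.5, seed=seed,
                                max_iter=800)
            scores = score_recovery(extract_snp_sets(f, g), truth, g)
            if all(s["snp_jaccard"] >= 0.8 and s["subject_jaccard"] >= 0.8
                   for s in scores):
                recovered += 1
        assert recovered >= 8


class TestLabels:
    def test_label_encoding(self):
        s = SNPSet.from_members(7, 4, ["a"], ["x"])
        assert s.label == "G_7_4"
        assert parse_label("G_7_4") == (7, 4)

    def test_mismatched_label_rejected(self):
        with pytest.raises(ValueError):
            SNPSet("G_2_1", 3, 1, ["a"], ["x"])

    def test_factor_index_bounds(self):
        with pytest.raises(ValueError):
            SNPSet("G_2_3", 2, 3, ["a"], ["x"])

    def test_json_round_trip(self):
        sets = [SNPSet.from_members(2, 1, ["a", "b"], ["x"]),
                SNPSet.from_members(2, 2, ["c"], ["y", "z"])]
        assert sets_from_json(sets_to_json(sets)) == sets


@pytest.fixture(scope="module")
def small_input():
    cfg = CohortConfig(n_subjects=50, n_snps_chd=15, n_snps_t2d=10,
                       pattern_counts=(8, 12, 12, 18), seed=2)
    g, _, _ = simulate_cohort(cfg)
    return encode_matrix(g), g


class TestRunSweep:
    def test_k_max_5_gives_14_sets(self, small_input):
        X, g = small_input
        sets, _ = run_sweep(X, g, k_min=2, k_max=5, max_iter=30)
        assert len(sets) == 2 + 3 + 4 + 5

    def test_k_max_2_labels(self, small_input):
        X, g = small_input
        sets, _ = run_sweep(X, g, k_min=2, k_max=2, max_iter=30)
        assert [s.label for s in sets] == ["G_2_1", "G_2_2"]

    def test_default_k_max_is_sqrt_m(self, small_input):
        X, g = small_input
        sets, results = run_sweep(X, g, max_iter=5)
        assert results[-1].k == int(np.sqrt(X.shape[0]))

    def test_determinism(self, small_input):
        X, g = small_input
        s1, _ = run_sweep(X, g, k_min=2, k_max=4, seed=9, max_iter=50)
        s2, _ = run_sweep(X, g, k_min=2, k_max=4, seed=9, max_iter=50)
        assert s1 == s2

    def test_per_rank_seeds_differ(self):
        assert child_seed(1, 2) != child_seed(1, 3)
        assert child_seed(1, 2) == child_seed(1, 2)

    def test_bad_range_rejected(self, small_input):
        X, g = small_input
        with pytest.raises(ValueError):
            run_sweep(X, g, k_min=1, k_max=3)
        with pytest.raises(ValueError):
            run_sweep(X, g, k_min=4, k_max=3)
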