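import itertools
import math

import numpy as np
import pytest
from scipy import stats

from snpsetarch.prefilter import (
    GwasResult, hwe_exact_p, qc_filter, logistic_gwas, pool_panels,
    compute_pcs,
)

from conftest import make_genotypes


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact HWE P by direct enumeration of heterozygote counts."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab

    def prob(het):
        hom_a = (na - het) // 2
        hom_b = n - het - hom_a
        if hom_a < 0 or hom_b < 0 or (na - het) % 2:
            return 0.0
        return math.exp(
            het * math.log(2) + math.lgamma(n + 1)
            - math.lgamma(het + 1) - math.lgamma(hom_a + 1)
            - math.lgamma(hom_b + 1) + math.lgamma(na + 1)
            + math.lgamma(2 * n - na + 1) - math.lgamma(2 * n + 1))

    probs = {h: prob(h) for h in range(min(na, 2 * n - na) + 1)
             if prob(h) > 0}
    obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


class TestHweExact:
    def test_equilibrium_counts_high_p(self):
        # (AA=25, AB=50, BB=25): the HWE-perfect configuration at nA=nB=100
        p = hwe_exact_p(25, 50, 25)
        assert p > 0.5
        assert p == pytest.approx(hwe_enumeration_oracle(25, 50, 25))

    @pytest.mark.parametrize("counts", [
        (5, 10, 5), (8, 4, 8), (0, 20, 0), (12, 6, 2), (3, 0, 17),
        (10, 10, 10), (1, 1, 1),
    ])
    def test_matches_enumeration(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-10)

    def test_extreme_disequilibrium_low_p(self):
        # all heterozygotes is wildly off equilibrium at large n
        assert hwe_exact_p(0, 100, 0) < 1e-6

    def test_empty_sample(self):
        assert hwe_exact_p(0, 0, 0) == 1.0


class TestQcFilter:
    def test_snp_missing_threshold_closed(self):
        # 6% missing removed; exactly 5% also removed (>= excludes)
        n = 100
        dos = np.tile([0, 1], (3, 50))
        miss = np.zeros((3, n), bool)
        miss[0, :6] = True   # 6%
        miss[1, :5] = True   # 5% boundary
        miss[2, :4] = True   # 4%
        g = make_genotypes(dos, miss)
        out, report = qc_filter(g, hwe_p_min=0.0)
        assert out.snp_ids == ["snp0002"]
        assert report.loc[report.step == "snp_missingness",
                          "snps_removed"].item() == 2

    def test_monomorphic_removed(self):
        dos = np.vstack([np.zeros(50), np.tile([0, 1], 25)])
        g = make_genotypes(dos)
        out, _ = qc_filter(g, hwe_p_min=0.0)
        assert out.snp_ids == ["snp0001"]

    def test_hwe_step_removes(self):
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.5, 200)
        bad = np.ones(200)          # all hets: extreme HWE violation
        g = make_genotypes(np.vstack([good, bad]))
        out, report = qc_filter(g)
        assert out.snp_ids == ["snp0000"]
        assert report.loc[report.step == "hwe", "snps_removed"].item() == 1

    def test_subject_call_rate(self):
        dos = np.tile([0, 1, 2, 1], (40, 10))  # 40 SNPs x 40 subjects
        miss = np.zeros_like(dos, bool)
        miss[:3, 0] = True   # subject 0: 7.5% missing; per-SNP only 2.5%
        g = make_genotypes(dos, miss)
        out, report = qc_filter(g, hwe_p_min=0.0)
        assert out.n_subjects == 39
        assert report.loc[report.step == "subject_call_rate",
                          "subjects_removed"].item() == 1

    def test_subject_permutation_invariance(self, rng):
        dos = rng.binomial(2, 0.3, (20, 60))
        miss = rng.random((20, 60)) < 0.03
        g = make_genotypes(dos, miss)
        perm = rng.permutation(60)
        g_perm = g.subset(subject_idx=perm)
        out1, _ = qc_filter(g)
        out2, _ = qc_filter(g_perm)
        assert out1.snp_ids == out2.snp_ids

    def test_all_removed_raises(self):
        g = make_genotypes(np.zeros((3, 50)))
        with pytest.raises(ValueError, match="all SNPs removed"):
            qc_filter(g)


class TestLogisticGwas:
    def test_null_p_uniform(self, rng):
        # 200 null SNPs at n=500: Wald p should be uniform (KS at alpha=.01)
        n = 500
        dos = rng.binomial(2, 0.3, (200, n))
        y = rng.binomial(1, 0.5, n)
        g = make_genotypes(dos)
        res = logistic_gwas(g, y)
        ps = [r.wald_p for r in res if not r.flagged]
        assert len(ps) == 200
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_dosage_flagged(self):
        g = make_genotypes(np.ones((1, 40)))
        y = np.tile([0, 1], 20)
        res = logistic_gwas(g, y)
        assert res[0].flagged and res[0].wald_p == 1.0

    def test_two_by_two_collapse_matches_odds_ratio(self):
        # dosage 0/1 only, no covariates: beta = log cross-product OR
        #        y=1  y=0
        # d=1     30   10
        # d=0     20   40
        dose = np.array([1] * 40 + [0] * 60)
        y = np.array([1] * 30 + [0] * 10 + [1] * 20 + [0] * 40)
        g = make_genotypes(dose[None, :])
        res = logistic_gwas(g, y)
        assert res[0].beta == pytest.approx(math.log((30 * 40) / (10 * 20)),
                                            rel=1e-6)

    def test_missing_dropped_per_snp(self, rng):
        n = 300
        dos = rng.binomial(2, 0.4, (2, n))
        miss = np.zeros((2, n), bool)
        miss[0, :150] = True
        y = rng.binomial(1, 0.5, n)
        g = make_genotypes(dos, miss)
        res = logistic_gwas(g, y)
        # SNP 0 fit on the complete half only
        g_half = make_genotypes(dos[:1, 150:])
        ref = logistic_gwas(g_half, y[150:])
        assert res[0].beta == pytest.approx(ref[0].beta, rel=1e-8)

    def test_covariate_rescaling_invariance(self, rng):
        n = 400
        dos = rng.binomial(2, 0.3, (3, n))
        cov = rng.normal(size=(n, 2))
        y = rng.binomial(1, 1 / (1 + np.exp(-0.5 * cov[:, 0])), n)
        g = make_genotypes(dos)
        res1 = logistic_gwas(g, y, covariates=cov)
        res2 = logistic_gwas(g, y, covariates=cov * np.array([1000.0, 0.001]))
        for a, b in zip(res1, res2):
            assert a.beta == pytest.approx(b.beta, rel=1e-6)

    def test_non_binary_y_rejected(self):
        g = make_genotypes(np.zeros((1, 10)))
        with pytest.raises(ValueError):
            logistic_gwas(g, np.zeros(10))


def _fake_results(snp_ids, disease, p):
    return [GwasResult(s, 0.1, 0.05, p, disease) for s in snp_ids]


class TestPoolPanels:
    def test_paper_panel_sizes(self, rng):
        dos = rng.binomial(2, 0.3, (250, 30))
        g = make_genotypes(dos)
        ids = g.snp_ids
        chd = _fake_results(ids[:110], "CHD", 1e-6) + \
            _fake_results(ids[110:], "CHD", 0.5)
        t2d = _fake_results(ids[110:193], "T2D", 1e-6) + \
            _fake_results(ids[:110], "T2D", 0.5) + \
            _fake_results(ids[193:], "T2D", 0.9)
        pooled = pool_panels(g, chd, t2d)
        assert pooled.n_snps == 193
        assert (pooled.snp_meta["panel_label"] == "CHD").sum() == 110
        assert (pooled.snp_meta["panel_label"] == "T2D").sum() == 83

    def test_dual_hit_assigned_to_smaller_p(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, (1, 20)))
        sid = g.snp_ids[0]
        pooled = pool_panels(
            g, _fake_results([sid], "CHD", 1e-6),
            _fake_results([sid], "T2D", 1e-5))
        assert pooled.snp_meta.at[0, "panel_label"] == "CHD"
        assert bool(pooled.snp_meta.at[0, "dual_hit"])

    def test_count_identity(self, rng):
        # pooled count = |CHD hits| + |T2D hits| - |dual hits|
        g = make_genotypes(rng.binomial(2, 0.3, (10, 20)))
        ids = g.snp_ids
        chd = _fake_results(ids[:4], "CHD", 1e-6) + \
            _fake_results(ids[4:], "CHD", 0.5)
        t2d = _fake_results(ids[2:7], "T2D", 1e-6) + \
            _fake_results(ids[:2] + ids[7:], "T2D", 0.5)
        pooled = pool_panels(g, chd, t2d)
        assert pooled.n_snps == 4 + 5 - 2

    def test_risk_direction_from_or(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, (2, 20)))
        chd = [GwasResult(g.snp_ids[0], 0.5, 0.1, 1e-6, "CHD"),
               GwasResult(g.snp_ids[1], -0.5, 0.1, 1e-6, "CHD")]
        pooled = pool_panels(g, chd, [])
        assert pooled.snp_meta["risk_direction"].tolist() == \
            ["risk", "protective"]

    def test_empty_pool_raises(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, (5, 20)))
        with pytest.raises(ValueError, match="no SNP"):
            pool_panels(g, _fake_results(g.snp_ids, "CHD", 0.5), [])


class TestComputePcs:
    def test_separates_subpopulations(self, rng):
        # two subpopulations with a frequency offset on every SNP
        n_half, m = 60, 80
        f1 = rng.uniform(0.1, 0.4, m)
        f2 = np.clip(f1 + 0.2, 0, 0.95)
        pop1 = rng.binomial(2, f1[:, None], (m, n_half))
        pop2 = rng.binomial(2, f2[:, None], (m, n_half))
        g = make_genotypes(np.hstack([pop1, pop2]))
        pcs = compute_pcs(g, n_pcs=2)
        labels = np.array([0] * n_half + [1] * n_half)
        r = np.corrcoef(pcs[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_zero_pcs_is_noop(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, (12, 15)))
        assert compute_pcs(g, n_pcs=0).shape == (15, 0)

    def test_duplicated_subjects_identical_coordinates(self, rng):
        dos = rng.binomial(2, 0.3, (30, 20))
        dos[:, 5] = dos[:, 4]
        g = make_genotypes(dos)
        pcs = compute_pcs(g, n_pcs=3)
        np.testing.assert_allclose(pcs[4], pcs[5], atol=1e-10)

    def test_deterministic_sign(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, (30, 25)))
        np.testing.assert_array_equal(compute_pcs(g, 3), compute_pcs(g, 3))

    def test_constant_matrix_raises(self):
        g = make_genotypes(np.ones((12, 12)))
        with pytest.raises(ValueError, match="degenerate"):
            compute_pcs(g, n_pcs=2)
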