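"""Scans, permutation thresholds, mixed models, heritability, transforms."""

import numpy as np
import pytest
import scipy.stats as sps

from crossepi.association import (LOD_SCALE, binary_scan_f2, effective_tests,
                                  liability_transform, lmm_scan,
                                  logistic_mixed_or, permutation_thresholds,
                                  pve_snp, reml_pve)
from crossepi.relatedness import Grm, centered_grm, near_pd


def counts_to_vectors(case_counts, control_counts):
    g = np.concatenate([np.repeat([0, 1, 2], case_counts),
                        np.repeat([0, 1, 2], control_counts)])
    y = np.concatenate([np.ones(sum(case_counts), int),
                        np.zeros(sum(control_counts), int)])
    return g, y


class TestBinaryScan:
    def test_lod_is_lrt_over_2ln10(self, rng):
        g = rng.integers(0, 3, (300, 5))
        y = rng.binomial(1, 0.4, 300)
        res = binary_scan_f2(g, y, fit_logistic=False)
        assert np.allclose(res.table.lod, res.table.lrt / (2 * np.log(10)))
        assert (res.table.lod >= 0).all()

    def test_null_lrt_chi2_2df(self, rng):
        """Under independence the 2-df statistic averages 2."""
        g = rng.integers(0, 3, (600, 4000)).astype(np.int8)
        y = rng.binomial(1, 0.5, 600)
        res = binary_scan_f2(g, y, fit_logistic=False)
        se = 2.0 / np.sqrt(4000)
        assert abs(res.table.lrt.mean() - 2.0) < 3 * se

    def test_allele_table_odds_ratio(self):
        """Case counts (10,20,30) vs controls (30,20,10): allele OR is 4.

        The incidences are exactly logit-linear in allele count here, so the
        additive logistic fit recovers a per-allele OR of 3; the 2x2
        allele-table cross-product (the classical oracle) gives 4.
        """
        g, y = counts_to_vectors((10, 20, 30), (30, 20, 10))
        res = binary_scan_f2(g[:, None], y)
        assert res.table.allele_or[0] == pytest.approx(4.0)
        assert res.table.odds_ratio[0] == pytest.approx(3.0, abs=1e-6)

    def test_monomorphic_marker_flagged(self):
        g = np.zeros((50, 1), dtype=np.int8)
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        res = binary_scan_f2(g, y)
        assert res.table.flagged[0]
        assert res.table.lod[0] == 0.0
        assert res.table.p[0] == 1.0

    def test_non_binary_phenotype_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            binary_scan_f2(rng.integers(0, 3, (10, 2)), np.arange(10))

    def test_missing_individuals_dropped_per_marker(self, rng):
        g = rng.integers(0, 3, (200, 1)).astype(np.int8)
        y = rng.binomial(1, 0.5, 200)
        g_missing = g.copy()
        g_missing[:50] = -1
        full = binary_scan_f2(g[50:], y[50:], fit_logistic=False)
        part = binary_scan_f2(g_missing, y, fit_logistic=False)
        assert part.table.lrt[0] == pytest.approx(full.table.lrt[0])


class TestPermutationThresholds:
    def test_single_marker_matches_chi2_limit(self, rng):
        """One marker: the 5% threshold approaches chi2_2(0.95)/(2 ln 10)."""
        g = rng.integers(0, 3, (2000, 1)).astype(np.int8)
        y = rng.binomial(1, 0.5, 2000)
        thr = permutation_thresholds(g, y, n_perm=2000, alphas=(0.05,), seed=3)
        expected = sps.chi2.ppf(0.95, 2) / LOD_SCALE  # 1.301
        assert thr[0.05] == pytest.approx(expected, abs=0.15)

    def test_alpha_one_gives_minimum(self, rng):
        g = rng.integers(0, 3, (200, 10)).astype(np.int8)
        y = rng.binomial(1, 0.3, 200)
        thr = permutation_thresholds(g, y, n_perm=100, alphas=(1.0, 0.5, 0.05),
                                     seed=1)
        assert thr[1.0] <= thr[0.5] <= thr[0.05]

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_thresholds(rng.integers(0, 3, (20, 2)),
                                   rng.binomial(1, 0.5, 20), n_perm=10)


class TestLmmScan:
    def test_identity_grm_equals_ols(self, rng):
        """With K = I the mixed model collapses to ordinary regression."""
        n, m = 250, 25
        G = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(size=n) + 0.4 * G[:, 3]
        K = Grm(np.eye(n), tuple(map(str, range(n))))
        scan = lmm_scan(G, y, K)
        ols_p = []
        for j in range(m):
            X = np.column_stack([np.ones(n), G[:, j]])
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            rss1 = ((y - X @ b) ** 2).sum()
            rss0 = ((y - y.mean()) ** 2).sum()
            ols_p.append(sps.chi2.sf(n * np.log(rss0 / rss1), 1))
        assert np.allclose(scan.table.p, ols_p, atol=1e-6)

    def test_null_pvalues_uniform(self, f2_cohort, rng):
        """With no genetic variance, scan p-values are uniform."""
        n = 300
        K = near_pd(centered_grm(f2_cohort.genotypes[:n], f2_cohort.ids[:n]))
        G = rng.integers(0, 3, (n, 2000)).astype(float)
        y = rng.binomial(1, 0.3, n).astype(float)
        scan = lmm_scan(G, y, K)
        ks = sps.kstest(scan.table.p, "uniform").statistic
        assert ks < 0.05

    def test_constant_marker_flagged(self, rng):
        n = 50
        G = np.column_stack([np.ones(n), rng.integers(0, 3, n)]).astype(float)
        y = rng.normal(size=n)
        K = Grm(np.eye(n), tuple(map(str, range(n))))
        scan = lmm_scan(G, y, K)
        assert scan.table.flagged[0]
        assert scan.table.p[0] == 1.0


class TestRemlPve:
    def _structured_grm(self, f2_cohort, n):
        K = near_pd(centered_grm(f2_cohort.genotypes[:n], f2_cohort.ids[:n]))
        scaled = K.values / np.mean(np.diag(K.values))
        return Grm(scaled, K.ids)

    def test_recovers_known_pve(self, f2_cohort, rng):
        n, true_pve = 1000, 0.4
        K = self._structured_grm(f2_cohort, n)
        w, U = np.linalg.eigh(K.values)
        g = U @ (np.sqrt(np.maximum(w, 0) * true_pve) * rng.normal(size=n))
        y = g + rng.normal(scale=np.sqrt(1 - true_pve), size=n)
        vc = reml_pve(y, K)
        assert abs(vc.pve - true_pve) < 2 * vc.pve_se

    def test_pure_noise_pve_near_zero(self, f2_cohort, rng):
        n = 500
        K = self._structured_grm(f2_cohort, n)
        vc = reml_pve(rng.normal(size=n), K)
        assert vc.pve < max(2 * vc.pve_se, 0.05)

    def test_variances_non_negative(self, f2_cohort, rng):
        K = self._structured_grm(f2_cohort, 200)
        vc = reml_pve(rng.normal(size=200), K)
        assert vc.v_g >= 0 and vc.v_e >= 0
        assert 0 <= vc.pve <= 1


class TestLiabilityTransform:
    def test_zero_pve(self):
        assert liability_transform(0.0, 0.3, 0.5) == 0.0

    def test_balanced_case_reduces_to_half_pi(self):
        """At P = A = 1/2 the correction factor is exactly pi/2."""
        assert liability_transform(0.10, 0.5, 0.5) == pytest.approx(
            0.10 * np.pi / 2, abs=1e-6)

    def test_rare_disease_ascertained_half(self):
        assert liability_transform(0.10, 0.01, 0.5) == pytest.approx(
            0.0552, abs=2e-4)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            liability_transform(0.1, 0.0, 0.5)
        with pytest.raises(ValueError):
            liability_transform(0.1, 0.5, 1.0)


class TestPveSnp:
    def test_values(self):
        assert pve_snp(0.5, 0.0, 1.0) == 0.0
        assert pve_snp(0.5, 0.2, 1.0) == pytest.approx(0.01)
        # quadratic in beta
        assert pve_snp(0.3, 0.4, 2.0) == pytest.approx(4 * pve_snp(0.3, 0.2, 2.0))

    def test_conventional_factor_two(self):
        assert pve_snp(0.5, 0.2, 1.0, conventional=True) == pytest.approx(0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pve_snp(0.6, 0.1, 1.0)
        with pytest.raises(ValueError):
            pve_snp(0.5, 0.1, 0.0)


class TestEffectiveTests:
    def test_perfect_ld_collapses_to_one(self, rng):
        col = rng.integers(0, 3, 400)
        G = np.tile(col[:, None], (1, 8))
        m_eff, thr = effective_tests(G)
        assert m_eff == pytest.approx(1.0, abs=1e-8)
        assert thr["suggestive"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_markers_approach_m(self, rng):
        G = rng.integers(0, 3, (5000, 40))
        m_eff, _ = effective_tests(G)
        assert abs(m_eff - 40) < 3

    def test_suggestive_threshold_from_meff(self):
        """M_eff = 542 gives a suggestive threshold of 1.8e-3 (2 sig figs)."""
        suggestive = 1.0 / 542
        assert float(f"{suggestive:.1e}") == 1.8e-3

    def test_thresholds_scale(self, rng):
        G = rng.integers(0, 3, (200, 10))
        m_eff, thr = effective_tests(G)
        assert thr["significant"] == pytest.approx(0.05 / m_eff)
        assert thr["suggestive"] == pytest.approx(1.0 / m_eff)


class TestLogisticMixed:
    def test_identity_grm_matches_plain_logistic(self, rng):
        import statsmodels.api as sm
        n = 800
        x = rng.integers(0, 3, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(1.0 - 0.5 * x)))
        K = Grm(np.eye(n), tuple(map(str, range(n))))
        res = logistic_mixed_or(x, y, K)
        glm = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert abs(res.beta - glm.params[1]) < 1e-3

    def test_null_or_near_one(self, rng):
        n = 800
        x = rng.integers(0, 3, n).astype(float)
        y = rng.binomial(1, 0.3, n)
        K = Grm(np.eye(n), tuple(map(str, range(n))))
        res = logistic_mixed_or(x, y, K)
        assert abs(np.log(res.odds_ratio)) < 2 * res.se

    def test_allele_relabeling_inverts_or(self, rng):
        n = 500
        x = rng.integers(0, 3, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(1.0 - 0.4 * x)))
        K = Grm(np.eye(n), tuple(map(str, range(n))))
        r1 = logistic_mixed_or(x, y, K)
        r2 = logistic_mixed_or(2 - x, y, K)
        assert r1.odds_ratio * r2.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20) * 2]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        K = Grm(np.eye(40), tuple(map(str, range(40))))
        res = logistic_mixed_or(x, y, K)
        assert res.flagged
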