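"""The two-locus physiological-epistasis statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossepi.epistasis import (TwoLocusTable, contrast_coefficients,
                                decompose, decompose_incidence,
                                incidence_table, partner_snp, scale_effects)
from crossepi.epistasis import test_effects as run_cell_tests


def brute_force_effects(P):
    """Unweighted least-squares fit of mean + row + column on the 9 cells."""
    rows = []
    for i in range(3):
        for j in range(3):
            r = [1.0, 0, 0, 0, 0]
            if i < 2:
                r[1 + i] = 1.0
            else:
                r[1] = r[2] = -1.0
            if j < 2:
                r[3 + j] = 1.0
            else:
                r[3] = r[4] = -1.0
            rows.append(r)
    A = np.array(rows)
    coef = np.linalg.lstsq(A, P.ravel(), rcond=None)[0]
    return (P.ravel() - A @ coef).reshape(3, 3)


class TestIncidenceTable:
    def test_cell_counts_and_incidence(self, rng):
        g1 = rng.integers(0, 3, 500)
        g2 = rng.integers(0, 3, 500)
        y = rng.binomial(1, 0.25, 500)
        tab = incidence_table(y, g1, g2, defect="ASD", pair=("a", "b"))
        assert tab.n_total.sum() == 500
        assert tab.n_case.sum() == y.sum()
        i, j = 1, 1
        sel = (g1 == i) & (g2 == j)
        assert tab.incidence[i, j] == pytest.approx(y[sel].mean())

    def test_missing_excluded(self, rng):
        g1 = rng.integers(0, 3, 100)
        g2 = rng.integers(0, 3, 100)
        g1[:10] = -1
        y = rng.binomial(1, 0.3, 100)
        tab = incidence_table(y, g1, g2)
        assert tab.n_total.sum() == 90

    def test_degenerate_all_controls(self):
        g = np.repeat(np.arange(3), 30)
        tab = incidence_table(np.zeros(90, int), g, np.tile(np.arange(3), 30))
        assert (tab.incidence == 0).all()
        assert tab.uwa == 0.0

    def test_identical_loci_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            incidence_table([0, 1], [0, 1], [0, 1], pair=("a", "a"))


class TestDecompose:
    def test_additive_construction_null(self, rng):
        r = rng.uniform(0.1, 0.3, 3)
        c = rng.uniform(0.0, 0.2, 3)
        P = r[:, None] + c[None, :]
        _, eff = decompose_incidence(P)
        assert np.allclose(eff, 0.0, atol=1e-12)

    def test_documented_example(self):
        """All cells 0.10 except (BB,BB)=0.19: +0.04 / -0.02 / +0.01 pattern."""
        P = np.full((3, 3), 0.10)
        P[0, 0] = 0.19
        _, eff = decompose_incidence(P)
        assert eff[0, 0] == pytest.approx(0.04, abs=1e-12)
        assert eff[0, 1] == pytest.approx(-0.02, abs=1e-12)
        assert eff[2, 0] == pytest.approx(-0.02, abs=1e-12)
        assert eff[1, 2] == pytest.approx(0.01, abs=1e-12)

    def test_matches_brute_force_least_squares(self, rng):
        """Row/column-means form equals unweighted LS on 1000 random tables."""
        for _ in range(1000):
            P = rng.random((3, 3))
            _, eff = decompose_incidence(P)
            assert np.allclose(eff, brute_force_effects(P), atol=1e-10)

    def test_conservation(self, rng):
        for _ in range(50):
            P = rng.random((3, 3))
            _, eff = decompose_incidence(P)
            assert np.allclose(eff.sum(axis=0), 0, atol=1e-12)
            assert np.allclose(eff.sum(axis=1), 0, atol=1e-12)
            assert abs(eff.sum()) < 1e-12

    @given(st.floats(min_value=-0.5, max_value=0.5))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_location_invariance(self, shift):
        rng = np.random.default_rng(0)
        P = rng.random((3, 3)) * 0.4 + 0.3
        _, e1 = decompose_incidence(P)
        _, e2 = decompose_incidence(P + shift)
        assert np.allclose(e1, e2, atol=1e-12)

    def test_empty_cell_rejected(self):
        tab = TwoLocusTable("d", ("a", "b"),
                            n_case=np.zeros((3, 3), int),
                            n_control=np.array([[5] * 3, [5] * 3, [5, 5, 0]]))
        with pytest.raises(ValueError, match="empty"):
            decompose(tab)


class TestContrast:
    def test_contrast_reproduces_effect(self, rng):
        P = rng.random((3, 3))
        _, eff = decompose_incidence(P)
        for i in range(3):
            for j in range(3):
                lam = contrast_coefficients((i, j))
                assert np.sum(lam * P) == pytest.approx(eff[i, j], abs=1e-12)


class TestTestEffects:
    def _table(self, incidence, n_per_cell=200, defect="d"):
        n_case = np.round(incidence * n_per_cell).astype(int)
        return TwoLocusTable(defect, ("a", "b"), n_case, n_per_cell - n_case)

    def test_additive_table_nothing_significant(self):
        P = np.array([0.1, 0.2, 0.3])[:, None] + np.array([0.0, 0.1, 0.2])
        effects = run_cell_tests(self._table(P), n_pairs_for_defect=1)
        # rounding counts to integers leaves tiny residuals only
        assert all(not e.significant for e in effects)

    def test_bonferroni_threshold_for_one_pair(self):
        """x = 1 pair means nine tests: the cell threshold is 0.05/9."""
        P = np.full((3, 3), 0.10)
        P[0, 0] = 0.35
        effects = {e.cell: e for e in run_cell_tests(self._table(P, 400),
                                                   n_pairs_for_defect=1)}
        e = effects[(0, 0)]
        assert e.significant == (e.p < 0.05 / 9)
        assert e.significant
        # with many pairs the same p no longer clears the corrected threshold
        weak = self._table(np.full((3, 3), 0.10) + np.eye(3) * 0.001, 400)
        assert all(not x.significant
                   for x in run_cell_tests(weak, n_pairs_for_defect=10 ** 6))

    def test_type_one_error_calibrated(self, rng):
        """Independent loci: the arcsine contrast rejects at ~5%."""
        nrep, ncell = 10_000, 200
        cases = rng.binomial(ncell, 0.1, size=(nrep, 3, 3))
        hits = 0
        for k in range(nrep):
            tab = TwoLocusTable("d", ("a", "b"), cases[k], ncell - cases[k])
            if run_cell_tests(tab, 1)[0].p < 0.05:
                hits += 1
        rate = hits / nrep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / nrep)

    def test_effects_conserved_and_scaled(self):
        P = np.full((3, 3), 0.10)
        P[0, 0] = 0.19
        effects = run_cell_tests(self._table(P, 1000), n_pairs_for_defect=1)
        raw = np.array([e.effect for e in effects])
        scaled = np.array([e.scaled_effect for e in effects])
        assert abs(raw.sum()) < 1e-12
        assert abs(scaled.sum()) < 1e-12
        uwa = np.mean(P)
        assert np.allclose(scaled, raw / uwa)

    def test_genotype_classes_attached(self):
        effects = run_cell_tests(self._table(np.full((3, 3), 0.2)), 1)
        classes = [e.genotype_class for e in effects]
        assert classes.count("syn_homozygous") == 2
        assert classes.count("anti_homozygous") == 2
        assert classes.count("double_heterozygous") == 1
        assert classes.count("mixed") == 4


class TestScaleEffects:
    def test_example(self):
        assert scale_effects(np.array([0.04]), 0.11)[0] == pytest.approx(0.3636,
                                                                         abs=1e-4)

    def test_zero_uwa_rejected(self):
        with pytest.raises(ValueError):
            scale_effects(np.array([0.1]), 0.0)


class TestParameterRecovery:
    @pytest.mark.parametrize("delta", [0.05, 0.10, 0.15])
    def test_pair_deviation_recovered(self, delta, sparse_map):
        """Simulated two-locus deviations are recovered within 2 SE."""
        import crossepi as ce
        l1, l2 = sparse_map.ids[2], sparse_map.ids[40]
        dev = np.zeros((3, 3))
        dev[0, 0] = dev[2, 2] = -delta
        dev[0, 2] = dev[2, 0] = delta
        pen = ce.PenetranceSpec({"AVSD": ce.DefectModel(
            baseline=0.2, pair_deviations={(l1, l2): dev})})
        cohort = ce.simulate_cohort(
            ce.CrossDesign(strains=("B", "A"), generations=(("F2", 10_000),)),
            sparse_map, pen, seed=int(delta * 100))
        idx, y = cohort.case_control("AVSD")
        tab = incidence_table(y, cohort.genotypes[idx, sparse_map.index_of(l1)],
                              cohort.genotypes[idx, sparse_map.index_of(l2)],
                              defect="AVSD", pair=(l1, l2))
        truth = ce.true_epistasis_effects(pen, "AVSD", (l1, l2))
        e00 = {e.cell: e for e in run_cell_tests(tab, 1)}[(0, 0)]
        # SE is on the arcsine scale; convert locally to the incidence scale
        p_bar = tab.incidence.mean()
        se_inc = e00.se * 2 * np.sqrt(p_bar * (1 - p_bar))
        assert abs(e00.effect - truth[0, 0]) < 2 * se_inc

    def test_power_monotone_in_delta(self, sparse_map):
        import crossepi as ce
        l1, l2 = sparse_map.ids[2], sparse_map.ids[40]
        tstats = []
        for delta in (0.05, 0.10, 0.15):
            dev = np.zeros((3, 3))
            dev[0, 0] = dev[2, 2] = -delta
            dev[0, 2] = dev[2, 0] = delta
            pen = ce.PenetranceSpec({"AVSD": ce.DefectModel(
                baseline=0.2, pair_deviations={(l1, l2): dev})})
            cohort = ce.simulate_cohort(
                ce.CrossDesign(strains=("B", "A"), generations=(("F2", 10_000),)),
                sparse_map, pen, seed=77)
            idx, y = cohort.case_control("AVSD")
            tab = incidence_table(y,
                                  cohort.genotypes[idx, sparse_map.index_of(l1)],
                                  cohort.genotypes[idx, sparse_map.index_of(l2)],
                                  defect="AVSD", pair=(l1, l2))
            e00 = {e.cell: e for e in run_cell_tests(tab, 1)}[(0, 0)]
            tstats.append(abs(e00.t))
        assert tstats[0] < tstats[1] < tstats[2]


class TestPartnerSnp:
    @pytest.fixture
    def scan(self):
        return pd.DataFrame({
            "marker": ["m1", "m2", "m3", "m4"],
            "chrom": [1, 1, 2, 3],
            "bp": [5_000_000, 12_000_000, 50_000_000, 30_000_000],
            "p": [1e-6, 1e-4, 1e-3, 1e-2],
        })

    def test_runner_up_returned(self, scan):
        assert partner_snp(scan, ["m1"]) == "m3"  # m2 linked within 10 Mb

    def test_exclusion_window(self, scan):
        scan2 = scan.copy()
        scan2.loc[1, "bp"] = 40_000_000  # unlink m2 from m1
        assert partner_snp(scan2, ["m1"]) == "m2"

    def test_no_candidate_signaled(self, scan):
        with pytest.raises(ValueError, match="eligible"):
            partner_snp(scan.iloc[:1], ["m1"])
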