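"""Tests of the cross simulator: meiosis model, cohorts, ground truth, masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossepi.epistasis import decompose_incidence
from crossepi.simulate import (CrossDesign, DefectModel, MarkerMap, Marker,
                               PenetranceSpec, haldane_recomb, mask_genotypes,
                               simulate_cohort, true_epistasis_effects,
                               uniform_map)


class TestHaldane:
    @pytest.mark.parametrize("cm,expected", [
        (0.0, 0.0),
        (50.0, 0.31606),
        (10_000.0, 0.5),
    ])
    def test_map_function_values(self, cm, expected):
        assert haldane_recomb(cm) == pytest.approx(expected, abs=1e-5)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_recomb(-1.0)
        with pytest.raises(ValueError):
            haldane_recomb(float("nan"))

    @given(st.floats(min_value=0, max_value=1e4),
           st.floats(min_value=0, max_value=1e4))
    @settings(deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, d1, d2):
        r1, r2 = haldane_recomb(d1), haldane_recomb(d2)
        assert 0.0 <= r1 < 0.5 or r1 == pytest.approx(0.5, abs=1e-12)
        if d1 < d2:
            assert r1 <= r2


class TestMarkerMap:
    def test_positions_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            MarkerMap((Marker("a", 1, 100, 1.0), Marker("b", 1, 100, 2.0)))

    def test_no_sex_chromosomes(self):
        with pytest.raises(ValueError):
            MarkerMap((Marker("a", 20, 100, 1.0),))

    def test_uniform_map_spacing(self):
        m = uniform_map(21.0, 0.5)
        assert 100 <= len(m) <= 130  # ~120 markers at 19-24 Mb spacing
        bp = m.bp[m.chrom == 1]
        assert np.all(np.diff(bp) == 21_000_000)


class TestSimulateCohort:
    def test_f2_mendelian_frequencies(self, f2_cohort):
        """F2 single-marker genotype frequencies are (1/4, 1/2, 1/4)."""
        g = f2_cohort.genotypes
        n = g.size
        for code, expect in zip((0, 1, 2), (0.25, 0.5, 0.25)):
            freq = (g == code).mean()
            se = np.sqrt(expect * (1 - expect) / n)
            # markers are correlated within an individual; be generous
            assert abs(freq - expect) < max(3 * se, 0.02)

    def test_baseline_incidence_binomial(self, f2_cohort):
        """With no modifier effects, defect risk is pure binomial at baseline."""
        mut = f2_cohort.mutant
        n_mut = int(mut.sum())
        frac = (f2_cohort.phenotype[mut] == "ASD").mean()
        se = np.sqrt(0.137 * 0.863 / n_mut)
        assert abs(frac - 0.137) < 3 * se

    def test_mutant_fraction_mendelian(self, f2_cohort):
        frac = f2_cohort.mutant.mean()
        se = np.sqrt(0.25 / f2_cohort.n)
        assert abs(frac - 0.5) < 3 * se

    def test_only_mutants_affected(self, f2_cohort):
        wild = ~f2_cohort.mutant
        assert (f2_cohort.phenotype[wild] == "normal").all()

    def test_determinism(self, sparse_map, baseline_penetrance):
        design = CrossDesign(strains=("B", "A"), generations=(("F2", 200),))
        c1 = simulate_cohort(design, sparse_map, baseline_penetrance, seed=9)
        c2 = simulate_cohort(design, sparse_map, baseline_penetrance, seed=9)
        assert np.array_equal(c1.genotypes, c2.genotypes)
        assert np.array_equal(c1.phenotype, c2.phenotype)
        assert np.array_equal(c1.mutant, c2.mutant)

    def test_map_expansion_in_advanced_intercross(self, combined_cohort):
        """Adjacent-marker genotype discordance grows from F2 to F10."""
        sl = combined_cohort.marker_map.chromosome_slices()[1]

        def discordance(gen):
            g = combined_cohort.genotypes[combined_cohort.generation == gen, sl]
            return (g[:, :-1] != g[:, 1:]).mean()

        assert discordance("F10") > discordance("F2")

    def test_aic_keeps_heterozygosity(self, combined_cohort):
        """Random (non-sib) mating keeps heterozygosity near 1/2, no inbreeding."""
        for gen in ("F10", "F14"):
            g = combined_cohort.genotypes[combined_cohort.generation == gen]
            het = (g == 1).mean()
            assert 0.42 < het < 0.58

    def test_invalid_penetrance_rejected(self, sparse_map):
        m = sparse_map.ids[0]
        pen = PenetranceSpec({"ASD": DefectModel(
            baseline=0.05, locus_effects={m: [-0.10, 0.0, 0.10]})})
        design = CrossDesign(strains=("B", "A"), generations=(("F2", 100),))
        with pytest.raises(ValueError, match="outside"):
            simulate_cohort(design, sparse_map, pen, seed=1)

    def test_unknown_marker_rejected(self, sparse_map):
        pen = PenetranceSpec({"ASD": DefectModel(
            baseline=0.1, locus_effects={"nope": [0, 0, 0]})})
        design = CrossDesign(strains=("B", "A"), generations=(("F2", 10),))
        with pytest.raises(ValueError, match="not in map"):
            simulate_cohort(design, sparse_map, pen, seed=1)


class TestTrueEpistasisEffects:
    def test_additive_table_has_zero_effects(self, sparse_map):
        m1, m2 = sparse_map.ids[0], sparse_map.ids[5]
        pen = PenetranceSpec({"ASD": DefectModel(
            baseline=0.2,
            locus_effects={m1: [-0.05, 0.0, 0.05], m2: [-0.02, 0.0, 0.02]})})
        eff = true_epistasis_effects(pen, "ASD", (m1, m2))
        assert np.allclose(eff, 0.0, atol=1e-12)

    def test_single_cell_offset_decomposition(self, sparse_map):
        """A lone +d offset spreads as +4d/9, -2d/9 (row/col), +d/9 elsewhere."""
        m1, m2 = sparse_map.ids[0], sparse_map.ids[5]
        d = 0.09
        dev = np.zeros((3, 3)); dev[0, 0] = d
        pen = PenetranceSpec({"ASD": DefectModel(
            baseline=0.2, pair_deviations={(m1, m2): dev})})
        eff = true_epistasis_effects(pen, "ASD", (m1, m2))
        assert eff[0, 0] == pytest.approx(4 * d / 9, abs=1e-12)
        assert eff[0, 1] == pytest.approx(-2 * d / 9, abs=1e-12)
        assert eff[1, 0] == pytest.approx(-2 * d / 9, abs=1e-12)
        assert eff[1, 1] == pytest.approx(d / 9, abs=1e-12)

    def test_round_trip_with_decompose(self, sparse_map, rng):
        """Ground truth equals decompose applied to the exact penetrance table."""
        m1, m2 = sparse_map.ids[1], sparse_map.ids[7]
        dev = rng.uniform(-0.02, 0.02, (3, 3))
        pen = PenetranceSpec({"ASD": DefectModel(
            baseline=0.2, pair_deviations={(m1, m2): dev})})
        eff = true_epistasis_effects(pen, "ASD", (m1, m2))
        table = 0.2 + dev
        _, expected = decompose_incidence(table)
        assert np.allclose(eff, expected, atol=1e-12)
        assert np.allclose(eff.sum(axis=0), 0, atol=1e-12)
        assert np.allclose(eff.sum(axis=1), 0, atol=1e-12)

    def test_unknown_defect_rejected(self, sparse_map, baseline_penetrance):
        with pytest.raises(KeyError):
            true_epistasis_effects(baseline_penetrance, "nope",
                                   (sparse_map.ids[0], sparse_map.ids[1]))


class TestMaskGenotypes:
    def test_rate_zero_is_identity(self, f2_cohort):
        masked, idx = mask_genotypes(f2_cohort, 0.0, seed=1)
        assert np.array_equal(masked.genotypes, f2_cohort.genotypes)
        assert len(idx) == 0

    def test_masking_rate_binomial(self, f2_cohort):
        masked, idx = mask_genotypes(f2_cohort, 0.05, seed=2)
        n_calls = f2_cohort.genotypes.size
        frac = len(idx) / n_calls
        se = np.sqrt(0.05 * 0.95 / n_calls)
        assert abs(frac - 0.05) < 3 * se

    def test_truth_fully_recoverable(self, f2_cohort):
        masked, idx = mask_genotypes(f2_cohort, 0.05, seed=3)
        assert (masked.genotypes[idx.rows, idx.cols] == -1).all()
        assert np.array_equal(f2_cohort.genotypes[idx.rows, idx.cols],
                              idx.true_codes)

    def test_invalid_rate_rejected(self, f2_cohort):
        with pytest.raises(ValueError):
            mask_genotypes(f2_cohort, 1.0, seed=1)
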