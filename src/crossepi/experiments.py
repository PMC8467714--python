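"""Reference experiments that recompute the methodological benchmark numbers.

Each experiment regenerates its inputs from the simulator under the study
conditions (cross design, marker spacing, incidence) and measures one
quantity: permutation LOD thresholds of the F2 binary-trait scan, HMM
imputation confidence on a sparse panel, and the Mantel similarity of the
combined-cohort GRM before and after the nearest-PD adjustment.  They are
used by the acceptance script and the test suite.
"""

from __future__ import annotations

import numpy as np

from . import association, impute, relatedness
from .simulate import (CrossDesign, DefectModel, PenetranceSpec,
                       simulate_cohort, uniform_map)

__all__ = [
    "permutation_threshold_experiment",
    "imputation_confidence_experiment",
    "grm_similarity_experiment",
]

_NEUTRAL = PenetranceSpec({"defect": DefectModel(baseline=0.10)})


def permutation_threshold_experiment(seed: int, n: int = 1500,
                                     n_perm: int = 1000,
                                     alphas=(0.05, 0.2),
                                     incidence: float = 0.10) -> dict:
    """Genome-wide permutation LOD thresholds on a null F2.

    Simulates an F2 of ``n`` newborns genotyped on the sparse panel
    (19 autosomes, ~21 Mb marker spacing, 1 cM = 2 Mb), draws a binary
    phenotype independent of genotype at the given incidence, and returns
    the empirical (1 - alpha) quantiles of the genome-wide maximum LOD of
    the 2-df binary-trait scan over ``n_perm`` phenotype permutations.
    """
    rng = np.random.default_rng(seed)
    marker_map = uniform_map(21.0, 0.5)
    design = CrossDesign(strains=("B", "A"), generations=(("F2", n),))
    cohort = simulate_cohort(design, marker_map, _NEUTRAL, seed=seed)
    y = rng.binomial(1, incidence, cohort.n)
    thresholds = association.permutation_thresholds(
        cohort.genotypes, y, n_perm=n_perm, alphas=alphas, seed=seed + 1)
    return {"thresholds": thresholds, "n": n, "n_markers": len(marker_map),
            "n_perm": n_perm}


def imputation_confidence_experiment(seed: int, n: int = 1000,
                                     grid_cm: float = 1.5,
                                     error_rate: float = 0.005) -> dict:
    """Imputation confidence at a dense grid of untyped F2 positions.

    Simulates an F2 genotyped on the sparse ~21 Mb panel and imputes a
    grid of untyped positions every ``grid_cm`` cM (3 Mb at 1 cM = 2 Mb)
    between panel markers with the three-state forward-backward HMM.
    Returns the percentage of target posteriors whose maximum exceeds 0.70
    and the percentage below 0.50.
    """
    marker_map = uniform_map(21.0, 0.5)
    design = CrossDesign(strains=("B", "A"), generations=(("F2", n),))
    cohort = simulate_cohort(design, marker_map, _NEUTRAL, seed=seed)
    params = impute.HmmParams(error_rate)
    confidences = []
    for chrom, sl in marker_map.chromosome_slices().items():
        cm = marker_map.cm[sl]
        grid = np.arange(cm.min(), cm.max(), grid_cm)
        grid = np.setdiff1d(np.round(grid, 9), np.round(cm, 9))
        if grid.size == 0:
            continue
        result = impute.impute_cohort_chromosome(
            cohort.genotypes[:, sl], cm, "F2", params, target_cm=grid)
        confidences.append(result.confidence.ravel())
    conf = np.concatenate(confidences)
    summary = impute.confidence_summary(conf, thresholds=(0.70, 0.50))
    return {
        "pct_above_70": 100.0 * summary["fraction_above_0.7"],
        "pct_below_50": 100.0 * summary["fraction_below_0.5"],
        "n_targets": int(conf.size),
        "n": n,
    }


def grm_similarity_experiment(seed: int, n_per_generation: int = 500) -> dict:
    """Mantel similarity of the combined GRM before/after the PD adjustment.

    Simulates a combined F2 + F10 + F14 cohort on the dense ~3 Mb panel,
    builds the centered GRM, applies the F2 block override (0.5
    off-diagonal, 1 diagonal), adjusts to the nearest positive definite
    matrix, and reports 100 x the Pearson correlation of the
    lower-triangle off-diagonal entries of the pre- and post-adjustment
    matrices.
    """
    marker_map = uniform_map(3.0, 0.5)
    design = CrossDesign(
        strains=("B", "F"),
        generations=(("F2", n_per_generation), ("F10", n_per_generation),
                     ("F14", n_per_generation)))
    cohort = simulate_cohort(design, marker_map, _NEUTRAL, seed=seed)
    grm = relatedness.centered_grm(cohort.genotypes, cohort.ids)
    f2_ids = [i for i, g in zip(cohort.ids, cohort.generation) if g == "F2"]
    overridden = relatedness.override_f2_block(grm, f2_ids)
    adjusted = relatedness.near_pd(overridden)
    r, _ = relatedness.mantel_similarity(overridden, adjusted)
    return {
        "mantel_pct": 100.0 * r,
        "n": cohort.n,
        "n_markers": len(marker_map),
        "min_eig_before": overridden.min_eigenvalue(),
        "min_eig_after": adjusted.min_eigenvalue(),
    }
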