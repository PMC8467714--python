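"""Physiological epistasis: higher-order effects at two-locus genotypes.

The central statistic of the package.  For a pair of loci, each of the
nine two-locus genotype classes has an observed defect incidence among
mutant carriers.  Under the null model of independently acting loci the
expected incidence of cell (i, j) is the unweighted main-effects fit

    expected_ij = rbar_i + cbar_j - m

where rbar_i and cbar_j are the unweighted row/column means of the 3x3
incidence table and m its unweighted grand mean.  The epistatic effect at
a cell is observed - expected; positive effects raise defect risk,
negative effects lower it.  Effects sum to zero over every row, every
column, and the whole table, so their magnitudes redistribute risk rather
than change the average.

Significance testing is done on the arcsine square-root scale, where a
binomial proportion estimated from n individuals has approximate variance
1/(4n) regardless of its value.  The effect at a cell is a fixed linear
contrast of the nine transformed incidences (coefficient 4/9 at the cell,
-2/9 for cells sharing its row or column, +1/9 elsewhere), giving an
exact standard error under independence of cells.  For comparison across
defects with different incidences, effects are divided by the unweighted
average incidence (UWA) over the nine cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coadaptation import classify

__all__ = [
    "TwoLocusTable",
    "EpistasisEffect",
    "incidence_table",
    "decompose",
    "decompose_incidence",
    "contrast_coefficients",
    "test_effects",
    "scale_effects",
    "partner_snp",
]


@dataclass(frozen=True)
class TwoLocusTable:
    """Case/control counts over the nine genotypes of a locus pair."""

    defect: str
    pair: tuple[str, str]
    n_case: np.ndarray     # (3, 3) int
    n_control: np.ndarray  # (3, 3) int
    population_incidence: float = np.nan

    def __post_init__(self):
        nc = np.asarray(self.n_case, dtype=int)
        nk = np.asarray(self.n_control, dtype=int)
        if nc.shape != (3, 3) or nk.shape != (3, 3):
            raise ValueError("count tables must be 3x3")
        if (nc < 0).any() or (nk < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "n_case", nc)
        object.__setattr__(self, "n_control", nk)

    @property
    def n_total(self) -> np.ndarray:
        return self.n_case + self.n_control

    @property
    def incidence(self) -> np.ndarray:
        """Per-cell incidence; NaN for empty cells."""
        tot = self.n_total.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            inc = np.where(tot > 0, self.n_case / tot, np.nan)
        return inc

    @property
    def uwa(self) -> float:
        """Unweighted average incidence over the nine cells."""
        return float(np.mean(self.incidence))

    @property
    def has_empty_cells(self) -> bool:
        return bool((self.n_total == 0).any())


@dataclass(frozen=True)
class EpistasisEffect:
    """Observed-minus-expected deviation at one two-locus genotype cell."""

    defect: str
    pair: tuple[str, str]
    cell: tuple[int, int]
    n_case: int
    n_total: int
    observed: float
    expected: float
    effect: float
    se: float
    t: float
    p: float
    significant: bool
    scaled_effect: float
    genotype_class: str
    testable: bool = True


def incidence_table(y: Sequence[int], g1: Sequence[int], g2: Sequence[int],
                    defect: str = "", pair: tuple[str, str] = ("locus1", "locus2"),
                    ) -> TwoLocusTable:
    """Tabulate case/control counts over the nine two-locus genotypes.

    ``y`` is the binary phenotype (1 = defect, 0 = normal control); ``g1``
    and ``g2`` are the genotype codes at the two loci with -1 for missing.
    Individuals missing either genotype are excluded.
    """
    if pair[0] == pair[1]:
        raise ValueError("the two loci of a pair must be distinct")
    y = np.asarray(y, dtype=int)
    g1 = np.asarray(g1, dtype=int)
    g2 = np.asarray(g2, dtype=int)
    if not (len(y) == len(g1) == len(g2)):
        raise ValueError("y, g1, g2 must have equal length")
    ok = (g1 >= 0) & (g2 >= 0)
    y, g1, g2 = y[ok], g1[ok], g2[ok]
    n_case = np.zeros((3, 3), dtype=int)
    n_ctrl = np.zeros((3, 3), dtype=int)
    np.add.at(n_case, (g1[y == 1], g2[y == 1]), 1)
    np.add.at(n_ctrl, (g1[y == 0], g2[y == 0]), 1)
    pop_inc = float(y.mean()) if len(y) else np.nan
    return TwoLocusTable(defect, tuple(pair), n_case, n_ctrl, pop_inc)


def decompose_incidence(incidence: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted main-effects decomposition of a 3x3 incidence table.

    Returns ``(expected, effects)`` where ``expected`` is the additive
    (independent loci) fit and ``effects = incidence - expected``.  This is
    the unweighted least-squares fit of mean + row + column, so effect rows
    and columns each sum to zero.
    """
    p = np.asarray(incidence, dtype=float)
    if p.shape != (3, 3):
        raise ValueError("incidence table must be 3x3")
    if np.isnan(p).any():
        raise ValueError("incidence table has undefined (empty) cells")
    grand = p.mean()
    rows = p.mean(axis=1)
    cols = p.mean(axis=0)
    expected = rows[:, None] + cols[None, :] - grand
    return expected, p - expected


def decompose(table: TwoLocusTable) -> tuple[np.ndarray, np.ndarray]:
    """Expected incidences and epistatic effects for a two-locus table."""
    if table.has_empty_cells:
        empty = [tuple(c) for c in np.argwhere(table.n_total == 0)]
        raise ValueError(
            f"pair {table.pair} ({table.defect}): empty genotype cells {empty}; "
            "cannot decompose")
    return decompose_incidence(table.incidence)


def contrast_coefficients(cell: tuple[int, int]) -> np.ndarray:
    """Contrast over the nine cells whose value is the effect at ``cell``.

    4/9 at the cell itself, -2/9 for cells sharing exactly its row or
    column, +1/9 elsewhere.  Applying it to the incidence table reproduces
    ``decompose``'s effect at that cell; applying it to arcsine-transformed
    incidences gives the variance-stabilized test statistic's numerator.
    """
    i, j = cell
    lam = np.full((3, 3), 1.0 / 9.0)
    lam[i, :] = -2.0 / 9.0
    lam[:, j] = -2.0 / 9.0
    lam[i, j] = 4.0 / 9.0
    return lam


def test_effects(table: TwoLocusTable, n_pairs_for_defect: int,
                 alpha: float = 0.05) -> list[EpistasisEffect]:
    """Estimate and test the nine epistatic effects of a locus pair.

    Incidences are arcsine square-root transformed; each cell's effect is
    the fixed linear contrast of the transformed incidences, with variance
    sum(lambda^2 / (4 n)) over cells.  Two-tailed tests use the normal
    reference; the significance threshold is Bonferroni corrected for the
    9 * n_pairs_for_defect two-locus genotypes tested per defect.
    """
    if n_pairs_for_defect < 1:
        raise ValueError("n_pairs_for_defect must be >= 1")
    expected, effects = decompose(table)
    inc = table.incidence
    n = table.n_total.astype(float)
    theta = np.arcsin(np.sqrt(inc))
    var_theta = 1.0 / (4.0 * n)
    uwa = table.uwa
    if uwa <= 0:
        raise ValueError("UWA is zero; scaled effects undefined")
    threshold = alpha / (9.0 * n_pairs_for_defect)

    out: list[EpistasisEffect] = []
    for i in range(3):
        for j in range(3):
            lam = contrast_coefficients((i, j))
            contrast = float(np.sum(lam * theta))
            se = float(np.sqrt(np.sum(lam ** 2 * var_theta)))
            t = contrast / se
            p = float(2.0 * sps.norm.sf(abs(t)))
            out.append(EpistasisEffect(
                defect=table.defect, pair=table.pair, cell=(i, j),
                n_case=int(table.n_case[i, j]), n_total=int(n[i, j]),
                observed=float(inc[i, j]), expected=float(expected[i, j]),
                effect=float(effects[i, j]), se=se, t=float(t), p=p,
                significant=bool(p < threshold),
                scaled_effect=float(effects[i, j] / uwa),
                genotype_class=classify(i, j)))
    return out


def scale_effects(effects: np.ndarray, uwa: float) -> np.ndarray:
    """Divide raw effects by the unweighted average incidence."""
    if uwa <= 0:
        raise ValueError("UWA must be positive to scale effects")
    return np.asarray(effects, dtype=float) / uwa


def effects_frame(effects: Sequence[EpistasisEffect]) -> pd.DataFrame:
    """Flatten a list of effects into the per-pair report table."""
    return pd.DataFrame([{
        "defect": e.defect, "locus1": e.pair[0], "locus2": e.pair[1],
        "g1": e.cell[0], "g2": e.cell[1], "n_case": e.n_case,
        "n_total": e.n_total, "observed": e.observed, "expected": e.expected,
        "effect": e.effect, "scaled_effect": e.scaled_effect, "se": e.se,
        "t": e.t, "p": e.p, "significant": e.significant,
        "genotype_class": e.genotype_class} for e in effects])


def partner_snp(scan: pd.DataFrame, existing_loci: Sequence[str],
                window_bp: int = 10_000_000) -> str:
    """Pick the next most significant marker as an interaction partner.

    When a defect has only one mapped locus, pairwise analysis needs a
    second; the fallback is the most significant scan marker that is not
    one of, and not within ``window_bp`` on the same chromosome of, the
    existing loci.  ``scan`` must have columns marker, chrom, bp, p.
    """
    if scan.empty:
        raise ValueError("scan is empty")
    existing = set(existing_loci)
    keep = scan[~scan["marker"].isin(existing)].copy()
    anchors = scan[scan["marker"].isin(existing)]
    for _, a in anchors.iterrows():
        linked = (keep["chrom"] == a["chrom"]) & \
                 (np.abs(keep["bp"] - a["bp"]) < window_bp)
        keep = keep[~linked]
    keep = keep[np.isfinite(keep["p"])]
    if keep.empty:
        raise ValueError("no eligible partner marker outside the exclusion window")
    return str(keep.loc[keep["p"].idxmin(), "marker"])
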