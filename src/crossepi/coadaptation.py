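"""Strain-origin classification of two-locus genotypes and coadaptation tests.

Two interacting loci in a cross of inbred strains B and X define nine
two-locus genotypes.  Classifying them by parental origin —
syn-homozygous (both loci homozygous for the same strain), anti-homozygous
(homozygous for opposite strains), double heterozygous, or mixed — lets us
ask whether epistatic deviations that lower risk concentrate in
syn-homozygous configurations, the signature of genetic coadaptation.
"""

from __future__ import annotations

from typing import Iterable, TYPE_CHECKING

import numpy as np
import pandas as pd

from .stats import prop_ztest

if TYPE_CHECKING:  # pragma: no cover
    from .epistasis import EpistasisEffect

SYN = "syn_homozygous"
ANTI = "anti_homozygous"
DOUBLE_HET = "double_heterozygous"
MIXED = "mixed"

CLASSES = (SYN, ANTI, DOUBLE_HET, MIXED)

#: genotype cells by class: 2 syn, 2 anti, 1 double het, 4 mixed
SYN_CELLS = ((0, 0), (2, 2))
ANTI_CELLS = ((0, 2), (2, 0))


def classify(g1: int, g2: int) -> str:
    """Classify a two-locus genotype (codes 0=BB, 1=het, 2=XX) by strain origin."""
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise ValueError(f"genotype codes must be in {{0,1,2}}, got ({g1}, {g2})")
    hom1, hom2 = g1 != 1, g2 != 1
    if hom1 and hom2:
        return SYN if g1 == g2 else ANTI
    if not hom1 and not hom2:
        return DOUBLE_HET
    return MIXED


def protective_fractions(effects: Iterable["EpistasisEffect"]) -> pd.DataFrame:
    """Per-class fraction of significant epistatic effects that are protective.

    "Protective" means a negative effect (the two-locus genotype lowers
    defect risk relative to the independent-loci expectation).  Each class
    fraction is tested against 0.5 with a two-sided one-sample z-test;
    classes with no significant effects are flagged with NaN statistics.
    """
    effects = [e for e in effects if e.significant]
    rows = []
    for cls in CLASSES:
        sub = [e for e in effects if e.genotype_class == cls]
        n = len(sub)
        k = sum(1 for e in sub if e.effect < 0)
        if n > 0:
            frac = k / n
            z, p = prop_ztest(k, n, p0=0.5)
        else:
            frac, z, p = np.nan, np.nan, np.nan
        rows.append({"genotype_class": cls, "n_significant": n,
                     "n_protective": k, "fraction_protective": frac,
                     "z_vs_half": z, "p_vs_half": p})
    return pd.DataFrame(rows)


def class_comparisons(effects: Iterable["EpistasisEffect"]) -> pd.DataFrame:
    """Pairwise two-sample z-tests of protective fractions between classes."""
    summary = protective_fractions(effects).set_index("genotype_class")
    rows = []
    for i, c1 in enumerate(CLASSES):
        for c2 in CLASSES[i + 1:]:
            n1 = int(summary.loc[c1, "n_significant"])
            n2 = int(summary.loc[c2, "n_significant"])
            if n1 == 0 or n2 == 0:
                z, p = np.nan, np.nan
            else:
                z, p = prop_ztest(int(summary.loc[c1, "n_protective"]), n1,
                                  int(summary.loc[c2, "n_protective"]), n2)
            rows.append({"class_1": c1, "class_2": c2, "z": z, "p": p})
    return pd.DataFrame(rows)


def _pair_effect_grid(effects: list["EpistasisEffect"]) -> dict:
    grid = {}
    for e in effects:
        grid[e.cell] = e
    return grid


def congruence_tests(effects: Iterable["EpistasisEffect"]) -> pd.DataFrame:
    """Sign congruence between syn- and anti-homozygous cells of a pair.

    For every locus pair with all nine cells available, two kinds of anchor
    are considered: a significantly protective syn-homozygous cell and a
    significantly deleterious anti-homozygous cell.  For each anchor the
    report gives the proportion of pairs where the companion cells carry
    the congruent sign:

    - protective syn anchor -> other syn cell also protective
    - protective syn anchor -> the two anti cells deleterious
    - deleterious anti anchor -> other anti cell also deleterious
    - deleterious anti anchor -> the two syn cells protective

    Denominators count locus pairs (an anchor cell is counted once per
    pair), and each proportion is tested against 0.5 with a two-sided
    z-test.
    """
    by_pair: dict = {}
    for e in effects:
        by_pair.setdefault((e.defect, e.pair), []).append(e)

    counters = {
        "syn_protective_vs_other_syn": [0, 0],
        "syn_protective_vs_anti_deleterious": [0, 0],
        "anti_deleterious_vs_other_anti": [0, 0],
        "anti_deleterious_vs_syn_protective": [0, 0],
    }

    for pair_effects in by_pair.values():
        grid = _pair_effect_grid(pair_effects)
        if len(grid) < 9:
            continue
        # syn anchors: significantly protective syn cells
        for cell, other in ((SYN_CELLS[0], SYN_CELLS[1]),
                            (SYN_CELLS[1], SYN_CELLS[0])):
            anchor = grid[cell]
            if anchor.significant and anchor.effect < 0:
                counters["syn_protective_vs_other_syn"][1] += 1
                if grid[other].effect < 0:
                    counters["syn_protective_vs_other_syn"][0] += 1
                counters["syn_protective_vs_anti_deleterious"][1] += 1
                if all(grid[a].effect > 0 for a in ANTI_CELLS):
                    counters["syn_protective_vs_anti_deleterious"][0] += 1
        # anti anchors: significantly deleterious anti cells
        for cell, other in ((ANTI_CELLS[0], ANTI_CELLS[1]),
                            (ANTI_CELLS[1], ANTI_CELLS[0])):
            anchor = grid[cell]
            if anchor.significant and anchor.effect > 0:
                counters["anti_deleterious_vs_other_anti"][1] += 1
                if grid[other].effect > 0:
                    counters["anti_deleterious_vs_other_anti"][0] += 1
                counters["anti_deleterious_vs_syn_protective"][1] += 1
                if all(grid[s].effect < 0 for s in SYN_CELLS):
                    counters["anti_deleterious_vs_syn_protective"][0] += 1

    rows = []
    for relation, (k, n) in counters.items():
        if n > 0:
            prop = k / n
            z, p = prop_ztest(k, n, p0=0.5)
        else:
            prop, z, p = np.nan, np.nan, np.nan
        rows.append({"relation": relation, "n_anchors": n,
                     "n_congruent": k, "proportion": prop, "z": z, "p": p})
    return pd.DataFrame(rows)
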