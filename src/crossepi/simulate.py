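"""Simulation of F2 and advanced-intercross cohorts with binary defect phenotypes.

The generator emulates crosses of two inbred mouse strains (a reference
strain B and a second strain X, e.g. A/J or FVB/N) segregating a
heterozygous mutation whose carriers are at risk of congenital heart
defects.  F2 individuals are the union of two recombinant F1 gametes;
advanced-intercross (AIC) generations arise by continued random non-sib
mating from the F2 onward, which expands the genetic map.  Meiosis follows
the Haldane (no crossover interference) map function.

Each mutant carrier's defect is drawn from penetrances defined on the
probability scale: a per-defect baseline, additive single-locus offsets,
and two-locus deviation matrices.  Because penetrance is additive on the
probability scale, the ground-truth epistatic effect of a configured pair
deviation equals its unweighted main-effects residual exactly, which makes
estimator-recovery tests sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .epistasis import decompose_incidence

__all__ = [
    "MOUSE_AUTOSOME_MB",
    "Marker",
    "MarkerMap",
    "uniform_map",
    "CrossDesign",
    "DefectModel",
    "PenetranceSpec",
    "Cohort",
    "MaskIndex",
    "haldane_recomb",
    "simulate_cohort",
    "true_epistasis_effects",
    "mask_genotypes",
]

#: Approximate physical lengths (Mb) of the 19 mouse autosomes (GRCm38).
MOUSE_AUTOSOME_MB: dict[int, float] = {
    1: 195.5, 2: 182.1, 3: 160.0, 4: 156.5, 5: 151.8, 6: 149.7, 7: 145.4,
    8: 129.4, 9: 124.6, 10: 130.7, 11: 122.1, 12: 120.1, 13: 120.4,
    14: 124.9, 15: 104.0, 16: 98.2, 17: 95.0, 18: 90.7, 19: 61.4,
}

MISSING = -1
VALID_GENERATIONS = ("F2", "F10", "F14")


def haldane_recomb(distance_cm: float) -> float:
    """Recombination fraction from map distance via the Haldane function.

    r = (1 - exp(-2 d)) / 2 with d in Morgans; no crossover interference.
    """
    d = float(distance_cm)
    if not np.isfinite(d) or d < 0:
        raise ValueError(f"map distance must be finite and non-negative, got {distance_cm}")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass(frozen=True)
class Marker:
    id: str
    chrom: int
    bp: int
    cm: float


@dataclass(frozen=True)
class MarkerMap:
    """Ordered autosomal marker map with both physical and genetic positions."""

    markers: tuple[Marker, ...]

    def __post_init__(self):
        markers = tuple(self.markers)
        if not markers:
            raise ValueError("marker map is empty")
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")
        last: dict[int, Marker] = {}
        for m in markers:
            if not 1 <= m.chrom <= 19:
                raise ValueError(f"chromosome must be an autosome 1-19, got {m.chrom}")
            if m.bp < 1 or m.cm < 0:
                raise ValueError(f"invalid position for marker {m.id}")
            if m.chrom in last:
                prev = last[m.chrom]
                if m.bp <= prev.bp or m.cm <= prev.cm:
                    raise ValueError(
                        f"positions must be strictly increasing within chr {m.chrom} "
                        f"({prev.id} -> {m.id})")
            last[m.chrom] = m
        object.__setattr__(self, "markers", markers)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def chrom(self) -> np.ndarray:
        return np.array([m.chrom for m in self.markers])

    @property
    def bp(self) -> np.ndarray:
        return np.array([m.bp for m in self.markers])

    @property
    def cm(self) -> np.ndarray:
        return np.array([m.cm for m in self.markers], dtype=float)

    def index_of(self, marker_id: str) -> int:
        try:
            return self.ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in map") from None

    def chromosome_slices(self) -> dict[int, slice]:
        """Contiguous index slice of each chromosome (map is chromosome-sorted)."""
        chrom = self.chrom
        out: dict[int, slice] = {}
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            out[int(c)] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def adjacent_recomb(self, expansion: float = 1.0) -> np.ndarray:
        """Recombination fraction between adjacent markers; 0.5 across chromosomes."""
        cm = self.cm
        chrom = self.chrom
        r = np.empty(len(cm) - 1)
        for k in range(len(cm) - 1):
            if chrom[k + 1] != chrom[k]:
                r[k] = 0.5
            else:
                r[k] = haldane_recomb((cm[k + 1] - cm[k]) * expansion)
        return r


def uniform_map(spacing_mb: float = 21.0, cm_per_mb: float = 0.5,
                prefix: str = "m") -> MarkerMap:
    """Evenly spaced genome-wide panel over the 19 mouse autosomes.

    ``spacing_mb`` about 21 gives a sparse F2-style panel (~115 markers);
    about 3 gives a dense combined panel (~815 markers).  The genetic map
    is linear in physical position at ``cm_per_mb``.
    """
    markers = []
    for c in range(1, 20):
        length = MOUSE_AUTOSOME_MB[c]
        pos = spacing_mb
        k = 0
        while pos < length:
            bp = int(round(pos * 1e6))
            markers.append(Marker(f"{prefix}{c}_{k}", c, bp, pos * cm_per_mb))
            pos += spacing_mb
            k += 1
    return MarkerMap(tuple(markers))


@dataclass(frozen=True)
class CrossDesign:
    """A two-strain cross: which generations to sample and how many mutants."""

    strains: tuple[str, str] = ("B", "X")
    generations: tuple[tuple[str, int], ...] = (("F2", 3000),)
    mutant_fraction: float = 0.5
    name: str = ""
    aic_census_pairs: int = 100  # breeding pairs per AIC generation

    def __post_init__(self):
        labels = [g for g, _ in self.generations]
        if len(set(labels)) != len(labels):
            raise ValueError("generation labels must be unique")
        for g, n in self.generations:
            if g not in VALID_GENERATIONS:
                raise ValueError(f"generation label must be one of {VALID_GENERATIONS}")
            if n <= 0:
                raise ValueError("n_individuals must be positive")
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("mutant_fraction must be in [0, 1]")
        if self.aic_census_pairs < 2:
            raise ValueError("need at least 2 breeding pairs")


@dataclass(frozen=True)
class DefectModel:
    """Penetrance model for one defect type.

    ``baseline`` is the penetrance of a mutant with no modifier effects;
    ``locus_effects[marker]`` is a length-3 probability offset indexed by
    genotype (BB, het, XX); ``pair_deviations[(m1, m2)]`` is a 3x3 offset
    over the two-locus genotypes — the ground-truth higher-order effect.
    """

    baseline: float
    locus_effects: Mapping[str, Sequence[float]] = field(default_factory=dict)
    pair_deviations: Mapping[tuple[str, str], Sequence[Sequence[float]]] = \
        field(default_factory=dict)


@dataclass(frozen=True)
class PenetranceSpec:
    """Ordered per-defect penetrance models; order fixes assignment priority."""

    defects: Mapping[str, DefectModel]

    def marker_ids(self) -> set[str]:
        out: set[str] = set()
        for model in self.defects.values():
            out.update(model.locus_effects)
            for a, b in model.pair_deviations:
                out.update((a, b))
        return out

    def penetrance_matrix(self, genotypes: np.ndarray,
                          marker_map: MarkerMap) -> np.ndarray:
        """Per-individual, per-defect penetrance implied by the genotypes.

        Raises if any realized penetrance leaves [0, 1] or if the per-row
        sum exceeds 1 (the defects are disjoint outcomes).
        """
        n = genotypes.shape[0]
        pens = np.empty((n, len(self.defects)))
        for d, (name, model) in enumerate(self.defects.items()):
            p = np.full(n, model.baseline, dtype=float)
            for marker, offsets in model.locus_effects.items():
                g = genotypes[:, marker_map.index_of(marker)]
                p += np.asarray(offsets, dtype=float)[g]
            for (m1, m2), dev in model.pair_deviations.items():
                g1 = genotypes[:, marker_map.index_of(m1)]
                g2 = genotypes[:, marker_map.index_of(m2)]
                p += np.asarray(dev, dtype=float)[g1, g2]
            bad = (p < 0) | (p > 1)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"defect {name!r}: realized penetrance {p[i]:.4f} outside "
                    f"[0, 1] for genotype row {i}: {genotypes[i].tolist()}")
            pens[:, d] = p
        total = pens.sum(axis=1)
        if (total > 1.0 + 1e-12).any():
            i = int(np.argmax(total))
            raise ValueError(
                f"summed penetrance {total[i]:.4f} exceeds 1 for genotype row {i}")
        return pens


@dataclass
class Cohort:
    """Simulated individuals with strain-origin genotypes and defect phenotypes."""

    ids: list[str]
    cross: str
    generation: np.ndarray          # (n,) str labels
    mutant: np.ndarray              # (n,) bool
    genotypes: np.ndarray           # (n, m) int8; 0=BB, 1=het, 2=XX, -1 missing
    phenotype: np.ndarray           # (n,) str: defect label or "normal"
    marker_map: MarkerMap

    def __post_init__(self):
        codes = np.unique(self.genotypes)
        if not np.isin(codes, [MISSING, 0, 1, 2]).all():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")
        defects = self.phenotype != "normal"
        if (defects & ~self.mutant).any():
            raise ValueError("only mutant individuals may carry a defect")

    @property
    def n(self) -> int:
        return len(self.ids)

    def defect_labels(self) -> list[str]:
        return sorted(set(self.phenotype) - {"normal"})

    def case_control(self, defect: str) -> tuple[np.ndarray, np.ndarray]:
        """Indices and binary phenotype for one defect vs shared normal controls.

        Cases are mutants with the given defect; controls are normal
        mutants.  Mutants with a different defect are excluded, matching a
        design where every defect is analyzed against the same controls.
        """
        mask = self.mutant & ((self.phenotype == defect) | (self.phenotype == "normal"))
        idx = np.flatnonzero(mask)
        y = (self.phenotype[idx] == defect).astype(int)
        return idx, y


@dataclass(frozen=True)
class MaskIndex:
    """Bookkeeping for genotypes hidden by mask_genotypes."""

    rows: np.ndarray
    cols: np.ndarray
    true_codes: np.ndarray

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# meiosis

def _random_walk_haplotypes(n: int, r: np.ndarray, rng: np.random.Generator
                            ) -> np.ndarray:
    """Haplotypes as strain-origin mosaics from a Markov walk along markers.

    Origin at the first marker is Bernoulli(1/2); between adjacent markers
    the origin switches with the interval's recombination fraction (0.5 at
    chromosome boundaries, making chromosomes independent).
    """
    m = len(r) + 1
    flips = np.empty((n, m), dtype=bool)
    flips[:, 0] = rng.random(n) < 0.5
    flips[:, 1:] = rng.random((n, m - 1)) < r
    # cumulative xor: origin changes at every True flip
    return np.logical_xor.accumulate(flips, axis=1).astype(np.uint8)


def _gametes(h1: np.ndarray, h2: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per row from parental haplotype pairs via Haldane meiosis."""
    choice = _random_walk_haplotypes(h1.shape[0], r, rng).astype(bool)
    return np.where(choice, h2, h1)


def _next_generation(h1: np.ndarray, h2: np.ndarray, parent_key: np.ndarray,
                     n_off: int, r: np.ndarray, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random non-sib mating: offspring haplotypes and their parent keys.

    ``parent_key`` identifies each individual's parental pair so that full
    sibs can be rejected as mates.
    """
    n_pop = h1.shape[0]
    mothers = rng.integers(0, n_pop, size=n_off)
    fathers = rng.integers(0, n_pop, size=n_off)
    bad = (mothers == fathers) | (parent_key[mothers] == parent_key[fathers])
    while bad.any():
        fathers[bad] = rng.integers(0, n_pop, size=int(bad.sum()))
        bad = (mothers == fathers) | (parent_key[mothers] == parent_key[fathers])
    g_m = _gametes(h1[mothers], h2[mothers], r, rng)
    g_f = _gametes(h1[fathers], h2[fathers], r, rng)
    key = mothers.astype(np.int64) * n_pop + fathers
    return g_m, g_f, key


def _simulate_f2_haplotypes(n: int, r: np.ndarray, rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    # F1 parents are heterozygous everywhere, so an F1 gamete is itself a
    # strain-origin random walk.
    return (_random_walk_haplotypes(n, r, rng),
            _random_walk_haplotypes(n, r, rng))


def simulate_cohort(design: CrossDesign, marker_map: MarkerMap,
                    penetrance: PenetranceSpec, seed: int) -> Cohort:
    """Simulate a cohort for every generation requested by the design.

    F2 individuals are unions of independent F1 gametes.  For F10/F14, a
    breeding line of ``2 * aic_census_pairs`` individuals is propagated by
    random non-sib mating from the F2; cohort members of generation Ft are
    offspring of random non-sib pairs of the F(t-1) census.  Mutant status
    is Bernoulli(mutant_fraction); a mutant's defect is drawn from its
    genotype-determined penetrances by a single uniform and cumulative
    thresholds in the spec's defect order, so each defect's marginal
    probability equals its realized penetrance and at most one defect is
    assigned.
    """
    unknown = penetrance.marker_ids() - set(marker_map.ids)
    if unknown:
        raise ValueError(f"penetrance references markers not in map: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    r = marker_map.adjacent_recomb()
    wanted = dict(design.generations)
    max_gen = max(int(g[1:]) for g in wanted)

    blocks: list[tuple[str, np.ndarray]] = []
    if "F2" in wanted:
        h1, h2 = _simulate_f2_haplotypes(wanted["F2"], r, rng)
        blocks.append(("F2", (h1 + h2).astype(np.int8)))

    if max_gen > 2:
        census = 2 * design.aic_census_pairs
        h1, h2 = _simulate_f2_haplotypes(census, r, rng)
        key = np.arange(census, dtype=np.int64)  # F2 sibs share an F1 pair; treat
        # census F2s as unrelated founders for mating purposes (they come from
        # many F1 pairs in practice)
        for t in range(3, max_gen + 1):
            label = f"F{t}"
            if label in wanted:
                g_m, g_f, _ = _next_generation(h1, h2, key, wanted[label], r, rng)
                blocks.append((label, (g_m + g_f).astype(np.int8)))
            h1, h2, key = _next_generation(h1, h2, key, census, r, rng)

    order = {g: i for i, (g, _) in enumerate(design.generations)}
    blocks.sort(key=lambda b: order[b[0]])
    genotypes = np.concatenate([b[1] for b in blocks], axis=0)
    generation = np.concatenate([np.full(b[1].shape[0], b[0]) for b in blocks])
    n = genotypes.shape[0]

    mutant = rng.random(n) < design.mutant_fraction
    phenotype = np.full(n, "normal", dtype=object)
    if mutant.any():
        pens = penetrance.penetrance_matrix(genotypes[mutant], marker_map)
        cum = np.cumsum(pens, axis=1)
        u = rng.random(mutant.sum())
        # first defect whose cumulative threshold exceeds u; none -> normal
        hit = (u[:, None] < cum).argmax(axis=1)
        assigned = u < cum[:, -1]
        labels = np.array(list(penetrance.defects), dtype=object)
        pheno_mut = np.where(assigned, labels[hit], "normal")
        phenotype[np.flatnonzero(mutant)] = pheno_mut

    prefix = design.name or "x".join(design.strains[::-1])
    ids = [f"{prefix}-{g}-{i:05d}" for i, g in enumerate(generation)]
    return Cohort(ids=ids, cross=prefix, generation=generation, mutant=mutant,
                  genotypes=genotypes, phenotype=np.asarray(phenotype, dtype=object),
                  marker_map=marker_map)


def true_epistasis_effects(penetrance: PenetranceSpec, defect: str,
                           pair: tuple[str, str]) -> np.ndarray:
    """Ground-truth epistatic effects implied by a penetrance spec.

    Builds the exact 3x3 penetrance table of the pair (baseline plus both
    single-locus offsets plus the pair deviation) and returns its
    unweighted main-effects residual — the same decomposition the
    estimator applies to observed incidences, so recovery tests compare
    like with like.  Effects from other loci shift all nine cells equally
    in expectation and are removed by the decomposition.
    """
    if defect not in penetrance.defects:
        raise KeyError(f"unknown defect {defect!r}")
    model = penetrance.defects[defect]
    m1, m2 = pair
    table = np.full((3, 3), model.baseline, dtype=float)
    if m1 in model.locus_effects:
        table += np.asarray(model.locus_effects[m1], dtype=float)[:, None]
    if m2 in model.locus_effects:
        table += np.asarray(model.locus_effects[m2], dtype=float)[None, :]
    if (m1, m2) in model.pair_deviations:
        table += np.asarray(model.pair_deviations[(m1, m2)], dtype=float)
    elif (m2, m1) in model.pair_deviations:
        table += np.asarray(model.pair_deviations[(m2, m1)], dtype=float).T
    _, effects = decompose_incidence(table)
    return effects


def mask_genotypes(cohort: Cohort, rate: float, seed: int
                   ) -> tuple[Cohort, MaskIndex]:
    """Hide observed genotypes independently at the given rate.

    Returns a new cohort with masked entries set to the missing sentinel
    and an index recording the hidden truth for later imputation scoring.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("mask rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    geno = cohort.genotypes.copy()
    observed = geno != MISSING
    hide = observed & (rng.random(geno.shape) < rate)
    rows, cols = np.nonzero(hide)
    truth = geno[rows, cols].copy()
    geno[rows, cols] = MISSING
    masked = Cohort(ids=list(cohort.ids), cross=cohort.cross,
                    generation=cohort.generation.copy(), mutant=cohort.mutant.copy(),
                    genotypes=geno, phenotype=cohort.phenotype.copy(),
                    marker_map=cohort.marker_map)
    return masked, MaskIndex(rows=rows, cols=cols, true_codes=truth)
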