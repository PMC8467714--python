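"""End-to-end orchestration: simulate -> QC -> impute -> GRM -> scan ->
epistasis -> coadaptation -> severity report.

Every stage writes its inputs and outputs as plain-text artifacts under the
run directory and registers them in a manifest, so any stage can be re-run
from its recorded inputs.  All randomness derives from the single run seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, coadaptation, epistasis, impute, io, relatedness
from .simulate import (Cohort, CrossDesign, DefectModel, MarkerMap,
                       PenetranceSpec, mask_genotypes, simulate_cohort,
                       uniform_map)
from .stats import kendall_partial

logger = logging.getLogger("crossepi")

__all__ = [
    "CrossConfig",
    "RunConfig",
    "SeverityReport",
    "default_config",
    "load_config",
    "run_end_to_end",
    "severity_correlation",
]

DEFAULT_SEVERITY = {"ASD": 1, "mVSD": 2, "muVSD": 2, "AVSD": 3}


@dataclass
class CrossConfig:
    """One strain cross: generations to simulate and its marker panel."""

    name: str
    strains: tuple[str, str]
    generations: tuple[tuple[str, int], ...]
    map_spacing_mb: float
    cm_per_mb: float = 0.5

    def design(self) -> CrossDesign:
        return CrossDesign(strains=tuple(self.strains),
                           generations=tuple((g, int(n)) for g, n in self.generations),
                           name=self.name)

    def marker_map(self) -> MarkerMap:
        return uniform_map(self.map_spacing_mb, self.cm_per_mb,
                           prefix=f"{self.name}_c")


@dataclass
class RunConfig:
    seed: int
    outdir: str
    crosses: list[CrossConfig]
    penetrance: dict[str, PenetranceSpec]  # keyed by cross name
    severity: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SEVERITY))
    qc_max_missing: float = 0.10
    mask_rate: float = 0.03
    error_rate: float = 0.005
    n_perm: int = 300
    alphas: tuple[float, float] = (0.05, 0.2)
    max_pairs_per_defect: int = 6
    locus_window_bp: int = 10_000_000


def _penetrance_from_dict(d: dict) -> PenetranceSpec:
    defects = {}
    for name, spec in d.items():
        pair_devs = {}
        for key, mat in spec.get("pair_deviations", {}).items():
            pair = tuple(key.split(",")) if isinstance(key, str) else tuple(key)
            pair_devs[pair] = np.asarray(mat, dtype=float)
        defects[name] = DefectModel(
            baseline=float(spec["baseline"]),
            locus_effects={k: np.asarray(v, dtype=float)
                           for k, v in spec.get("locus_effects", {}).items()},
            pair_deviations=pair_devs)
    return PenetranceSpec(defects=defects)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    crosses = [CrossConfig(name=c["name"], strains=tuple(c["strains"]),
                           generations=tuple((g["label"], int(g["n"]))
                                             for g in c["generations"]),
                           map_spacing_mb=float(c["map_spacing_mb"]),
                           cm_per_mb=float(c.get("cm_per_mb", 0.5)))
               for c in raw["crosses"]]
    penetrance = {name: _penetrance_from_dict(block)
                  for name, block in raw["penetrance"].items()}
    return RunConfig(
        seed=int(raw["seed"]), outdir=str(raw.get("outdir", "crossepi_run")),
        crosses=crosses, penetrance=penetrance,
        severity={k: int(v) for k, v in raw.get("severity", DEFAULT_SEVERITY).items()},
        qc_max_missing=float(raw.get("qc_max_missing", 0.10)),
        mask_rate=float(raw.get("mask_rate", 0.03)),
        error_rate=float(raw.get("error_rate", 0.005)),
        n_perm=int(raw.get("n_perm", 300)),
        alphas=tuple(raw.get("alphas", (0.05, 0.2))),
        max_pairs_per_defect=int(raw.get("max_pairs_per_defect", 6)),
        locus_window_bp=int(raw.get("locus_window_bp", 10_000_000)))


def default_config(outdir: str = "crossepi_run", seed: int = 1,
                   scale: float = 1.0) -> RunConfig:
    """Demonstration configuration with a known genetic architecture.

    Two crosses mirror the intended study conditions: a sparse-panel AxB
    style F2 and a denser-panel FxB style F2 + F10 + F14 combined cohort.
    Four defect types follow the incidence ordering ASD > membranous VSD >
    muscular VSD > AVSD (about 30% of mutants affected in total), with
    single-locus effects for every defect and two-locus deviations whose
    magnitude grows with defect severity; AVSD deviations are protective in
    syn-homozygous and deleterious in anti-homozygous configurations.
    ``scale`` multiplies cohort sizes (use < 1 for quick smoke runs).
    """
    sparse = uniform_map(21.0, 0.5, prefix="AxB_c")
    dense = uniform_map(7.0, 0.5, prefix="FxB_c")

    def mid_marker(mmap: MarkerMap, chrom: int) -> str:
        idx = [i for i, m in enumerate(mmap.markers) if m.chrom == chrom]
        return mmap.markers[idx[len(idx) // 2]].id

    def arch(mmap: MarkerMap) -> dict:
        l_asd1, l_asd2 = mid_marker(mmap, 3), mid_marker(mmap, 4)
        l_vsd1, l_vsd2 = mid_marker(mmap, 8), mid_marker(mmap, 6)
        l_avsd1, l_avsd2 = mid_marker(mmap, 5), mid_marker(mmap, 16)
        syn_anti = lambda d: [[-d, 0.0, d], [0.0, 0.0, 0.0], [d, 0.0, -d]]
        return {
            "ASD": {"baseline": 0.13,
                    "locus_effects": {l_asd1: [-0.02, 0.0, 0.02],
                                      l_asd2: [-0.015, 0.0, 0.015]},
                    "pair_deviations": {f"{l_asd1},{l_asd2}": syn_anti(0.012)}},
            "mVSD": {"baseline": 0.075,
                     "locus_effects": {l_vsd1: [-0.02, 0.0, 0.02],
                                       l_vsd2: [-0.015, 0.0, 0.015]},
                     "pair_deviations": {f"{l_vsd1},{l_vsd2}": syn_anti(0.022)}},
            "muVSD": {"baseline": 0.05,
                      "locus_effects": {l_vsd2: [-0.015, 0.0, 0.015],
                                        l_asd2: [-0.01, 0.0, 0.01]},
                      "pair_deviations": {f"{l_vsd2},{l_asd2}": syn_anti(0.018)}},
            "AVSD": {"baseline": 0.045,
                     "locus_effects": {l_avsd1: [-0.01, 0.0, 0.01],
                                       l_avsd2: [-0.005, 0.0, 0.005]},
                     "pair_deviations": {f"{l_avsd1},{l_avsd2}": syn_anti(0.028)}},
        }

    # one architecture instantiated per cross on that cross's own panel
    penetrance = {"AxB": _penetrance_from_dict(arch(sparse)),
                  "FxB": _penetrance_from_dict(arch(dense))}

    s = scale
    crosses = [
        CrossConfig(name="AxB", strains=("B", "A"),
                    generations=(("F2", max(200, int(3000 * s))),),
                    map_spacing_mb=21.0),
        CrossConfig(name="FxB", strains=("B", "F"),
                    generations=(("F2", max(200, int(3000 * s))),
                                 ("F10", max(100, int(1200 * s))),
                                 ("F14", max(100, int(1200 * s)))),
                    map_spacing_mb=7.0),
    ]
    return RunConfig(seed=seed, outdir=outdir, crosses=crosses,
                     penetrance=penetrance)


def recovery_config(outdir: str = "crossepi_recovery", seed: int = 1,
                    n_per_cross: int = 24_000) -> RunConfig:
    """Configuration for the directional-recovery experiment.

    Two F2 crosses with the four-defect architecture whose two-locus
    deviations grow with defect severity: scaled deviations (relative to
    each defect's unweighted average incidence) are about 0.09 (ASD), 0.32
    (membranous VSD), 0.40 (muscular VSD) and 0.55 (AVSD), protective in
    syn-homozygous and deleterious in anti-homozygous configurations.
    Cohort sizes come from an a priori power calculation for the arcsine
    contrast test at F2 genotype frequencies: with ``n_per_cross`` newborns
    (half of them mutant carriers), the VSD and AVSD deviations are
    detectable at the Bonferroni threshold with good power while the small
    ASD deviations mostly are not — mirroring a severity-graded
    architecture.  Both crosses are genotyped on the dense ~3 Mb panel so
    the selected scan peak sits close to the true locus (a marker more
    than ~10 Mb away attenuates the measured deviation), and F2-only
    designs keep the experiment inexpensive because no mixed-model algebra
    is required.
    """
    def arch(mmap: MarkerMap) -> PenetranceSpec:
        def mid(chrom: int) -> str:
            idx = [i for i, m in enumerate(mmap.markers) if m.chrom == chrom]
            return mmap.markers[idx[len(idx) // 2]].id
        syn_anti = lambda d: [[-d, 0.0, d], [0.0, 0.0, 0.0], [d, 0.0, -d]]
        spec = {
            "ASD": {"baseline": 0.13,
                    "locus_effects": {mid(3): [-0.02, 0.0, 0.02],
                                      mid(4): [-0.015, 0.0, 0.015]},
                    "pair_deviations": {f"{mid(3)},{mid(4)}": syn_anti(0.012)}},
            "mVSD": {"baseline": 0.075,
                     "locus_effects": {mid(8): [-0.02, 0.0, 0.02],
                                       mid(6): [-0.015, 0.0, 0.015]},
                     "pair_deviations": {f"{mid(8)},{mid(6)}": syn_anti(0.024)}},
            "muVSD": {"baseline": 0.05,
                      "locus_effects": {mid(11): [-0.015, 0.0, 0.015],
                                        mid(14): [-0.01, 0.0, 0.01]},
                      "pair_deviations": {f"{mid(11)},{mid(14)}": syn_anti(0.020)}},
            "AVSD": {"baseline": 0.04,
                     "locus_effects": {mid(5): [-0.008, 0.0, 0.02],
                                       mid(16): [-0.004, 0.0, 0.012]},
                     "pair_deviations": {f"{mid(5)},{mid(16)}": syn_anti(0.027)}},
        }
        return _penetrance_from_dict(spec)

    map_a = uniform_map(3.0, 0.5, prefix="AxB_c")
    map_f = uniform_map(3.0, 0.5, prefix="FxB_c")
    crosses = [
        CrossConfig(name="AxB", strains=("B", "A"),
                    generations=(("F2", n_per_cross),), map_spacing_mb=3.0),
        CrossConfig(name="FxB", strains=("B", "F"),
                    generations=(("F2", n_per_cross),), map_spacing_mb=3.0),
    ]
    return RunConfig(seed=seed, outdir=outdir, crosses=crosses,
                     penetrance={"AxB": arch(map_a), "FxB": arch(map_f)},
                     n_perm=200)


@dataclass
class SeverityReport:
    """Cross-defect summary linking incidence and effect sizes to severity."""

    defect_table: pd.DataFrame
    effects: pd.DataFrame
    correlations: dict
    class_summary: pd.DataFrame
    congruence: pd.DataFrame


def severity_correlation(effects: pd.DataFrame, defect_table: pd.DataFrame,
                         severity: dict[str, int]) -> dict:
    """Partial Kendall correlations of incidence and effect size with severity.

    Incidence vs severity uses the per-defect-per-cross incidences with the
    cross label and case count as covariates (when they vary).  Effect size
    vs severity uses the absolute scaled effects of significant epistatic
    deviations, controlling for the observed incidence at the two-locus
    genotype.  Severity ranks are configuration, not inference.
    """
    out: dict = {}
    dt = defect_table.dropna(subset=["incidence"])
    if dt["defect"].nunique() >= 3 and len(dt) >= 4:
        sev = dt["defect"].map(severity).astype(float)
        # control for the cross; the analyzed sample size is a deterministic
        # function of incidence in simulated cohorts (shared controls plus
        # all cases), so conditioning on it would remove the signal by
        # construction rather than remove confounding
        covs = []
        if dt["cross"].nunique() > 1:
            covs.append(pd.factorize(dt["cross"])[0].astype(float))
        try:
            pc = kendall_partial(dt["incidence"].to_numpy(), sev.to_numpy(), covs)
            out["incidence_vs_severity"] = {"tau": pc.tau, "p": pc.p, "n": pc.n}
        except ValueError as exc:
            out["incidence_vs_severity"] = {"error": str(exc)}
    else:
        out["incidence_vs_severity"] = {"error": "fewer than 3 defects with estimates"}

    sig = effects[effects["significant"]].copy()
    if len(sig) >= 4 and sig["defect"].map(severity).nunique() >= 2:
        x = sig["scaled_effect"].abs().to_numpy()
        sev = sig["defect"].map(severity).astype(float).to_numpy()
        covs = [sig["observed"].to_numpy()]
        try:
            pc = kendall_partial(x, sev, covs)
            out["effect_vs_severity"] = {"tau": pc.tau, "p": pc.p, "n": pc.n}
        except ValueError as exc:
            out["effect_vs_severity"] = {"error": str(exc)}
    else:
        out["effect_vs_severity"] = {
            "error": "too few significant effects spanning distinct severities"}
    return out


def _select_loci(scan: pd.DataFrame, threshold_p: float | None,
                 threshold_lod: float | None, window_bp: int,
                 max_loci: int = 4) -> list[str]:
    """Pick the peak marker of each chromosome that clears the threshold.

    A sparse panel cannot resolve multiple QTLs on one chromosome, and
    shoulder markers of a single peak would otherwise be double counted as
    distinct loci, so selection keeps at most one marker per chromosome.
    """
    df = scan.copy()
    if threshold_lod is not None:
        df = df[df["lod"] >= threshold_lod].sort_values("lod", ascending=False)
    else:
        df = df[df["p"] <= threshold_p].sort_values("p")
    chosen: list[tuple[str, int]] = []
    for _, row in df.iterrows():
        if all(row["chrom"] != c for _, c in chosen):
            chosen.append((row["marker"], row["chrom"]))
        if len(chosen) >= max_loci:
            break
    return [m for m, _ in chosen]


def _impute_cohort(cohort: Cohort, error_rate: float) -> tuple[Cohort, dict]:
    """Fill missing genotypes with HMM hard calls, per generation per chromosome."""
    geno = cohort.genotypes.copy()
    params = impute.HmmParams(error_rate)
    confidences = []
    slices = cohort.marker_map.chromosome_slices()
    for gen in np.unique(cohort.generation):
        rows = np.flatnonzero(cohort.generation == gen)
        for sl in slices.values():
            block = geno[np.ix_(rows, range(sl.start, sl.stop))]
            if not (block == -1).any():
                continue
            result = impute.impute_cohort_chromosome(
                block, cohort.marker_map.cm[sl], gen, params,
                allow_unobserved=True)
            miss = block == -1
            block[miss] = result.calls[miss]
            geno[np.ix_(rows, range(sl.start, sl.stop))] = block
            confidences.append(result.confidence[miss])
    if confidences:
        conf = np.concatenate(confidences)
        summary = impute.confidence_summary(conf, thresholds=(0.70, 0.50))
    else:
        summary = {"n": 0}
    filled = Cohort(ids=list(cohort.ids), cross=cohort.cross,
                    generation=cohort.generation, mutant=cohort.mutant,
                    genotypes=geno, phenotype=cohort.phenotype,
                    marker_map=cohort.marker_map)
    return filled, summary


def run_end_to_end(config: RunConfig) -> SeverityReport:
    """Run the whole pipeline and write all stage artifacts.

    Each defect is analyzed as cases against the cross's shared normal
    mutant controls.  Returns the severity report; artifacts land under
    ``config.outdir`` with a manifest.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": []}
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.crosses) * 4)
    seed_iter = iter(int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds)

    def register(path: Path):
        manifest["artifacts"].append(str(path.relative_to(outdir)))

    all_effects: list[epistasis.EpistasisEffect] = []
    defect_rows = []

    for cross_cfg in config.crosses:
        cname = cross_cfg.name
        cdir = outdir / cname
        cdir.mkdir(exist_ok=True)
        t0 = time.time()
        marker_map = cross_cfg.marker_map()
        cohort = simulate_cohort(cross_cfg.design(), marker_map,
                                 config.penetrance[cname], next(seed_iter))
        logger.info("%s: simulated %d individuals (%d mutants)", cname,
                    cohort.n, int(cohort.mutant.sum()))
        io.write_marker_map(marker_map, cdir / "markers.tsv")
        io.write_phenotypes(io.phenotype_frame(cohort), cdir / "phenotypes.tsv")
        register(cdir / "markers.tsv"); register(cdir / "phenotypes.tsv")

        if config.mask_rate > 0:
            cohort, mask = mask_genotypes(cohort, config.mask_rate, next(seed_iter))
            logger.info("%s: masked %d genotype calls", cname, len(mask))
        else:
            next(seed_iter)

        gtable = io.GenotypeTable(ids=list(cohort.ids),
                                  markers=marker_map.ids,
                                  codes=cohort.genotypes)
        gtable, qc_report = io.qc_filter_markers(gtable, config.qc_max_missing)
        qc_report.to_csv(cdir / "qc_report.tsv", sep="\t", index=False)
        register(cdir / "qc_report.tsv")
        keep_idx = [marker_map.index_of(m) for m in gtable.markers]
        marker_map = MarkerMap(tuple(marker_map.markers[i] for i in keep_idx))
        cohort.genotypes = gtable.codes
        cohort.marker_map = marker_map

        cohort, imp_summary = _impute_cohort(cohort, config.error_rate)
        (cdir / "imputation_summary.json").write_text(json.dumps(imp_summary, indent=2))
        register(cdir / "imputation_summary.json")
        io.write_genotypes(io.GenotypeTable(ids=list(cohort.ids),
                                            markers=marker_map.ids,
                                            codes=cohort.genotypes),
                           cdir / "genotypes_imputed.tsv")
        register(cdir / "genotypes_imputed.tsv")

        multi_generation = len(cross_cfg.generations) > 1
        mutants = np.flatnonzero(cohort.mutant)

        grm = None
        if multi_generation:
            g = relatedness.centered_grm(cohort.genotypes[mutants],
                                         [cohort.ids[i] for i in mutants])
            f2_ids = [cohort.ids[i] for i in mutants
                      if cohort.generation[i] == "F2"]
            g = relatedness.override_f2_block(g, f2_ids)
            g_pd = relatedness.near_pd(g)
            mantel, _ = relatedness.mantel_similarity(g, g_pd)
            grm = g_pd
            (cdir / "grm_report.json").write_text(json.dumps({
                "n": g.n, "mantel_similarity_pct": 100 * mantel,
                "min_eig_before": g.min_eigenvalue(),
                "min_eig_after": g_pd.min_eigenvalue()}, indent=2))
            register(cdir / "grm_report.json")
            logger.info("%s: GRM adjusted (Mantel %.2f%%)", cname, 100 * mantel)

        m_eff, meff_thresholds = association.effective_tests(
            cohort.genotypes[mutants]) if multi_generation else (None, None)

        for d_index, defect in enumerate(config.penetrance[cname].defects):
            idx, y = cohort.case_control(defect)
            n_cases = int(y.sum())
            incidence = float((cohort.phenotype[mutants] == defect).mean())
            geno_cc = cohort.genotypes[idx]
            if n_cases < 10:
                logger.warning("%s/%s: too few cases (%d); skipped", cname,
                               defect, n_cases)
                continue

            if multi_generation:
                sub = grm.values[np.ix_(
                    [list(grm.ids).index(cohort.ids[i]) for i in idx],
                    [list(grm.ids).index(cohort.ids[i]) for i in idx])]
                grm_cc = relatedness.near_pd(relatedness.Grm(
                    values=sub, ids=tuple(cohort.ids[i] for i in idx),
                    provenance=grm.provenance))
                scan = association.lmm_scan(geno_cc, y, grm_cc, marker_map)
                scan.thresholds = {"m_eff": m_eff, **meff_thresholds}
                loci = _select_loci(scan.table, meff_thresholds["suggestive"],
                                    None, config.locus_window_bp)
                vc = association.reml_pve(y, grm_cc)
                pve_l = association.liability_transform(
                    max(vc.pve, 0.0), incidence, float(y.mean()))
            else:
                # per-marker logistic fits are deferred to the selected loci
                scan = association.binary_scan_f2(geno_cc, y, marker_map,
                                                 fit_logistic=False)
                thr = association.permutation_thresholds(
                    geno_cc, y, n_perm=config.n_perm, alphas=config.alphas,
                    seed=(config.seed * 131 + d_index) % (2 ** 31))
                scan.thresholds = {f"lod_alpha_{a:g}": t for a, t in thr.items()}
                loci = _select_loci(scan.table, None,
                                    thr[max(config.alphas)],
                                    config.locus_window_bp)
                vc, pve_l = None, None

            scan.table.to_csv(cdir / f"scan_{defect}.tsv", sep="\t", index=False)
            (cdir / f"scan_{defect}_thresholds.json").write_text(
                json.dumps(scan.thresholds, indent=2))
            register(cdir / f"scan_{defect}.tsv")

            if len(loci) < 2:
                try:
                    partner = epistasis.partner_snp(
                        scan.table, loci, config.locus_window_bp)
                    loci = loci + [partner]
                    logger.info("%s/%s: partner marker fallback -> %s",
                                cname, defect, partner)
                except ValueError:
                    logger.warning("%s/%s: no eligible locus pair", cname, defect)
                    continue

            # odds ratio and per-marker PVE at the top locus; the marker PVE
            # uses the linear-scale effect on the 0/1 phenotype
            top = loci[0]
            jtop = marker_map.index_of(top)
            if multi_generation:
                orr = association.logistic_mixed_or(geno_cc[:, jtop].astype(float),
                                                    y, grm_cc)
                odds = orr.odds_ratio
                beta_lin = float(scan.table.set_index("marker").loc[top, "beta"])
            else:
                g_top = geno_cc[:, jtop].astype(float)
                obs_mask = g_top >= 0
                beta_logit, _ = association._additive_logistic(
                    g_top[obs_mask], y[obs_mask])
                odds = float(np.exp(beta_logit))
                beta_lin = float(np.polyfit(g_top[obs_mask], y[obs_mask], 1)[0])
            obs = geno_cc[:, jtop]
            obs = obs[obs >= 0]
            maf = float(min(obs.mean() / 2.0, 1 - obs.mean() / 2.0))
            pv = float(np.var(y))
            pve_marker = (association.pve_snp(maf, beta_lin, pv)
                          if np.isfinite(beta_lin) and maf > 0 else np.nan)

            defect_rows.append({
                "cross": cname, "defect": defect, "incidence": incidence,
                "n_cases": n_cases, "n_controls": int(len(y) - n_cases),
                "top_locus": top, "odds_ratio": odds,
                "pve_snp": pve_marker,
                "pve": vc.pve if vc else np.nan,
                "pve_liability": pve_l if pve_l is not None else np.nan,
                "n_loci": len(loci)})

            # epistasis over all pairs of selected loci
            pairs = [(a, b) for i, a in enumerate(loci) for b in loci[i + 1:]]
            pairs = pairs[:config.max_pairs_per_defect]
            usable = []
            for a, b in pairs:
                tab = epistasis.incidence_table(
                    y, geno_cc[:, marker_map.index_of(a)],
                    geno_cc[:, marker_map.index_of(b)], defect=defect,
                    pair=(a, b))
                if tab.has_empty_cells:
                    logger.warning("%s/%s: pair (%s, %s) has empty cells; skipped",
                                   cname, defect, a, b)
                    continue
                usable.append(tab)
            for tab in usable:
                all_effects.extend(
                    epistasis.test_effects(tab, n_pairs_for_defect=len(usable)))

        manifest["stages"][cname] = {"seconds": round(time.time() - t0, 2)}

    effects_df = epistasis.effects_frame(all_effects) if all_effects else \
        pd.DataFrame(columns=["defect", "locus1", "locus2", "g1", "g2",
                              "n_case", "n_total", "observed", "expected",
                              "effect", "scaled_effect", "se", "t", "p",
                              "significant", "genotype_class"])
    effects_df.to_csv(outdir / "epistasis_effects.tsv", sep="\t", index=False)
    register(outdir / "epistasis_effects.tsv")

    class_summary = coadaptation.protective_fractions(all_effects)
    congruence = coadaptation.congruence_tests(all_effects)
    class_summary.to_csv(outdir / "coadaptation_classes.tsv", sep="\t", index=False)
    congruence.to_csv(outdir / "coadaptation_congruence.tsv", sep="\t", index=False)
    register(outdir / "coadaptation_classes.tsv")
    register(outdir / "coadaptation_congruence.tsv")
    try:
        from .plots import protective_fraction_plot
        protective_fraction_plot(class_summary, outdir / "coadaptation_classes.png")
    except Exception as exc:  # pragma: no cover - plotting is best effort
        logger.warning("class plot failed: %s", exc)

    defect_table = pd.DataFrame(defect_rows)
    defect_table.to_csv(outdir / "defect_summary.tsv", sep="\t", index=False)
    register(outdir / "defect_summary.tsv")
    correlations = severity_correlation(effects_df, defect_table, config.severity)
    (outdir / "severity_report.json").write_text(json.dumps({
        "severity_ranks": config.severity, "correlations": correlations},
        indent=2))
    register(outdir / "severity_report.json")

    manifest["total_seconds"] = round(time.time() - t_start, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.1f s", manifest["total_seconds"])
    return SeverityReport(defect_table=defect_table, effects=effects_df,
                          correlations=correlations,
                          class_summary=class_summary, congruence=congruence)
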