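# crossepi

QTL mapping and physiological-epistasis analysis for binary malformation
phenotypes in inbred mouse strain crosses.

## The scientific problem

Mice heterozygous for a cardiac transcription-factor null allele (the
*Nkx2-5*<sup>+/−</sup> model of congenital heart disease) develop
anatomically distinct heart defects — secundum atrial septal defects (ASD),
membranous and muscular ventricular septal defects (VSD), and
atrioventricular septal defects (AVSD) — whose incidence falls as their
severity rises.  In crosses of two inbred strains (reference strain B and a
second strain X), modifier loci change the risk of each defect through
pairwise interactions with the mutation (operationally: QTLs for defect risk
among mutant carriers), and pairs of modifier loci interact with each other
(higher-order epistasis).  `crossepi` implements the full analysis chain for
such studies on simulated cohorts with a known generative architecture:

- **Cross simulation.**  F2 intercrosses and advanced-intercross (AIC)
  generations (F10, F14) under Haldane meiosis, with binary defect
  phenotypes drawn from penetrances that combine a per-defect baseline,
  additive single-locus offsets, and 3×3 two-locus deviation matrices — the
  exact ground truth for estimator-recovery tests.
- **Marker QC and I/O.**  Plain-text TSV and PED/MAP genotype formats;
  markers with more than 10% missing genotypes are removed.
- **HMM imputation.**  A three-state hidden Markov model (genotypes 0/1/2,
  stationary distribution ¼, ½, ¼) with exact forward–backward smoothing at
  typed-but-missing and untyped grid positions; AIC generations use a map
  expansion factor of *t*/2 for generation *t*.
- **Association scans.**  The F2 binary-trait scan uses the 2-df
  likelihood-ratio statistic of the three-genotype-class binomial model,
  reported as LOD = LRT/(2 ln 10), with genome-wide thresholds from
  phenotype permutations.  Combined F2 + AIC cohorts use the linear mixed
  model *y* = μ + *x*β + *u* + ε with cov(*u*) = v<sub>g</sub>·GRM, fit by
  ML on the GRM eigenbasis, with Bonferroni thresholds on the effective
  number of tests (Li–Ji).  The GRM is the centered estimator
  *G* = *WW*′/*p* with the F2 block overridden to pedigree expectations
  (0.5 off-diagonal, 1 diagonal) and a nearest-positive-definite adjustment.
- **Heritability.**  REML variance components, with case-control
  ascertainment corrected by the liability-scale transformation
  PVE<sub>l</sub> = PVE · P²(1−P)² / (A(1−A)z²).
- **Higher-order epistasis** (the core statistic).  For a pair of loci, the
  expected defect incidence at two-locus genotype (i, j) under independently
  acting loci is the unweighted main-effects fit
  r̄<sub>i</sub> + c̄<sub>j</sub> − m of the 3×3 incidence table; the
  epistatic effect is observed − expected.  Effects sum to zero over every
  row, column, and the table.  Significance is tested on the arcsine
  square-root scale (variance 1/(4n) per cell) with a Bonferroni threshold
  of 0.05/(9x) for x locus pairs per defect; for cross-defect comparison,
  effects are divided by the unweighted average incidence (UWA) over the
  nine cells.
- **Coadaptation.**  Two-locus genotypes are classified as syn-homozygous
  (both loci homozygous for the same strain), anti-homozygous, double
  heterozygous, or mixed; the package tests whether significant
  syn-homozygous effects are disproportionately protective and whether
  protective/deleterious anchors co-occur with congruent signs at the
  companion cells.
- **Severity report.**  Kendall partial rank correlations link incidence
  and (scaled) effect magnitudes to configured severity ranks
  (ASD = 1 < VSD = 2 < AVSD = 3).

## Worked example

```python
from crossepi.pipeline import recovery_config, run_end_to_end

report = run_end_to_end(recovery_config(outdir="out/recovery", seed=1))
print(report.correlations)
```

prints

```
{'incidence_vs_severity': {'tau': -0.849, 'p': 0.0074, 'n': 8},
 'effect_vs_severity':    {'tau':  0.693, 'p': 0.0017, 'n': 13}}
```

The configuration simulates two F2 crosses of 24,000 newborns each (half
mutant carriers) with two-locus deviations that grow with defect severity.
The negative incidence-vs-severity correlation says rarer defects are the
more severe ones; the positive effect-vs-severity correlation says the
significant epistatic deviations, scaled by each defect's unweighted average
incidence, are larger for severe defects.  `report.class_summary` shows the
coadaptation signature — in this run all 16 significant syn-homozygous
effects lower risk and all 15 anti-homozygous effects raise it.

The same pipeline is scriptable from the shell:

```bash
crossepi run-all --seed 1 --outdir out/demo      # built-in demo architecture
crossepi scan genotypes.tsv phenotypes.tsv ASD --n-perm 1000 --out scan.tsv
crossepi epistasis genotypes.tsv phenotypes.tsv ASD m1,m2 --out epi.tsv
```

An annotated YAML configuration for `run-all --config` is in
`examples/config.yaml`.

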