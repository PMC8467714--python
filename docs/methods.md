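# Methods

This note documents the models, numerical choices, and limitations behind
`crossepi`.  It is written for someone who wants to use or extend the
package, not as a results report: every number quoted here is recomputed by
the test suite or by `scripts/acceptance.py`.

## 1. Cross simulation

**Meiosis.**  Gametes are strain-origin mosaics generated by a Markov walk
along the marker map: the origin at the first marker of a chromosome is
Bernoulli(½) and switches between adjacent markers with the Haldane
recombination fraction r = (1 − e^(−2d))/2, d in Morgans.  Haldane's map
function assumes no crossover interference; interference would slightly
reduce double recombinants between nearby markers but has negligible effect
on the single-marker and two-locus statistics the package tests.  Chromosome
boundaries use r = 0.5.  The default genetic map is linear in physical
position at 0.5 cM/Mb over the 19 mouse autosomes (sex chromosomes are
outside scope, as in the analyses the package supports).

**F2 and advanced intercross.**  F1 parents are heterozygous everywhere, so
an F2 individual is the union of two independent mosaic gametes.  Advanced
intercross (AIC) generations are bred by random mating with full-sib
avoidance from a census of 100 breeding pairs per generation (configurable;
the census size of real AIC lines is rarely reported, and at 200 breeding
individuals drift over 12 generations is modest).  Sib avoidance is the
only pedigree constraint; real breeding schemes also exclude first cousins,
which changes the variance of relatedness negligibly at this census size.
Cohort members of generation F*t* are offspring of random non-sib pairs of
the F(*t*−1) census.

**Phenotypes.**  Half of the offspring carry the mutation (the expected
Mendelian ratio for a heterozygous × wild-type cross); only carriers are at
risk.  Penetrance is additive on the probability scale: baseline +
single-locus offsets (indexed by genotype BB/het/XX) + two-locus deviation
matrices.  Any realized penetrance outside [0, 1], or a per-individual sum
over defects above 1, is rejected with the offending genotype reported.  A
mutant's defect is assigned with a single uniform draw against the
cumulative penetrances in the configured defect order, so each defect's
marginal probability equals its realized penetrance exactly and an
individual has at most one defect.  This matches an analysis design in which
every defect is compared against the same normal controls; comorbidity is
not modeled.

Because penetrance is additive on the probability scale, the ground-truth
epistatic effect of a configured deviation matrix is exactly its unweighted
main-effects residual (`true_epistasis_effects` applies the same
decomposition as the estimator), which makes parameter-recovery tests sharp
rather than approximate.

**What the generator does not emulate.**  Genotyping batch effects,
platform-specific quality scores, segregation distortion, embryonic
lethality, X-linked loci, multi-allelic markers, and ascertainment of
controls by genotyping cost (the simulator analyzes all normal mutant
littermates as controls).  Passing tests therefore demonstrate correctness
of the statistical machinery under a clean genetic model, not robustness to
those artifacts.

## 2. Marker QC

Markers with a missing-genotype fraction **strictly greater** than 0.10 are
removed; a marker at exactly 10% is kept.  Minor allele frequency is
reported with the QC report but is not a filter — in a two-strain cross all
markers segregate near MAF 0.5 and a MAF filter would be inert.  The report
schema has a free-text `reason` column so additional criteria can be added
without changing the format.

## 3. HMM imputation

Hidden states are the genotype codes {0, 1, 2}; the F2 stationary
distribution is (¼, ½, ¼).  The transition matrix over an interval with
recombination fraction r is the two-independent-gametes kernel
[[q², 2qr, r²], [qr, q²+r², qr], [r², 2qr, q²]], q = 1 − r.  Emissions are
correct with probability 1 − ε and each wrong state with ε/2; the default
ε = 0.005 reflects a low but nonzero genotyping error rate and is
configurable in [0, 0.1].

AIC generations accumulate recombination.  Generation t is modeled by
scaling cM distances by the expected map expansion t/2 before applying the
Haldane function, and each generation is imputed separately with its own
factor (F2 → 1, F10 → 5, F14 → 7).

Posteriors are exact forward–backward marginals; untyped target positions
are merged into the chain as unobserved sites, so their posteriors are also
exact (verified against full hidden-path enumeration on chains of up to six
markers).  Imputation confidence is defined as the maximum posterior
probability, and hard calls are the posterior argmax.  Targets outside the
typed span of a chromosome are rejected rather than extrapolated.  An
individual with no observed marker on a chromosome is an error by default;
the pipeline opts into receiving the stationary prior for such rows, which
occurs when random masking blanks a short chromosome of the sparse panel.

## 4. Relatedness

The GRM is the centered estimator G = WW′/p (column-centered genotypes,
normalized by marker count).  Missing genotypes are mean-imputed per marker
for GRM construction only, never for association tests.  Because all F2
individuals of a cross are effectively full siblings, the F2 block is
overridden with pedigree expectations (0.5 off-diagonal, 1 diagonal) before
mixed-model use.  The override can introduce negative eigenvalues, so the
matrix is adjusted to the nearest positive definite matrix: with no
diagonal constraint, the alternating-projection scheme converges in one
step to the eigenvalue-clipped matrix, and a floor of 1e-8 on the
eigenvalues keeps Cholesky factorizations stable.  Similarity between the
pre- and post-adjustment matrices is quantified as the Pearson correlation
of the lower-triangle off-diagonal entries, expressed as a percentage (a
Mantel-style statistic; a permutation p-value over simultaneous row/column
shuffles is available).  A principal submatrix of the adjusted matrix is
itself positive semidefinite, so per-defect case-control subsets reuse the
adjusted matrix directly.

## 5. Association

**F2 binary scan.**  Per marker, the 2-df likelihood-ratio statistic of the
saturated three-genotype-class binomial model against the null — computed
as the G-statistic of the 2×3 case/control-by-genotype table with the
0·log 0 = 0 convention — reported as LOD = LRT/(2 ln 10).  Individuals
missing a marker are dropped for that marker; monomorphic markers are
flagged with LOD 0 and p = 1.  An additive-coded logistic fit supplies the
per-allele β and odds ratio; the 2×2 allele-table cross-product OR is
emitted alongside because the two differ whenever the three genotype
classes deviate from logit-additivity.  Scans are at genotyped markers
only; imputed positions can be appended as markers.

**Permutation thresholds.**  Case/control labels are shuffled and the
genome-wide maximum LOD recorded; thresholds are empirical (1 − α)
quantiles.  The permutation loop reuses the per-class indicator matrices,
so 1000 permutations of a ~1500 × 120 panel take seconds.

**Mixed-model scan.**  y = μ + xβ + u + ε with cov(u) = v_g·K.  The GRM is
eigendecomposed once; for every marker the profile maximum likelihood over
the variance ratio δ = v_e/v_g is found by bounded scalar optimization of
log δ on the rotated data (each evaluation is O(n)).  The LRT against the
marker-free null (fit once) is referred to χ²(1 df).  ML rather than REML
is used inside the per-marker LRT so the null and alternative likelihoods
are nested; REML is reserved for reported variance components, mirroring
common mixed-model GWAS practice.  The binary phenotype is analyzed on the
linear scale in this model (the common LMM approximation for case-control
GWAS); odds ratios come from the logistic mixed model below.

**Multiplicity for the combined scan.**  The effective number of tests
M_eff is the Li–Ji spectral count Σ [I(λ ≥ 1) + (λ − ⌊λ⌋)] over eigenvalues
of the marker correlation matrix; thresholds are 0.05/M_eff (significant)
and 1/M_eff (suggestive).

**REML heritability.**  One-dimensional REML over δ on the eigenbasis;
PVE = v_g/(v_g + v_e), with its standard error from the numerical curvature
of the profile restricted likelihood in PVE.  The liability transform
PVE_l = PVE · P²(1−P)²/(A(1−A)z²), z = φ(Φ⁻¹(1−P)), corrects case-control
ascertainment; at P = A = ½ the factor reduces to π/2.

**Per-marker variance explained.**  PVE_SNP = MAF(1−MAF)β²/PV as the
framework prints it.  The conventional additive-variance formula carries a
factor 2; a `conventional=True` flag applies it, the default does not.  β
here is the linear-scale effect of the marker on the 0/1 phenotype.

**Logistic mixed model.**  Penalized quasi-likelihood: the model is
re-linearized at the current fit, v_g is estimated by REML on the working
response (bounded scalar search; each evaluation costs one Cholesky of
v_g·K + W⁻¹), and fixed/random effects are updated by GLS, for four outer
iterations.  With K = I the fit agrees with plain logistic regression to
under 1e-3 on β.  Complete separation is detected on the initial plain
logistic fit and flagged without an estimate.  PQL is known to shrink
variance components for binary data; here it serves odds-ratio estimation
at genome-wide-selected loci, where that bias is immaterial.

## 6. Higher-order epistasis

For a locus pair and defect, the nine two-locus genotype cells carry
observed incidences p_ij among analyzed mutants (cases of this defect plus
shared normal controls; individuals missing either genotype are excluded).
The expectation under independently acting loci is the **unweighted**
main-effects fit expected_ij = r̄_i + c̄_j − m (row/column/grand means of
the incidence table, all nine cells weighted equally regardless of their
counts) — equivalently the unweighted least-squares regression of the
two-locus incidences onto the single-locus incidences, an equivalence the
tests assert against a brute-force fit.  The epistatic effect is
observed − expected; rows, columns, and the table sum to zero (asserted to
1e-12), so effects redistribute risk around the additive expectation.
Positive effects raise risk, negative effects lower it.

**Testing.**  Incidences are arcsine square-root transformed, which makes
the sampling variance of a cell approximately 1/(4n) independent of its
value.  The effect at cell (i, j) is the fixed linear contrast with
coefficients 4/9 at the cell, −2/9 for cells sharing its row or column, and
+1/9 elsewhere; the contrast of the transformed incidences divided by
√(Σλ²/(4n)) is referred two-tailed to the standard normal (cell counts are
large in the intended regime; the exact degrees of freedom of a
heteroscedastic contrast are not well defined, and the normal reference is
the limit all t choices share).  Because the effect is a single linear
contrast of the nine independent cells, its SE accounts exactly for the
covariance between a cell and its fitted expectation.  The significance
threshold is Bonferroni corrected to 0.05/(9x) for x pairs analyzed per
defect.  A cell with zero total count has infinite variance on this scale;
the pair is reported and skipped rather than imputed, since silent
imputation would corrupt the zero-sum conservation checks.

**Scaling.**  For comparison across defects with different incidences,
effects are divided by the unweighted average incidence (UWA) of the defect
over the nine cells; signs are preserved in records and absolute values
used for cross-defect magnitude comparisons.  Reported magnitudes are on
the incidence scale; only the test statistic lives on the arcsine scale.

**Partner-locus fallback.**  When a defect has a single mapped locus, the
pairwise analysis uses the next most significant scan marker that is
neither among nor within 10 Mb (same chromosome) of the existing loci.

## 7. Coadaptation

The nine two-locus genotypes classify into 2 syn-homozygous, 2
anti-homozygous, 1 double-heterozygous and 4 mixed cells; classification is
symmetric under locus exchange, and flipping one locus's strain coding
exchanges syn and anti labels.  "Protective" means a negative effect.  The
per-class fraction of significant effects that are protective is tested
against ½ with a two-sided one-sample z-test (null variance); classes are
compared with pooled two-sample z-tests.  Congruence analyses anchor on a
significantly protective syn cell or significantly deleterious anti cell
and report, per relation, the proportion of locus pairs whose companion
cells carry the congruent sign.  Denominators count locus pairs, not cells,
to avoid double counting within a pair (the alternative, cell-level
denominators, would weight pairs unevenly).

## 8. Nonparametric statistics

Kendall correlations use the tie-adjusted τ-b (incidence and effect data
contain ties).  Partial correlations come from the precision matrix of the
pairwise τ-b matrix, which reduces to the textbook first-order recursion
for one covariate; the two-sided p-value uses the normal approximation for
τ with the sample size reduced by the number of covariates.  The
Mann–Whitney U test uses exact enumeration when the smaller sample has at
most 8 tie-free observations and the tie-corrected normal approximation
otherwise.  Proportion z-tests use the null variance (one-sample) or pooled
variance (two-sample).

## 9. Pipeline and experiment design

`run_end_to_end` chains simulate → mask → QC → impute → GRM → scan →
epistasis → coadaptation → severity report, writing plain-text artifacts
and a manifest; all randomness derives from the single run seed, and
reruns are reproducible.  Locus selection keeps at most the peak marker per
chromosome above the suggestive threshold: a genome-wide panel cannot
resolve multiple QTLs on one chromosome, and shoulder markers of one peak
would otherwise enter as spurious "loci" whose mutual linkage empties the
anti-homozygous cells of their two-locus tables.

Severity ranks are configuration (ASD = 1, both VSD types = 2, AVSD = 3),
not inference.  The incidence-vs-severity correlation controls for the
cross; it does not control for the analyzed sample size because in
simulated cohorts that size is a deterministic function of incidence
(shared controls plus all cases), so conditioning on it would remove the
signal by construction rather than remove confounding.  The
effect-vs-severity correlation uses significant effects' absolute scaled
magnitudes and controls for the observed incidence at the two-locus
genotype.

**Problem sizes.**  The built-in demo (`default_config`) runs an F2 of
3,000 newborns on the sparse ~21 Mb panel plus a combined F2 (3,000) + F10
(1,200) + F14 (1,200) cohort on a ~7 Mb panel — large enough to exercise
every stage, including the mixed model, in a few minutes on one CPU.  The
directional-recovery experiment (`recovery_config`) uses two F2-only
crosses of 24,000 newborns on ~3 Mb panels: cohort sizes follow an a priori
power calculation for the arcsine contrast at F2 genotype frequencies
(t ≈ δ·√N/(2√(p̄(1−p̄))·1.222) for the corner cells), chosen so the VSD and
AVSD deviations are detectable at the Bonferroni threshold with good power
while the small ASD deviations mostly are not.  Dense panels matter here:
a selected peak more than ~10 Mb from the true locus attenuates the
measured deviation by the linkage factor and scrambles cross-defect
magnitude comparisons.

**Benchmark experiments** (`crossepi.experiments`, driven by
`scripts/acceptance.py`) use a null F2 of 1,500 for the permutation
thresholds (1,000 permutations), an F2 of 1,000 with a 3 Mb untyped grid
for imputation confidence, and a combined cohort of 500 per generation at
the ~3 Mb panel for the GRM similarity.

## 10. Known limitations

- The AIC breeding scheme omits the first-cousin exclusion and uses a
  fixed census; LD decay is realistic in expectation but its variance is
  slightly understated.
- PQL odds ratios are approximate for rare defects; a full adaptive
  quadrature fit is out of scope.
- The arcsine contrast treats the nine cells as independent binomials,
  which is exact under the simulator but only approximate if genotypes at
  the two loci are linked.
- Three-locus and higher interactions, haplotype-based epistasis, and
  natural-population (multi-allelic, rare-allele) extensions are
  deliberately not implemented; with rare alleles the population and
  unweighted average incidences decouple and these statistics lose their
  comparability across phenotypes.
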