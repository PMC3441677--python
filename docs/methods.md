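# Methods

## Statistical model

The analysis phenotype is a transformed estimated glomerular filtration
rate (eGFR). From serum creatinine (mg/dL), age (years) and sex, the
simplified MDRD equation gives

    eGFR = 186 · crea^(−1.154) · age^(−0.203) · (0.742 if female) · (1.210 if black)

in mL/min/1.73 m². eGFR is right-skewed, so it is Box-Cox transformed,
x ↦ (x^λ − 1)/λ (log at λ = 0), with λ chosen by maximizing the profile
log-likelihood over [−3, 3] (bounded scalar minimization, tolerance 1e−5;
a dense-grid cross-check in the tests agrees to within 0.01). Residual
positive kurtosis is tamed by winsorizing at mean ± 3 SD, with the bounds
computed once from the pre-clamp mean and SD (no iteration). Reported
skewness and kurtosis are the moment forms m₃/m₂^1.5 and m₄/m₂² − 3;
bias-corrected versions differ negligibly at n ≈ 1,000.

Association is tested per SNP by ordinary least squares *within each
local-ancestry stratum* (0, 1 or 2 copies of African ancestry at the
marker), adjusted for age, sex and global ancestry θ, with classical
homoskedastic standard errors. Within a homogeneous stratum of local
ancestry, genotype cannot be confounded by local ancestry — that is the
whole argument, and it requires no assumption that ancestry effects are
additive or that genotype and local ancestry are independent (they are
not, at an ancestry-informative marker). A stratum enters only if it has
at least 10 complete cases, a within-stratum minor-allele count of at
least 3, and a polymorphic coded genotype; smaller strata are skipped
with a recorded reason, never pooled. Covariate columns that are constant
within a stratum (e.g. θ in a one-ancestry cohort) are dropped from that
stratum's design rather than allowed to make it singular; a genotype
collinear with a conditioning covariate skips the stratum.

The per-stratum estimates are combined by inverse-variance-weighted
fixed-effects meta-analysis; the combined z = β_meta/se_meta is referred
to the standard normal. Fixed effects are the appropriate model because
the three strata exhaust the possible strata; a random-effects option is
deliberately not provided. The normal reference (rather than t) matches
standard IVW practice; it is very slightly anticonservative when a small
stratum carries non-trivial weight, visible as a type-I rate of ≈0.055 at
a nominal 0.05 in the calibration runs.

Ancillary tests: effect heterogeneity between the 0- and 2-copy strata by
z = (β₀ − β₂)/√(se₀² + se₂²); allele differentiation between those strata
(or between two ancestral reference panels) by the 1-df two-proportion
chi-square without continuity correction on chromosome counts; the
excess-ancestry (admixture) effect by regressing the phenotype on local
ancestry adjusted for age, sex and θ; Hardy–Weinberg equilibrium by the
exact conditional test (heterozygote counts enumerated given allele
counts, p = sum of outcome probabilities no larger than the observed
one), flagging heterozygote excess relative to the conditional
expectation.

## Fine-mapping

A locus is the inclusive physical interval spanned by the reference-panel
SNPs with r² ≥ 0.3 to the index SNP (degenerating to the index position
when no proxy qualifies); its members are all genotyped cohort SNPs inside
the interval. The effective number of independent tests is computed from
the eigenvalues λ_k of the members' dosage covariance matrix as
N_eff = (Σλ_k)²/Σλ_k². This is the covariance (not correlation) of
dosages, with missing dosages mean-imputed per SNP before decomposition —
so N_eff is not invariant to marker rescaling, which the tests assert as
the intended convention. N_eff equals K for independent equal-variance
markers, 1 for perfectly correlated ones, and 2/(1+ρ²) for a unit-variance
pair with correlation ρ. Within-locus p-values are Bonferroni-adjusted by
N_eff (a Šidák option exists behind a flag); comparing p·N_eff to α and p
to α/N_eff give identical decisions. No cross-locus correction is applied:
loci in a follow-up study are separate hypotheses, not one family. The
best SNP is the smallest meta p, ties broken by larger |z| then by
identifier. Conditional scans re-run the stratified analysis with the top
SNP's dosage as an additional covariate; the associated-region length is
the distance between the nearest non-associated markers flanking all
associated ones, reported as unbounded (with a warning) at panel edges.

## Permutation, power, variance

The differentiation permutation test draws k SNPs (default 11) without
replacement from the genome panel, counts how many pass the two-panel
allele-difference test at a per-SNP α (default 0.05 — a choice, since only
"significant differentiation" is specified), and reports the fraction of
replicates (default 10,000) reaching the observed count. The plain
proportion is reported; a (r+1)/(n+1) correction is available.

Power for an effect explaining a fraction q of phenotypic variance uses
the 1-df noncentral chi-square with noncentrality λ = n·q/(1−q); the
minimum detectable q inverts this by bisection to 1e−10. At n ≈ 1,000 the
difference from the exact F with n−k denominator degrees of freedom is
below 0.01 percentage points. At n = 1,018, α = 0.05 and 80% power this
gives q = 0.77%.

Variance explained by a predictor group is the difference of unadjusted R²
between nested OLS fits on the identical individual set. The sequential
report takes age + sex + θ as the baseline and adds, in order: all hit-SNP
dosages (pooled genotype component); genotype-within-stratum interaction
columns g·1[l = s] (the stratified genotype component — one of several
defensible aggregations, labelled as such); the local-ancestry columns;
and conditional secondary dosages. Under ancestry-heterogeneous effects
the stratified component exceeds the pooled one — the "masking" phenomenon
the stratified analysis exposes.

## Synthetic cohorts

The generator emulates a two-way admixed cohort at the study conditions
the package targets: defaults n = 1,018 individuals, mean African ancestry
0.80 (Beta-distributed θ with concentration 15, giving an SD of ≈0.10),
ancestral differentiation F_ST = 0.15, and a residual skewness of 2.4 so
the Box-Cox stage has real work to do.

- **Ancestral frequencies** follow the Balding–Nichols model: for each
  marker a base frequency p (uniform on [0.1, 0.9] by default) and two
  independent Beta(p(1−F)/F, (1−p)(1−F)/F) deviates, so each population's
  frequency has mean p and variance F·p(1−p). Frequencies are floored at
  0.01 to keep regressions well-posed. Finite reference-panel allele
  counts are drawn binomially from 120 chromosomes per population.
  Hudson's F_ST as a ratio of averages recovers the generating F; the
  plain mean of per-marker ratios is biased downward (Jensen), which is
  why both estimators exist.
- **Local ancestry** is laid down per chromosome as a two-state Markov
  chain with stationary probability θ_i and a per-marker redraw
  probability of 0.01 (an independent-per-marker mode, redraw rate 1.0, is
  used where exact recovery of θ from row means is asserted). Alleles are
  Bernoulli draws from the frequency of the chromosome's ancestry, so
  genotype and local ancestry covary exactly as in real admixed samples —
  the confounding structure the stratified analysis removes.
- **Phenotype**: y = Σ β_k g_k + γ·l + b_age(age−50) + b_sex·sex + e, with
  e a standardized shifted gamma hitting the target skewness (normal at
  skew 0). Age is uniform on 30–70 and sex Bernoulli(0.5) — arbitrary but
  recorded in the truth object. With `make_creatinine`, the trait is
  mapped to an eGFR scale (100 + 25·y, floored at 5) and serum creatinine
  is back-computed by inverting the MDRD equation, so the phenotype
  pipeline can be exercised end to end and reproduces the eGFR exactly.
- **LD blocks** for the N_eff machinery are drawn from finite haplotype
  pools: each individual's two chromosomes are uniform draws from a pool
  of H haplotypes; H = 2 complementary haplotypes give perfect
  correlation, large pools approach linkage equilibrium, and the
  pool-implied r² is available in closed form for oracle checks.

What the generator does *not* emulate: coalescent genealogies,
recombination maps, genotyping error, relatedness, missingness patterns,
assay calibration drift, or phenotype covariates beyond age and sex.
Passing tests therefore demonstrate the statistical machinery under the
assumed generating model, not robustness to everything real cohorts do.

## Problem sizes and determinism

Monte-Carlo checks use sizes chosen to give decisive margins at desk
scale: 2,000 replicates of n = 1,000 for type-I calibration (binomial SE
≈ 0.005), 500 replicates for effect recovery (relative bias resolved well
below the 5% band), 10,000 permutation replicates, and 50 locus
replicates for the conditional scan. Every stochastic routine takes an
explicit seed or `numpy` Generator; the same seed reproduces cohorts
bit-for-bit, and the pipeline runner writes byte-identical outputs on
rerun.

## Known limitations

- Local-ancestry calls are consumed as given (0/1/2 copies); inferring
  them from genotypes and reference panels is out of scope.
- Classical OLS standard errors by default (a robust option exists on
  `ols_fit` callers via statsmodels but is off, matching standard
  practice for this design); meta p-values use the normal approximation.
- The recessive model codes homozygous carriers of the coded allele; with
  no heterozygotes present it is an affine recoding of the additive model
  and carries the same test.
- Selection-scan statistics (e.g. iHS) are treated as pass-through
  annotations, never computed.
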