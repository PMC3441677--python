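# admixstrat

Local-ancestry-stratified association analysis for admixed cohorts.

## The problem

In an admixed population (e.g. African Americans, with roughly 80% African /
20% European ancestry on average), both the phenotype and the allele
frequencies vary with ancestry — at the level of the individual (global
ancestry θ) *and* at the level of the marker (local ancestry, the number of
chromosome copies of African origin at a locus). Ordinary regression of a
trait on genotype is therefore confounded: a marker can appear associated
simply because its allele frequency differs between ancestral populations
that also differ in the trait. Covariate adjustment for local ancestry
assumes additivity and genotype–ancestry independence, neither of which
holds at an ancestry-informative marker.

`admixstrat` implements the stratified alternative: within a stratum of
individuals all carrying the same local ancestry (0, 1 or 2 African
chromosome copies) at the tested marker, genotype cannot be confounded by
local ancestry. Each SNP is tested by OLS within every usable stratum,

    y ~ β0 + β·g + b_age·age + b_sex·sex + b_θ·θ ,

and the per-stratum estimates (β_s, se_s) are combined by inverse-variance
weighted fixed-effects meta-analysis:

    w_s = se_s⁻² ,  β_meta = Σ w_s β_s / Σ w_s ,  se_meta = (Σ w_s)^(-1/2) .

The fixed-effects model is the right one because the three local-ancestry
strata exhaust the possible strata.

Around this core the package provides the full follow-up-study toolkit:

- **Phenotype construction** — MDRD eGFR from serum creatinine
  (186 × crea⁻¹·¹⁵⁴ × age⁻⁰·²⁰³, ×0.742 if female, ×1.210 if black),
  Box-Cox normalization by maximum likelihood, winsorization at ±3 SD.
- **Fine-mapping** — locus sets from a reference-panel LD table (r² ≥ 0.3 to
  the index SNP), effective degrees of freedom N_eff = (Σλ_k)²/Σλ_k² from
  the eigenvalues of the members' dosage covariance matrix, per-locus
  Bonferroni adjustment by N_eff, best-SNP selection, conditional scans for
  secondary signals, and associated-region length.
- **Ancestry diagnostics** — global ancestry from local-ancestry calls,
  LD-prune → thin → PCA with Velicer's minimum-average-partial test,
  Hudson's F_ST, 0-vs-2-stratum allele-differentiation and
  effect-heterogeneity tests, the excess-ancestry (admixture) effect test,
  and an exact Hardy–Weinberg test.
- **Permutation, power and variance accounting** — a genome-panel
  permutation test for excess differentiation among hit loci, noncentral
  chi-square power / minimum-detectable-variance calculations, and nested
  ΔR² variance partitions.
- **Synthetic cohorts** — a Balding–Nichols generator of admixed cohorts
  (ancestral frequency divergence at a chosen F_ST, per-chromosome Markov
  local-ancestry tracks, skewed residuals, invertible creatinine), with a
  truth record so every estimator can be tested for recovery.

## Worked example

```python
import admixstrat as ax
from admixstrat.simulate import SimConfig, sample_ancestral_freqs, sample_cohort

panel = sample_ancestral_freqs(200, fst=0.15, seed=7)
sid = "snp000000"                      # causal marker, common in both ancestries
cfg = SimConfig(n=1018, m=200, causal_effects={sid: 0.5},
                make_creatinine=True, seed=7)
cohort, truth = sample_cohort(cfg, panel)

y, report = ax.phenotype_pipeline(cohort.creatinine, cohort.age, cohort.sex == 1)
print(report)

fit = ax.stratified_assoc(cohort.phenotype, cohort.dosage(sid), cohort.local_at(sid),
                          cohort.age, cohort.sex, cohort.global_anc, snp_id=sid)
for s in fit.strata:
    print(f"stratum {s.stratum}: beta={s.beta:+.3f} se={s.se:.3f} n={s.n}")
print(f"combined: beta_meta={fit.beta_meta:+.3f} se_meta={fit.se_meta:.3f} "
      f"z={fit.z:.2f} p={fit.p:.3g}")
```

prints

```
phenotype pipeline report
  box-cox lambda          -1.3261
  skewness before/after   +1.777 / +0.020
  excess kurtosis b/a     +5.223 / -0.148
  values winsorized       1

stratum 0: beta=+0.371 se=0.149 n=57
stratum 1: beta=+0.587 se=0.080 n=296
stratum 2: beta=+0.484 se=0.053 n=665
combined: beta_meta=+0.504 se_meta=0.042 z=11.86 p=1.94e-32
```

The pipeline report shows the right-skewed eGFR distribution (skew 1.78)
brought to near-symmetry by the Box-Cox transform and winsorization. The
stratified fit recovers the planted effect of 0.5 phenotype units per coded
allele in each local-ancestry stratum separately; the combined estimate
β_meta = 0.504 ± 0.042 pools them with inverse-variance weights. The
0-vs-2-stratum heterogeneity test on the same fit gives z = −0.71
(p = 0.47): the genotype effect is ancestry-consistent even though the
allele frequencies differ between the strata (χ² = 8.3, p = 0.004).

A command-line interface mirrors the library
(`admixstrat simulate | phenotype | structure | assoc | permtest | power |
run-all`); `admixstrat run-all config.yaml` runs the whole pipeline from
files to TSV reports.

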