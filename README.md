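# ipmeta

Joint association testing of a binary disease status and an intermediate
quantitative phenotype against a single SNP, within one study population.

## The problem

Case-control GWAS of complex diseases are underpowered for variants with
per-allele odds ratios around 1.1–1.2. When the pathway to disease runs
through a measurable quantitative trait — an *intermediate phenotype* such
as cigarettes-per-day for lung cancer — the trait carries association
signal that a pure case-control analysis discards. `ipmeta` implements a
meta-analysis of two tests computed on the *same* samples:

* **test 1** — logistic regression of disease status *D* on the SNP dosage
  *X*: Wald statistic Z₁;
* **test 2** — linear regression of the trait *Y* on *X*, adjusted for
  disease status: Wald statistic Z₂\*.

Under the null of no SNP–disease-locus association the two tests are
independent, so they can be combined per SNP:

* **Fisher's combined probability test**: χ² = −2[ln p₁ + ln p₂] ~ χ²₄;
* **modified inverse-variance weighting (IVW)**: the trait-test effect is
  rescaled by c = √(σ₁²/σ₂\*²) so both effects share the variance of test 1
  (this absorbs the arbitrary measurement unit of the trait), then

  S = (b Z₁ + (1−b) Z₂) / √(½ V(Z₁)),  b = ½,

  which is the variance-minimizing weight and reduces to the Stouffer form
  S = (z₁ + z₂)/√2. Unlike Fisher's test, S is *signed*: discordant effect
  directions cancel instead of compounding, which suppresses false signals
  when the trait truly lies on the causal pathway.

The package also ships the generative model used to study these tests: a
disease locus A (MAF q₁) in linkage disequilibrium (correlation r) with a
tested marker M (MAF m₁), an intermediate trait Y = β₀ + β₁X_A + ε with
the genotype effect β₁ solved from a target locus heritability h², and a
logistic penetrance P(D|X_A, Y) = expit(γ₀ + γ₁X_A + γ₂Y) calibrated by
Gauss–Hermite quadrature to a 5% population incidence. Case-control
cohorts are ascertained by rejection sampling; r = 0 is the null.

## Worked example

```python
import numpy as np
from ipmeta import (build_scenario, ascertain_case_control, logistic_assoc,
                    linear_assoc_adjusted, fisher_combine, ivw_combine)

# medium-risk additive dual-pathway scenario: gamma1 = log 1.15, h2 = 0.010,
# marker-locus correlation r = 0.8; gamma2 calibrated to 5% incidence
scenario = build_scenario("medium", "additive", disease_model=3, r=0.8, h2=0.010)
cohort = ascertain_case_control(scenario, rng=np.random.default_rng(2026))

t1 = logistic_assoc(cohort.d, cohort.g_marker)
t2 = linear_assoc_adjusted(cohort.y, cohort.g_marker, cohort.d)
fisher = fisher_combine(t1.p, t2.p)
ivw = ivw_combine(t1, t2)
```

prints (via the obvious format calls):

```
calibrated gamma0=-3.1000 gamma1=0.1398 gamma2=0.2929
test 1 (logistic): beta=0.1712 se=0.0484 z=3.539 p=4.014e-04
test 2 (linear):   beta=0.1355 se=0.0240 z=5.654 p=1.566e-08
Fisher:  chi2=51.586 p=1.684e-10
IVW:     S=6.501 p=7.996e-11 (c=2.018)
```

The 2000-case/2000-control cohort carries a modest direct effect
(per-allele OR ≈ e^0.17 ≈ 1.19 at the marker) that logistic regression
detects at p ≈ 4×10⁻⁴; the trait test is far stronger because the locus
raises the trait, and the combined S sharpens the signal beyond either
component — with the IVW p-value below Fisher's, as the two effects point
the same way.

## Command line

```bash
# per-variant scan of dosage data (VCF with DS/GT, or a dosage-matrix TSV)
ipmeta assoc --geno matrix.tsv --pheno pheno.tsv --out results.tsv \
       --transform sqrt --maf-floor 0.01 --threshold 5

# synthetic case-control dataset with a right-skewed count trait
ipmeta fixture --samples 2291 --variants 1000 --causal 5 --seed 1 --out demo

# Monte-Carlo power / type-I-error study over a scenario grid
ipmeta power --config grid.yaml --out power.tsv
```

`assoc` writes one row per variant with beta/se/z/p for both component
tests, the Fisher and IVW statistics and p-values, −log10(p) columns, a
`promising` flag for −log10(p) > 5, and reports per-test genomic-control
inflation factors λ. The phenotype TSV has columns `sample_id`, `status`,
`trait`.

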