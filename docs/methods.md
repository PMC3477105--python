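# Methods

## Generative model

An individual is the union of two haplotypes drawn from a four-category
distribution over a disease locus A (minor-allele frequency `q1`) and a
marker M (`m1`). Linkage disequilibrium is parameterized by the allele
correlation `r` through `D = r * sqrt(m1 m2 q1 q2)`, giving haplotype
frequencies `(m1 q1 + D, m1 q2 - D, m2 q1 - D, m2 q2 + D)`. An `r` that
would drive a frequency negative is rejected with the maximum feasible `r`
in the error message. Random mating implies Hardy–Weinberg marginals at
both loci, and the genotype-count correlation between loci equals `r`
(each locus's count is the sum of two independent haplotype draws, so the
haplotype-level correlation carries over).

The quantitative trait is `Y = beta0 + beta1 * code(G_A) + eps`,
`eps ~ N(0, sigma2_E)`, with coding additive (0,1,2), dominant (0,1,1) or
recessive (0,0,1). `beta1` is solved from a target locus heritability:
`Var(beta1 * code(G)) = h2 * total_variance` over the genotype
distribution, and `sigma2_E = (1 - h2) * total_variance`. For additive
coding under Hardy–Weinberg this is the classical decomposition
`sigma2_A = 2 m1 m2 a^2` with no dominance deviation.

Disease status is Bernoulli with logistic penetrance
`expit(gamma0 + gamma1 * code(G_A) + gamma2 * Y)`.

A deliberate asymmetry: the generative equations act on the **disease
locus**, while all association tests are applied to the **marker**. With
equal MAFs at the two loci the variance formulas coincide, the marginal
marker–disease association decays with `r`, and `r = 0` is an exact null —
the configuration in which power-versus-`r` curves and a null calibration
are both meaningful.

## Calibration

The tabulated scenarios fix `(gamma0, gamma1)` per risk level (medium /
low), coding and disease model, but not `gamma2`, `beta0` or `sigma2_E`.
The package fixes `beta0 = 0` and total trait variance 1 (so
`sigma2_E = 1 - h2`) and solves `gamma2 >= 0` so that the *marginal*
incidence

`P(D) = sum_g P(g) * E_Y[ expit(gamma0 + gamma1 c_g + gamma2 Y) | g ]`

equals the 5% target. The trait expectation is a 64-node Gauss–Hermite
quadrature (exact genotype sum), and the root is found by Brent's method;
64 nodes put the quadrature error many orders below the 1e-6 calibration
tolerance for a Gaussian integrand of this smoothness. The reverse
direction — fixing `gamma2` and solving `gamma0` on the bracket [-20, 20],
where incidence is monotone in the intercept — is also exposed. Raising
`gamma2` spreads a (near) zero-mean linear predictor and therefore raises
a sub-target incidence monotonically toward 1/2, so the root is unique; a
scenario whose incidence already exceeds the target at `gamma2 = 0` is
rejected.

Disease-model semantics: model 1 severs the genotype→trait path
(`beta1 = 0`; trait and locus act on disease independently), model 3 keeps
both the direct and the mediated path, model 2 (pure mediation,
`gamma1 = 0`) is constructible but outside the default grid because its
parameters are not tabulated.

## Ascertainment

Case-control cohorts are rejection-sampled: population batches sized from
the expected prevalence are drawn until the exact case and control quotas
are met (a ~5% prevalence means roughly 10 population draws per retained
sample when cases bind). A cap of `1e4 * (n_cases + n_controls)` total
draws turns a miscalibrated scenario into an error rather than a hang.
Per cohort, the genotype, trait and disease draws come from three child
streams spawned from one seed, so each layer is independently
reproducible.

## Tests

Both component tests report Wald statistics: `z = beta/se` from the
maximum-likelihood logistic fit (status ~ dosage) and the OLS fit
(trait ~ dosage + status), with two-sided normal p-values. Score and Wald
statistics are asymptotically equivalent at these sample sizes; the Wald
form makes the IVW rescaling well-defined in terms of reported effects and
standard errors. Degenerate fits (monomorphic dosage, a single outcome
class, perfect separation, non-convergence, collinearity) return flagged
results with missing p-values instead of raising, so a genome scan never
aborts mid-stream; standard errors above 1e3 are treated as numerical
separation.

Fisher's combination refers `-2(ln p1 + ln p2)` to chi-square with 4 df;
p-values are floored at 1e-300 (with a warning) before the logs. The IVW
combination rescales the trait effect by `c = se1/se2` — equivalent to
multiplying the raw trait by a constant, hence invariant to its
measurement unit — and forms `L = b*beta1 + (1-b)*c*beta2` with variance
`(b^2 + (1-b)^2) * se1^2`. The weight `b^2 + (1-b)^2` is uniquely
minimized at `b = 1/2`, where `S = (z1 + z2)/sqrt(2)` exactly; the
equal-weight default is therefore the minimum-variance member of the
family. A `direction="negative"` switch flips the trait-test sign for
traits negatively related to disease; the default assumes a positive
relationship. Two-sided p-values are used throughout, including as
Fisher's inputs.

Genomic control uses the median definition: each p-value is mapped to its
1-df chi-square quantile and the median is divided by 0.454936.

## Power engine

Each replicate ascertains a fresh cohort and computes all four tests on
the marker; a rejection is `p < alpha` (default 0.01). Replicate seeds are
spawned sequentially from a per-scenario seed derived from the master seed
and a stable scenario key, which makes results bit-reproducible, invariant
to grid execution order, and prefix-consistent (the first k replicates of
a long run equal a k-replicate run). Flagged fits are dropped from the
affected test's denominator, with a 1% failure ceiling before the scenario
errors out. Default replicates: 1000 for power curves, 10,000 for type-I
studies. Grid defaults follow the study conventions: MAF 0.3 at both loci,
`r` in 0–0.8, `h2` in 0.002–0.010 (step 0.002), 2000+2000 samples for
medium-risk additive/dominant scenarios, 6000+6000 recessive, 4000/8000
for low risk.

## Data scan and fixture

The scan applies the same four test functions per variant (no separate
code path), complete-case per variant, with a folded-MAF floor (default
0.01) excluding rare variants from the genomic-control lambdas and a
`-log10(p) > 5` screening flag. Dosages come from a VCF (DS field
preferred, GT fallback) or a dosage-matrix TSV, aligned to the phenotype
sample order.

The synthetic fixture emulates the *shape* of a lung-cancer/smoking
dataset: ~2300 samples at a 1154:1137 case:control split, imputation-like
fractional dosages, and a non-negative right-skewed count trait built as
the square of a latent Gaussian (location 4.5, SD 1 — roughly
sqrt(cigarettes-per-day)), so the square-root transform in the reader
recovers a near-Gaussian trait exactly. Causal variants act through both
a direct log-odds path (default per-allele OR 1.8) and the latent trait
(default per-locus h2 0.02); observed causal dosages are noisy copies
(SD 0.25, clipped to [0,2]) of the causal genotypes. These effects are
deliberately stronger than the simulation grid so that a small panel
yields an unambiguous positive control. What the fixture does *not*
emulate: LD structure between panel variants, population stratification,
genotyping batch effects, or missingness patterns — a clean scan of it
shows pipeline correctness, not robustness to those artifacts.

## Numerical and test-design choices

* Monte-Carlo problem sizes were chosen so sampling error sits well inside
  each assertion's band: 1e6 draws for incidence (SE ≈ 2e-4 against a
  ±2e-3 band), 2e5 for heritability recovery, 1e5 for allele frequencies
  and the Fisher null mean, 5000 null replicates for distributional checks
  (shared across tests via a session fixture; the type-I check uses the
  first 2000, identical to a standalone 2000-replicate run by the prefix
  property), 1000 replicates per power scenario.
* The strict power-ordering check (IVW > Fisher > logistic under the
  dual-pathway model) is evaluated at `h2 = 0.006`, `r = 0.6`: at the top
  of both grids the combined tests saturate at power 1.0 and the ordering
  degenerates to a tie, so an unsaturated grid point is the informative
  one. Monotonicity in `r` is checked at `h2 = 0.010` over r ∈ {0, 0.4,
  0.8} with a 2-binomial-SE slack.
* Regression reference values in the unit tests were computed once with an
  independent GLM/OLS implementation (R's `glm`/`lm`) and frozen; the
  package itself never calls R.
* Ties, floors, degenerate inputs: p-value floor 1e-300 in Fisher's
  statistic; `r = 1` with equal MAFs makes the marker a copy of the
  disease locus (tested as an identity on the statistics); `h2 = 0` yields
  `beta1 = 0` exactly; `sigma2_E -> 0` makes the trait affine in genotype.

## Known limitations

Single-locus architectures only; no covariates beyond disease status in
test 2; no population-structure simulation; no mediation decomposition of
direct versus indirect effects; the trait-in-cases-only design is not
implemented. The IVW test assumes the two component effects point the
same way under the alternative — for a protective trait the direction
switch must be set, and for traits genuinely unrelated to disease the
combination sacrifices roughly half the power of logistic regression
alone, as the independent-pathway simulations show.
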