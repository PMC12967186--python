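# Methods

## Model and scope

`medmr` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics, with a two-step mediation decomposition on top. The
causal model for one exposure X, mediator M and binary outcome Y is the
standard instrumental-variable setup: each SNP j has an effect
&gamma;<sub>j</sub> on X; if the three IV assumptions hold (relevance,
no confounding, exclusion restriction), the per-SNP Wald ratio
r<sub>j</sub> = &beta;<sub>Yj</sub>/&beta;<sub>Xj</sub> estimates the
causal effect of X on Y (log odds ratio per SD of exposure), and the
five estimators pool the ratios under progressively weaker assumptions:

- **IVW** — inverse-variance weighted mean of the ratios with
  first-order weights w<sub>j</sub> = &beta;<sub>Xj</sub>²/se<sub>Yj</sub>²;
  algebraically the weighted least-squares slope of &beta;<sub>Y</sub> on
  &beta;<sub>X</sub> through the origin. Unbiased only when *all*
  instruments are valid. Default variance model multiplies the
  fixed-effect SE by max(1, &radic;(Q/(k−1))) (multiplicative random
  effects), so heterogeneity widens but never narrows the CI.
- **MR-Egger** — the same regression with a free intercept after
  orienting every SNP to &beta;<sub>X</sub> &ge; 0. The intercept
  estimates the average directional pleiotropic effect; inference is
  t(k−2) with the residual scale floored at 1.
- **Weighted median** — interpolated weighted median of the ratios;
  consistent while valid instruments hold > 50% of the weight.
- **Simple / weighted mode** — argmax of a Gaussian kernel density over
  the ratios (equal vs IVW weights), bandwidth
  h = &phi;·0.9·min(sd, IQR/1.349)·k<sup>−1/5</sup>, evaluated on a
  512-point grid spanning [min(r)−3h, max(r)+3h]; consistent when the
  largest cluster of instruments is valid.

SEs for the median/mode estimators come from a parametric bootstrap
(resampling &beta;<sub>X</sub>, &beta;<sub>Y</sub> from their sampling
distributions, 1000 replicates by default, seeded and bit-reproducible).
First-order Wald SEs ignore exposure-side noise (the NOME
approximation); exposure uncertainty enters the median/mode methods
through the bootstrap only. One visible consequence: when the true
effect is nonzero, Cochran's Q is slightly over-dispersed (rejection
~8% at nominal 5% in our clean-causal simulations), which is a property
of the convention, not of this implementation.

## Instrument processing

Instruments are selected at p < 1e-5 (strict), greedily LD-clumped
(r² < 0.001 within ±1000 kb, best p kept first), harmonized to a common
effect allele (swapped alleles negate the outcome beta and complement
EAF; strand complements are reconciled; palindromic A/T and C/G pairs
and duplicated SNP ids are dropped outright), and strength-filtered at
F = (&beta;/se)² > 10. F is the squared marginal z score — the standard
summary-data approximation needing neither sample size nor allele
frequency. LD is injected as a pairwise r² table (no reference panel is
bundled); absent pairs count as independent.

## Screening criterion

A pair "passes" iff IVW p < 0.05, all five ORs are strictly on the same
side of 1, Q p > 0.05 and Egger-intercept p > 0.05 (both gate thresholds
configurable); a passing pair is "starred" when ≥ 3 of 5 method p-values
are < 0.05. No multiple-testing correction affects pass/fail; Bonferroni
and Benjamini-Hochberg columns are emitted for context because a screen
of ~1400 exposures at nominal 0.05 expects ~70 false IVW hits — the
direction-concordance and diagnostic gates cut this (measured compound
null pass rate 0.037 vs 0.041 IVW-only at k = 10), but do not control it.

## Mediation

For each exposure&rarr;mediator&rarr;outcome pathway, the mediated
effect is &beta;1·&beta;2 (product of coefficients), its SE the Sobel
first-order formula &radic;(&beta;1²se2² + &beta;2²se1²) (Aroian
variant behind a flag), significance a normal Z-test, and the mediated
proportion 100·&beta;1&beta;2/total with a CI formed by dividing the
mediated-effect CI endpoints by the total effect — the convention that
exactly reproduces the published worked example this package ships as a
test (−10.4%, CI −1.03% to −19.8%). When mediated and total effects
oppose, the proportion is negative by design; nothing is clamped.
&beta;2 is the univariable mediator-on-outcome IVW estimate (no
multivariable adjustment for the exposure), a caveat when exposure and
mediator share genetic architecture. In the pipeline's own mediation
studies, mediator instruments additionally exclude SNPs associated with
the exposure (p < 1e-5), the standard guard against the mediator
instrument set leaking the direct path.

## Synthetic data generator

Summary statistics are sampled directly at the summary level — no
individual genotypes — giving exact control of the truth at negligible
cost. Per SNP: MAF ~ U(0.05, 0.5); true exposure effect
&gamma; ~ N(0, effect_sd²); mediator effect &theta;1&gamma; (+ its own
effect for mediator-specific loci, below); outcome effect
&theta;2&mu; + &theta;<sub>direct</sub>&gamma; + &alpha;, where &alpha;
is a direct (pleiotropic) effect carried by a configured fraction of
invalid instruments. Observed betas add Gaussian noise with
se = 1/&radic;(2p(1−p)n) for standardized continuous traits and the
effective sample size n<sub>eff</sub> = 4/(1/cases + 1/controls) for the
case-control outcome. Defaults mirror the scale of the real resources
the pipeline targets: exposure GWAS n = 14,824, mediator GWAS n = 8,299,
outcome 2,846 cases / 450,887 controls.

Key parameter choices:

- **effect_sd = 0.2** (SD units per allele): emulates the strong
  cis-acting protein/metabolite QTLs that dominate cytokine and
  metabolite instrument sets; implies mean instrument F ≈ 2×10² at the
  default exposure sample size, with a realistic minority of candidates
  falling below the p < 1e-5 selection threshold.
- **m_mediator_snps**: loci acting on the mediator directly (zero
  exposure effect). If every mediator instrument acted through the
  exposure (the degenerate default), the mediator-on-outcome Wald ratio
  would be &theta;2 + &theta;<sub>direct</sub>/&theta;1 for every SNP
  and the mediation decomposition would be unidentifiable; real
  metabolites have their own GWAS loci, which this models.
- **one_sided_effects**: draws &gamma; half-normal, i.e. instruments
  reported aligned to the exposure-increasing allele. Needed for
  *directional* pleiotropy scenarios: with symmetric &gamma; the ratio
  shifts &alpha;/&gamma; have random signs and cancel in expectation,
  inflating IVW's variance but not its mean.
- **LD** is modelled as blocks of tag SNPs whose true effects are
  attenuated by &rho; = &radic;r² and whose sampling noise correlates
  with the index SNP at &rho;, plus an explicit pairwise r² table —
  exactly the granularity clumping consumes.

What the generator does *not* emulate: realistic human LD maps,
population stratification, sample overlap between the two GWAS,
winner's-curse-corrected effect sizes, non-normal effect-size
distributions. Passing recovery tests therefore demonstrate correctness
of the estimators and plumbing under the stated model, not robustness
to those real-data complications.

## Validation studies and numerical choices

The `studies` module re-runs the full user-facing pipeline on simulated
data (problem sizes chosen to keep each study in the minutes range on
one core):

- **Calibration** (2000 replicates, k = 10): Cochran's Q on null
  homogeneous sets is exactly &chi;²(k−1) conditional on the observed
  exposure effects, so its type-I error sits at 0.05. The Egger
  intercept test is evaluated under balanced pleiotropy with spread
  comparable to the outcome sampling SE (N(0, 0.02²) on all
  instruments); when pleiotropy variance is far below sampling noise the
  residual-scale floor at 1 makes the test conservative by construction
  (type-I ≈ 0.025) — intended behavior, since the floor prevents
  anti-conservative CIs on under-dispersed data.
- **Recovery** (500 triplets, ~100 instruments each, &theta;1 = 0.3,
  &theta;2 = −0.5, &theta;<sub>direct</sub> = −0.1): mean IVW total and
  mediated proportion are compared to truth with tolerance
  max(3·MC SE of the mean, 1% of |truth|). The 1% floor reflects the
  analytic attenuation of IVW with in-sample instrument selection
  (regression dilution ≈ |&theta;|·mean(se<sub>x</sub>²)/mean(&beta;<sub>x</sub>²) ≈ 0.5%
  here), a property of the estimator that no replicate count removes.
- **Robustness** (200 replicates, k ≈ 60, 40% invalid weight,
  directional pleiotropy N(0.1, 0.05²)): IVW must be biased by > 10% of
  the truth while the weighted median's bias stays under half of IVW's.
  The weighted median keeps a finite-noise quantile-shift bias
  (≈ +0.05 on −0.25 here) that vanishes as SEs shrink; its exact
  consistency is tested separately at near-zero SEs.
- **Screen strictness** (2000 null pairs): the compound criterion's
  pass rate must fall below the IVW-only rate.

Degenerate inputs: a single instrument falls back to the flagged Wald
ratio for IVW; k < 3 withholds the regression/median/mode methods and
auto-fails screening (`insufficient_methods`); zero exposure effect
raises rather than producing an infinite ratio; identical ratios give
Q = 0, p = 1 and a zero-bandwidth mode that returns the common value;
bootstrap SEs are floored at the smallest positive float so p-values
remain defined. Ties in clumping are broken by p-value order with a
stable sort, making output order deterministic.

## Known limitations

Reported p-values are nominal; the screening stage deliberately mirrors
a no-correction design and should be interpreted accordingly. The
mediation decomposition assumes no exposure–mediator interaction and
uses univariable &beta;2. CIs use 1.96-SE normal intervals throughout
(t-based only for Egger). The LD model is a coarse block approximation;
clumping against a misspecified r² table silently yields correlated
instruments.
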