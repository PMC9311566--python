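# Methods

`bovrr` analyzes two longitudinal traits of crossbred beef cows — cow
weight at pregnancy diagnosis (CW, kg) and cumulative weight weaned
(WtW, kg) — with genomic random-regression models that separate additive
and dominance genetic effects, back-solve per-variant effects, and relate
the dominance side of productivity to pedigree and genomic indicators of
heterosis. Because no real herd ships with the package, a first-class
synthetic-herd generator produces every input under known truth; this
note documents the models, the generator, the numerical choices, and what
the tests do and do not establish.

## Trait records

A WtW record is created for every breeding exposure, starting with the
exposure intended to produce a calf at age 2: its value is the weaning
weight of the calf from that breeding (zero if none was weaned) plus the
sum of all previous calves' weaning weights, so WtW is non-decreasing
within cow and its final value is lifetime weaned weight. CW records are
the cow's weights at each pregnancy diagnosis. Ages are intended calving
ages on a half-year grid: a pregnancy advances the next intended age by
1.0 year, an open (non-pregnant) diagnosis shifts the cow to the opposite
breeding season (+0.5 year), and a second consecutive open diagnosis
culls her.

Fixed effects are an opportunity group — birth season crossed with the
maximum single-breed composition bin (<50%, 50–<75%, 75–<87.5%, ≥87.5%;
the lowest bin is ours, added so advanced-generation crosses with no
majority breed still have a group) — the intended calving age as a factor
over 0.5-year classes, and, for WtW only, a cumulative calf-sex covariate
(males weaned minus females weaned). Missing cow weights at a test are
skipped rather than imputed: CW is an observation, not a derived value.

## Relationship matrices

After QC (0.95 call-rate filters by variant then animal, then strict
MAF > 0.005 on the retained animals) and LD pruning (variants within
50 kb with |r| > 0.98 are dropped and mapped to the earlier retained
variant; |r| because the sign flips under allele relabeling), missing
calls are mean-imputed per variant and two GRMs are built from the same
calls:

* additive, VanRaden method 1: `G = M M' / (2 Σ p_j q_j)` with
  `M = calls − 2p`;
* dominance, genotypic dominance-deviation coding: per variant the codes
  are `−2p²` (call 0), `2pq` (call 1), `−2q²` (call 2), and
  `D = H H' / Σ (2 p_j q_j)²`. A configuration switch offers the centered
  0/1 heterozygosity-indicator coding instead.

Allele frequencies come from the analyzed animals themselves. Genomic
inbreeding is `F_g = diag(G) − 1`. Both scalings (`c_a`, `c_d`) are kept
because the back-solve uses `M M' = c_a G` and `H H' = c_d D` directly.

## Random-regression REML

For records `y_it` of cow `i` at age `t`,

    y_it = x_it' b + phi(t)' a_i + phi(t)' d_i [+ phi(t)' p_i] + e_it

where `phi` is the normalized Legendre basis (default order 1:
intercept + slope) on age standardized from [2, 8] to [−1, 1],
`a ~ N(0, K_a ⊗ G)`, `d ~ N(0, K_d ⊗ D)`, an optional
permanent-environment term uses an identity relationship, and residuals
are iid (homogeneous across ages by default — the simplest identifiable
choice). Order 1 is the default because smooth monotone variance trends
over age are representable there; the order is configurable.

Variance components are estimated by REML on the mixed-model equations.
Each iteration performs one Cholesky factorization of the MME coefficient
matrix, from which the restricted log-likelihood, the solutions, the EM
updates, the analytic gradient, and the average-information (AI) matrix
are all derived. The step rule: try the AI step at fractions 1 and 0.25
and accept the first that strictly increases the restricted likelihood;
otherwise try extrapolated EM steps (2x and 4x the EM direction);
otherwise take the plain EM step, which is monotone by construction. AI
trials pause for three iterations after a failure, since near a variance
boundary the quadratic model is persistently wrong. Convergence is
declared when the likelihood change falls below `tol` (default 1e-6;
the parameter-recovery studies use 1e-3, where the variance ratios are
stable long before the boundary crawl ends).

Numerical safeguards, all logged when triggered:

* `G` and `D` are rank-deficient whenever variants do not outnumber
  animals, so before inversion their smallest eigenvalue is pinned to
  1e-4 x mean diagonal (a no-op for well-conditioned matrices). This is
  the same order of perturbation as the common practice of blending a
  few percent of the identity into a genomic relationship matrix.
* `K` updates are projected to the PSD cone with an eigenvalue floor of
  1e-6 x var(y); smaller floors leave the MME numerically indefinite when
  a component collapses to the boundary (a singular `K_d` is the rule,
  not the exception, when true dominance is small).
* Fixed-effect design columns are reduced to full rank by pivoted QR.

BLUPs come from the converged MME solve; genotyped animals without
records receive predictions through `G`. Projections to age `t` are
`phi(t)'` times the coefficient BLUPs; variance fractions at age `t` are
`phi(t)' K phi(t)` over the total including the residual.

## Variant effects

Projected age-8 animal effects are distributed over variants by the
minimum-norm back-solve `alpha = M'(M M')⁻¹ u_a` (dominance analogously
with `H`), solving against `c_a G` rather than forming `M M'`. Effects
are standardized to z-scores (sample SD, ddof = 1). Significance: the
entries of the animal-effect vector are permuted B times (default 5000;
tests use 200–500), the back-solve and z-scoring repeated, and each
variant's observed |z| divided by the SD of its permuted z-scores is
referred to the two-sided standard normal. This is the only reading of a
"standard error of the z-scores" that yields a per-variant p; Bonferroni
selection multiplies p by the number of tested variants and thresholds at
0.05. Pruned variants inherit their representative's effect, p, and flag.

## Heterosis metrics

* `pHet = 1 − Σ_b s_b d_b` over base breeds of the sire and dam
  compositions, after expanding composites (Brangus = 3/8 Brahman + 5/8
  Angus; Santa Gertrudis = 3/8 Brahman + 5/8 Shorthorn; Beefmaster = 1/2
  Brahman + 1/4 Hereford + 1/4 Shorthorn; MARC II and III = four quarter
  breeds; ChiAngus = 0.8 Angus + 0.2 Chianina) and merging Red Angus into
  Angus.
* `gHet` = heterozygous calls / non-missing calls (missingness excluded
  from the denominator).
* ROH and HRR by the consecutive method: a run extends over consecutive
  variants while calls are in-state (homozygous for ROH, heterozygous
  for HRR), tolerating at most one missing call and no opposite-state
  calls per run, with inter-variant gaps capped at 1 Mb; runs must span
  ≥1 Mb (ROH) or ≥100 kb (HRR) and contain ≥15 / ≥3 in-state variants.
  Only the two length minima are externally fixed; the secondary
  parameters mirror common consecutive-method tooling and are exposed in
  configuration. Span is end minus start position; segments export to
  BED as 0-based half-open.

Cows are split into halves at the mean projected total merit
(additive + dominance, age 8) per trait and into the four quadrants (LL,
LH, HH, HL); ties at a mean go to the Low half. Group summaries report
mean and SE = SD/√n; dominance and total projections are regressed on
each indicator and reported as R² x 100.

## The synthetic herd

The generator emulates the structure the analysis assumes, not any real
breed's biology:

* **Breed divergence** — Balding–Nichols: breed frequencies are Beta
  draws around a shared ancestral `p0 ~ Uniform(0.05, 0.95)` with a
  single `F_ST` parameter (default 0.15; 0.2 in the heterosis scenario so
  purebreds carry chance runs of homozygosity at desk-scale marker
  density).
* **Pedigree** — a crossbreeding plan of purebred lines, F1s of adjacent
  breeds, backcrosses and three-way crosses over two generations;
  composite founders (e.g. Brangus) are declared by decomposed
  composition. Offspring compositions are parental averages; offspring
  sexes alternate within a mating so every cohort can parent the next
  stage.
* **Genotypes** — gene dropping with Haldane (no-interference)
  recombination at 1 cM/Mb over a desk-scale genome (default 5 x 100 Mb;
  scenarios that need ROH-detectable density use 3 x 50 Mb with ~20
  variants/Mb). Founder haplotypes are drawn per chromosome from breed
  frequencies, with each haplotype's breed label sampled from the
  founder's composition.
* **Events** — exposures from age 2 under the seasonal shift/culling
  rules above; conception is Bernoulli with a logistic probability
  shifted by the cow's standardized dominance value (this is the
  generator's heterosis-fertility link; its strength is a parameter);
  calf weaning weight is a base (230 kg) ± a sex effect (12 kg) + a
  scaled cow genetic contribution + Normal noise, weaned with
  probability 0.95.
* **Genetic values** — either *coefficient sampling* (coefficients drawn
  with covariance exactly `K ⊗ G` and `K ⊗ D`, so CW-style records follow
  the fitted model exactly — the mode used for parameter recovery) or
  *variant effects* (per-variant additive effects and dominance effects
  on the heterozygosity coding; a `directional_dominance` parameter sets
  the fraction of dominance variance carried by a heterozygosity-linked
  component, which is what makes dominance behave as heterosis).
  Coefficient covariances are intercept-dominant with positive
  intercept–slope covariance, scaled so `phi(8)' K phi(8)` hits the
  requested share of the age-8 phenotypic variance (default total
  2500 kg²).

What the generator does **not** emulate: breed-specific trait means for
real breeds, selection across generations, maternal genetic effects
separate from the cow's own values, genotyping error, imputation error,
and age-dependent residual variance. Tests passing on this generator
therefore establish that the estimators recover the generating process
and that the code implements the stated formulas — not that any
particular heritability or correlation magnitude would be observed in a
real herd.

## Problem sizes used in the checks

Parameter recovery runs 10 replicates per regime at 1000 cows x 1000
variants (regimes: age-8 additive/dominance ratios 0.5/0.05 "CW-like"
and 0.1/0.2 "WtW-like"), asserting mean recovery within ±0.1 and a
monotone restricted likelihood in every replicate. The end-to-end
heterosis scenario uses 400 cows x 3000 variants. Permutation
calibration uses 200 animals x 500 variants at B = 500. The tiny REML
oracle compares the optimizer against brute-force maximization of the
closed-form restricted likelihood at 30 cows. The acceptance script runs
the same computations at the same or slightly reduced replicate counts.

## Known limitations

* The AI step is dropped near variance-component boundaries rather than
  reparametrized; convergence there leans on (extrapolated) EM and a
  likelihood-change stop, so the converged `K_d` can sit on the floor
  eigenvalue rather than at exactly zero.
* The WtW records are cumulative sums, so their residuals are serially
  correlated within cow; the homogeneous-residual random-regression
  model is deliberately misspecified for them, exactly as a records-based
  analysis of cumulative production must be. Recovery checks therefore
  use the CW-style records; WtW fits are interpreted qualitatively.
* Permutation p-values are approximate (normal reference for |z|/SE);
  an empirical-rank alternative is available behind a flag.
* The consecutive-run scanner restarts after each emitted or failed
  candidate run; with a nonzero missing-call budget, overlapping
  alternative windows that re-use the budget differently are not
  revisited (matching the behavior of sequential consecutive-method
  implementations).
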