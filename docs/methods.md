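# Methods

`haploquant` estimates the quantitative-genetic basis of ordinal traits
scored on females from haplodiploid pedigrees — the motivating system is
the identity-signalling colour patterning of *Polistes fuscatus* paper
wasps, scored 0–4 on wild single-foundress colonies.  This note records
the models, the priors and numerical choices, what the synthetic-data
generator does and does not emulate, and known limitations.

## Haplodiploid relatedness

Females are diploid, males haploid.  Kinship is computed by recursion in
pedigree order: founders are mutually unrelated; a female's kinship with
an older individual averages her parents' kinships; a male's equals his
mother's; self-kinship is ½(1 + F) for females (F = kinship of her
parents) and 1 for males.  The additive relationship matrix over females
is A = 2φ, giving the characteristic r = 0.75 between full sisters
(sisters share their father's entire genome) and 0.5 between mother and
daughter.  Missing parents are treated as unique unrelated founders;
each simulated nest receives one implicit haploid sire (monogamy enters
through the data design, not the algebra).  Matrices are dense; the
intended scale is ≤ 5,000 individuals.

A gene-dropping Monte-Carlo estimator (unique founder allele labels,
random transmission, IBD counting over all four allele-slot pairs, with
per-entry standard errors) serves as an independent oracle for the
recursion in the test suite; it is never used for inference.

## The threshold animal model

An ordinal score y ∈ {0..K−1} is a censored Gaussian liability:

    y_i = k  iff  τ_k < l_i ≤ τ_{k+1}
    l = μ + a + Z_m m + Z_y y + e
    a ~ N(0, V_A S),  m ~ N(0, V_M I),  y ~ N(0, V_Y I),  e ~ N(0, I)

with S the haplodiploid additive relationship matrix.  Identification:
residual variance fixed at 1, first interior threshold fixed at 0,
remaining interior thresholds sampled.  Maternal identity is the dam id
(individuals with unknown dams get unique levels); the year effect is
indexed by birth-cohort label.

### Priors

* Variances: scaled inverse chi-square with scale 1 and degree of belief
  0.002 (weakly informative; configurable, and summaries are insensitive
  to a ten-fold change of scale — checked in the test suite).
* Bivariate additive covariance G_A: inverse Wishart, scale I, 2.002
  degrees of freedom.
* Threshold gaps: independent Gamma(2, 0.8).  A proper gap prior is a
  requirement, not a refinement: with a flat gap prior and the
  near-scale-invariant variance prior, the posterior is unbounded along
  the ridge on which liabilities, thresholds and variances grow together
  against the fixed unit residual, and a well-mixing sampler drifts to
  an additive proportion of 1.  The default is set by prior prediction:
  equal-frequency 5-category cuts have gaps near 0.55 × total liability
  SD, so Gamma(2, 0.8) (mean 2.5, SD 1.8) stays diffuse over total SDs
  from below 1 to roughly 10 — additive proportions up to ~0.99 — while
  penalizing degenerate zero gaps and the runaway ridge.  Published
  threshold-model estimates with upper intervals like 0.9999 are the
  signature of that ridge under flatter priors.

### Sampler

Gibbs sampling with blocks chosen for mixing on full-sibship designs;
every move leaves the stated posterior invariant:

1. **Thresholds**: joint random-walk Metropolis on log gaps with the
   liabilities collapsed out (ordinal likelihood of the linear
   predictor), followed immediately by an exact truncated-normal redraw
   of the liabilities — a valid blocked update of (τ, l).  The step size
   adapts toward ~0.3 acceptance during burn-in only.
2. **Liabilities**: inverse-CDF truncated-normal draws.
3. **Location effects**: intercept (flat prior); additive effects
   blocked in the eigenbasis of S, where their full conditional is
   diagonal (one O(n²) rotation per sweep); maternal and year levels by
   groupwise Gaussian updates.
4. **Exchange moves**: exact Gibbs updates along the directions that add
   δ to a group effect (intercept, a dam level, a cohort level) while
   subtracting it from the group's breeding values.  The linear
   predictor is unchanged, so the conditional is Gaussian in the two
   priors alone.  These reallocation moves break the severe coupling
   between V_A and V_M/V_Y — on a full-sib design 0.75·V_A of family
   variance is exchangeable with the maternal term.  Dam levels in
   different pedigree components are exactly S-orthogonal, so the
   updates run as a few batched rounds (one level per component per
   round).
5. **Variances**: conjugate scaled-inverse-chi-square draws, then a
   per-component ASIS (non-centred) rescaling: s = √V is proposed from
   its Gaussian likelihood-conditional with the effects held fixed in
   the non-centred frame and accepted against the induced prior.
6. **Global scale move**: a Metropolis step multiplying liabilities,
   location effects, thresholds (and variances by c²) by a common
   factor; the ratio reduces to the residual Gaussian term, the gap and
   variance priors and the transform's Jacobian.  It is O(n) and applied
   ten times per sweep so the weakly identified overall liability scale
   mixes as fast as everything else.

The bivariate sampler shares 1–3 with two-dimensional liabilities
(residual covariance fixed to I), updates the rotated effect pairs with
closed-form 2×2 algebra, and gives G_A an inverse-Wishart full
conditional.  Bivariate fits support only the additive term; they exist
to estimate genetic correlations r_G = G_A[0,1]/√(G_A[0,0]·G_A[1,1]).

Full conditionals are validated against grid-integration oracles on a
three-female pedigree, and the collapsed threshold move against a 1-D
grid posterior, in the test suite.

### Summaries

Posterior mode via a Gaussian KDE (Silverman bandwidth, 512-point grid);
95% intervals as shortest (HPD) intervals; variance proportions divide
each component by the sum of sampled components plus the fixed unit
residual, so proportions sum to one within every draw.  Effective sample
size and split-chain R-hat are computed per variance component.

## DIC model comparison

Four variants are fitted per trait — additive; +maternal; +year;
+maternal +year — and ranked by DIC = D̄ + p_D with the deviance
conditional on the sampled location effects, the convention of the
MCMC mixed-model package this analysis re-implements.  Two estimator
choices reduce Monte-Carlo noise to well below meaningful DIC
differences: D̄ averages the Rao-Blackwellized liability deviance
(analytic truncated-normal second moments given η and τ), and p_D is
the closed-form effective-parameter count tr(H) of the location hat
matrix at posterior-median variances (computed in the S-eigenbasis with
a Schur complement for the grouped terms).  The ordinal-probability
deviance of the observed categories is also implemented
(`deviance_scale="ordinal"`).

**A structural caveat, verified by simulation.**  On a design of
full-sibships, conditional DIC cannot penalize re-expressing family
variance: the maternal term can absorb up to 0.75·V_A of between-family
variance and fit the same liabilities with fewer effective parameters
(≈ one level per dam instead of n correlated breeding values), so on
purely additive data the maternal variants often win by tens of DIC
units even though the generating model has no maternal effect.  The
effect is a property of the conditional focus, not of estimator noise —
D̄ is identical across variants to within a few units while the entire
difference sits in p_D.  Variance-focused alternatives (liability
deviance marginal over location effects) were prototyped and are noisier
without removing the preference.  Consequently: a *detected* maternal
model (maternal data) is meaningful, but an extra-term win on its own is
weak evidence against a purely additive architecture; corroborate with
the variance-component posteriors (is V_M's interval away from zero?).
This caveat equally applies to published DIC rankings produced by the
conventional samplers this package re-implements.

## Mendelian segregation tests

Under haplodiploid monogamy a single-locus presence/absence trait can
only segregate 0:1, 1:1 or 1:0 among full sisters.  Nests with at least
20 phenotyped daughters are tested against the 50:50 null with a
continuity-corrected one-sample proportion chi-square,
χ² = 2(max(0, |k − n/2| − ½))²/(n/2) on 1 df; all-or-none nests are
classified but deliberately not tested.  The corrected statistic
reproduces the published per-nest p-values at printed precision for ten
of the twelve testable nests; the two remaining printed values (0.53 and
0.84) disagree in the last digit with every standard test, including the
exact binomial, and are treated as printing slips.  The correction makes
the test conservative: simulated type-I error at α = 0.05 is below
nominal for all n in 20–34.  An exact binomial cross-check utility is
provided.

## Synthetic data

The generator reproduces the study design: 83 single-foundress nests
allocated round-robin to four birth cohorts (2008–2011); brood sizes
from a truncated negative binomial (mean 9.3, dispersion 12, min 1);
one implicit haploid sire per nest; foundresses phenotyped alongside
daughters (~856 scored females); foundress birth cohort one season
before her nest; four foundresses drawn from prior-cohort broods (the
known mother-of-foundress links).  Liabilities are a + m + y + e with
a ~ N(0, V_A S) sampled per pedigree component (block Cholesky), m per
dam, y per cohort, e unit normal; scores count thresholds strictly
below the liability.  Default thresholds sit at equal-frequency
quantiles of the total liability SD; default variances are V_A = 9,
V_E = 1 (additive proportion 0.9, the modal published estimate for the
facial traits), V_M = V_Y = 0.  A separate single-locus mode (dam Aa or
aa, haploid sire A or a, dominant presence) calibrates the segregation
tests and is never mixed with the polygenic generator.

What the generator does **not** emulate: multi-foundress nests and
reproductive skew, worker drifting between nests, scorer error in the
ordinal assignments, non-additive (dominance/epistatic) genetic
variance, and trait-specific threshold asymmetries.  Passing recovery
tests therefore demonstrates internal consistency of the inference
under the stated model, not robustness to those features of real data.

## Problem sizes and determinism

Recovery checks and model-selection batteries run at the study's design
scale (83 nests × ~10 daughters, foundresses phenotyped) with
desk-scale chains of 6,000–10,000 iterations; the library default
(65,000 / 15,000 / thin 50) is sized for final analyses.  Every stochastic
path — simulation, gene dropping, both samplers — is driven by a single
seeded generator, and identical seeds reproduce byte-identical outputs.

## Known limitations

* Additive scaling for males (cross-sex relatedness on the phenotypic
  scale) is deliberately unsupported; all phenotyped wasps are female.
* Bivariate fits estimate no maternal/year components and fix the
  residual cross-trait covariance at zero (not estimable from single
  ordinal observations).
* The absolute liability scale is only weakly identified by ordinal
  data; variance *proportions* are the stable quantities, and the gap
  prior bounds — rather than removes — the upper tail of the scale.
* Dense relatedness algebra only; no sparse A-inverse machinery.
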