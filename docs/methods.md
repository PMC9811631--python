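# Methods

## The experiment the package models

A single legume host genotype is grown with rhizobial inocula drawn from a
panel of *S* strains, each available as a red- and a green-marked isogenic
variant.  Every block of a randomized complete block design contains one
one-strain pot per (strain, marker) combination (2*S* pots), two pots per
unordered strain pair with the marker assignment swapped between them
(*S*(*S*−1) pots), and a fixed number of uninoculated controls.  With the
default *S* = 8, 8 blocks and 2 controls per block this is 592 pots and 28
strain pairs.  (The one-strain treatments must appear under both markers for
the block size to come out at 74; the design generator follows that
arithmetic.)

Phenotypes live at three grains: the pot (shoot mass in grams), the
strain-within-pot (nodule occupancy: a strain scores 1 per nodule of its own
colour and 0.5 per mixed-colour nodule; its proportion is its score over the
pot total, undefined in nodule-free pots, which are excluded from proportion
analyses), and the nodule (colony-forming units per occupying strain, for a
dissected subset — by default the first two blocks).

## Variance partitioning (sge)

For two-strain pots, each trait is modelled as a Gaussian linear mixed model
with fluorescent marker as a fixed effect and random effects for focal-strain
genotype (DGE), competitor genotype (main SGE), their interaction (G × G),
block, and — for dyadic traits — pot:

* **nodule number**: two rows per pot (one per strain), unconstrained
  components, ordered-pair G × G, pot random effect for the within-pot
  dependence.
* **nodule proportion**: the two orientations of a pot are linearly dependent
  (shares sum to 1), so one row per pot is used, with the lexicographically
  smaller strain as focal.  DGE and SGE are constrained equal with
  focal–competitor correlation −1.  This is implemented by reparameterization:
  a single strain-effect vector entering +1 for the focal and −1 for the
  competitor strain, which is exactly equivalent to the correlated bivariate
  formulation and numerically simpler.  G × G is indexed by unordered pair.
  Identity scale (share residuals are close to symmetric and unimodal).
* **shoot mass**: one row per pot on the natural-log scale (mass is
  right-skewed and multiplicative); DGE = SGE with correlation +1, i.e. one
  strain effect entering +1 for each of the two strains; unordered-pair G × G.
  The marker covariate is the marker of the lexicographic focal strain (a
  reporting convention; a switch drops the marker term entirely).

Reported variance proportions follow the convention that a constrained model
lists DGE and SGE as separate rows carrying the same variance, which the
phenotypic total therefore counts twice (each observation receives the strain
effect through two incidence entries).

### REML engine

Estimation is restricted maximum likelihood over variance ratios
γ_k = σ²_k/σ²_e, optimized on the log scale (L-BFGS-B with analytic
gradients, two default starts at γ = 0.1 and 1.0, a floor of 1e−10 standing
in for the boundary at zero, ratios below 1e−8 reported as 0).  The residual
variance is profiled out.  Each evaluation reduces by the Woodbury identity
to one Cholesky factorization of a q × q matrix (q = total random-effect
levels, ≈ 530 for the dyadic model at full size), so a full fit takes well
under a second.  The reported log-likelihood is the complete error-contrast
density (including its constants and the |X′X| term), so it matches a
brute-force multivariate-normal computation to machine precision — the test
suite checks this, and agreement with closed-form ANOVA estimators on
balanced one-way layouts to 1e−6 relative error.

Each component is tested by removing it and refitting (fixed effects
unchanged): χ² = 2 Δ log-likelihood on 1 df, clamped at zero (discrepancies
within 1e−3 of zero are treated as boundary ties).  For a constrained model
the single shared strain parameter carries both the DGE and the SGE row, so
those rows report one identical test.  The χ²₁ reference is conservative
when the true variance sits on the boundary; no mixture correction is
applied, and the measured type-I error of the G × G test is accordingly
below nominal (~2% at α = 5%).

## Partner choice, sanctions (discrimination)

Strain genotypic means are unweighted means over pots (across blocks and both
marker variants; reciprocal-marker duplicates are not averaged first).
Discrimination tests are ordinary least squares of one mean column on another
with an F test of the slope on (1, S−2) df: nodulation success (one-strain
nodule number; two-strain nodule proportion) against one-strain shoot-mass
benefit — the benefit axis used everywhere — plus allometric variants
(nodules per gram, shoot per nodule, with undefined ratios excluded and
counted), an optional axenic growth-rate column supplied by the user, and the
sanctions regressions: per-strain mean CFU in single-colour nodules
(among-nodule) and per-strain mean CFU share within mixed nodules, computed
per nodule then averaged (intra-nodule), both restricted to two-strain pots.

## Benefit of partner choice (deviation)

For each two-strain pot, `deviation = (W_pair − m)/m` with
m = (W1 + W2)/2, where W1, W2 are the strains' one-strain genotypic means —
strain-level quantities, not block-matched values, because the neutral
expectation is defined per strain; W_pair is that pot's shoot mass (or shoot
mass per nodule in the per-nodule variant).  The statistic is scale-invariant
and zero exactly at the neutral point.  The pair's "more beneficial" strain
is fixed once from the global benefit ranking; ties break lexicographically
and are flagged.  Each pot contributes its own record (reciprocal-marker
duplicates are not averaged).  The test model is a linear mixed model of the
deviation on the proportion of nodules founded by the better strain, with
random intercepts for strain, competitor strain and block, fitted by maximum
likelihood; significance is a 1-df likelihood-ratio χ² against the
intercept-only mixed model (the χ² is reported rather than a Wald statistic).
A log-transform sensitivity analysis is not implemented: the statistic takes
negative values and no defensible shift is canonical, so the model is run on
the raw scale only.

## The synthetic-data generator

The generator emulates the study conditions: 8 strains × 8 blocks × 2
controls, a per-strain quality axis (default evenly spaced on [0, 1]) that
simultaneously drives host benefit, nodulation success and within-nodule
proliferation — the deliberate confounding that constitutes the
partner-choice/sanctions signal, severable via `choice_strength = 0`,
`couple_benefit_to_occupancy = False` or `cfu_link = 0` for null simulations.

* **Nodule scores.**  A focal strain's latent score is
  `T·logistic(c·(q_i − q_j)) + marker + d_i + s_j + g_ij + block + pot + e`
  with T = 16 expected nodules per pot, choice slope c = 3, and independent
  Gaussian components defaulting to 32/14/7/3/7/37% of a total variance of 9
  (DGE/SGE/G × G/block/pot/residual).  Counts are made tally-consistent by
  drawing a Poisson(1.5) mixed-nodule count and rounding singles so that
  `singles + 0.5·mixed` tracks the latent score; a pure-Gaussian mode skips
  the discretization for exact recovery experiments.  Scores are modelled
  (and generated) as Gaussian rather than Poisson deliberately: the analysis
  models counts with Gaussian residuals, and at a mean of ~8 per strain the
  discretization contributes ~1% of the variance.
* **Shoot mass** is log-normal: one-strain log-mean μ + β·q (μ = log 0.3 g,
  β = 1), controls at log 0.05 g; a two-strain pot's deterministic mean is the
  occupancy-weighted mixture of the two strains' one-strain expectations
  (neutral average when decoupled), plus strain effects with equal
  focal/competitor weight, unordered-pair G × G, block and residual terms on
  the log scale (2.9/2.9/6.3/10.9/77% of 0.25).
* **CFU.**  Single-colour nodule counts are log-normal with log-mean
  11.5 + q (≈1e5 at quality 0), sd 0.5; mixed-nodule totals are split with a
  Beta-distributed share whose mean is logistic in the quality difference.
  Dissection follows the study protocol: first `cfu_blocks` blocks, one
  nodule per one-strain plant, up to two singles and one mixed per two-strain
  plant.

All randomness flows from one seed through named substreams, so a config and
seed determine the dataset bit-for-bit.  Latent draws (effects, residuals,
discretization offsets) are stored for recovery tests.

**What the generator does not emulate.**  Real nodule counts are
overdispersed integers, not rounded Gaussians; greenhouse heterogeneity
beyond block effects, plant mortality and missing data are absent; and the
allometric ratio traits behave monotonically here, whereas in real data
within-strain dispersion lets both nodules-per-gram and shoot-per-nodule
rise with benefit (a Jensen-type effect) — the generator reproduces the
per-nodule direction, not the per-gram one.  Passing tests therefore
establish the correctness and calibration of the estimators under the
assumed model, not robustness to these departures.

## Calibration experiments and problem sizes

`rhizosge.experiments` packages the standard runs: (i) recovery — 50
full-design simulations at the 32/14/7/3/7/37 truth, fitting the dyadic
model; with only 8 strain levels the variance the drawn effects realize
fluctuates around its target by several points, so per-simulation accuracy is
scored against the realized shares (median |error| ≲ 2.5 points per
component) while unbiasedness is scored as the median estimate against the
generative truth; (ii) G × G type-I error over 500 simulations at a 4 × 4
design; (iii) deviation-model type-I error over 500 simulations at a 6 × 4
design with benefit decoupled from occupancy.  The reduced designs keep the
500-replicate runs in the tens of seconds; rejection behaviour at those sizes
is the quantity of interest, not a stand-in for the full design.  Measured
levels: the boundary G × G test rejects at roughly half nominal, and the
deviation model's ML likelihood-ratio test runs close to nominal with the
mild upward drift (~6–7% at α = 5%) expected of a maximum-likelihood ratio
test on ~120 records with three variance components.

## Numerical and design choices

* Optimization over log-ratios with a floor rather than a constrained
  solver; boundary estimates are reported as exact zeros.
* Dense q × q linear algebra throughout — adequate to a few thousand
  observations; no sparse machinery.
* The canonical orientation for pot-level traits (lexicographic focal) is a
  pure convention; the signed parameterization makes the likelihood
  orientation-invariant.
* Genotypic means are unweighted pot-level means; a pooled-counts mode for
  intra-nodule CFU shares is available via `genotypic_means` on raw tables.
* Zero-nodule pots: excluded from proportion and deviation analyses (the
  quantities are undefined), counted and logged.
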