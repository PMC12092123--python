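# Methods

This note documents the models, conventions and numerical choices behind
`venomphylo`, and what the synthetic-data generator does and does not
emulate.

## Units and label matching

Trees are rooted and time-calibrated with branch lengths in millions of
years (Myr), the native unit of divergence-time databases; the
prey-specificity statistic is reported in hundreds of millions of years
(Hmya) by dividing MRCA ages by 100. Divergence-time operations require
ultrametricity, checked as equal root-to-tip depths within a relative
tolerance of 1e-6. Taxon labels match case-insensitively after trimming,
with spaces and underscores interchangeable. Tables are UTF-8 CSV with
"." decimals, and every schema violation reports its row and column.

## Diet scoring

Qualitative abundance labels map to proportions 0.60 / 0.20 / 0.05 / 0.01
(major / common / uncommon / rare). When a species' report carries both a
qualitative label and a quantitative proportion for the same prey taxon,
that proportion (the mean, if several) re-calibrates every
qualitative-only taxon with the same label — this reproduces the published
worked example, where a qualitative-only "common" group receives 0.21
rather than the 0.20 default. The rule is switchable
(`calibrate=False`) to plain defaults, since the underlying scoring
walk-through admits either reading. Estimates are then divided by their
sum; profiles store full float precision and must total 1 within ±0.01.

Displayed weights truncate toward zero at 3 decimals, the convention of
the source tables this echoes (0.21/1.45 = 0.1448 is shown as 0.144).
The tabulated column total is the sum of the displayed entries and may
fall slightly below 1; it is validated against the stated "100% ± 1%"
band rather than digit-for-digit, because the published row mixes
truncation and rounding across entries and no consistent rule reproduces
every printed digit.

Diet class richness counts distinct prey classes (≤ 12) with positive
weight. Inferring a diet from a congener is an explicit copy requiring
the donor species to be named — the original inferences were case-by-case
literature judgements that code should not automate.

## Prey specificity (D)

D is the diet-weighted mean divergence time between the assay model
organism and the prey taxa. Divergence is the age of the most recent
common ancestor (not the patristic path, which is twice that on an
ultrametric tree); a `metric="patristic"` switch supports sensitivity
checks. Prey taxa recorded at class/order rank resolve to the named clade
on the reference tree; a model organism inside the prey clade is at
divergence 0, the conservative reading given that within-clade distances
are unobservable at the rank resolution of diet data. Weights are
renormalized to sum exactly to one before weighting, so D is a true
weighted mean bounded by the smallest and largest per-prey divergences.

## Allometry

Length (mm) converts to mass (g) as mass = coefficient · length^2.6 with
coefficient 1.0 by default — the conversion formula as published carries
no coefficient, so the default preserves it verbatim and the coefficient
is user-configurable. Scaling exponents are ordinary least squares on
log10–log10 scale with a t-based 95% interval (n − 2 df); OLS on logs is
a deliberate simplification standing in for an unspecified GLM
family/link. On noiseless power-law data the interval collapses to the
point estimate.

## Phylogenetic mixed model

The animal model y = Xβ + Za + Zs + e with a ~ N(0, σ²ₐA),
s ~ N(0, σ²ₛI), e ~ N(0, σ²ₑI). A is the Brownian-motion correlation
matrix: entry (i, j) is the shared root-to-MRCA path length divided by
total tree depth, diagonal exactly 1. Both random terms use the same
species-incidence matrix Z: the animal term carries phylogenetic
structure, the species term absorbs repeat-measure variance.

All conditionals are conjugate, so the sampler is plain Gibbs:

* β | rest ~ N((XᵀX)⁻¹Xᵀ(y − Za − Zs), σ²ₑ(XᵀX)⁻¹) under an improper
  flat prior;
* a | rest from the precision matrix A⁻¹/σ²ₐ + diag(counts)/σ²ₑ (one
  Cholesky per sweep; the species-effect conditional is diagonal);
* each variance from its inverse-gamma conditional.

"Flat non-informative" variance priors are realized as inverse-gamma
(0.001, 0.001), the weakest conventional conjugate choice; both shape and
scale are configurable per component, and `VariancePrior.strong(v)` pins
a component near a known value (used by the generalized-least-squares
oracle test). Default chain settings are 2 400 000 iterations, 40 000
burn-in, thinning 100, 3 chains — the published protocol, which yields
more than 1000 retained draws per parameter. The test suite and examples
use documented scaled-down chains (typically 20 000 iterations, thinning
16, one chain), chosen so the full parameter-recovery study completes on
a desktop; posterior means at these lengths agree with the GLS oracle to
within Monte-Carlo error. Every chain draws from its own
`SeedSequence`-spawned stream, so runs are bit-reproducible.

Summaries report posterior means, equal-tailed 95% credibility intervals
(matching the common default of the original tooling, not HPD), the
CI-excludes-zero significance rule, per-draw heritability
h² = σ²ₐ/(σ²ₐ + σ²ₛ + σ²ₑ) — the three-component denominator is the
default because the source analysis does not state one; an
animal + residual option exists — the Gelman–Rubin R-hat
(√(((n−1)/n·W + B/n)/W)) when ≥ 2 chains ran, and rank-normalized
effective sample sizes. Categorical fixed effects carry explicit
reference levels (injection route baseline IP; silk reference
non-silk-hunter). Rank-deficient designs fail fast, naming the collinear
columns via pivoted QR.

## Ancestral states

Binary-trait Mk model with likelihood by Felsenstein pruning. ER uses the
closed form P01(t) = (1 − e^(−2qt))/2; ARD uses the 2-state matrix
exponential in closed form. The root is weighted by equilibrium
frequencies (ER: ½, ½; configurable to observed frequencies). The ER rate
is optimized on log10 scale by bounded Brent — the likelihood is flat in
the rate for large rates, which traps linear-scale minimizers on a
boundary — with bounds [1e-9, 100/tree-depth]; ARD starts Nelder–Mead
from the ER solution. ER is the default for a binary trait at modest
sample sizes; ARD remains available. Marginal (not joint) node
probabilities come from the up-down algorithm, equivalent to re-rooting
at every node; partial likelihoods are rescaled to avoid underflow. When
all tips share a state the rate fit sits at the lower boundary and every
node is reconstructed in that state with probability ≈ 1.

## Synthetic data

The generator mirrors the structure of the comparative dataset the
pipeline targets, with these defaults as the study conditions:

* **Tree**: Yule (pure-birth) with the crown split at the root, rescaled
  to 300 Myr root depth; 75 tips.
* **Diets**: per-species Dirichlet(1) weights over a random subset of the
  12-class prey universe; subset size 1 + Poisson(3), giving a median
  diet class richness of 4, the empirical median diet breadth.
* **Prey reference tree**: a fixed calibrated tree over the 12 prey
  classes plus model organisms (mouse, cricket, housefly), with depths
  loosely patterned on published arthropod/vertebrate timescales
  (root 700 Myr). It is illustrative, not authoritative.
* **Traits**: log10 body length ~ N(1.0, 0.35²) mm (≈ 3–60 mm); mass via
  the length^2.6 law; silk use evolved on the tree under ER Mk with rate
  0.004 /Myr (a slowly-evolving trait, a few expected transitions per
  root-to-tip path).
* **LD50 assays**: 1 + Binomial(4, 0.35) assays per species (mean ≈ 2.4;
  64 diet-covered species ⇒ ≈ 153 records), model organism uniform among
  the three, route uniform among that organism's routes (vertebrate:
  IP/IV/SC, invertebrate: thorax/abdomen). log10 LD50 follows the mixed
  model exactly, with effect sizes anchored to the reported magnitudes:
  slope 0.4 on D, route contrasts 2.01/1.01, zero mass and silk effects.
  Variance components default to σ²ₐ = 0.05, σ²ₛ = 0.10, σ²ₑ = 0.25 —
  round values chosen once so that all three components are estimable at
  ~150 observations while residual noise dominates.
* **Yields**: log10 yield = 0.75·log10 mass + N(0, 0.3²), 60 measures
  over 47 species.

A dataset-level seed is split into fixed per-component sub-streams
(tree, silk, diets, traits, assays, yields, subsets), so regeneration is
byte-identical and adding one component never perturbs another.

What the generator does **not** emulate: literature heterogeneity in
reporting quality (qualitative labels are only exercised through the
worked example and unit fixtures, not generated), correlations between
diet and phylogeny (diets are drawn independently of the tree),
measurement error in divergence times, venom chemistry, or non-Gaussian
residuals. Passing recovery tests therefore show that the estimators are
correct under the model's own assumptions — not that real literature
data satisfy those assumptions.

## Known limitations

* The mixed model is Gaussian-response only, one response at a time.
* The two random terms share the species grouping; with a single
  observation per species, σ²ₛ and σ²ₑ separate only through their
  priors.
* h² near zero is estimated with upward bias at small n because the
  inverse-gamma prior keeps σ²ₐ positive; the null-recovery test bounds
  the posterior mean below 0.1 at 60 species rather than at zero.
* Clade-resolved prey taxa use the clade's MRCA age to the model
  organism, identical for all members; species-level prey resolution is
  outside the scope of the rank-level diet data.
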