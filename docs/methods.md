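# Methods

This note records the statistical models the package implements, the
conventions and defaults it fixes where the underlying methods leave
choices open, what the synthetic-data generator does and does not
emulate, and known limitations.

## Phylogenetic regression (PGLS)

The core model for each nucleus is a log-log allometry with an additive
binary regime term:

    log y_i = alpha + beta * log x_i + Delta * g_i + eps,
    eps ~ N(0, sigma^2 * C(lambda))

`C` is the Brownian-motion covariance implied by the tree: `C[i, j]` is
the depth of the most recent common ancestor of species i and j, in the
tree's time units (millions of years). Pagel's lambda multiplies the
off-diagonal entries; lambda = 0 is a star phylogeny (ordinary
regression), lambda = 1 full Brownian dependence.

Estimation whitens by the Cholesky factor of `C(lambda)` and solves OLS
in the whitened space. Conventions fixed here:

* **sigma^2** is profiled at its ML value RSS/n inside the likelihood;
  coefficient standard errors use the unbiased RSS/(n − p), and the
  group-term p-value is a two-sided t-test with n − p degrees of
  freedom (p = rank of the design matrix).
* **lambda** is maximised over [0, 1] by bounded Brent search seeded
  from a 101-point grid, with both endpoints evaluated explicitly
  (profiles are very often maximised at a boundary); tolerance 1e-6.
* **AIC** counts every estimated parameter: the regression coefficients
  plus sigma^2 plus lambda (k = 5 for the additive models, since lambda
  is estimated independently per regression). Competing models for the
  same response are labelled Best / Tied / No with the conventional
  2-unit support window, and only significant models enter the ranking.
* **R^2** is 1 − RSS/TSS in the whitened space, with TSS taken about
  the GLS (phylogenetically weighted) mean. PGLS R^2 has no unique
  definition; this is the conventional whitened-space one.
* **Effect size**: the intercept difference Delta is scaled by the
  maximum value of the predictor (1 for binary regimes) and
  back-transformed, `effect% = 100*(exp(Delta*max) − 1)`. Because the
  response is a natural log, this exactly inverts a multiplicative
  volume shift: inflating focal-species volumes by (1+e) yields
  effect% = 100e. Effect sizes are reported as 0 when the group term is
  not significant at alpha = 0.05 (two-sided).

## Trait engineering

Individual-level tables are reduced in a fixed order: left/right
hemisphere columns are averaged within an individual, individuals are
averaged within a species, and the species mean volume is then
log-transformed (log of the mean, not mean of logs).

The compound allocare score is the sum of seven non-negative component
scores (male/other provisioning, male/other carrying, allonursing, male
protection, communal work); the no-carry variant drops the two carrying
components. Discretization into cooperative breeders uses exact 1-D
two-cluster k-means: in one dimension the optimal partition respects the
sort order, so an exhaustive scan over the n − 1 sorted split points
finds the global within-cluster-SS minimum deterministically — no random
restarts, no dependence on initial centroids. The reported break point
is the midpoint between the two boundary observations, matching
interval-style breaks. `elicit_care` is the elementwise OR of the
cooperative-breeder and domesticated flags.

## Phylogenetic signal

**Blomberg's K** is the observed ratio MSE0/MSE (mean squared deviation
from the phylogenetically corrected mean over the variance of
phylogenetically corrected residuals) divided by its Brownian
expectation `(tr C − n / sum(C^-1)) / (n − 1)`. Permutation p-values
shuffle trait values across tips; all permutation and simulation
p-values in the package use the add-one estimator
`(1 + #extreme) / (N + 1)`, which cannot return zero.

**delta** for binary traits follows the entropy-based construction: fit
a symmetric 2-state Markov model by ML (rate bounded in log-space),
compute marginal ancestral-state probabilities at internal nodes by the
standard up-down algorithm, reduce each node's distribution to a
linearised entropy in [0, 1] (for two states, 2·(1 − max prob), clipped
to [1e-4, 1 − 1e-4]), fit Beta(a, b) to the node entropies by ML, and
report delta = b̂/â. The original formulation averages over a Bayesian
posterior of ancestral reconstructions by MCMC; the ML version here is
deterministic given the data and considerably cheaper. Absolute delta
values are therefore not comparable to MCMC-based ones, but the
significance test — tip-label randomisation, p = proportion of
randomised delta ≥ observed — applies the same approximation to both
sides, so p-values remain interpretable.

## Wheatsheaf index

Traits are standardised to unit variance (multi-trait input is combined
by Euclidean distance). Each pairwise phenotypic distance is penalised
for relatedness:

    D'_ij = D_ij * (1 + rho_ij),    rho_ij = C_ij / sqrt(C_ii * C_jj)

so phenotypic similarity between close relatives (rho near 1) counts
less toward convergence than similarity between distant species (rho
near 0). W is the mean of D' over all pairs divided by its mean over
focal pairs. The reference R implementation was not available to copy
the weight form from; this (1 + rho) inflation implements the stated
principle and is the package's fixed convention.

The test bootstraps species with replacement within the focal and
non-focal strata. Pairs formed by two copies of the same resampled
species are excluded from both means — such self-pairs have distance
exactly zero by construction and otherwise bias W upward (with them
included, the null rejection rate roughly doubles; with them excluded it
sits at the nominal 5% in simulation). The 95% CI is the 2.5/97.5
percentile interval of the bootstrap W values; the expectation of W
under non-convergence is estimated by recomputing W for randomly drawn
focal sets of the observed size on the original data, and p is the
add-one proportion of bootstrap replicates that fail to exceed that
expectation. If all focal phenotypes are identical W is +inf (reported
with a warning).

## Phylogenetic ANOVA

The classical one-way F statistic is computed on the species values; its
null distribution comes from traits simulated under Brownian motion on
the tree, with the rate estimated from the data by REML (the quadratic
form of the residuals about the phylogenetic mean divided by n − 1).
Pairwise post-hoc comparisons use pooled-variance |t| statistics
referred to their own simulated nulls, Holm-corrected by default (the
correction is configurable, including "none"). Group labels enter as an
arbitrary categorical; every level must be non-empty.

## Ancestral states

Under Brownian motion tips and ancestors are jointly Gaussian, so the ML
estimate at each internal node is the conditional expectation
`mu + C_at C_tt^-1 (y − mu)`, where mu is the GLS phylogenetic mean and
`C_at` the ancestor-tip shared-path matrix. This equals the phylogenetic
mean of the tree re-rooted at each node (the construction the test suite
uses as an independent oracle) and is linear in the tip values. The
pipeline reconstructs the raw volume ratios L/BLA and B/BLA by default
(the quantities displayed on painted trees); a log-ratio option exists
because ratios are not themselves Brownian — this is a descriptive
smoothing, not a generative model of the ratio.

## Synthetic-data generator

The generator reproduces the *statistical structure* of the motivating
17-species design, not its actual species values:

* An ultrametric pure-birth (Yule) tree, simulated by explicit
  exponential waiting times (including a final waiting time, so no
  terminal branch has zero length) and rescaled to depth 170 Ma —
  roughly the span of a mammal-wide sample.
* log BLA evolves by Brownian motion with tip s.d. 1.8 natural-log
  units, emulating the several-orders-of-magnitude volume range from
  shrews to humans; this strong allometric spread is what drives the
  R^2 ≥ 0.97 values the regressions show.
* log L and log B follow the allometry with slope 1, baseline volume
  fractions 0.28 and 0.46 of BLA, injected shifts +0.353 / −0.298 in
  the six focal species, and Brownian residuals with tip s.d. 0.05
  (within-lineage deviations from the allometry are small, and this
  keeps the group term detectable at n = 17, mirroring the motivating
  design). AB is the remainder BLA − L − B, so the three nuclei sum to
  the BLA exactly and anatomical nesting can never be violated; with
  the default fractions the two shifts cancel almost exactly in L + B,
  so AB carries no induced shift. AC = BLA/u with u around 0.6.
* Three focal species are labelled cooperative breeders and three
  domesticated, disjoint, chosen uniformly at random on the tree.
  Allocare component sums are drawn in [3.8, 5.0] for cooperative
  breeders and [0.2, 2.0] for the rest, with 10–20% of each sum on the
  two carrying components; the generator *verifies* that k-means
  discretization of both the full and no-carry sums recovers exactly
  the designed breeders and raises rather than adjusting if a draw
  violates this (or any positivity constraint). Over thousands of
  seeds the failure rate is zero at the defaults.
* Optional individual-level expansion adds per-individual lognormal
  noise (default CV 3%) and left/right hemisphere columns for testing
  the aggregation path.

What the generator does **not** emulate: the real topology of the
mammal tree (focal species are placed at random, whereas real
domesticates/cooperative breeders cluster taxonomically to some
degree), measurement error correlated across nuclei within a study,
literature heterogeneity between volumetric sources, and the actual
allocare scoring of real species. Passing tests therefore demonstrate
that the estimators recover truth under the assumed generative model,
not that the biological conclusions are robust to violations of it.

## Problem sizes and seeds

The test suite and the acceptance script run desk-scale versions of the
stochastic checks: 300–1000 replicate studies for recovery and type-I
error, 500 Brownian replicates for K calibration, 100 convergence and
150–200 null datasets for the Wheatsheaf and ANOVA calibrations, 1000
bootstrap iterations per Wheatsheaf test, and 50 random trees for the
ancestral-state oracle. The pipeline defaults mirror the much larger
iteration counts of the motivating study (100,000 permutations for K,
10,000 iterations for delta, the Wheatsheaf bootstrap and the ANOVA
null) and are configurable. Every random draw descends from a single
configured seed through spawned numpy generators, so all outputs,
including permutation p-values, reproduce bit for bit.

## Known limitations

* Only Pagel's lambda covariance is offered (no Ornstein-Uhlenbeck or
  early-burst models), and no measurement-error variance in PGLS.
* delta is implemented for binary traits only, and its absolute scale
  differs from the MCMC-based original (see above).
* The Wheatsheaf penalisation form is the package's own fixed
  convention for the stated principle; W values from other
  implementations may differ by a bounded factor.
* Regressing a nucleus against the whole complex (AC) retains the
  part-whole overlap present in the motivating design; the package does
  not subtract the response from the predictor.
* No confidence intervals on ancestral-state estimates, and no
  stochastic character mapping.
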