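# Methods

## Problem

Random forests are widely used to rank SNPs in case-control association
studies, and their variable-importance measures are often credited with
finding gene-gene interactions (epistasis). `epiforest` is a simulation
laboratory for asking precisely what those measures can and cannot do: it
generates case-control data in which the interaction structure between two
designated SNPs is known and tunable, grows classification forests, and
measures how often single-variable importances *capture* the interacting
SNPs (rank both highly) and how often pairwise importances *detect* the
interaction itself (rank the pair highly).

## Disease model

Genotypes are minor-allele counts g in {0, 1, 2} drawn under Hardy-Weinberg
equilibrium, g ~ Binomial(2, f). A dataset has two interacting SNPs (allele
frequency `maf_I`), `n_marginal` marginal-only SNPs (`maf_M`, default 5) and
`n_noise` noise SNPs whose frequency is drawn fresh per dataset from
Uniform(0, 1) (used as-is, not folded to <= 0.5). The binary phenotype
follows an additive logit model

    logit P(case) = beta_0 + beta_M * sum(marginal genotypes)
                    + m1*beta_I*g1 + m2*beta_I*g2 + i12*beta_I*g1*g2

where the multipliers (m1, m2, i12) encode the interaction model:

| model            | m1 | m2 | i12 | interpretation                          |
|------------------|----|----|-----|-----------------------------------------|
| interaction_only | 0  | 0  |  1  | no marginal effects, pure interaction   |
| modifier_snp     | 0  | 1  |  1  | one marginal effect, amplified jointly  |
| no_interaction   | 1  | 1  |  0  | marginal effects only                   |
| redundant        | 1  | 1  | -1  | joint effect no larger than each alone  |
| synergistic      | 1  | 1  |  1  | marginal effects plus interaction       |

The interaction term is the product of the additive codings; the implied
logit increments over baseline for genotype cells (1,1), (1,2), (2,2) are
1, 2 and 4 times `beta_I`, which reproduces the published penetrance table
for the interaction-only model at `beta_I = 0.4` (0.35 baseline; 0.44, 0.54,
0.72 in the variant cells after truncation to two decimals — the printed
values are truncations, not roundings, and comparisons against them
truncate). Penetrance = expit of the linear predictor, so every cell lies in
(0, 1) and the table is transpose-symmetric for all models except
`modifier_snp`.

`beta_0` is calibrated so that the expected prevalence equals
`target_prevalence` (default 0.5, i.e. balanced cases and controls). Because
the noise SNPs carry no effect, the expectation is computed exactly by
enumerating the joint genotype distribution of the 7 effect SNPs; the
marginal-only block enters only through its genotype sum, which is
Binomial(2*n_marginal, maf_M), so the enumeration is 3 x 3 x (2m+1) cells.
Brent root-finding on the strictly monotone map beta_0 -> prevalence gives
|error| < 1e-10. Tests verify the shortcut against the literal 3^7-cell
enumeration. A fixed printed baseline (e.g. probability 0.35) can be
supplied instead of calibrating; the published baseline for the printed
table is not exactly the balanced-prevalence solution, so both modes exist.

## Linkage disequilibrium mode

Real-panel LD (originally resampled from reference haplotypes) is replaced
by a parametric Gaussian copula: a latent normal vector with first-order
autoregressive correlation (adjacent-pair correlation `decay`, so
rho_ij = decay^|i-j|, always positive definite for decay in [0, 1)) is
thresholded at the normal quantile of each SNP's allele frequency (drawn
Uniform(0.05, 0.2), matching a low-frequency panel); two haplotypes sum to
a genotype. `calibrate_decay` bisects on `decay` until the simulated mean
pairwise genotype r-squared reaches a target (default 0.14, a typical dense
low-MAF panel value); D' is reported alongside. For genotype input, D is
estimated by the composite (Burrows) covariance cov(g_i, g_j)/2, unbiased
under HWE, and normalized by its frequency-bound maximum; r-squared is the
squared allele-count correlation. Monomorphic SNPs make both statistics
undefined, so such pairs are skipped and counted. In LD mode the
exact-enumeration calibration no longer applies (effect SNPs are dependent
with panel frequencies), so `beta_0` is solved on the realized linear
predictors of the drawn genotypes — exact for that dataset and monotone in
`beta_0`.

What the generator does **not** emulate: genuine recombination hotspots and
block structure, frequency-dependent LD decay, genotyping error, missing
data, population stratification, and higher-order epistasis. Passing tests
therefore certify the behaviour of the importance measures under the stated
generative model, not under the full complexity of real cohorts.

## Random forest

Bagged CART for binary outcomes, written against flat node arrays with a
numba kernel per tree. Bootstrap of n rows with replacement (out-of-bag set
recorded per tree); at each node a fresh draw of `mtry` candidate variables
without replacement; genotypes are ordered numeric dosages, so candidate
thresholds are 0.5 and 1.5; the split maximizes the count-weighted Gini
decrease n_p*G_p - n_L*G_L - n_R*G_R (the count-weighted convention only
rescales importances by a constant; it is stated for reproducibility). Trees
are grown to purity.

Numerical and policy choices:

* **Zero-gain splits are allowed at impure nodes.** A balanced checkerboard
  (pure two-way interaction) offers no first split with positive gain;
  forbidding zero-gain splits would make "grown to purity" unattainable and
  blind the forest to pure interactions by construction. The decrease is
  computed in a sum-of-squares form and clamped at zero so exact ties
  compare equal.
* **Tie-break**: among candidate splits with equal decrease, the earliest
  candidate in the node's seeded shuffle order wins (and threshold 0.5
  before 1.5 within a candidate) — deterministic given the tree seed. A
  fixed index-preferring rule is *not* used: exact ties in the discrete
  count-based decrease are common in small nodes, and preferring low
  indices measurably inflates the importance of low-index columns (an
  order-of-magnitude excess in the null capture fraction). The reference
  `best_split` function, which receives an explicit candidate set, breaks
  ties by the smallest (variable, threshold) for a stable contract.
* **Candidate fallback**: the mtry draw is the first mtry entries of a
  seeded full shuffle of all variables. If none of the drawn candidates can
  split an impure node (all constant within the node), the remaining
  shuffled variables are scanned in order and the best split of the first
  splittable one is used. Leaves are therefore impure only when their
  in-bag covariate rows are identical. Without the fallback, rare candidate
  draws would strand impure nodes and break the purity contract.
* **Ties in leaf majorities and forest votes** resolve by the seeded RNG
  stream, so results are deterministic but unbiased.
* **Seeding**: one master seed per experiment; per-replicate and per-tree
  seeds derive through `numpy` SeedSequence spawning, so any replicate or
  tree is reproducible in isolation.

## Importance measures

*Gini importance*: per tree, sum the Gini decreases of nodes splitting on
x_i; average over all trees (trees without x_i contribute 0). The per-forest
totals conserve: summing over variables gives the mean per-tree total
impurity decrease.

*Permutation importance*: per tree, OOB accuracy minus OOB accuracy after
permuting x_i's OOB values, one fresh permutation per (tree, variable);
averaged over trees with non-empty OOB sets. Scores are raw unscaled
accuracy differences (no SD normalization, no z-scores) and may be negative.

*Pairwise permutation importance (PPI)*: both columns of a pair are permuted
simultaneously. By default the **same** row permutation is applied to both
columns, which preserves the pair's joint genotype distribution while
breaking its association with the outcome; independent permutations are
available behind a flag since "simultaneously" admits both readings.

*Joint importance by maximal subtrees (JMST)*: an x_i-subtree is maximal if
no larger x_i-subtree contains it; its depth is the distance of its root
from the tree root. The second-order (x_j, x_i) depth is the shallowest x_j
split inside any maximal x_i-subtree, in edges from that subtree's root.
Per tree the depth is normalized by tree height; trees lacking the nested
structure (or of height zero) contribute a penalty of 1.0. The pair score
is the mean of the (i,j) and (j,i) per-forest averages; lower = more
important. The normalization and penalty conventions are this package's own
(the original maximal-subtree implementation does not document its exact
choices); both are isolated in one function.

*Joint variable importance (JVIMP)*: the noise-up procedure drops an OOB
observation down the tree until it reaches the root of any maximal subtree
of a listed variable; every further split resolves by a fair coin flip
(child choice unweighted — randomizing proportionally to in-bag counts is
the other defensible reading). V_S = mean per-tree (OOB accuracy minus
noised-up accuracy); the interaction score of a pair is
(V_i + V_j) - V_ij. All noise-up queries of one forest reuse the same
per-tree coin-flip streams (common random numbers), which reduces Monte
Carlo variance and makes V_ij collapse exactly to V_i when x_j is absent.
Ranking uses |score| by default (the sign convention for "interaction
effect" is not canonical); signed ranking is available.

## Ranking and top-k statistics

Rank 1 is most important in each measure's own direction. Ties take the
worst rank of their group (competition ranking): many inert SNPs share an
exact zero score, and awarding capture on such ties would flatter every
measure. Capture fraction: share of replicates with both interacting SNPs'
ranks <= k (k = 2..10). Detection fraction: share with the true pair's rank
<= k (k = 1..10) within the evaluated pair set — pairs containing noise
SNPs are excluded from pairwise rankings, leaving the C(7,2) = 21 effect
pairs in the default design. A marginal-top-k criterion tracks whether all
5 marginal-only SNPs (k = 5..15) or all 10 of their pairs (k = 10..20)
reach the top k. All fractions are non-decreasing in k by construction.

A caution about null baselines: even with all effects at zero, the two
designated SNPs are **not** rank-exchangeable with the noise SNPs, because
they keep a fixed MAF while noise frequencies are Uniform(0, 1) and
importance depends strongly on MAF (intermediate-frequency SNPs are split
more and accumulate more impurity decrease). The exchangeable-ranks value
C(k,2)/C(100,2) for the null capture fraction holds only on a panel where
every SNP follows the same frequency law; the null-calibration checks use
such an equal-frequency panel for that comparison.

## Experiment grid and problem sizes

The full design crosses beta_M, beta_I in {0.4, 0.8}, MAF_M, MAF_I in
{0.2, 0.4}, mtry in {10, 50} and the 5 models (160 cells; with the five
measures, 800 scenario-measure combinations), each at n = 1000 individuals
and 100 SNPs. Appended variants: 2 marginal-only SNPs; 2493 noise SNPs; LD
mode with the null and all four effect combinations.

The package's default execution profile is desk-scale: 30 replicates and
200 trees per forest, with the production profile (100 replicates, 500
trees) available through configuration. The test suite and the acceptance
script evaluate the directional contrasts on the sub-grid where they are
sharpest (interaction-only vs no-interaction at beta = 0.4, MAF = 0.2),
with 30 and 15 replicates respectively; null-calibration checks use 200
replicates of a reduced forest (n = 300, 40 trees). These sizes keep every
Monte Carlo check against an explicit standard-error budget (3-4 SE) while
remaining single-machine runs.

## Known limitations

* Fraction-of-replicates curves at desk scale carry binomial noise of
  roughly 0.09 (30 replicates); only directional statements are tested.
* The forest is binary-classification only: no regression, survival or
  probability trees, no terminal-node-size tuning, no subsampling without
  replacement.
* Pairwise measures are restricted to two-way interactions, and the
  evaluated pair set must exclude noise pairs to stay tractable.
* The LD simulator reproduces target mean r-squared, not the full joint
  distribution of a sequenced panel; D' is an emergent property of the
  copula, not a calibrated one.
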