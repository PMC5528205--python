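# Methods

This note documents the statistical machinery implemented in `commstruct`,
the assumptions behind the synthetic-study generator, and the numerical
choices made where the design was genuinely open.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Community structure statistics

**Patristic distances and MNTD.**  For a rooted tree with branch lengths in
time units, the patristic distance between tips is the sum of branch lengths
along the connecting path, computed as
`d(a,b) = depth(a) + depth(b) − 2·depth(MRCA(a,b))`.  The mean nearest taxon
distance of a plot is the average over its species of the distance to the
closest co-occurring species.  Trees with absent branch lengths are refused
rather than defaulted to unit lengths: a silent unit assumption would corrupt
every standardized effect size downstream.

**Null models and SES.**  Each plot's statistic is compared against `n_iter`
(default 999) randomizations of species identities over the regional pool:

- *shuffle* — a uniform permutation of pool labels applied to the community
  (membership structure untouched, identities relabelled);
- *richness* — a uniform k-subset of the pool, k = plot richness.

For a single plot's presence-based statistic the two nulls coincide in
distribution (the relabelled membership of one plot is a uniform k-subset);
both are exposed because the choice matters for multi-plot co-occurrence
structure and because published analyses with Phylocom rarely record which
model was run.  SES uses the sample (n−1) standard deviation of the null
replicates.  The **NTI** negates the z-score so that positive values mean
phylogenetic clustering; trait SES keeps the raw sign so positive values mean
functional overdispersion.  Two-tailed rank p-values use the +1 correction,
`p = 2·min(r_low, r_high)/(n_iter+1)` capped at 1, so p is never 0.  A null
with zero standard deviation yields a degenerate-flagged record, not an
exception.

**Importance values and weighting.**  In mixed tree/shrub vegetation,
abundance alone misstates ecological importance, so species weights are
importance values, the mean of relative abundance, relative height, and
relative coverage within the plot (they sum to 1 per plot).  Trait dispersion
metrics (variance, mean pairwise distance, mean nearest-neighbour distance;
the range is unweighted by definition) accept these weights.  In the null,
weights are treated as properties of the plot's occupancy slots while trait
values are shuffled over the pool — observed and null statistics therefore
sit on the same weighting footing, and the SES isolates identity
randomization.  NTI is presence-based (unweighted), since the phylogenetic
distances already encode pairwise relationships.

## Blomberg's K per community

K is the standard ratio statistic: with C the phylogenetic covariance matrix
(shared root-to-MRCA path lengths), GLS ancestral mean
`â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)`, `MSE0 = (x−â)ᵀ(x−â)/(n−1)`,
`MSE = (x−â)ᵀC⁻¹(x−â)/(n−1)`, and
`E_BM = [tr(C) − n/(1ᵀC⁻¹1)]/(n−1)`, then `K = (MSE0/MSE)/E_BM`.  On a star
tree C is a scaled identity and K = 1 exactly for any non-constant trait; the
implementation is cross-checked against R `phytools::phylosig` in the test
suite.  K is invariant to affine transforms of the trait.

Significance uses the variance of phylogenetically independent contrasts as
the permutation statistic: trait values are permuted across tips, and low
observed contrast variance indicates signal (one-tailed, +1-corrected).  The
contrast recursion is linear in the tip values, so the permutation test
precomputes the (n−1)×n contrast operator and evaluates all permutations as a
matrix product.  Polytomies (common in age-smoothed supertrees) are resolved
arbitrarily with zero-length branches for the contrast statistic only, with
zero lengths then replaced by 1e-8 × tree depth (logged); the K formula
itself uses C directly and needs no resolution.  The convention of permuting
the contrast variance rather than K itself was adopted because it is the
standard implementation choice and the two are monotonically related on a
fixed tree.

Signal is assessed *per community*: the pool tree is pruned to each plot's
species (patristic distances among retained tips are preserved exactly;
degree-2 nodes are collapsed).  Plots with fewer than 3 species yield
degenerate-flagged records, since contrast variance needs at least two
contrasts to be meaningful.  Per-community K values are then regressed on
environment factors (OLS slope, R², F-test p), with counts of plots with
K > 1 and with significant permutation p reported alongside.

Intraspecific trait variance is not modelled; each species carries one value
per analysis.

## BLADJ age smoothing

Undated nodes receive ages by even interpolation: processing nodes from the
root down, each undated node is placed on the chain from its nearest dated
ancestor to its nearest dated descendant (fewest intervening nodes, ties
broken by traversal order; tips are dated at age 0 unless fixed), and ages
are spaced evenly along that chain.  Because assigned nodes immediately count
as dated, a pure chain receives the classic evenly spaced solution, and the
procedure is idempotent on a fully dated tree.  Branch lengths are recomputed
as `age(parent) − age(child)`; mutually inconsistent anchor ages (an ancestor
younger than a descendant) are rejected up front.

## Hierarchical variance partitioning

Goodness of fit is the OLS R² (responses — MNTD and CWMs — are continuous).
All 2^k predictor subsets are fitted (k ≤ 12 enforced).  The independent
contribution I_i of predictor i is the Chevan–Sutherland average, over
hierarchy levels, of the mean R² gain from adding i to subsets lacking it —
a Shapley-value decomposition, so **Σ I_i = R²(full model)** exactly (tested
to 1e-9) and the I_i are order-invariant.  The joint contribution is
J_i = marginal R²_i − I_i; with correlated predictors Σ(I+J) equals the sum
of marginal R²s, not the full-model R² — the efficiency identity belongs to
the I's alone.  Reported percentages are I_i/ΣI·100 (summing to 100); raw
values are also emitted.  Near-duplicate predictors (|r| > 0.999, e.g. a
temperature variable computed deterministically from elevation) are refused,
and rank-deficient subset fits fall back to a pseudo-inverse solution with a
warning.

## PCA compound gradients

PCA is an eigendecomposition of the correlation matrix of standardized
factors; scores are the standardized data projected on the loadings, so
scores have zero mean per axis and diagonal covariance equal to the
eigenvalues.  Axis signs are fixed by making each axis's largest-|loading|
factor load positive — sign flips change no inference, and the convention
makes outputs reproducible.

## Synthetic-study generator

The generator emulates a 40-plot elevational survey (1,140–3,480 m) with a
regional pool of 389 species, ~148 of them observed — the observed pool is a
uniform subset so the community-to-pool ratio (38%) sits inside the 30–60%
band where null-model power is adequate.

- **Pool phylogeny** — pure-birth (Yule) tree, rescaled to unit depth.  One
  time unit is therefore "one tree depth"; MNTD values are on that scale.
- **Traits** — Brownian motion (variance σ²·branch length, default σ² = 1),
  simulated by preorder accumulation; several independent traits per study,
  the first being the assembly-relevant (focal) trait.
- **Environment** — elevation is uniform over its range; each factor is
  Gaussian with a configured correlation to elevation taken by default from
  the survey's correlation structure (SWC 0.895, TN 0.470, AN 0.456,
  NN −0.005, RAP 0.492, pH 0.349, slope −0.131).  A single-latent-driver
  Gaussian copula keeps the implied matrix positive definite; the latent
  correlation is pre-corrected for the probit-to-uniform attenuation
  (√12/(2√π) ≈ 0.977) so *realized* Pearson correlations hit their targets.
  Marginal scales are realistic field values (SWC in g/g, pH units, etc.).
  WCD (summed coverage) is computed from the assembled communities, so its
  near-zero correlation with elevation is emergent, not configured.
- **Assembly** — per-plot richness uniform on [10, 25] by default.
  *Neutral*: uniform draws without replacement.  *Filtering*: inclusion
  probability ∝ exp(−(x−opt(e))²/2τ²) with τ = σ_pool/strength and a linear
  elevation-to-optimum sweep across the pool trait range (drawn without
  replacement via Gumbel-top-k).  *Limiting similarity*: sequential uniform
  draws rejecting candidates within δ = strength·σ_pool/k of any resident,
  with a 200-restart budget and an explicit error suggesting lower strength
  if a plot cannot be seated.  Strength 0 reduces every regime to the same
  neutral code path.
- **Abundance/height/coverage** — log-normal (abundance rounded up to ≥ 1).
  Their coupling to the focal trait is configurable; the default is 0
  (ecological equivalence), the cleanest neutral baseline for calibrating
  the weighted SES machinery.  Non-zero coupling exercises IV weighting
  against informative weights.

What the generator does *not* emulate: spatial structure and dispersal
limitation, intraspecific trait variation, multi-trait joint filtering
(compose single-trait runs instead), observation error in abundance or
coverage, and realistic taxonomic tree shape (a Yule tree is more balanced
than a supertree grafted on a taxonomy).  Passing calibration and recovery
tests therefore demonstrates correctness of the statistical machinery under
the stated model, not robustness to these field complications.

**Trend-recovery scenario.**  To emulate a trait whose phylogenetic signal
strengthens with elevation, per-plot trait values evolve under an
Ornstein–Uhlenbeck pull toward a common optimum whose strength *declines*
with elevation: strong pull at low elevation erases phylogenetic signal
(K < 1), while high-elevation communities remain near-Brownian (K ≈ 1),
producing a positive K-vs-elevation slope.  OU transitions use the exact
conditional normal (mean θ+(x₀−θ)e^{−αt}, variance σ²(1−e^{−2αt})/2α), which
reduces bit-exactly to Brownian motion at α = 0.

## Reproducibility and problem sizes

One root seed governs a run.  Every (stage, plot, trait) combination derives
its own substream via a blake2b hash of the seed and scope names, so results
are independent of plot processing order and identical seeds reproduce
bundles checksum-identically (manifest records input hashes, seed, and
package version).

Validation problem sizes were chosen to give stable Monte-Carlo estimates on
a single CPU: null-model calibration uses 400 neutral plots on a 100-species
pool at 999 nulls/plot (binomial SE of a 5% rejection rate ≈ 1.1 points);
K calibration uses 100 Brownian replicates on 128-tip trees and 1,000
permutation-test replicates at 199 permutations; regime recovery uses 40
plots per strength level; trend recovery uses 100 replicates of 12 plots ×
16-species communities from 48-tip pools.  The rejection-rate calibration
deliberately sets the observed pool equal to the full pool: a subsetted
realized pool (as in the headline scenario) leaves each plot marginally
calibrated but correlates plots through the shared subset, inflating the
variance of an empirical rejection rate without biasing its mean.

## Known limitations

- Label-shuffle and richness nulls only; abundance-matrix swap algorithms
  (independent/trial swap) and spatially constrained nulls are out of scope.
- NTI is presence-based; an abundance-weighted MNTD variant is not provided.
- Hierarchical partitioning is limited to 12 predictors by design.
- The CLI accepts any user-supplied dated newick; taxonomy-based megatree
  assembly and molecular dating are out of scope.
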