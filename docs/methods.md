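# Methods

This note records the modelling and numerical choices behind `pseudoclust`,
with their defaults and the reasoning where a choice was genuinely open.

## Model

Observed data are log-transformed expression values y_j ∈ R^T for genes
j = 1..n_g over T cells, mean-centred per gene (the zero-mean base GP below
makes centring the natural preprocessing; `read_expression` does it by
default).  A cell order **o** is a permutation of the T cells; capture times
are coarse stage labels used only for initialisation and subsampling, never
as a hard constraint on the order.

### Order → pseudotime

τ(**o**) is the cumulative Euclidean path length between consecutive cells
along the order (in the full expression space), normalised to τ₁ = 0,
τ_T = 1.  This is a deterministic function of the order — required so that
order proposals change the likelihood — and approximates geodesic distance
along the trajectory by the distance along the current ordering itself.  A
graph-based geodesic (shortest paths over a neighbourhood graph) is *not*
used: it is order-independent and would make the pseudotime map insensitive
to the sampled orders.  Degenerate data with zero total path length fall
back to a uniform grid rather than erroring.

### Hierarchical GP mixture

Pseudotime profiles are modelled in two levels with squared-exponential
covariances Σ(τ, σ², l):

- cluster mean: GP(0, Σ(τ, 3a² + ε, L));
- gene around its cluster mean: GP(μ, Σ(τ, a²·a₁, 1) + a²(1−a₁) I_T).

The gene-level length scale is fixed at 1 on the [0,1] pseudotime scale:
gene-specific deviations are smooth distortions over the whole trajectory,
while the cluster mean's own length scale L is free.  a₁ ∈ (0,1) splits
around-mean variation into smooth signal (a₁) and white noise (1−a₁).  The
3a² + ε parameterisation ties the mean amplitude to the gene-level
amplitude with a free offset ε.

Cluster assignments follow a Dirichlet process; collapsing the cluster means
gives, for a cluster of n_c genes, a zero-mean Gaussian with covariance
I⊗A + J⊗B, A = Σ(τ, a²a₁, 1) + a²(1−a₁)I, B = Σ(τ, 3a²+ε, L).  The
block-structure identities (see README) reduce all determinants and solves
to T×T operations; the likelihood cache additionally reuses the Cholesky
factor of A and per-gene solves so a Gibbs candidate costs O(T²).

### Priors

- α ~ Gamma(shape 2, rate 4) — read as shape/rate (mean 0.5), the common
  convention for DP concentrations;
- a₁ ~ Beta(4, 1) — most around-mean variation is smooth;
- log a ~ N(0, 1), log L ~ N(0, 1) — weakly informative on the unit
  pseudotime scale;
- ε ~ Exponential(rate 10) — a small positive offset;
- orders carry a uniform prior over permutations.

The priors on a, L and ε were an open design point; the lognormal/
exponential forms keep every parameter positive with heavy enough tails to
reach data-driven scales.

## Sampling

One iteration = one Metropolis order move + one collapsed Gibbs sweep over
genes + hyperparameter updates.

- **Order moves** (mixture probabilities, defaults): adjacent swap 0.4,
  segment reversal 0.3, single relocation 0.25, full reversal 0.05.  All
  four draw positions uniformly, making each proposal symmetric (log
  proposal ratio 0).  No iteration-dependent proposal schedule is used.
- **Allocations**: collapsed Gibbs; gene j joins existing cluster c with
  probability ∝ n_c·exp(Δ_c) or a new cluster ∝ α·exp(Δ_new), Δ the change
  in summed cluster marginal log-likelihoods.  Empty clusters are removed
  and labels compacted every sweep.
- **Hyperparameters**: random-walk Metropolis on log a, log L, log ε and
  logit a₁ (Jacobians included), step size 0.1, batch-adapted during
  burn-in towards 25–40% acceptance with a diminishing adaptation factor
  and frozen afterwards.  α uses the standard two-step auxiliary-variable
  (Beta auxiliary + two-component Gamma mixture) update.
- **Initialisation**: order sorts cells by capture time with a random
  shuffle inside each stage; all genes start in one cluster; L, a₁, ε, α
  start from prior draws.  The amplitude a starts moment-matched at half
  the data standard deviation (the marginal variance of an observation is
  ≈ 4a²): starting a at a prior draw leaves a long transient while the
  random walk drifts to the data scale, which shows up as spurious
  non-stationarity in the log posterior.
- **Defaults**: 3000 iterations, burn-in fraction 0.5, thinning 5.
- Chains are bit-for-bit reproducible from (seed, config, data); numerical
  failures of a proposal's Cholesky reject that proposal and are logged.

Cholesky factorisations add no jitter on first attempt; on failure a
relative jitter of 1e-6·trace/T is added, retried once at 10×, then a
numerical error is raised.

### Subsampled parallel chains

Each chain receives an independent stratified subsample (default 10 cells
per capture time) and an independent seed, both derived from the master
seed.  When cells come from distinct groups (e.g. different cell lines),
chains are assigned to groups round-robin and subsample within their group,
so heterogeneous datasets contribute separate chains that are only merged
at the PSM stage.

## PSMs, summaries, combination

The PSM of a chain is the co-clustering frequency matrix of its retained
samples — symmetric, unit diagonal, entries in [0,1], and positive
semidefinite (an average of partition indicator matrices, each PSD); this
also makes PSMs admissible kernels.

A summary clustering cuts an average-linkage dendrogram of 1 − PSM at the
k ∈ 1..k_max maximizing PEAR,

    PEAR = (Σ_{i<j} I_ij π_ij − S_I S_π / C) / (½(S_I + S_π) − S_I S_π / C),

the posterior expected adjusted Rand index of labels against the PSM.  Ties
resolve to the smallest k; a vanishing denominator scores 0 ("no better
than chance").  Average linkage and k_max = min(n_g − 1, 20) are defaults,
both exposed.

Chain combination:

- **mean** — element-wise average (convex combination, stays a PSM).
- **DPM+PEAR / PY+PEAR** — genes are observations; chain m contributes a
  feature block (its PSM columns, centred per feature).  A DP (or
  Pitman–Yor, discount 0.25) mixture over genes is fitted by collapsed
  Gibbs (1000 sweeps, first half burn-in) with Gaussian components (fixed
  noise variance 0.04, mean-prior variance 0.25) and a Bernoulli(½)
  inclusion indicator per block: an included block follows the
  cluster-specific means, an excluded one a single shared component.  A
  chain's weight is its normalised posterior inclusion frequency.  Chains
  whose PSM carries no shared structure gain nothing from the partition and
  are excluded, hence downweighted.  The concentration is resampled
  (auxiliary-variable update for the DP; random-walk Metropolis under the
  Pitman–Yor partition probability), with the same Gamma(2, 4) prior.
- **lmkk** — localized multiple kernel k-means: alternating minimisation of
  Tr((I − HHᵀ) K_θ) with K_θ(i,j) = Σ_m θ_im θ_jm PSM_m(i,j), H the top-k
  eigenvectors of K_θ and each per-gene weight row θ_i updated by an exact
  simplex-constrained quadratic program (the Hessian is diagonal, so the
  KKT system is solved by bisection on the dual variable — no external QP
  solver).  Stops at relative objective change < 1e-6 or 100 iterations;
  the objective is monotone non-increasing.  Hard labels come from
  k-means++-seeded k-means in the embedding H.  A failed weight update
  falls back to a uniform row and is logged.  The number of clusters for
  lmkk is chosen by scanning k = 2..k_max and keeping the labelling with
  maximal PEAR against the mean PSM.

## Convergence reporting

Three criteria, thresholds configurable (defaults in parentheses):

1. mean pairwise entry-wise distance between chain PSMs over gene pairs
   (≤ 0.1);
2. minimum ARI between the all-chain summary and every leave-one-chain-out
   summary (≥ 0.8);
3. potential scale reduction on the log-posterior series (≤ 1.1).  Chains
   sharing the same cells are compared directly (classic across-chain
   R-hat, floored at 1).  Chains on different subsamples target different
   posteriors whose log-density levels are not comparable, so each chain is
   instead split in half and the worst within-chain R-hat is reported.

The third criterion is deliberately conservative: the log posterior mixes
slowly because order moves are local, so it can stay elevated after the
partition distribution has stabilised.  The PSM-level criteria are the
operative check on the clustering; the R-hat flags residual order-space
non-stationarity.

## Synthetic data generator

The generator produces trajectory data with known structure while avoiding
the inference model's own parameterisation (single-level GP means rather
than the hierarchical form, so recovery tests are not circular):

- k cluster mean trajectories drawn from a GP on a uniform grid over [0,1]
  (squared-exponential, Matérn-3/2 or linear; mean length scale 0.25);
- per gene: a smooth GP deviation (variance 0.09, length 0.3) plus white
  noise (sd 0.2), cluster labels assigned round-robin;
- capture times in consecutive blocks (thirds at the 60-cell default), with
  the within-stage order destroyed by `permute_within_capture`;
- defaults: 20 genes, 5 clusters, 60 cells, 3 capture times.

"High" separability draws means with variance 9 and redraws until the
smallest between-mean L2 distance is at least 5× the largest total
gene-level deviation norm — the benchmark is solvable by construction
(a plain correlation clustering of the noiselessly ordered data recovers
the truth, property-tested).  "Low" separability uses unit-variance means,
doubled noise and no separation constraint, so cluster structure is only
accessible through the ordering.  The linear kernel's marginal variance
grows as scale·t² and vanishes at the trajectory start, so its amplitude
is inflated 9× to give line trajectories a spread comparable to the
stationary families.

Dropout zeroes currently non-zero entries independently with a global or
per-gene-group rate, optionally sparing a designated cell subset
(`protected_factor`); dropout probability is deliberately independent of
expression level, which perturbs the data more aggressively than an
intensity-dependent model.  `simulate_large` supports thousands of cells by
drawing GP draws on a 256-point coarse grid and interpolating with cubic
splines, adding noise in cell blocks; nothing larger than
(genes × cells) is ever materialised.

What the generator does not emulate: count-level noise (negative binomial /
UMI sampling), batch effects, branching trajectories, or genes with no
pseudotemporal signal.  Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated generative
conditions, not performance on raw counts or branching biology.

## Problem sizes and defaults used in the shipped experiments

The packaged experiments (test suite and `scripts/acceptance.py`) use
20 genes, 5 clusters, 60 cells, 3 capture times, 4 chains of 3000
iterations on 30-cell subsamples, and 20 replicates for the weighting
study.  These sizes were chosen so that each experiment completes in a few
minutes on a single core while leaving the qualitative conclusions
(near-perfect recovery with clear separation; graceful degradation under
dropout and covariance misspecification; uniform weights for exchangeable
chains and downweighting of inconsistent ones) clearly measurable.

## Known limitations

- Single chains mix slowly over orders; inference quality rests on
  combining many subsampled chains, not on any one chain's convergence.
- The pseudotime map assumes a single non-branching trajectory.
- The DPM/PY weighting model fixes its Gaussian noise and prior variances;
  grossly different PSM scales (e.g. chains with very few retained samples)
  may need those adjusted.
- PEAR maximisation searches only cuts of one dendrogram; it is a good,
  fast heuristic rather than an exhaustive search over partitions.
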