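# pseudoclust

Joint Bayesian inference of pseudotemporal cell orderings and gene clusters
for single-cell expression data.

## The problem

Clustering genes by their expression dynamics along a trajectory usually
proceeds in two steps: estimate a pseudotime ordering of the cells, then
cluster genes as if that ordering were known.  Pseudotime estimates carry
substantial uncertainty, and conditioning on a single ordering produces
over-confident, sometimes wrong, gene clusters.  `pseudoclust` samples cell
orders and gene partitions *jointly*, so the reported co-clustering
probabilities integrate over ordering uncertainty.

## The model

Input is a genes × cells matrix of pre-processed, log-transformed expression
values y_j (one vector per gene over T cells) plus a coarse capture time per
cell.  A cell order **o** (a permutation) is mapped deterministically to
pseudotimes τ(**o**) ∈ [0,1] by cumulative Euclidean distance between
consecutive cells in expression space.

Genes are partitioned by a Dirichlet-process mixture of hierarchical
Gaussian processes.  With Σ(τ, σ², l) the squared-exponential covariance
σ² exp(−(τ_i−τ_j)²/2l²):

- cluster mean:  μ ~ GP(0, Σ(τ(**o**), 3a²+ε, L)), clusters drawn from a
  DP(α, G₀) over these means, α ~ Gamma(2, 4);
- gene j in the cluster:  y_j(**o**) ~ GP(μ, Σ(τ(**o**), a²·a₁, 1) + a²(1−a₁)·I_T),
  a₁ ~ Beta(4, 1) splitting around-mean variation into smooth signal and
  white noise.

The cluster means are integrated out analytically.  The covariance of a
stacked cluster of n_c genes is I⊗A + J⊗B (A the gene-level, B the mean-level
block), whose determinant and inverse reduce to T×T operations:

    logdet = (n_c−1)·logdet A + logdet(A + n_c B)
    yᵀM⁻¹y = Σ_j (y_j−ȳ)ᵀA⁻¹(y_j−ȳ) + n_c ȳᵀ(A+n_c B)⁻¹ȳ

so likelihood cost is O(T³) per cluster, independent of cluster size.

MCMC alternates symmetric Metropolis moves on the order (adjacent swap,
segment reversal, single relocation, full reversal), a collapsed Gibbs sweep
over gene allocations (Chinese-restaurant-process conditional with marginal
likelihood ratios), and random-walk updates of (a, L, a₁, ε) plus the
standard auxiliary-variable update of α.

For more than a few dozen cells, many short chains are run on stratified cell
subsamples (equal numbers per capture time).  Each chain yields a posterior
similarity matrix (PSM): the frequency with which two genes co-cluster.
PSMs are combined by

- `mean` — element-wise average;
- `DPM+PEAR` / `PY+PEAR` — weighted average, with chain weights from a
  Dirichlet-process / Pitman–Yor mixture over genes with per-chain
  feature-selection indicators (chains inconsistent with the shared
  structure are downweighted);
- `lmkk` — localized multiple kernel k-means over the PSMs (each PSM is a
  valid kernel), learning per-gene per-chain weights.

A single summary clustering is cut from a combined PSM by maximizing the
posterior expected adjusted Rand index (PEAR).

## Worked example

```python
import numpy as np
import pseudoclust as pc

design = pc.SimulationDesign(n_genes=12, n_clusters=3, n_cells=60, rng_seed=0)
dataset = pc.simulate_dataset(design)
dataset = pc.permute_within_capture(dataset, np.random.default_rng(1))

config = pc.MCMCConfig(n_iter=3000, n_chains=4, cells_per_capture=10, rng_seed=2)
summaries, traces, psms = pc.run_pipeline(dataset.data, config,
                                          methods=("mean", "PY+PEAR"))

for method, sc in summaries.items():
    ari = pc.adjusted_rand_index(sc.labels, dataset.true_labels)
    print(f"{method:8s} clusters={sc.n_clusters}  PEAR={sc.pear_score:.3f}  "
          f"ARI vs truth={ari:.3f}")
print("PY chain weights:", np.round(summaries["PY+PEAR"].chain_weights, 3))

report = pc.convergence_report(
    traces, psms, lambda ps: pc.summary_clustering_pear(pc.mean_psm(ps)))
print(f"mean pairwise PSM distance: {report.mean_pairwise_psm_distance:.4f}")
print(f"leave-one-chain-out ARI (min): {report.loo_ari_min:.3f}")
print(f"log-posterior split R-hat: {report.per_chain_logpost_gr:.3f}")
```

Output (about a minute on one core):

```
mean     clusters=3  PEAR=0.978  ARI vs truth=1.000
PY+PEAR  clusters=3  PEAR=0.978  ARI vs truth=1.000
PY chain weights: [0.25 0.25 0.25 0.25]
mean pairwise PSM distance: 0.0175
leave-one-chain-out ARI (min): 1.000
log-posterior split R-hat: 1.563
```

All four chains agree: three clusters are recovered exactly (ARI 1 against
the generative truth), the summary clustering is near-certain under the
posterior (PEAR 0.978), the per-chain PSMs are nearly identical (mean
entry-wise distance 0.017) and the summary is unchanged by dropping any one
chain.  Under the Pitman–Yor weighting all chains are equally consistent, so
the weights come out uniform.  The split R-hat on the log posterior is the
most conservative diagnostic — it reflects slow mixing over the discrete
order space within single chains, which is precisely what combining many
subsampled chains compensates for; the PSM-level criteria are the operative
check on the clustering itself.

## Command line

The same workflow is available as a CLI:

```bash
pseudoclust simulate --design design.yaml --out sim/
pseudoclust chains --data sim/expression.csv --capture sim/capture.csv \
                   --config run.yaml --out chains/
pseudoclust combine --psms chains/ --method py-pear --out combined.csv
pseudoclust summary --psm combined.csv --kmax 20 --out labels.csv
pseudoclust score --labels labels.csv --truth sim/truth.json
pseudoclust report --chains-dir chains/ --out report.json
```

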