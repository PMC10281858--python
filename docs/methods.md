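# Methods

## Neighborhood SNP sets

Each gene in the PPI network defines one hypothesis: its *k*-hop neighborhood
(default k = 1). The SNP set for gene *v* is the union — not concatenation —
of the SNP columns of all member genes: a SNP shared by two member genes (or
two overlapping genes) enters once, since a duplicated column only rescales
the kernel without adding information. SNPs are mapped to genes by positional
overlap with the annotated interval (1-based, inclusive on both ends).
Genes with no SNPs remain in the network as topology but are skipped as test
centers (their kernel would be empty); their neighbors are unaffected.
Aggregation is a pure function of the (network, slot map, k) triple, so it is
deterministic and independent of edge-list order.

## The set test

The trait is regressed on fixed effects X_f (intercept by default; principal
components can be appended to absorb structure beyond what the permutation
scheme already preserves) plus one random effect whose covariance is the
neighborhood kernel:

* Linear kernel ⟨l_i, l_j⟩ — main (additive) SNP effects.
* Inhomogeneous quadratic kernel (1 + ⟨l_i, l_j⟩)² — adds all pairwise SNP
  interaction features without ever materializing them.

Design columns are standardized (mean 0, variance 1) before the kernel by
default; monomorphic columns are zeroed. The kernel is rescaled to unit
diagonal, K̃_ij = K_ij / √(K_ii K_jj), which makes the statistic invariant to
overall scaling of the design; samples with a zero raw diagonal (no signal in
the set) get zero rows, and an identically zero normalized kernel marks the
neighborhood untestable.

REML fitting follows the FaST-LMM parameterization: the covariance is written
σ²(K̃ + δI) with δ = σ_e²/σ_s², the kernel is eigendecomposed once, y and X_f
are rotated into the eigenbasis, and the restricted likelihood is profiled in
closed form over σ² and β_f, leaving a one-dimensional problem in δ. For the
linear kernel the spectrum comes from an economy SVD of the normalized n × ns
design, so a set costs O(n·ns²); eigenvalues below 1e−12 of the largest are
treated as exact zeros through complement-space identities. The optimizer
evaluates a 33-point grid on log₁₀ δ ∈ [−8, 8] to bracket the optimum, then
Brent refinement (xatol 1e−6), then compares against the analytic σ_s² = 0
boundary; ties within 1e−9 (relative) go to the null. The statistic is
t = max(0, 2·ΔLL). Whether the factor 2 is included is immaterial: the null
distribution is empirical and undergoes the same transform.

## Permutation null and p-values

One permutation index m applies jointly:

1. **Circular SNP rotation.** Only gene-mapped SNPs participate, ordered
   genomically across chromosomes and wrapped into a circle. A rotation
   offset r ∈ [1, p−1] (drawn without replacement across permutations; the
   identity is excluded because it would reproduce the observed statistics)
   reassigns the column at circle position i−r to position i. Coordinates —
   and therefore gene membership of positions — stay fixed; relative SNP
   order is conserved, so the SNP–SNP correlation matrix is exactly the
   original under a cyclic index shift (LD preserved), and sample rows are
   never permuted (relatedness and population structure preserved).
2. **Degree-preserving network rewiring.** Double-edge swaps, rejecting any
   candidate whose four endpoints are not distinct or where an edge already
   connects the two pairs, until ≥ 50% of the original edges are displaced
   (an edge later swapped back stops counting) or 100·|E| draws have been
   made (best effort with a warning — on swap-free graphs such as cliques the
   input is returned unchanged). Degree sequence and edge count are invariant
   by construction.

Neighborhoods are re-aggregated on the permuted network with the same k and
re-tested, and all statistics from all permutations are pooled into T0 —
pooling across the ng neighborhoods is what lets ~20–100 permutations yield
fine-grained p-values. p = (1 + #{t⁰ ≥ t}) / (1 + |T0|): the +1 pseudocount
keeps p > 0, and ties count for the null (conservative). Every permutation is
reproducible from the manifest (rotation offset + network seed per index),
and the pool is order-insensitive, so permutations could be computed in any
order or in parallel.

**Calibration caveat.** The REML likelihood-ratio statistic for a single
variance component has a point mass at t = 0 (the boundary; asymptotically a
½χ²₀ + ½χ²₁ mixture). The conservative tie rule maps this entire atom — in
both the observed statistics and the pool — to p = 1. Small p-values are
therefore calibrated (empirical type-I error at α = 0.05 lands in
[0.03, 0.07] in the pure-noise experiment), but the full p-value distribution
is *not* uniform: it carries an atom of mass ≈ 0.5–0.6 at 1, and its
Kolmogorov–Smirnov distance to U(0,1) is approximately that mass. Only a
randomized tie-broken p-value could remove this, at the price of
irreproducibility and anti-conservatism; we keep the conservative rule.

## Multiple testing

For a single trait, Benjamini–Hochberg at level α. For T traits × ng
neighborhoods, a two-stage hierarchical procedure: each trait's p-values are
combined by Simes into a trait-level p; BH across the T trait-level p-values
selects R traits; within each selected trait, BH at level α·R/T. With T = 1
this reduces exactly to plain BH. The construction is one isolated function
so an alternative hierarchical variant can be swapped in.

## Synthetic data

The generators emulate, at desk scale, the ingredients of a semi-simulated
benchmark (real genotypes and networks are deliberately not required):

* **Genotypes** (n=300, p=1000 by default): latent-Gaussian threshold model.
  Each haplotype's latent value for SNP j in block b (block size 10) is
  √w·f_b + √(1−w)·e with w = 0.7; an allele is carried when the latent falls
  below the MAF quantile (MAF ~ U(0.1, 0.45)); the dosage sums two
  haplotypes. This yields blockwise LD with independent blocks on two
  chromosomes — it does not reproduce long-range LD decay, population
  stratification or relatedness, so passing tests speak to the block-LD
  regime only.
* **Network** (ng=100, mean degree 4): preferential attachment with triad
  formation — hubs *and* local clustering, both characteristic of PPI
  networks. Pure preferential attachment has no triangles and cannot host
  high causal-neighbor ratios. Genes tile the chromosomes as disjoint
  contiguous intervals (~p/ng SNPs each); real overlapping genes are
  supported by the mapping but not generated.
* **Causal configuration** (ncg=15, rc=0.8, rcn=0.8): for RCN 0, pairwise
  non-adjacent genes; otherwise one greedily grown dense cluster mixed with
  isolated singletons, refined by swap-based local search until the realized
  mean ratio of causal neighbors is within ±0.1 of the target (bounded
  restarts, hard error reporting the best achievable otherwise). ⌈rc·slots⌉
  SNPs per causal gene are causal.
* **Phenotype**: y = c·s_lin + (1−c)·s_int + ε with standard-normal weights
  on standardized causal columns; interaction columns are products of a
  random subsample of causal-slot pairs (min(2·#slots, all pairs) — the full
  quadratic design is implicitly sparse and not desk-feasible). Both signal
  components are scaled to unit variance before mixing so c is the linear
  amplitude fraction; noise variance is var(signal)/SNR, and the realized
  SNR is recorded. Default SNR 0.5 corresponds to total heritability 1/3 —
  mid-range for a complex trait.

AUPRC over genes (scored by −p; causal genes as positives) is computed with
the standard step-curve average precision; a constant scoring yields the
prevalence. The k=0 "gene-linear" method — the same LMM on single-gene sets —
is the baseline representing network-blind set testing.

## Experiment sizes and known limitations

The calibration experiment uses n=300, p=1000, ng=100, 20 permutations and
5 seeds; power experiments use the anchor scenario with 5 replicates and 15
permutations; trend sweeps use n=200, p=600, ng=60, 8 permutations. These
sizes give stable means while keeping a full run on one CPU in minutes.

At desk scale, prevalence (15% causal genes) is four times higher than in
published semi-simulated settings, which compresses the AUPRC gap between
the network method and the single-gene baseline: with per-gene noncentrality
n·h²/ncg ≈ 5 the baseline ranks genes well above its floor, so the network
advantage is a factor ~1.4 rather than >2, and in the RCN = 0 breakdown the
1-hop neighborhood dilutes each isolated causal gene's signal ~5-fold and
falls *below* the baseline instead of matching it. The directions — a large
advantage with clustered causal genes, which vanishes (and reverses) without
them, AUPRC rising with SNR and with RCN — reproduce robustly.

Other limitations: binary traits, dosage (non-integer) genotypes, VCF input,
weighted or directed networks and rare-variant regimes are out of scope;
the hierarchical FDR variant is one documented construction among several
possible; the CLI covers the null and p-value steps through the combined
`run` subcommand rather than as separate subcommands.
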