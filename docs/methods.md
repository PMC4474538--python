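# Methods

`nbspanel` stratifies tumors into molecular subtypes from somatic mutation
profiles by combining network smoothing, graph-regularized non-negative
matrix factorization (NMF) and consensus clustering, and then tests the
subtypes against survival and clinical covariates. This note records the
model, its parameters, the numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

## The stratification model

**Mutation coding.** Each tumor is a binary vector over genes: 1 if the
gene carries at least one *functional* somatic mutation (non-synonymous,
splice-site, or stop-codon-affecting; frameshift and in-frame indels are
included in this class), 0 otherwise. Synonymous, intronic and intergenic
calls never set a bit. Samples with fewer than 6 mutated genes (full-exome
mode) or no mutated panel gene (panel mode) are discarded as outliers.
Gene symbols are matched by uppercase exact string after trimming; no alias
resolution is attempted, since that would pull in an external resource and
silently change results as the resource evolves.

**Network smoothing.** Because two tumors of the same subtype rarely share
mutated genes, raw profiles are nearly orthogonal. Mutations are therefore
diffused over a gene interaction network (an edge-weighted, undirected
graph; the top 10% most confident edges are kept by default) with the
random-walk-with-restart iteration

    F_{t+1} = a · A · F_t + (1 − a) · F_0,

with retention weight `a = 0.7` and convergence declared when the max-abs
change between iterates falls below `10^-3` (iteration cap 1000). The raw
adjacency can have spectral radius far above `1/a`, under which this
iteration diverges, so `A` is the symmetric degree-normalized adjacency
`D^(-1/2) A D^(-1/2)` (spectral radius ≤ 1) by default; `none` and
`row-stochastic` are available as config switches. The fixed point is
`(1 − a)(I − aA)^{-1} F_0`, which the tests use as an independent oracle.
Propagation is linear and column-separable; per-column and whole-matrix
runs agree to machine precision (asserted in tests).

After convergence, quantile normalization forces every patient column onto
the common reference distribution (the mean of within-column sorted
values). Profiles originate from binary vectors, so within-column ties are
pervasive; tied entries receive the mean of the reference values over the
tied rank range, making the map equivariant to reordering within a column.
Normalization is applied once, after convergence.

**Graph-regularized NMF.** The smoothed matrix `F` (genes × patients) is
factorized by minimizing

    ‖F − W H‖_F² + λ · tr(Wᵀ L W),    W ≥ 0, H ≥ 0,

where `W` (m × K) holds "metagenes", `H` (K × n) the patient loadings, and
`L = D − C` is the Laplacian of the k-nearest-neighbor connectivity graph
(`k = 11`, union rule: i and j are connected if either is among the other's
k highest-weight neighbors; ties at the k-th weight broken by lexicographic
gene symbol; binary connectivity by default). The penalty pushes each
metagene to vary smoothly over the network, i.e. toward pathway-shaped
basis vectors. `λ = 200` by default. The solver uses multiplicative
updates,

    H ← H ⊙ (WᵀF) ⊘ (WᵀWH)
    W ← W ⊙ (FHᵀ + λCW) ⊘ (WHHᵀ + λDW),

which preserve non-negativity and never increase the objective (asserted
on every trace). Stopping: absolute objective decrease below 0.1 — stated
for the objective, with a relative-change fallback of `10^-6` so that
large-scale objectives are not stopped prematurely in absolute terms.
Denominators are floored at machine epsilon. Initialization is i.i.d.
uniform(0,1) scaled by `mean(F)/K`, fully determined by the seed; the first
multiplicative step rescales the factors, so the initial scale only needs
to be positive and finite. Patients are assigned to the metagene with the
largest loading (ties to the lowest index; an all-zero loading column is
an error naming the sample).

**Consensus clustering.** Stability comes from resampling: each of
`n_reps` replicates (default 500; analyses in this repository use 30–100,
a desk-scale choice recorded below) draws `floor(0.8 n)` patients without
replacement, re-applies quantile normalization to the sampled columns, and
re-runs the factorization. Because propagation is column-separable, the
full-cohort smoothed matrix is computed once and sliced per replicate —
mathematically identical to re-propagating the subset. Replicate
randomness comes from patient resampling alone (per-replicate sampling
seeds are spawned from the master seed; the factorization initialization
is tied to the master seed itself), so `subsample = 1` reproduces the same
replicate exactly. The consensus matrix entry (i, j) is the fraction of
replicates containing both i and j in which they shared a cluster;
never-co-sampled pairs (probability ≈ (1 − 0.64)^500 ≈ 10^-222 at
defaults) fall back to similarity 0 with a warning. Final labels come from
average-linkage hierarchical clustering of `1 − consensus`, cut to exactly
K clusters; the cophenetic correlation coefficient (ccc) between consensus
distances and the dendrogram's cophenetic distances measures how
block-like the consensus is (≈1 for clean, stable clusters). The tree is
cut by cluster count, not height, so the cut always matches the NMF rank.

**Clinical association.** Survival separation is tested with the K-sample
log-rank test (chi-square, df = K − 1; tied event times share a risk set);
Kaplan–Meier curves are exported per subtype. Association with grade or
stage uses Fisher's exact test: for 2×2 tables the exact two-sided
hypergeometric rule (total probability of tables no more likely than the
one observed), for larger tables a seeded Monte-Carlo exact test (100 000
tables drawn with the observed margins by Patefield's algorithm, +1/+1
continuity correction, simulation count reported). Patients without
clinical records are dropped from association tests with a logged count.
Raw p-values are reported with no multiplicity adjustment across K values
and gene sets; the run report records every test performed so users can
correct downstream.

The model layer (`NetworkStratification.fit` → `StratificationResults`)
wires these stages together; `run_pipeline` repeats them for each gene set
(full exome and/or panels) and each K, letting every gene set apply its own
outlier filter — so different gene sets may legitimately retain different
patient subsets, and association tests use each run's own cohort.

## Synthetic studies

The generator produces the structure the method assumes, plus ground truth
for recovery scoring.

* **Network**: planted-partition graph. Within-module edges appear with
  probability `p_in = 0.3` and carry weights uniform(0.5, 1);
  between-module edges with `p_out = 0.02`, weights uniform(0, 0.5).
  Modules play the role of pathways/communities.
* **Cohort**: each patient gets a subtype; genes of the subtype's module
  mutate independently at `driver_rate = 0.2`, all other genes at
  `background_rate = 0.01`. Profiles are redrawn until they carry ≥ 6
  mutated genes, so the full-exome filter keeps the whole cohort. With
  50-gene modules this yields ~10 driver and ~1–2 background mutations per
  patient — sparse profiles in which same-subtype patients share few exact
  genes but hit the same community.
* **Noisy-exome regime**: purely i.i.d. background noise turns out to be
  nearly harmless to this pipeline — diffuse noise is incoherent across
  patients and is washed out by propagation plus consensus, so full-exome
  profiles match or beat any panel under that noise model. What degrades
  real exome-based stratification is the *structured* component of
  passenger mutation load. The generator models it with
  `passenger_bursts`: per patient, that many randomly chosen non-driver
  modules additionally mutate at the driver rate, creating spurious
  network-coherent signal uncorrelated with subtype. The packaged noisy
  regime uses 240 genes in 8 modules (4 driver, 4 passenger),
  `background_rate = 0.03` and one burst per patient.
* **Panels**: `floor(coverage × module size)` genes sampled per covered
  module plus `decoys` genes from outside the covered modules. Targeting
  the driver modules (coverage 0.8, 10 decoys) emulates a clinically
  designed panel: enriched for driver pathways, blind to passenger ones.
* **Survival**: exponential event times with subtype-proportional hazards
  (baseline 10^-3 per day); independent exponential censoring with rate
  `μ = c/(1−c) · λ` per subtype, so the expected censored fraction is
  exactly the requested `censor_rate` (default 0.2). A binary grade is
  attached with P(high) increasing in the subtype's hazard. Exponential
  survival is the simplest proportional-hazards family; Weibull shapes are
  a possible config extension, not currently implemented.

What the generator does **not** emulate: real mutation-rate spectra per
cancer type, hypermutator phenotypes, gene-length and replication-timing
covariates of passenger load, panel gene lists as marketed, or
inter-patient burden heterogeneity beyond the burst mechanism. Passing
recovery tests therefore demonstrates correctness and internal consistency
of the machinery on data satisfying its assumptions — not clinical
performance on any real cohort.

## Problem sizes and determinism

Analyses shipped with the package run at desk scale: 120–150 patients,
200–240 genes, 30–100 consensus replicates — chosen so a full study
completes in seconds on one CPU while leaving all algorithmic behavior
(sparsity, ties, consensus dispersion) intact. The consensus default in
the config remains 500 replicates. Every random choice flows from one
master seed: replicate sampling seeds are spawned children of it, the NMF
init is tied to it, and Monte-Carlo Fisher tests take it explicitly. Two
runs with identical config and seed produce byte-identical label and
consensus files (asserted in tests).

## Numerical and design choices

* Propagation convergence uses the max-abs entrywise norm; the threshold
  `10^-3` gives agreement with the closed form well under `10^-4` on
  50-gene networks.
* Duplicate directed edges in input networks are symmetrized by maximum
  weight; self-loops are dropped.
* Edge thresholding keeps `ceil(fraction × E)` edges and retains all edges
  tied with the cutoff weight, so the kept count can slightly exceed the
  nominal number; isolated genes stay in the gene list as zero rows.
* The k-NN graph is built from the thresholded network by default
  (configurable), and its connectivity is binary by default because the
  regularizer is defined on a 0/1 neighbor graph.
* Mutation matrices are embedded into the full network gene space before
  propagation (zero rows for genes without mutation data), so panel-
  restricted profiles still diffuse over the whole network — a panel
  limits which genes *seed* the diffusion, not where signal may flow.
* Hierarchical clustering and the cophenetic coefficient raise on
  degenerate inputs (fewer than 3 patients; all-equal distances).
* 2×2 Fisher p-values follow the "probability mass ≤ observed" two-sided
  rule; other two-sided conventions exist and give different numbers.

## Limitations

* No alternative propagation kernels (heat kernel, personalized PageRank)
  and no KL or sparse NMF losses.
* Rank selection is left to the user: the pipeline reports ccc per K
  (default K ∈ {3,4,5,6}) but applies no PAC/delta-K rule.
* No Cox regression or multivariate adjustment; survival association is
  the unadjusted K-sample log-rank test.
* The multiplicative solver converges to a local optimum; different seeds
  can yield different factorizations. Consensus clustering is the intended
  mitigation, not a guarantee.
* Tissue-specific networks, copy-number or methylation signal, and
  gene-ID alias handling are out of scope.
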