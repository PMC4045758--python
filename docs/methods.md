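# Methods

This note documents the models, estimators, defaults and numerical
choices behind `cnvtrn`, and what the synthetic-data tests do and do not
establish about real cohorts.

## Copy-number profiling

**Segmentation.** `segment_profile` is a circular binary-segmentation
scheme: within the current segment, every arc `(i, j]` is scored by the
pooled-variance |t| between the markers inside and outside the arc
(leftmost arc wins ties; both sides must contain at least `min_width`
markers, default 2). The best arc's significance is assessed by
permuting the segment's values `n_perm` times (default 1000) and
comparing the maximal permuted statistic with the observed one,
add-one-corrected; the split is accepted at `p < alpha` (default 0.01)
and recursion continues on the pieces. An arc with zero pooled variance
but a mean difference (an exact step) scores t = ∞ and is accepted
whenever `n_perm ≥ 1/alpha − 1`, so noiseless piecewise-constant
profiles are segmented exactly. Segment boundaries are placed at
midpoints between flanking markers so segments tile the profiled
interval; this matters for length-weighted gene averaging. The search
is O(m²) per split with permutations vectorised over arc starts, which
is comfortable at the marker densities used here (hundreds of markers
per chromosome) but not tuned for SNP-array-scale profiles.

**Gene-level copy number.** A gene's value is the length-weighted mean
of overlapping segment means (a weighted mean, not a median, so it is
exactly checkable against a per-basepair brute-force average). Genes
overlapping no segment are missing and drop out of downstream
denominators.

**Recurrent regions.** Per gene and direction, the G-score sums the
per-sample amplitude in excess of the threshold (+0.3 amplification,
−0.3 deletion). The null permutes every sample's gene values
independently, preserving each sample's amplitude distribution while
destroying locus alignment. Because genes are exchangeable under this
null, null G-scores are pooled across genes and rounds — per-gene nulls
would quantize the empirical p at 1/(n_perm+1) and starve the BH step.
P-values are BH-adjusted jointly across genes × directions; regions are
maximal runs of genome-adjacent significant genes with a common
direction, reported with q < 0.25. Region frequency is the fraction of
samples whose mean gene-level value across the region passes the
directional threshold. This caller intentionally omits peel-off,
arbitrated peaks and marker-level q plateaus: downstream analysis
consumes only region membership, direction, frequency and q.

## TRN inference

**Mutual information.** Plug-in MI in nats over `B` equal-frequency bins
per variable, `B = floor(sqrt(n/5))` clamped to [3, 10]. Bin edges are
the empirical `i·n/B` order statistics; tied values always share a bin,
so a constant vector has zero MI, while for distinct values each bin
holds exactly `n/B` samples and self-MI equals `log B`. Rank-based
binning makes every downstream score invariant under strictly monotone
transforms of expression.

**CLR.** Each candidate edge's MI is z-scored against the empirical MI
distribution (population SD) of all candidate pairs incident to each of
its endpoints, floored at zero, and combined as the root of summed
squares. The background is the candidate set (prior plus null pairs)
rather than the all-against-all MI matrix: the screen only ever scores
candidates, and the full matrix would be quadratic in the gene count. A
node with fewer than two incident pairs, or zero MI spread, contributes
z = 0 from its side.

**Null screen.** For each TF, 1000 non-prior (TF, gene) pairs are drawn
without replacement and scored identically; a prior edge is retained iff
its CLR strictly exceeds the nearest-rank 95th percentile of its TF's
null CLR sample. Per-TF nulls are the default (each module judged
against its own TF's background); a single global null is available via
`null_scope="global"` for sensitivity. Under independence the strict cut
retains ~5% of prior edges, which the calibration study confirms (the
reproduction script reports the retained fraction measured across 50
seeded cohorts at the default study size: 20 TFs × 50 prior targets,
200 samples).

**Variance filter.** The 5% of genes with the smallest sample SD are
removed first (ties broken lexicographically by gene id for
determinism).

## Module selection

Pathway enrichment uses the expressed-gene background; CNV-gene
enrichment uses the network-gene background. Both are one-sided Fisher
tests (upper hypergeometric tail) with gene sets intersected with the
background before counting, BH-corrected within each screen — the
correction family is a package choice, applied across all module × set
tests in the pathway screen and across modules in the CNV screen.
"Biological function" is operationalised as ≥ 1 pathway set at
q < 0.05; a module is kept iff it also is CNV-TF regulated or CNV-gene
enriched, which fixes its type label.

The network tally partitions nodes into CNV-TF / non-CNV-TF / CNV-gene /
non-CNV-gene (a target that is itself a TF counts as a TF) and edges
into seven classes: the three TF→TF classes are keyed by the unordered
pair of CNV statuses — the mixed class covers both orientations — so
that the seven classes exactly partition any edge set; TF→gene classes
are ordered.

## Pathway integration

Overlapped nodes are pathway nodes that are CNV-genes or CNV-TF targets
in the retained network. Neighbor expansion is 1-hop in both edge
directions ("neighbors" is otherwise unqualified). The merged graph
keeps parallel edges from the two sources as separately attributed
edges and never invents an edge absent from both; regulatory edges
enter only if incident to an overlapped node. Gene-to-pathway-node
mapping is exact id equality, so multi-gene pathway nodes must be
pre-expanded in the input; pathway graphs are consumed as SIF-like TSV.

## Subtype clustering

**NMF.** KL-divergence NMF with the classical multiplicative updates and
uniform(0,1] random initialisation per seed. The update rule guarantees
a non-increasing objective; iteration stops at `max_iter` or when the
relative objective drop over a 10-iteration check interval falls below
`tol` (default 1e-5). Nonnegativity of the input is obtained by a single
global shift of −min(V), the simplest distance-preserving choice.

**Consensus.** Per rank k (default 2–5), 30 restarts each assign samples
to their argmax metagene; a restart that leaves a cluster empty is
re-drawn up to three times. The consensus matrix of co-clustering
frequencies is clustered by average linkage on (1 − consensus); the
cophenetic coefficient (Pearson correlation of dendrogram cophenetic
distances with consensus distances) selects the rank, smaller k winning
ties, and the dendrogram cut at k gives the final labels.

**LOOCV and DE.** KNN uses Euclidean distance with k = 3; weighted
voting weights each gene by its signal-to-noise ratio
(μ₁−μ₂)/(s₁+s₂) and votes on the sign of w·(x − (μ₁+μ₂)/2), ties to the
lower class index; CART is a Gini tree with depth ≤ 3 and minimum leaf
size 3. Differential expression is a Welch (unequal-variance) t-test at
p < 0.001; per-cluster enrichment of up-regulated genes reports raw
p < 0.05 without FDR.

## Synthetic data

The generator emulates exactly the structures the pipeline is supposed
to detect: contiguous amplified/deleted regions carried by a
Bernoulli(carrier_freq) subset of samples with Gaussian marker noise
(markers tile chromosomes at 10 kb by default; planted amplitudes must
exceed the 0.3 calling threshold or they would be undetectable by
construction); linear-Gaussian regulons in which a TF is N(cluster
mean, 1), an active target is β·TF + N(0, noise_sd) — so active-pair
correlation concentrates at β/√(β²+noise_sd²) — and everything else is
independent noise; and balanced sample clusters created by shifting an
informative subset of genes by `cluster_shift` in one cluster each. At
most one active regulator is planted per target and TF expression is
never overwritten, so every planted edge carries the undiluted effect.
With unit per-gene noise the average silhouette of the true labels is
roughly `1 − sqrt(2p/(2p + s²m))` for m informative genes of p at shift
s; the default informative fraction of 0.8 makes shift-3 clusters
clearly separable (silhouette ≈ 0.5). A single integer seed fans out to
fixed per-stage child seeds.

What passing these tests does **not** show: robustness to probe-level
normalisation artifacts, batch effects, LD/marker correlation,
allele-specific copy number, non-monotone regulation, unbalanced or
overlapping subtypes, or identifier-mapping noise — none of which the
generator emulates.

## Study sizes

The bundled studies run at desk scale, chosen to make the measured
quantities statistically stable: null calibration over 50 seeded cohorts
(20 TFs × 50 prior targets, per-TF nulls of 1000, 200 samples); regulon
recovery over 100 cohorts (8 TFs × 25 targets, 150 samples); one CNV
cohort of 100 samples, 40 genes, ~5 markers per gene, 200 segmentation
permutations and 500 calling permutations; clustering recovery at 200
genes × 60 samples with 30 restarts per rank.

## Known limitations

- The CART leave-one-out check on planted two-cluster data stabilises
  around 6–7% error rather than below 5%: a greedy depth-limited tree
  almost always finds a single gene that perfectly separates the
  training samples (with ~160 informative genes and n = 59 this is near
  certain) and therefore generalises as a one-gene threshold, whose
  error at a 3σ cluster separation is ≈ 2Φ(−1.5) ≈ 6.7%. KNN and
  weighted voting aggregate all genes and reach 0% on the same data.
  This is a property of axis-aligned single-split classifiers at this
  effect size, not of the clustering.
- The segmentation permutation test is exact only conditionally on the
  recursive acceptance path; no correction is applied across splits,
  matching standard practice for this algorithm family.
- Region q-values are enforced strictly below 0.25; borderline regions
  just above the threshold are dropped, not annotated.
- The G-score caller reports maximal significant runs; two adjacent
  independent events of the same direction merge into one region.
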