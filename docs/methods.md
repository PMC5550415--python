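# Methods

## Dispensing model

Nuclei are dispensed into `n_wells` nanowells independently; occupancy
per well is Poisson(λ) with λ = `mean_occupancy` (default 1.0, one
nucleus per 50 nL dispense at the working dilution). Wells with
occupancy exactly 1 are flagged *selected*, mirroring the imaging step
that excludes empty wells and doublets. At λ = 1 the expected selected
fraction is e⁻¹ ≈ 0.368; the often-quoted "~1800 usable wells" and
"about 30% of wells" figures are both loose summaries of this same
quantity, so the simulator exposes λ rather than hard-coding either.
Each well carries a distinct 11 nt barcode drawn without replacement
from a seeded whitelist (the physical chip's barcodes are preprinted
and known).

## Expression generator

Counts for gene *g* in cell *c* are negative binomial with mean
μ(g,c) and size parameter `nb_dispersion` (variance μ + μ²/size,
default size 2 — strong overdispersion typical of shallow
single-nucleus data). Per-gene baseline means are lognormal around
`nb_mean` (default 2 counts, log-SD 1). The mean is modulated
multiplicatively by:

* **planted copy-number segments** — genes inside a segment get
  μ·2^(log2_ratio) in cells of the affected (aneuploid)
  subpopulations; diploid cells never carry segments;
* **subpopulation markers** — `marker_effect` (default 4-fold) on each
  subpopulation's marker genes;
* **cell-cycle programs** — `phase_effect` (default 2-fold) on the
  active phase's gene set; phases are drawn multinomially
  (defaults G1 0.5625, S 0.25, G2 0.125, M 0.0625, so G2+M = 18.75%).

Counts are then zeroed by Bernoulli dropout with probability logistic
in log2 μ (midpoint 0, slope 1 by default): weakly expressed genes
drop out most often, the zero-inflation that motivates zero-inflated
negative-binomial models of such data. Setting
`dropout_midpoint=None` disables dropout.

The default `tnbc-default` scenario plants the composition of a
triple-negative tumor analysis: 380 normal baseline nuclei; 502
selected tumor-sample nuclei of which 5 are diploid stromal cells and
497 aneuploid tumor cells in subpopulations A/B/C of 259/145/93 cells
(52.2/29.1/18.8%); 22 chromosomes × 150 genes; arm-level events at
|log2 ratio| = 0.5 on the chromosomes recurrently altered in such
tumors (1q and 19q gains; 1p, 3, 4, 11p, 12q, 17p and 22 losses); ten
4-fold markers per subpopulation.

**What the generator does not emulate:** sequencing errors, adapter
content, alignment ambiguity, ambient RNA, doublets, batch effects,
gene-length bias, and correlated gene programs beyond the planted
ones. Passing planted-truth tests therefore demonstrates that the
pipeline recovers segment-level dosage, subpopulation structure and
phase programs under realistic count noise and dropout — not that it
is robust to every artifact of real libraries.

## Reads, demultiplexing, UMI counting

Read 1 is barcode (11 nt) + UMI (10 nt) + oligo-dT remnant; read 2 is
a random placeholder because gene identity travels in a read→gene
sidecar table (alignment is out of scope — any aligner's output can be
substituted). One read is emitted per molecule, UMIs are distinct
within a cell by construction, and extra duplicate reads are injected
so the expected duplicate fraction equals `duplication_rate`.

Demultiplexing is exact whitelist matching on the first 11 nt
(conservative default); `--correct-1mm` rescues barcodes with exactly
one Hamming-1 whitelist neighbor and rejects ambiguous ones. Reads
shorter than 21 nt or with `N` in the UMI are rejected and tallied;
assigned + unassigned + rejected = total always holds. UMI collapse is
by exact sequence identity — count(g, w) = distinct UMIs among reads
of gene g in well w — matching the dedup rule of dropping exact
duplicate UMIs; no edit-distance networks. Both UMI counts and raw
read counts are available downstream (dedup is a per-read table
operation, not baked into the matrix type).

## QC and normalization conventions

* Gene filter: keep a gene iff count ≥ 10 in ≥ 30 cells (both
  configurable). The rule is applied in this "keep" parse; the
  alternate reading of the inclusion thresholds is one flag away.
* Cell filter: ≥ 500 genes detected and ≥ 1000 molecules (defaults are
  deliberately loose — an order of magnitude below typical per-nucleus
  yields — and intended to drop failed wells only).
* log transform: log2(x+1), tracked by a normalization-state tag so
  transforms cannot be applied twice or out of order.
* z-scores use the population SD (divide by n); constant genes are
  dropped with a warning. The convention is fixed so that exact tests
  (e.g. a 2-cell gene [2, 4] → [−1, +1]) are well-defined.
* TPM from counts + gene lengths is provided as a utility; the
  pipeline accepts quantifier-produced TPM directly.

## Copy-number inference

Order of operations (each step is a public function; `run_cna_pipeline`
chains them):

1. **scale_cells** — each cell's log2(x+1) values are multiplied by
   100,000 / (cell total), so per-cell totals are identical. Scaling
   the log-scale values (rather than the raw TPM) follows the
   procedure this pipeline reproduces; the conventional
   scale-then-log order can be had by composing the functions
   differently. All-zero cells are left untouched and logged.
2. **order_filter_genes** — genes without annotation are dropped,
   the rest sorted by (chromosome, start) with natural chromosome
   order (1…22, X, Y); genes with mean scaled expression < 0.15 are
   removed (a gene at exactly 0.15 is kept). Coordinates are 0-based
   half-open internally; 1-based input is accepted with a flag.
3. **relative_to_baseline** — subtract the per-gene mean over the
   diploid baseline cells (which must have passed through the same
   scaling), then clip to [−3, 3]. Clipping tames the heavy tails of
   single-cell expression so single outlier genes cannot mimic a
   segment.
4. **moving_average** — within each chromosome, every run of 50
   consecutive genes (stride 1) is averaged into one profile row;
   windows never cross chromosome boundaries, and a chromosome with
   fewer genes than the window contributes its single
   whole-chromosome mean. Full windows only: every profile row
   averages exactly min(window, chromosome size) genes, which keeps
   the estimator's variance uniform and the brute-force oracle
   unambiguous. Each cell's profile is then centered by subtracting
   its own mean (per-cell mean 0 ± 1e−8).
5. **call_ploidy** — Ward linkage on Euclidean distances over all
   cells (sample + baseline), dendrogram cut at k = 2; the group with
   the majority of baseline cells is diploid, the other aneuploid.
   The two groups are then polished by reassigning each cell to the
   nearer group mean profile until convergence: the agglomerative cut
   is greedy and occasionally strands a borderline cell in the wrong
   branch even when it is strictly closer to the other group's mean;
   the refinement removes exactly that artifact (`refine=False`
   restores the bare cut). If all profiles are identical everything
   is labeled diploid; an exact 50/50 baseline split raises a tie
   error advising a larger baseline. Deeper cuts for multi-clone
   exploration are available via the cluster ids.
6. **purity** — 100 × (aneuploid ∩ selected set) / |selected set|.

## Signatures

Gene-set scores are the per-cell mean of log2(TPM+1) (or
log2(count+1)) over the set's genes present in the matrix; absent
genes are dropped with a warning, a fully absent set is an error
naming the set. Phase assignment centers the four phase scores per
phase, Ward-clusters cells (default 5 clusters: the four phases plus
one for cells with no positive program), labels each cluster by its
maximal positive mean centered score, and marks clusters with no
positive program `G0/unassigned` (quiescent nuclei show an absence of
cycling scores). In the orchestrated pipeline, phase scoring uses the
full gene universe (cell-filtered only): the count-based gene filter
keeps high-count genes and would otherwise thin the cycle sets
themselves.

Subtype classification is nearest-centroid over the genes shared with
a user-supplied gene × subtype centroid table; the confidence is the
Spearman correlation between cell and centroid, so labels are
invariant to any strictly monotone transform of the cell's
expression. Cells whose best correlation is below 0.7 are `undefined`;
argmax ties break by subtype name order. An optional pre-filter
excludes cells expressing a caller-supplied hormone-receptor marker
before TNBC-style subtyping. Because the exact confidence formula of
published subtype classifiers is implementation-defined, the simplest
rank-correlation definition is used and documented here.

## Subpopulations

PCA runs on the gene-standardized matrix with cells as samples (full
SVD, deterministic); the selected genes are the union of the top 20
|loading| genes from each of the first 5 components (elbow default;
both knobs configurable), reported in matrix gene order. The SNN
graph connects each cell to its k = 20 nearest neighbors (Euclidean;
neighbor sets include the cell itself) with edges weighted by the
Jaccard overlap of the two neighbor sets and zero-weight edges
pruned. Modularity is maximized by seeded Leiden local moving at
resolution 1.0 (equivalent to Louvain-style modularity optimization
for this purpose and deterministic under the seed); cluster ids are
relabeled by decreasing size. Note that modularity maximization on a
kNN graph of structureless noise yields several clusters — this is a
property of the objective, shared by standard single-cell toolkits,
so "one cluster on noise" is not a contract of this method.

The marker test is a self-contained two-part stand-in for bimodal
likelihood-ratio tests that live in external packages: per gene and
cluster (one vs rest), a two-proportion z-test on detection rates and
a Wilcoxon rank-sum on expressed values, combined by Fisher's method
(χ², 4 df), BH-adjusted across genes within each cluster. Markers
require FDR < 0.05 and |log2FC| ≥ 1, with fold change computed on
mean expression with pseudocount 1. Under label permutation on null
counts the combined test is well calibrated (~5% at p < 0.05 over
1000 genes). Clusters with fewer than 3 cells are skipped with a
warning.

## Problem sizes and determinism

The default scenario is 3300 genes × 882 cells, chosen to match the
~3000 genomically ordered genes (~130–150 per chromosome) that survive
the expression filter in a typical analysis of this design; the full
run completes in seconds and the test suite in well under a minute.
Read-level stages are exercised on a small scenario (120 genes, ~50
cells) because a full-depth read simulation would emit tens of
millions of reads without changing what the tests demonstrate. All
randomness flows from a single integer seed through seeded NumPy
generators (per-purpose streams), so identical seed + config gives
byte-identical outputs; the run manifest records SHA-256 digests of
every stage output to make this checkable.

## Known limitations

* Copy-number profiles are relative, smoothed dosage estimates — no
  integer copy numbers, breakpoints, or sub-arm events near the
  50-gene resolution floor; chromosomes with very few expressed genes
  (e.g. Y) contribute a single noisy window.
* The ploidy call is binary by design; subclonal copy-number
  structure requires deeper dendrogram cuts and manual review.
* The marker test is a calibrated stand-in, not a likelihood-ratio
  bimodal model; borderline genes can differ from model-based tests.
* Phase assignment depends on the provided gene sets; scores are
  unnormalized means, so sets of very different sizes or expression
  ranges should be compared only after the built-in centering.
* The generator's independence assumptions (genes conditionally
  independent given the planted structure) understate the correlation
  of real transcriptional programs.
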