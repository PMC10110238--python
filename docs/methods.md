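# Methods

`commnet` re-implements, as a tested library, a single-nucleus transcriptomic
analysis of intercellular communication in the diabetic mouse heart: QC and
clustering of nuclei, rank-based differential screens, ligand–receptor (LR)
connection networks per condition, a receptor-driver screen for a focal cell
type (cardiac fibroblasts), PPI hub ranking, focal-type subclustering with
bootstrap-supported dendrograms, and hypergeometric over-representation
analysis. This note records the models, parameter choices and their
rationale, and what the synthetic benchmark does and does not establish.

## Quality control and normalization

A nucleus is removed if it has fewer than 500 or more than 4,000 detected
genes, more than 8,000 UMIs, or more than 10% of counts on mitochondrial
genes (prefix `mt-`, configurable). A cell failing several rules is removed
once but reported under every rule it trips, so the QC report columns need
not sum to the number removed. Filtering is idempotent.

Normalization is counts-per-10,000 followed by `log1p` — the de facto
convention of the droplet toolchain this analysis style comes from. All
fold changes are computed on back-transformed (`expm1`) normalized means
with a pseudocount of 1e-9, so stated log2FC cutoffs refer to linear
expression ratios; the pseudocount only guards zero denominators and is far
below any mean of a detected gene.

## HVG selection, PCA, and clustering

Highly variable genes are ranked by dispersion (variance/mean of the
back-transformed values) z-scored within 20 mean-abundance bins; ties break
lexicographically so the selection is deterministic. Genes with zero
variance never outrank variable genes. Default: 2,000 HVGs.

PCA is centered and per-gene unit-scaled; component signs are fixed so the
largest-magnitude loading of each component is positive, making embeddings
reproducible across BLAS builds. The number of components is chosen by an
explicit elbow rule: the smallest k after which the variance-share curve is
flat, i.e. the first k with (share[k+1] − share[k+2]) below 5% of the total
drop across the curve, floored at 10 components when available. The floor
keeps smooth, signal-poor curves from collapsing to one or two components.

Clustering is Leiden modularity optimization (resolution 1.0 by default,
seeded) on an unweighted k-nearest-neighbour graph (k = 20, Euclidean in PC
space). Labels are relabelled by decreasing cluster size so the same
partition always yields the same label numbering. Cluster-to-type
annotation picks, per cluster, the type whose canonical markers have the
highest mean z-scored expression; a cluster expressing no marker at all
stays `unassigned`, and ties resolve alphabetically with a warning.

## Differential screens

All tests are two-sided Wilcoxon rank-sum tests on log-normalized values.
The scalar test uses the exact permutation null when the pooled sample has
at most 20 observations and no ties, otherwise the normal approximation
with midranks, tie correction and continuity correction; genome-wide scans
use the vectorized normal approximation (group sizes here are hundreds of
cells, where the exact and asymptotic tests are indistinguishable).
Benjamini–Hochberg adjustment is applied within each contrast — one cluster
versus rest, or one type's condition comparison — not globally across
contrasts, matching the convention of the toolchain the analysis style
derives from. NaN p-values propagate and are excluded from the number of
tests.

Three screens, thresholds inclusive at the boundary (the sources mix "≤"
and "<"; inclusivity is uniform here and exposed as configuration):

* **cluster markers** — upregulated, fold ≥ 1.28, detected in > 25% of the
  cluster's cells ("more than" is strict), FDR ≤ 0.05;
* **cell-type-specific genes** — one type vs all other cells, FDR ≤ 0.01
  and log2FC ≥ 1, with a uniqueness flag for genes qualifying in exactly
  one type;
* **condition DE** — diabetic vs control within each type, FDR ≤ 0.05 and
  |log2FC| ≥ 0.36, both directions retained with labels.

Cells are pooled across animals within each condition; no animal-level
blocking is applied, so p-values describe cell-level, not mouse-level,
replication. A **uni-DEG** is a gene significant in exactly one cell type's
condition contrast; per-type uni-DEG sets are disjoint by construction and
their percentages of the total sum to 100.

## Communication networks and the driver screen

A gene is "expressed" in a population if detected (count > 0) in more than
20% of its cells; the threshold is exposed because connection-count
magnitudes depend on it, and an alternative mode defines per-type genes by
the specific-gene screen instead. Connection matrices count, per ordered
(sender, receiver) pair of types, the LR pairs with the ligand expressed in
the sender and the receptor in the receiver; the autocrine diagonal is
included. Matrices are built per condition from that condition's cells only
and then differenced. Per-type totals count row plus column sums with the
autocrine entry counted once.

The driver screen intersects the focal type's specific genes with the LR
receptor universe, keeps receptors with at least one condition-upregulated
cognate ligand in any sender type, and merges them with the focal type's
upregulated uni-DEGs. The merged set is the input for PPI hub ranking,
which uses node degree only (ties broken by symbol); isolated members of
the input set are retained at degree 0 so the report shows screen genes
without PPI support. The PPI edge list is a user input: no online database
is queried, and results depend on the supplied edges.

## Subpopulations and bootstrap support

The focal type is re-clustered on its own 500 HVGs and 20 PCs (resolution
0.5 by default — subclusters are expression programs within one type, where
the full-resolution default oversplits). Subpopulation relatedness uses
mean log-normalized profiles over those HVGs: Pearson correlation,
average-linkage clustering on distance 1 − r, and branch support as the
fraction of gene-resampled bootstrap trees (sampling genes with
replacement; genes, not cells, because the profiles are the objects being
clustered) containing the same leaf bipartition. Supports are ordinary
(single-scale) bootstrap proportions; the multiscale approximately-unbiased
correction is not implemented. At least 100 replicates are required;
defaults use 500–1,000.

## Over-representation analysis

One-sided hypergeometric upper-tail tests per gene set, BH-adjusted across
the tested sets, significant at FDR ≤ 0.05. The universe defaults to the
measured genes (those surviving QC) — the honest background for a
single-experiment query — with an option to supply a genome-wide list.
Sets with no overlap with the universe are excluded rather than assigned
p = 1; query genes outside the universe are dropped with a warning.

## Synthetic benchmark

The generator emulates a two-condition, multi-type droplet experiment:
gene-wise log-normal baseline means (median 0.8 counts/cell, σ = 1), NB
counts with size 2, log-normal library-size factors (CV 0.3), and a
10-gene mitochondrial block receiving a per-cell fraction drawn uniformly
from [0.01, 0.08]. Defaults: 5 cell types × 2 conditions × 300 cells and
2,000 genes — desk-scale, chosen so the full suite runs in minutes while
group sizes (hundreds of cells per type and condition) remain in the regime
of the real study's statistics.

Planted signal: 20 marker genes per type at fold 4 (both conditions; real
populations differ in dozens of genes, and 20 is enough for near-perfect
type separation without making the task trivial), 10 condition-DE genes per
type at fold 2 (diabetic cells of that type only — so each is a uni-DEG of
its type by construction), and one driver pair: the receptor (named
`Pdgfra`) is a fibroblast marker, its ligand (`Pdgfc`) the best-expressed
of the macrophage sender's condition-DE genes — the motivating ligands are
robustly expressed growth factors, and designating a well-expressed gene
keeps the planted circuit condition-upregulated by construction rather
than only in expectation. Planted genes are drawn from baseline means in
[0.5, 3] so markers behave like real markers — reliably detected in their
own population; planting signal on near-zero genes would test dropout, not
the screens. Note that planted condition-DE genes are also genuinely
elevated (~1.5-fold) in their type when conditions are pooled, so the
marker screen's truth set for false-discovery accounting includes them.

The subtype scenario (`subtype_scenario()`) additionally plants three
expression programs within the fibroblasts — 20 genes at fold 4 for two of
them, 40 genes at fold 8 for the third — so the third separates as a
divergent outgroup in the profile dendrogram. The default configuration
carries no subtypes: the two scenarios keep the top-level clustering
benchmark (clean 5-type design) and the subclustering benchmark from
interfering with each other. A `null_scenario()` plants nothing and is used
for calibration.

What the generator does **not** emulate: doublets, ambient RNA, batch or
animal effects beyond library size, gene–gene correlation beyond the
planted programs, and realistic LR/PPI topology (decoy pairs and background
edges are random). Passing recovery tests therefore demonstrates that the
implementation detects the effects it is pointed at under idealized noise —
not that the thresholds have the same operating characteristics on real
nuclei.

## Numerical and degenerate-input choices

Pooled-constant genes get p = 1 (the asymptotic statistic is 0/0 there).
Duplicate gene symbols in input matrices are summed, not suffixed, so
per-gene statistics see one row per symbol. PPI self-loops are dropped with
a count; duplicate edges keep the maximum score. Profile correlation
refuses constant profiles by name. The pipeline funnels all randomness
through the single config seed and hashes every artifact, so two runs with
one config are byte-identical.
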