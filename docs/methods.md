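# Methods

`scwithin` re-implements, as a tested and reusable pipeline, a
within-subject single-cell analysis of an acute drug exposure: each
participant contributes a pre-infusion and a post-infusion PBMC sample, and
the question is which genes change expression after infusion, in which
immune cell types, against inter-individual transcriptomic variability that
is larger than the drug effect itself.

## Synthetic data model

The generator (`scwithin.simulate`) draws UMI counts from a Negative
Binomial (Gamma-Poisson) model per gene and cell,

    mu[g, s] = lib_share[s] * base_mean[g]
               * marker_fold ^ [g is a marker of s's type]
               * program_fold ^ [g is a program gene of s's type]
               * 2 ^ shift[g, participant(s)]
               * 2 ^ (lfc[g, type(s)] * [condition(s) = post]),
    var = mu + alpha * mu^2        (alpha = nb_dispersion, default 0.5).

Design defaults mirror the emulated study: 2 participants x {pre, post},
~4,000 cells per sample, a 20,000-gene universe, and eight PBMC types
(CD4+ T 34.6 %, IL7R CD4+ T 8.4 %, CD8+ T 17.4 %, B 13.2 %, NK 12.3 %,
CD14+ monocytes 10.0 %, FCGR3A monocytes 3.8 %, DC 0.3 %) with disjoint
literature marker genes (six per type: CD3D/CD3E/... for CD4+ T, MS4A1/
CD79A/... for B, GNLY/NKG7/... for NK, and so on). Tests and the
demonstration configuration scale the cell and gene counts down
(2,000-2,400 cells, 1,500 genes) to keep runs desk-sized; the model is
unchanged.

Key generator choices:

- **Participant effects dominate condition effects.** Per-participant,
  per-gene log2 shifts are drawn once per participant with SD 0.5 —
  larger than typical planted condition fold-changes — so unadjusted data
  clusters by participant, the batch structure the adjustment stage must
  remove.
- **Type programs beyond markers.** Real cell types differ in broad
  expression programs, not only in the handful of curated markers. Each
  type therefore additionally up-regulates `program_genes_per_type`
  (default 50) non-marker genes by `program_fold` (default 3x). Without
  this, whole-transcriptome PCA cannot separate eight types whose only
  difference is six marker genes each, and no clustering chain would
  recover them; with it, clustering quality reflects the method rather
  than an impossible design. The mapping stage never sees which genes are
  program genes.
- **Planted QC failures.** High-mitochondrial cells get their
  mitochondrial counts re-drawn to a 30 % share (>10 % rule); doublets are
  summed profiles of two random cells of different types, inflated above
  the 100,000-read cap. Both are recorded in the ground truth so filters
  can be checked exactly.
- **Expression levels of informative genes.** Marker and planted-effect
  genes sit at the 85th percentile of the base-expression distribution,
  program genes at the 70th; weakly expressed genes would carry no
  detectable signal at desk-scale depths (~2,500 UMIs/cell), and curated
  markers and validated DEGs are in practice well-expressed genes.
- All randomness flows from a single `numpy` generator seeded by
  `config.seed`; a fixed seed reproduces the dataset byte for byte.

The generator does **not** model ambient RNA, UMI collisions,
read-level error, gene-gene correlation within a condition (beyond type
structure), or cell-cycle and other continuous covariates. Passing tests
therefore say the pipeline recovers planted structure under clean NB
noise with known markers — not that it is robust to, e.g., ambient
contamination or marker misspecification on real data.

## QC and normalization

A gene is kept if detected (count >= 1) in at least one cell. A cell is
removed iff its mitochondrial read fraction exceeds 0.10 (strict), it
expresses fewer than 370 genes (strict), or its total reads exceed
100,000 (a read-count doublet proxy, strict). All thresholds are
evaluated on the raw count matrix before any filter is applied, which
makes the gene and cell filters commute. The QC report records every
rule that fired per cell.

Normalization is counts-per-10,000 with natural-log `log1p`:
`x = log(1 + 10000 * count / cell_total)`; consequently
`sum(exp(x) - 1) = 10000` per cell and the transform is invariant to
sequencing depth.

## Batch adjustment

`qc.combat` implements parametric empirical-Bayes location/scale
adjustment: per-gene standardization against a design with batch
indicators (plus covariates), per-batch location (gamma) and scale
(delta) estimates shrunk toward a normal / inverse-gamma prior by the
standard iterative moment-matched updates (convergence 1e-4), then
back-transformation. Two deliberate choices:

- **Condition is a model covariate by default**, so the adjustment does
  not absorb the pre/post signal downstream stages test (the batch label
  is the participant, and each participant contributes both conditions);
  `covariate_keys=()` disables this.
- **A final per-gene recentring restores the pre-adjustment grand mean
  exactly** (the EB back-transformation preserves it only approximately).
  Recentring adds a per-gene constant, so batch-mean *differences* are
  untouched.

Zero-variance genes pass through unchanged and are flagged. A single
batch is an identity transform with a warning. The non-parametric ComBat
variant is not implemented.

## Embedding and clustering

Normalized, adjusted expression is standardized per gene, reduced to
`n_pcs = 30` principal components, and embedded in 2-D by t-SNE with
perplexity 20 and 3,000 iterations (deterministic given the seed). The
embedding's Euclidean distances are converted into a symmetric
k-nearest-neighbour graph (edge iff either endpoint lists the other),
and communities are found by multi-level modularity optimization
(Louvain, `igraph.community_multilevel`, resolution 1). Cluster ids are
relabeled by decreasing size from 1, and the reported modularity is the
Newman-Girvan modularity of the returned partition.

`k` defaults to 60. With k = 20 the Louvain partition over-splits even
perfectly pure type clusters (12+ communities for 8 types at 2,000
cells), which destroys agreement with the planted partition however good
the embedding is; k = 60 yields 8-9 communities of unchanged purity.
Over-splitting is expected in this chain — clusters are merged into
types by the mapping stage — but the coarser default keeps the cluster
partition itself interpretable. `k` is exposed in the configuration.

## Marker-regression cell typing

For cell *s* and type *c* the binary marker column is regressed on the
cell's expression over the G panel genes (linear probability model):

    y_c = b0 + b1 * x_s + e,   t_cs = b1 / SE(b1),  df = G - 2.

A cell is a candidate for type c iff p_cs < p0 (default 0.01) and
t_cs > 0. Per-cell calls take the smallest p among candidates (ties:
larger t, then lexicographic type name — the tie rule is a design choice;
any deterministic rule works, and smallest p uses the strongest
evidence). Clusters vote through

    P[c, k] = (1 / N_k) * sum over cells s in cluster k of
              I(t_cs > 0) * I(p_cs < p0),

which counts threshold passes independently of the single-type call, so
rows may sum above 1. Each cluster is assigned `argmax_c P[c, k]`;
clusters below `min_cluster_frac` (default 0.5 %) of cells or with an
all-zero profile are merged into the type of the nearest assigned
cluster by centroid distance in the embedding, and the merge is logged.
Perfect fits (zero residual variance) are capped at |t| = 1e6 with
p = 0 so sorting stays stable; cells with constant expression across the
panel are unassignable. Expression supplied to the scorer is the
normalized, batch-adjusted value.

## Differential expression

Within each cell type with at least `min_cells` (default 50) cells and
both conditions present, each gene detected in at least 1 % of the
type's cells is fitted with

    expr ~ 1 + condition + (1 | participant)     (REML),

and the condition coefficient (post - pre on the log-normalized scale)
is Wald-tested. With two participants the random-intercept variance is
weakly identified: a fit that fails to converge, produces a non-finite
standard error, or collapses the variance component below 1e-8 falls
back to OLS with participant as a fixed covariate, and the per-gene
`fit_method` column records which path produced each estimate. Constant
expression yields effect 0, p = 1 (`degenerate`). Benjamini-Hochberg
adjustment is applied within each cell type across its tested genes —
not pooled across types — because significance is declared
transcriptome-wide per cell type.

The sharing report classifies genes significant (q < 0.05) in exactly
one tested type as *specific* and in two or more as *shared*, flags a
*core* set significant in at least three types, and marks whether all
significant effects share a sign (*concordant*).

## Networks, overlap, enrichment

Candidate genes are those with nominal p < 0.001 (strict) in a cell
type's DE table. Only candidate pairs present in the supplied prior
edge list (e.g. KEGG-derived) are tested: OLS of one gene on the other
across the cells of one (cell type, condition) stratum, two-sided slope
p, BH within the stratum, significant at q < 0.05. Slope-testing on a
bivariate Gaussian is p-equivalent to testing the Pearson correlation,
which reconciles "correlation network" language with a regression test.
The edge OLS carries no participant covariate by default. A **hub** is
a node with degree >= 4 in the pre- or the post-condition network —
degrees are never summed across conditions.

Receptor co-expression correlates a receptor gene with every other
expressed gene in a stratum (Pearson, t-transform p, BH), and the
pre/post significant lists are compared with the exact hypergeometric
overlap statistic: expected overlap |A||B|/N, representation factor
observed/expected, p = P[X >= k] for X ~ Hypergeom(N, |A|, |B|). The
same engine drives gene-set enrichment over GMT collections (sets with
fewer than 5 members in the universe are skipped; the universe is the
set of genes tested for DE in that cell type, not the whole genome).

## Pipeline

Stages run in a fixed order (ingest/simulate, qc_norm, embed_cluster,
cellmap, de_lmm, netsets) and communicate only through on-disk
artifacts, so any stage can be re-run from its predecessors' outputs.
The manifest records a parameter snapshot, per-stage wall times and
SHA-256 hashes of every artifact. One global seed derives per-stage
seeds through `numpy.random.SeedSequence`, so changing one stage's
randomness does not perturb another's. The YAML configuration rejects
unknown keys and range-checks every threshold before any stage runs.

In synthetic mode the ingest stage also writes a prior edge list (all
pairs among planted-effect genes plus random filler pairs) and a small
GMT (the planted shared and specific response sets plus random sets), so
the network and enrichment stages exercise realistic inputs. Because the
generator draws genes independently within a condition, co-expression
networks on synthetic data are expected to be nearly empty — the planted
structure lives in mean shifts, not covariances.

## Numerical and degenerate-input choices

- Strict inequalities everywhere the rules state them: a cell with
  exactly 370 expressed genes, mito fraction exactly 0.10, or exactly
  100,000 reads is retained; a DE gene with p exactly 0.001 is not a
  network candidate.
- Hypergeometric tails use `scipy.stats.hypergeom.sf(k - 1, ...)`
  (exact upper tail including k).
- LPM perfect fits: |t| capped at 1e6, p = 0; constant-x cells
  unassignable rather than erroring.
- Edge/receptor tests declare a gene untestable on exact zero range
  (`ptp == 0`), avoiding float-noise pseudo-variance on constant columns.
- ComBat iterations stop at relative change < 1e-4 (cap 500).

## Problem sizes

Default test and demonstration sizes: 2,000-2,400 cells x 1,500 genes
for the end-to-end run; 2,000 simulated genes for mixed-model
calibration; 200 genes for effect recovery; 500 cells per batch for the
adjustment check; 200 replicates for edge power/null rates. These sizes
are the package's chosen desk-scale study conditions; the generator
accepts the full-scale design unchanged.

## Known limitations

- With two participants the mixed model frequently falls back to the
  fixed-participant OLS; the two agree closely here because participant
  effects are additive and balanced, but the fallback is a necessity of
  the n = 2 design, not a general equivalence.
- Cell-type assignment is cluster-mediated: a cell in an impure cluster
  inherits the cluster's type regardless of its own call.
- The hypergeometric enrichment is a simple over-representation test; it
  ignores gene-gene correlation and set overlap structure.
- t-SNE + kNN + Louvain cluster counts are sensitive to perplexity and
  k; only the downstream type assignment, not the cluster count, is
  treated as a stable output.
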