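# Methods

This note documents the models, defaults and design choices behind
`crossortho`, in the order the pipeline runs them.

## Quality control

Cells are filtered before genes, in a fixed order: (1) cells with fewer
than `min_genes_per_cell` (default 200) detected genes; (2) cells whose
mitochondrial count fraction exceeds `max_mito_fraction` (default 0.20),
with mitochondrial genes identified by a case-insensitive symbol prefix
(default `MT-`) or an explicit id list; (3) genes detected in fewer than
`min_cells_per_gene` (default 3) of the *surviving* cells.  A cell failing
both cell rules is counted once, under the detected-genes rule.  The
mitochondrial rule is implemented as a hard per-cell threshold — the
conventional reading of "filter cells above 20 %" — rather than as a
regression covariate; for a hard threshold it is irrelevant whether it is
applied per replicate or per merged dataset.  Removing every cell is an
explicit error, never an empty matrix.

## Normalization

Two layers with different jobs:

* **lognorm** (`ln(1 + s·x_gc/N_c)`, scale factor s = 10,000).  Sparse,
  zero-preserving, invariant to per-cell sequencing depth.  Used for
  differential expression, detection-based panel scoring, cluster-average
  profiles and cross-species correlations.
* **Analytic NB Pearson residuals** with fixed inverse-dispersion θ = 100:
  `r_gc = (x_gc − μ_gc)/√(μ_gc + μ_gc²/θ)` under the null
  `μ_gc = N_c·n_g/N` (cell total × gene total / grand total), clipped to
  ±√n_cells; genes with zero total get all-zero rows.  This closed-form
  variance-stabilizing transform replaces per-gene regularized NB
  regression deliberately: it has the same statistical intent, no fitted
  state, no seed, and is exactly testable at desk scale.  Anchor-based
  dataset integration is likewise not performed — replicates are simply
  concatenated, and a cluster × replicate composition table is emitted so
  replicate bias can be inspected.

Highly variable genes are ranked by per-gene variance of the residual
layer, descending, ties broken toward the lower gene index.

## Embedding and clustering

PCA is computed by SVD of the gene-centered cell × HVG residual matrix
(default 30 components, 2,000 HVGs), with a deterministic sign convention:
the largest-magnitude loading of each component is made positive.  The
number of components is a fixed, configurable parameter rather than a
permutation-based selection — standard practice, and deterministic.

The neighbourhood graph takes each cell's k = 15 Euclidean nearest
neighbours (self excluded), joins the union of those relations as
undirected edges, weights each edge by the Jaccard overlap of the two
endpoint neighbour sets, and drops zero-weight edges.  Communities are
found by Leiden with the RBConfiguration objective at resolution 0.5 under
a mandatory seed; labels are renumbered by decreasing cluster size (ties:
first cell index), so outputs are stable and byte-reproducible.

## Differential expression

Markers are tested per cluster against all other cells on the lognorm
layer.  A gene is tested when it is detected in ≥ `min_pct` (0.10) of
either group *and* its natural-log fold change — `ln` of the ratio of
group means of `expm1`(lognorm), pseudocount 1e-9 added inside the means —
has magnitude ≥ `min_logfc` (0.25).  P-values are two-sided Wilcoxon
rank-sum: when both groups have ≤ 8 cells, by exhaustive enumeration of
the permutation distribution of the rank sum, defined as
`P(|S − E[S]| ≥ |s_obs − E[S]|)`, which remains exact under ties; otherwise
by the tie-corrected normal approximation without continuity correction.
Benjamini–Hochberg correction spans all tests performed across clusters.
Clusters with fewer than 3 cells are an error.  A pairwise mode
additionally requires the gene to pass against every other cluster
separately and reports the most conservative p-value.

## Panel annotation

For each cluster and panel, the score is the z-score (across clusters) of
the mean detection fraction of the panel's genes (fraction of the
cluster's cells with count > 0, averaged over the panel genes present;
symbols matched case-insensitively).  Each cluster takes the argmax
panel's label unless the margin to the runner-up is below `min_margin`
(default 0.5 z-units), in which case it is labeled ambiguous; exact ties
break toward the earlier panel in config order with a warning.  Detection
fraction is used rather than mean expression because it is robust to the
normalization layer and mirrors how marker dot-plots are read.  Expert
curation can override the rule via a label file.  Germ-cell subsets are
re-clustered from scratch (normalization, HVGs, PCA, graph, Leiden all
recomputed on the subset).

## Ortholog harmonization and anchoring

Within each pairwise table, deduplicated rows are kept only when both
genes occur exactly once in that table — paralogs and ambiguous mappings
are discarded entirely rather than resolved (a highest-confidence-pair
mode is deliberately out of scope).  Reference genes surviving every
pairwise table form the 1-1-…-1 map; each species matrix is then
re-indexed to the reference gene order, with absent genes zero-filled and
counted.  Cluster profiles are arithmetic means of lognorm values over all
mapped genes (not HVG-restricted — the conservative choice when no gene
restriction is specified; a mean-of-`expm1` switch exists because either
convention appears in practice).  Anchoring is per-row argmax of the
Pearson correlation matrix with margin and a tie flag (`tie_epsilon`
1e-9); a zero-variance profile correlates 0 with everything (warned) so
anchoring stays total.

## Conserved markers

A species' SSC set is the genes with q < 0.05 and ln-fold-change > 0.25
for the SSC group in one-vs-rest DE over the germ-subtype grouping; the
thresholds are recorded in the output headers because such counts are not
auditable otherwise.  Sets are mapped to reference ids and intersected;
unmapped ids are dropped and counted; the operation is commutative in
species order, and an empty intersection is a legitimate result.  Adding a
fourth species (e.g. an outgroup) is the same call with one more set.  The
`marker_profile` table reports per-gene, per-subtype mean lognorm
expression (plus row-scaled z-values) for a configurable gene list whose
default — *EXOSC10, FGFR3, MKI67, DMRT1* — contrasts the A_dark versus
A_pale immunostaining discriminators across SSC → progenitor →
differentiating → late-differentiating spermatogonia.

## Synthetic data

The generator emulates the structure the analysis assumes.  Per species,
cell `c` of type `t` draws
`x_gc ~ NB(mean = lib_c · w_gt / Σ_g w_gt, θ)` as a gamma–Poisson mixture
(variance mean + mean²/θ, θ shared across genes — richer dispersion
models add nothing for testing).  `w_gt` is a log-normal baseline, shared
across species for the ortholog genes and drawn independently for each
species' private genes, multiplied by `marker_fold` when gene `g` is a
planted marker of type `t` active in that species.  Conserved markers are
disjoint blocks of ortholog genes (identical fold in every species —
exactly the structure the correlation anchoring presumes); species-
specific markers live in the private pool of one species.  Library sizes
are log-normal (median 5,000 UMIs); a configurable fraction of genes
(default 1 %) carries `MT-` symbols, and 5 % of cells have those genes
boosted 60-fold, pushing their mitochondrial fraction far above the QC
threshold so the mito filter is exercised (ambient RNA is not modeled).
Pairwise ortholog tables contain the true 1-1 backbone plus injected
spurious rows pairing private genes on both sides — contamination that
exercises the many-to-many filtering and can leak spurious map rows, but
can never silently delete a true backbone row.  Panel genes for the
annotation stage are the planted markers with the lowest baselines
(detection-based scoring discriminates poorly on saturated genes), and the
first four planted types carry the canonical SSC / progenitor /
differentiating / meiotic panel symbols.

Reference study conditions (the defaults): 3 species, K = 5 shared types,
2,000 ortholog + 300 private genes per species, 900 cells per species,
marker fold 2.5, 30 conserved + 20 species-specific markers per type,
θ = 10.  What passing on these data shows — and does not show: the
simulation has no batch effects, doublets, ambient RNA, cell-cycle
structure or gradual state transitions, so success here validates the
pipeline's logic and statistics, not its robustness to every artifact of
real droplet data.

## Determinism and numerical conventions

All stochastic steps (simulation, Leiden) take seeds from one
configuration value; TSVs are written with fixed float formatting and
manifests avoid timestamps and absolute paths, so rerunning any stage with
identical config and seed is byte-identical.  Tie-breaks are specified
everywhere they can occur (HVG ranking, cluster renumbering, panel argmax,
anchor argmax).  Degenerate inputs have defined behaviour: zero-total
cells are an instructive error before lognorm, zero-count genes give zero
residual rows, zero-variance profiles correlate 0.

## Problem sizes

The bundled example config and the CLI tests use two-to-three species of a
few hundred cells and genes; the end-to-end benchmark and the acceptance
script use the reference study conditions above, which run in well under a
minute per replicate on a single CPU.  These sizes were chosen as the
smallest at which every planted effect is comfortably detectable.

## Known limitations

* Annotation assumes marker panels with reasonable detection contrast;
  panels of uniformly high-expressed genes saturate the detection fraction
  and lose discrimination.
* Strict 1-1 filtering discards genuinely informative paralogs; the map
  shrinks as species are added.
* Cluster-level (not per-cell) annotation: a cluster mixing two states is
  labeled as one of them or ambiguous.
* The DE normal approximation is used for all but very small groups;
  p-values for groups of ~10–30 cells are approximate (the exact path
  bounds at 8 per group for enumeration cost).
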