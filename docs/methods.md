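# Methods

This note documents the models, algorithms and parameter choices behind
`circuitscan`, and what the package's validation does and does not show.

## Synthetic atlas (`circuitscan.simulate`)

**Count law.** UMI counts are negative binomial, parameterized by mean μ and
dispersion θ (variance μ + θμ²), drawn as a gamma–Poisson mixture with a
per-cell size factor. Size factors are lognormal with σ = 0.3 and unit mean,
emulating cell-to-cell depth variation. Default θ = 0.4.

**Gene universe.** Per-gene baseline means are drawn from a lognormal across
genes (σ = 1.0, mean = `base_mean`, default 0.5 counts/cell), reflecting the
orders-of-magnitude spread of real transcriptomes; a flat mean profile would
make dispersion-based HVG selection degenerate (all informative genes in one
expression bin). Structural genes are pinned: four lineage-defining genes
(*Epcam*, *Cldn5*, *Col1a2*, *Ptprc*) and `marker_genes_per_type` exclusive
markers per type at `marker_fold` × base mean (default 8×) in their own
type; ten mitochondrial genes (`mt-` prefix, mouse convention) scaled so the
mito fraction of a healthy cell is `mito_gene_fraction` (default 0.05, below
the 0.10 QC cutoff); and a pool of cytokines and receptors (*Cxcl1*, *Il33*,
*Ccl2*, … with matching receptors) at 4 × base mean, since induced
chemokines/alarmins are among the better-expressed transcripts in inflamed
lung — planted effects on well-expressed genes are the regime the recovery
studies are meant to probe.

**Design.** Default: 4 cell types spanning the four lung lineages
(AT2, lipofibroblast, capillary EC, alveolar macrophage), 3 treatment groups
(sham + 2 particles), 2 samples per group, 50 cells per sample per type —
i.e. 100 cells per (treatment, type) group before QC, 1,200 cells total,
1,500 genes. These sizes keep a full 20-seed recovery study around a minute
on one CPU while leaving every group large enough for the stated power
targets.

**Planted truth.** A circuit (treatment, sender, ligand, receiver, receptor,
log2-effect, default 1.5) multiplies the NB mean of the ligand in the sender,
and of the receptor plus 15 downstream target genes in the receiver, by
2^effect under that treatment only. Targets are drawn from adequately
expressed background genes and raised to the well-expressed baseline. The
matched resources give each planted ligand regulatory potential
U(0.65, 1) on its targets and U(0, 0.25) elsewhere; decoy pairs/ligands are
drawn from genes with no planted effect.

**Doublets** are sums (not averages) of two random parent count vectors,
matching UMI additivity; parents are recorded in the truth metadata.

**What the simulator does not model:** batch effects beyond per-sample size
factors, gene–gene correlation networks, spatial structure, ambient RNA.
Passing recovery tests therefore demonstrates correctness of the pipeline's
logic and calibration under the stated noise model, not robustness to every
artifact of real tissue data.

## QC and normalization (`circuitscan.qc`)

Gene filter: total count ≥ 1 and expressed in ≥ 5 cells. Cell filter
(applied after the gene filter): mitochondrial fraction < 0.10 (cells at
exactly 10 % are removed), ≥ 300 detected genes and ≥ 500 total counts
(cells at exactly the minima are kept). Mitochondrial genes are found by
case-insensitive `mt-` prefix, with an override list; if none are present a
warning is raised and the fraction is 0. Filtering only drops rows/columns,
never alters counts, and is idempotent.

Normalization is counts-per-10,000 followed by log1p. The bare-log1p reading
(no depth normalization) is available via `normalize: none`; the CP10K
default exists because cross-cell comparisons are depth-confounded without
it.

**Doublet detection** re-implements the simulated-doublet idea: synthetic
doublets are sums of random observed pairs (one per observed cell); observed
and synthetic cells are pooled, CP10K/log1p-transformed, embedded with 30
PCs, and each observed cell is scored by the fraction q of its k nearest
neighbours that are synthetic (k = ½√n), converted to a likelihood
(q/r)/(q/r + 1 − q) for simulation ratio r. The threshold is the valley
between the two modes of the synthetic-score histogram when it is clearly
bimodal; with discrete, well-separated cell types the synthetic scores are
often unimodal-high, so the fallback sets the threshold at the synthetic
25th percentile — an operating point defined by 75 % synthetic-doublet
recall. Homotypic doublets are largely undetectable after depth
normalization; this is inherent to the approach.

## Clustering and annotation (`circuitscan.cluster`)

HVGs are computed per sample (Seurat normalized-dispersion flavor, top
2,000 by default; smaller universes should scale this down, the studies here
use 300) and a gene enters the consensus only when flagged in ≥ 2 samples.
The consensus rule is read as "flagged HVG in ≥ 2 samples" — the only
reading under which per-sample computation is meaningful.

Scaled consensus-HVG values are embedded with PCA (50 PCs, capped at the
data rank) and a kNN graph (k = 15). Leiden uses the RB-configuration
objective, resolution 1.0 (tier 1) / 0.8 (tier 2), fixed seed. Marker genes
are one-vs-rest Wilcoxon rank-sum tests (tie-corrected normal
approximation; exact enumeration for single small contrasts), BH-adjusted
within each cluster contrast; a marker requires q < 0.05 **and**
log2FC > 0.5, where log2FC = log2 of the ratio of de-logged group means with
a 1e-9 pseudocount.

Annotation is two-tier: each cluster gets the lineage whose defining gene
has the highest mean expression (exact ties broken by the fixed order
epithelial, endothelial, stromal, immune); within each lineage, HVG
selection, PCA/kNN and Leiden are repeated and fine clusters are labelled by
the best mean-expression match among that lineage's reference marker sets,
so a fine label can never leave its lineage. Niches follow the reference's
type→niche map. Lineage blocks too small to re-cluster are matched as one
block.

## Differential expression (`circuitscan.dge`)

Welch's t statistic, the Welch–Satterthwaite degrees of freedom and
two-sided t-distribution p-values are computed from the textbook formulas,
vectorized over genes, on log-normalized values. "Expressed in at least 10
cells" is evaluated on the union of the two compared groups (a per-group
reading is a flag). BH runs within each (cell type, treatment) contrast.
Zero-variance genes get p = 1 when means agree and never produce NaN.
Direction: up ⇔ q < 0.05 and log2FC > 0.5; down symmetric. The effect-size
summary counts up/down genes per (cell type, treatment).

## Gene-set scoring (`circuitscan.genesets`)

`score_gene_set` bins genes by average expression into 25 rank bins and, for
each bin touched by the set, samples 50 control genes per set gene from the
bin's non-set genes (a bin fully inside the set contributes whole, so a set
equal to the universe scores exactly 0); the score is set mean minus control
mean per cell. Scores are location-invariant by construction.

`gsva_scores` implements the kernel-ECDF / rank / random-walk recipe:
per-gene Gaussian-kernel ECDF across samples (bandwidth sd/4), per-sample
ordinal ranks converted to the symmetric statistic |p/2 − r|, and a weighted
random walk (hit steps ∝ stat^τ with τ = 1, miss steps uniform). The score
is the "maxdiff" convention — largest positive plus largest negative
deviation; the single largest-magnitude deviation is an option. Gaussian
mode expects log-scale input.

`gsea_preranked` is the weighted Kolmogorov–Smirnov statistic on a
log2FC-ranked list (hit weight |stat|^p, p = 1; p = 0 gives the classical
KS statistic) with gene-label permutation p-values
((1 + worse)/(1 + same-sign permutations)) and NES = ES divided by the mean
same-sign permutation magnitude; 1,000 permutations by default, BH across
sets within a contrast.

## Circuit inference (`circuitscan.circuits`)

Edges are directed sender → receiver (ligand side → receptor side);
undirected views are recoverable by symmetrization. The connectome
conditions only on up-regulation of ligand and receptor, not baseline
expression, matching the induced-edge definition; edge weight equals the
number of qualifying pairs; autocrine self-edges are allowed; duplicate
resource rows collapse with a warning; the log2FC > 0.5 cut is strict.

Ligand activity reduces the full NicheNet workflow to its two decisive
filters: PCC of the regulatory-potential vector against the 0/1 program
membership over the prior's target universe (intersected with DGE-tested
genes), strict PCC > 0.05, and ≥ 10 % expressing cells in at least one
sender type (raw count > 0). Degenerate cases — empty or universe-wide
programs, constant potential rows — yield undefined PCC and fail with the
reason recorded. Circuit reports are the inner join of edges with passing
ligands on (ligand, receiver), ranked by (PCC, weight) descending; response
genes are receiver up-set members among the ligand's above-median prior
targets.

## Pipeline and reproducibility (`circuitscan.pipeline`, CLI)

One YAML config holds every threshold under its reference default
(log2FC 0.5, FDR 0.05, 10 % mito, 300 genes, 500 counts, 5 cells/gene,
10 cells per DGE test, 50 PCs, 10 % sender fraction, PCC 0.05). A single
global seed expands into per-stage seeds by hashing the stage name, so
stages are independently reproducible; the manifest records a SHA-256 per
output file, and reruns with equal config and seed reproduce identical
hashes.

## Validation studies (`circuitscan.experiments`)

*Null calibration*: sham-only atlases (2,000 genes, 200 cells, one type),
20 random relabelings into two pseudo-groups; measured: fraction of genes
with q < 0.05 (≈ 0 under BH), connectome edges from 50 decoy pairs (≈ 0),
z-scores of 20 random 30-gene signature scores, and the KS uniformity of
permutation p-values for 200 random 15-gene sets against a null log2FC
ranking. The permutation p-value is discrete (granularity ≈ 1/1000), so KS
p-values near the tail occasionally occur by chance at any sample size.

*Planted recovery*: 20 atlases at the default design with two circuits at
log2-effect 1.5; cell types come from Leiden clustering plus annotation (not
the planted labels), so the metrics — ARI against planted types, planted-DE
recall at the up-call, connectome edge precision/recall, planted ligand
top-5 rate — exercise the full chain.

## Known limitations

- The two-filter ligand-activity scoring omits NicheNet's candidate-ligand
  pre-selection by receptor expression; with small priors the PCC can be
  noisy for very small receiver programs.
- GSVA is O(genes × samples²) in the ECDF step and intended for
  group/pseudobulk matrices, not tens of thousands of single cells.
- Annotation assumes the reference marker sets discriminate the fine types;
  it performs no novel-cell-state discovery.
- The simulator's independence across genes makes clustering easier than in
  real data at matched effect sizes; recovery rates here are upper bounds.
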