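# Methods

`orthostage` implements a cross-species single-cell transcriptomics analysis:
placing an unlabeled population of cells from one species (here, sorted human
pluripotent stem cell fractions) onto the developmental axis defined by a
labeled single-cell reference from another species (macaque pre- and
post-implantation embryos). The pipeline has four computational stages —
orthologous metaexon construction, count-matrix QC, rank-based cross-species
harmonization, and joint-PCA staging — plus stage-specific gene-panel
summaries and a synthetic-data generator that provides ground truth for every
stage.

## 1. Orthologous metaexons

Cross-species expression comparison requires a quantification unit whose
sequence is confidently 1:1 orthologous and equally mappable in both genomes.
Starting from every annotated exon of the query species (species A):

1. **Alignment.** Each exon is aligned against both genomes. At desk scale
   this uses the built-in k-mer-seeded ungapped aligner (`orthostage.align`):
   every exact k-mer (default k = 11) shared between the exon and a genome
   anchors a full-length ungapped alignment on that diagonal; identity is
   matching bases over aligned columns. Gapped alignment is deliberately not
   modeled at this scale; genome-scale runs should instead ingest external
   BLAT output via the PSL reader, whose identity is computed as
   matches / (matches + mismatches + query inserts + target inserts).
2. **Identity filter.** The best cross-species hit must reach ≥ 92% identity
   (boundary inclusive).
3. **Second-hit filter.** Any secondary (rank ≥ 2) hit with identity
   strictly above 90%, in either genome, removes the exon — the guard against
   paralogs and segmental duplications that would confound cross-species
   mapping.
4. **Reciprocity.** The exon's best same-species hit must overlap its own
   annotated locus (≥ 1 bp, same strand; the overlap requirement is
   configurable). When several filters would fire, the recorded reason code
   follows the precedence low_identity → second_hit → no_reciprocal: an exact
   duplicate elsewhere in the genome produces two identity-1.0 self hits, and
   the duplication (second hit) is the cause of removal even when the
   duplicate also happens to win the deterministic rank-1 tie-break
   (ties: longer alignment, then leftmost coordinate).
5. **Collapse.** Overlapping or bookended same-gene exons (isoform variants)
   merge into *metaexons*; bookended intervals ([100,200), [200,300)) merge
   because they encode contiguous exonic sequence. Species-B coordinates of a
   metaexon are the merged target intervals of its constituents' best
   cross-species hits, with strand taken from the hit orientation.
6. **Gene-level filters.** Removed are: metaexons overlapping an annotated
   exon of a second gene; all metaexons of genes annotated on two or more
   chromosomes in either species (genes absent from the other species'
   annotation are removed with a distinct `unannotated` code); and metaexons
   flanking an intron whose length differs between the species by ≥ 10,000 bp
   (boundary inclusive) — a signature of assembly or annotation problems.
   Introns are measured between adjacent retained metaexons of the same gene,
   in A from the merged intervals and in B from the paired coordinates. The
   flanking-side rule is configurable (`either`/`upstream`/`downstream`,
   default `either`, i.e. both neighbors of a discordant intron are removed);
   flagging is simultaneous over the current adjacency in a single 5'→3'
   pass, so removals do not cascade into newly adjacent pairs.

Every removal is logged in a `FilterReport` whose per-stage conservation
(removed + retained = input) is asserted.

Internal coordinates are 0-based half-open; GTF input (1-based closed) is
converted on read, BED output is written natively.

## 2. Quantification

Read intervals are counted featureCounts-style: a read is assigned once to
the unique feature it overlaps by ≥ 1 bp (configurable); reads overlapping
features of two or more genes are discarded as ambiguous; reads on
chromosomes absent from the feature set are logged as unassigned
(assigned + ambiguous + unassigned = total, asserted). A read overlapping two
metaexons of the *same* gene goes to the larger overlap (ties: leftmost).
Strand is ignored by default because the two platforms (UMI-based CelSeq2 vs
SC3-seq) differ in strandedness; `stranded=True` is available. Gene-level
counts are the column sums of the gene's metaexons, and bulk-style summaries
sum cells within individuals/embryos with exact count conservation.

## 3. QC and normalization

Cell filters follow the stated wording exactly: cells with *fewer than*
`min_total_counts`, *more than* `max_total_counts`, or fewer than
`min_genes_detected` detected genes are removed, so threshold-sitting cells
are kept. The defaults (12,500 / 60,000 / 4,500) are the deposited-data
values; the two published QC descriptions differ in whether the lower counts
bound applies, so all three thresholds are on by default and
`min_total_counts=None` reproduces the "<4,500 genes or >60,000 counts"
variant. These are dataset-scale parameters: the synthetic matrices
(~2,000 genes, ~25k counts/cell) use a scaled configuration
(`synthetic_qc_config()`: 5,000 / 150,000 / 500) chosen to sit in the same
relative position of the library-size distribution.

Expression is log2(CPM + 1), with CPM computed per cell on the *full*
pre-gene-filter matrix. Gene retention requires expression strictly above a
cutoff (1 log2(CPM+1) for the non-UMI reference, 5 for the UMI dataset —
platform-specific values reflecting each dataset's expression distribution;
the synthetic analysis uses 1 for both since the simulated platforms share a
depth scale) in at least 10% (inclusive) of the cells of at least one
phenotype group. A raw-count variant (≥ 1 count in ≥ 10% of a condition
group) serves the within-species path. The cross-species gene universe is the
deterministic sorted intersection of the two species' retained sets, mapped
through the metaexon table's gene pairing. Cell filtering precedes gene
filtering, and detection fractions are computed on post-QC cells; relaxing
any threshold can only grow the retained sets (a tested invariant). Pooled
size-factor normalization used upstream for within-species heatmaps is
deliberately replaced by plain CPM here, keeping the cross-species path
exactly as specified.

## 4. Harmonization

Within each cell, genes are ranked by abundance ascending (lowest = rank 1);
ties all receive the minimum rank of their tie group ([0, 3, 3, 7] →
[1, 2, 2, 4]). Rank direction is a convention (PCA subspaces are invariant to
the global sign flip) and is configurable by transforming the input. Zeros
participate as one large bottom tie group — no special dropout handling.
Ranks are then z-scored per cell (sample sd, n−1; the choice of n vs n−1
only rescales and cannot change PC subspaces); constant cells are emitted as
zero rows with a flag. Ranking operates on the common-gene submatrix, since
downstream analysis is restricted to the shared gene universe before
rescaling.

Because ranks depend only on within-cell ordering, the harmonized output is
**bit-identical** under any strictly increasing per-cell transform of
expression. This is the pipeline's central premise: a species/platform effect
that acts as a monotone distortion of expression is nullified *exactly*. The
merge is a row concatenation (dataset A then B, original order) carrying cell
metadata and dataset provenance.

## 5. Joint PCA and staging

PCA is a deterministic full SVD of the column-centered merged matrix — no
per-gene variance scaling, since rows are already rank-z-scored (scaling is
available via preprocessing if wanted). Component signs follow a fixed
convention (the largest-|loading| gene loads positively), making runs exactly
reproducible; a test cross-checks the spectrum and scores against an
independent PCA implementation. Variance fractions are reported against the
total variance of the input, so they sum to 1 at full rank.

In this design PC1 absorbs the residual species/platform split (driven by
detection-rate and dispersion differences that survive rank harmonization),
while the developmental signal lands on PC2 (pre- vs post-implantation axis)
and PC3 (post-implantation progression). The original analysis reads the
query cells' developmental position off these score plots; to make that
output testable, staging is made quantitative: each query cell is assigned
the reference stage minimizing Euclidean distance in a selected PC subspace
(default components 2 and 3), either to stage centroids (default) or by
k-nearest-neighbor majority (k = 15). Exact ties go to the smaller mean
distance, then to the earliest developmental stage, with a tie flag. Stages
with no reference cells are excluded with a warning. PCA is run jointly on
reference and query cells (matching "PCA on the merged data"); a
projection-style workflow can be built from the returned loadings and mean.

## 6. Stage panels

No formula is published for the stage-specific panels, so a transparent rule
stands in: a gene marks a stage set S when its mean log-expression in S
exceeds the complement mean by ≥ `min_effect` (default 1 log2 unit) and it is
detected (> 0) in ≥ `min_detect_frac` (default 0.5) of S's cells. Panels are
emitted for a configured list of stage sets (single stages plus nested spans,
mirroring the published figure's rows), and externally curated panels can be
supplied as a two-column TSV instead. Per-cell panel scores are the mean
log-expression over the panel's genes; summaries report median, quartiles,
extremes and the underlying values per cell group.

## 7. Synthetic data

The generator is first-class, tested code; its defaults define the study
conditions for every property test.

**Genomes** (`GenomeSimConfig`): 50 genes, 2–4 exons of 120–180 bp,
introns 200–800 bp, one chromosome per species, random strand per gene.
Species-B exons are copies of species-A exons carrying **exactly
round(divergence × length) substitutions** at distinct random positions
(default divergence 0.02). The exact count, rather than per-base Bernoulli
sampling, makes planted identity a deterministic function of length —
divergence 0.02 keeps every ortholog comfortably above the 92% floor, and
divergence 0.10 puts every ortholog below it — so retention tests probe the
filter, not sampling tails. Decoys are exact duplicate exon copies planted in
intergenic space (alternating genomes; 10 by default), which must leave via
the second-hit filter. Five genes receive one intron lengthened by 12,000 bp
in species B (other introns jitter by ≤ ±100 bp), so both metaexons flanking
the shifted intron must leave via the intron filter. The truth table records
the expected reason code per exon under the filter-precedence rules above.

**Counts** (`ExpressionSimConfig`): 5 ordered stages × 40 cells per stage per
species × 2,000 genes — minutes of CPU at most. Gene baselines are log-normal
(median 1, σ = 1 on the log scale). 15% of genes are stage markers
(+1.5 log2 in exactly one stage); 10% follow smooth profiles across the
ordered stages — half strictly monotone at full amplitude, half arch-shaped
at 0.7× amplitude. The arch is deliberately secondary: a developmental
trajectory's principal axis must dominate its curvature for stage order to be
readable from a single component, while the arch spreads the five stages into
a plane so that two components suffice for centroid staging. Informative
genes have their baseline floored at 1 (developmental regulators are not
vanishingly expressed). Species effects: a monotone power-law distortion of
expected expression (γ_A = 1, γ_B = 1.6) that harmonization must nullify
exactly; log-normal library sizes (medians 25k/30k, σ = 0.25); NB sampling
(dispersion 0.10 for the UMI-like platform A, 0.30 for the non-UMI-like B);
independent Bernoulli dropout (0.10 / 0.30). A `noiseless` mode emits rounded
expected counts for exact-recovery tests, and the truth object carries the
pre-noise relative-expression matrices, on which the monotone-invariance
property holds bit-exactly.

**What the generator does not emulate:** gapped/spliced alignment, UMI
collision structure, cell-cycle or lineage-priming covariation, doublets,
ambient RNA, batch structure within a species, and non-monotone platform
effects. Passing tests therefore demonstrate the pipeline's correctness under
its own model assumptions — shared stage programs plus species-specific
monotone distortion — not robustness to every artifact of real data. In
particular, rank harmonization only removes *monotone* cross-species effects;
gene-specific (non-monotone) platform biases would survive it.

## Numerical and degenerate-input choices

- Aligner seed k = 11; exons shorter than k yield zero hits plus a warning;
  an empty genome is an error. Hit identity below 0.5 is not reported.
- Zero-total cells are an error in `log2_cpm` (they should have been removed
  by cell QC); empty matrices pass through QC with a warning.
- Constant cells z-score to zero rows with a flag rather than NaN.
- Centroid ties use an absolute tolerance of 1e-12; assignments are
  deterministic across repeated runs, as is the PCA sign convention.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds reproduce fixtures byte-for-byte.

## Problem sizes used in tests and the acceptance script

Defaults throughout: 50-gene genomes (~100 kb per species) for orthology
checks; 200 random interval instances (≤ 20 intervals) for the collapse
oracle; 2 × 200 cells × 2,000 genes for the staging analysis, with the
species-A cells (200) as queries; 50 random matrices for QC monotonicity;
600 genes × 100 cells (noiseless, markers only) for panel recovery. These
sizes were chosen so the whole suite runs in seconds on one CPU while every
property is still measured on hundreds of independent units.
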