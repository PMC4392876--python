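# Methods

This note documents the models, rules and numerical choices implemented in
cistromix, and what the synthetic-data generators do and do not emulate.

## Coordinates and peak model

All intervals are 0-based, half-open. BED input is consumed as-is; GTF
coordinates are converted at the parsing boundary (start − 1). A peak
carries a summit (absolute coordinate, must lie inside the interval), an
FDR on the MACS percent scale (0–100, so "FDR < 10" means < 10%) and a
non-negative tag density. Peak tables may store the summit as an offset
from the peak start (the MACS convention) or as an absolute coordinate; a
dialect flag selects the interpretation and everything is normalised to
absolute internally.

The replicate-overlap measure is the fraction of the *shorter* peak covered
by the intersection. It is symmetric, lies in [0, 1], equals 1 for nested
peaks, and is 0 across chromosomes. When the two peaks have equal length
the choice of denominator is immaterial.

## Replicate consensus

High-confidence regions are derived in three steps:

1. build the bipartite graph between the two replicates with an edge
   wherever the overlap fraction is ≥ 0.5 (the cut-off is a parameter);
2. keep an edge only if at least **one** of its two peaks has FDR < 10 and
   TD > 15 — the gate is applied per overlapping pair, not per component,
   and all threshold comparisons are strict;
3. every connected component of surviving edges becomes one consensus
   region: the union interval of its members, with the summit taken from
   the member of highest tag density (ties broken by peak id).

Connected components make the one-to-many case deterministic and
order-independent: a chain of mutually overlapping peaks yields a single
region. Region counts are therefore counts of merged regions, not of
either replicate's peaks. The pooled ("combined reads") peak set is
filtered separately at FDR < 10 and TD > 30. Cross-cell-type comparison
classifies each peak as shared when it has a ≥ 50%-overlap partner in the
other set; shared + unique always equals the set size on each side.

An independent brute-force implementation (all pairs, networkx connected
components) backs the consensus rule in the test suite; the library itself
uses an interval tree for candidate lookup and union-find for components.

## Gene assignment and feature classes

A gene's TSS is strand-oriented (interval start on +, end on −). A peak is
ascribed to a gene when its **summit** falls in the window from 5 kb
upstream to 1 kb downstream of the TSS (distances are signed, negative =
upstream in gene orientation), or when its **interval** comes within 1 kb
of the gene's core promoter — the 5′UTR plus the 1 kb upstream of the TSS.
The two clauses deliberately use different anchors (summit vs whole peak).
Among candidates the smallest |summit − TSS| wins; exact ties break to the
lexicographically smallest gene id, and remaining candidates are reported
in an `alternates` column since promoter-dense loci can admit several
genes.

Feature classification assigns each summit one of five classes with
precedence `core_promoter > exon > intron > downstream_1kb >
distal_intergenic`; precedence is required because the classes overlap.
`downstream_1kb` is the 1 kb past the transcript 3′ end in gene
orientation. The genome background is the per-base-pair occupancy of the
same classes under the same precedence, computed by painting per-chromosome
class maps; observed and background vectors each sum to 1.

## Tag-density profiles

Tags are single-bp positions (5′ ends); no fragment extension is applied
because the profiling tool's extension settings are not part of the rule
set being modelled, and the simplest model keeps the geometry exact. Bin
*j* of a peak counts tags in `[summit − flank + j·b, summit − flank +
(j+1)·b)`; with the default 5 kb flank and 50 bp bins each row has exactly
200 bins and the summit sits at the left edge of bin 100. Peaks are
unstranded, so bins run left-to-right in genome coordinates. No library-
size normalization or smoothing is applied. Heatmap row order is descending
total signal with ties by peak id.

## Count normalization

Two stages, both built from geometric means:

- **Positive controls.** Each sample's scale factor is the cross-sample
  arithmetic mean of per-sample positive-control geometric means divided by
  that sample's geometric mean. This removes lane/technical efficiency
  differences while keeping the output on the input count scale (the target
  is the cohort mean, not a fixed constant).
- **Reference genes.** The same construction over the reference probes,
  computed on the stage-1 output. This removes RNA content differences.
  After it, the reference-probe geometric mean is identical across samples
  by construction.

The reference factor is applied to endogenous and reference probes; the
spike-in positive controls are fully corrected by stage 1 and are left on
that scale. This is what makes the composite exactly idempotent: on
re-application both stages compute unit factors (rescaling the spike-ins by
the content factor would de-equalize their geometric means and a second
pass would pick up a spurious common factor of mean(r)·mean(1/r) ≥ 1).
Zero counts entering a geometric mean are floored to 1 with a logged
warning; endogenous zeros are left untouched. The exact vendor formula
behind "default settings" normalization is not published; the
mean-of-geomeans target used here is the package's documented choice.

Downstream transforms: per-gene z-scores use the sample standard deviation
(n − 1); fold-to-normal-median divides each value by the gene's median over
normal samples (normal median ↦ 1). Zero-variance genes make z-scores
undefined and are rejected by the primitive; the workflow drops them with a
warning first, treating sd/|mean| < 1e−12 as constant to absorb
normalization-factor rounding at the 1e−16 level.

## Correlation ranking and clustering

Gene-vs-anchor association is the Pearson correlation across samples,
flagged at r strictly > 0.7; samples are reported sorted by ascending
anchor expression (the heatmap layout order). The workflow computes
correlations on log2(x + 1)-transformed normalised counts: co-expression
analysis conventionally operates on log intensities, and Pearson r on raw
skewed counts is systematically attenuated relative to the log scale
(for bivariate log-normal data with unit log-correlation the raw-scale
correlation is strictly below 1). The correlation primitive itself is
scale-agnostic; the CLI exposes `--log2/--raw`.

Hierarchical clustering uses 1 − Pearson distance with average linkage
(the defaults of the heatmap viewers this emulates), items pre-sorted by id
so ties resolve deterministically; anti-correlated items sit at distance 2.

## Group statistics

- **Mann–Whitney U** (two-sided) for tissue contrasts: exact enumeration
  when n₁ + n₂ ≤ 12 with no ties, tie-corrected normal approximation with
  continuity correction otherwise. The fully degenerate case (every value
  identical) is reported as U = n₁n₂/2, p = 1 rather than a division by a
  zero tie-corrected variance. Fold change is the ratio of group medians.
- **Boxplots** use quartiles by linear interpolation of order statistics
  (the originating software's hinge convention is not published; the
  bundled tests are convention-robust) and flag outliers strictly beyond
  1.5·IQR fences.
- **High/low partition** of tumours: high requires the value to exceed both
  mean + 2·sd (sample sd) and twice the mean of the normals, strictly.
  Both criteria scale with the data, so labels are invariant under a
  positive rescaling.
- **Knockdowns** use the unpaired two-tailed pooled-variance t test with
  fold change mean(treated)/mean(control) (control ≡ 1; log2 for heatmaps).
  Zero pooled variance is an error. The two-knockdown Venn partition counts
  genes significant in one, the other, or both arms, flagging intersection
  genes whose directions disagree.
- Raw p-values only, marked ** below 0.01 and * below 0.05; no
  multiple-testing correction anywhere, matching the reporting convention
  of the analyses modelled.

## Synthetic data

Generators are pure functions of a seeded configuration (same seed ⇒
byte-identical outputs) and emit ground-truth tables sufficient to score
every downstream module.

- **Peak replicates**: planned pairs placed on disjoint genomic slots with
  overlap fractions drawn on either side of the 0.5 cut-off
  (U(0.55, 0.95) surviving, U(0.05, 0.45) failing), FDR/TD marginals on
  either side of the gate (passing: FDR U(0, 9.5), TD U(16, 100); failing:
  FDR U(10.5, 40), TD U(1, 14)), plus partner-less peaks. Because slots are
  disjoint, the planned consensus outcome of every pair is exact. Lengths
  are U(200, 800) bp.
- **Tags**: uniform Poisson background (10⁻⁴ tags/bp) plus Gaussian
  enrichment at each summit (200 tags expected, sd 100 bp).
- **Expression**: log-normal counts, rounded — digital counts from
  biological replicates are over-dispersed relative to Poisson, and a
  log-normal model captures that with one spread parameter (natural-log
  sd 0.5). The cohort mirrors the clinical design: 24 normal vs 58 tumour
  samples (32 of the tumours late T stage), with a FOXM1-like anchor
  elevated four-fold in tumours, a 20-gene block planted at Pearson
  r = 0.8 with the anchor on the log scale (the scale the correlation
  analysis operates on; with r = 1 the block is an exact monotone function
  of the anchor), five anti-correlated genes (r = −0.6), null genes, the
  five clinical reference genes at constant level with 5% CV, a six-point
  geometric positive-control ladder, per-sample lane factors (log-sd 0.15,
  all probes) and RNA-content factors (log-sd 0.10, non-spike-ins). A
  78-sample variant (24 + 54) reproduces the size of the external cohort
  used for correlation ranking.
- **Knockdowns**: three arms (non-targeting control, siFOXM1, siLIN9),
  three replicates, per-gene planted log2 effects including one gene that
  moves in opposite directions under the two knockdowns, log2 noise
  sd 0.15.

What the generators do **not** emulate: real genomic sequence context and
peak-width/summit biases of actual peak callers, inter-gene correlation
beyond the planted block structure, batch effects, probe-specific
background, or censored/missing clinical metadata. Passing tests therefore
demonstrate correctness of the analysis rules under a controlled stochastic
model, not performance on any particular real dataset.

## Problem sizes and determinism

The bundled test suite and the acceptance script use deliberately modest
problem sizes — up to 50 peaks per replicate over ≥ 100 random instances
for the oracle-equivalence checks, 200 simulation seeds for correlation
recovery, and 2,000 null simulations for Mann–Whitney calibration — chosen
to make the whole suite run in well under a minute on one CPU while keeping
Monte-Carlo error far from the decision boundaries. All randomness flows
from explicit seeds; workflow outputs carry a provenance header (version,
config hash, seed) and are byte-identical on re-run in reproducible mode
(a timestamp line is added otherwise).

## Known limitations

- GTF parsing takes the 5′UTR as the span of annotated five_prime_utr
  features and BED12 as the TSS-to-thickStart span; genes with complex UTR
  structure are approximated by the enclosing interval.
- The per-pair FDR/TD gate follows the published wording ("in at least one
  of the experimental replicates"); a component survives if any of its
  edges survives, which is permissive for long chains.
- Multi-gene promoter assignments report a single nearest gene; alternates
  are listed but not scored.
- No read-level simulation (FASTQ/alignment) and no survival analysis.
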