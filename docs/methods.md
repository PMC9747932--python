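# Methods

## Scope and model

`bivalos` analyzes paired-end CUT&RUN fragment libraries for two histone
marks (H3K4me3, H3K27me3) in two cell types, with replicates. The unit of
observation is the *fragment* — a 0-based half-open genomic interval with a
mapping quality and (for synthetic data) a known duplicate flag. All
coordinates in the package are 0-based half-open (BED convention); for a −
strand gene the TSS is taken as the gene's `end` coordinate.

The analysis treats a promoter as the strand-aware window from 2 kb
upstream to 1 kb downstream of the TSS. Promoter state per cell type is a
four-way classification by ≥ 1 bp overlap with each mark's peak set:
`bivalent`, `K4only`, `K27only`, `none`. These states drive three
statistics:

- **Expression by state.** Two-sided Wilcoxon rank-sum (Mann–Whitney)
  contrasts of FPKM between state groups, Benjamini–Hochberg corrected
  across the reported contrasts. The scientific expectation is
  median(K4only) > median(bivalent) > median(K27only).
- **Mutually exclusive index.** With marginal promoter frequencies
  `p_K4`, `p_K27` and observed joint frequency `p_both`,
  `MEI = p_K4·p_K27 / p_both`. Orientation is expected/observed, so 1.0
  means the marks co-occur exactly as independence predicts and values
  above 1 mean bivalency is rarer than chance. The promoter universe is
  *all* annotated genes, not just marked ones. Uncertainty is a percentile
  bootstrap over genes (default 1,000 resamples, seeded). Zero cells are
  flagged (`infinite` when `p_both = 0`, `undefined` when a marginal is 0)
  rather than patched with pseudocounts, which would silently bias small
  universes.
- **Regulatory patterns.** For a cell-type-specific gene (selected at
  strict q < 0.05 and |log2FC| > 1 from a differential-expression table),
  each mark's anchored promoter signal is compared between cell types as
  `log2((s_A + f)/(s_B + f))` with a pseudo-floor `f`; |ratio| > 1 calls
  the mark higher in one type. The pattern is a pure function of the two
  calls and the expressing cell type: `derepression` (K4 similar, K27
  lower in the expressing type), `permissive_gain` (K4 higher, K27
  similar), `both`, `neither`; configurations pointing the wrong way are
  reported as `discordant`, never forced into a class. The |log2 ratio| > 1
  signal cutoff deliberately mirrors the expression cutoff; no independent
  signal threshold is claimed.

## Fragment retention

Filters run MAPQ → deduplication → insert size. MAPQ keeps ≥ 20
(inclusive). Insert-size bounds are a closed interval, 150 ≤ (end − start)
≤ 500, reading "between 150 and 500 bp" the way samtools-style closed
filters do. Deduplication keys on exact (chrom, start, end) per library and
keeps the highest-MAPQ copy (ties: first in input order). Because the
representative is MAPQ-maximal, the three filters commute — the surviving
*set* is independent of filter order, which the suite asserts on random
fixtures and which makes the generator's expected-survivor count
well-defined.

INTACT cell-counting QC: specificity = GFP+/(GFP+ + GFP−) × aliquot scale,
yield = bead-bound GFP+ / isolation GFP+ × aliquot scale, both reported as
percentages. The aliquot scale is applied verbatim and results are not
capped at 100%.

## Coverage and normalization

Fragments are counted into fixed-width bins (1 kb default) by **midpoint**
assignment: one bin per fragment, integral counts, totals conserved. This
differs slightly from overlap-weighted coverage tools; all comparisons in
the package are internal so the convention is self-consistent. CPM divides
by the total *input* fragment count (so fragments skipped for unknown
chromosomes still count in the denominator). Replicate concordance is
Pearson correlation over bins, dropping bins that are zero in every track
(the `--skipZeros` convention).

**Invariant-gene quantile anchoring.** Transcriptionally constant genes
(FPKM ≥ 1 in both cell types, |log2FC| ≤ 0.25) are assumed to carry equal
signal across samples. For each CPM track the per-bin signal inside the
constant-gene promoter windows forms a quantile vector; the cross-sample
reference is the mean of the sorted vectors (classical quantile
normalization, fixing both location and scale); each sample gets a
monotone piecewise-linear map from its own quantiles to the reference,
applied to every bin genome-wide. Numerical choices:

- knots are the actual anchor-bin values, so re-anchoring maps knots to
  themselves and the operation is idempotent (exact in the absence of
  ties; tied knot values are collapsed by averaging, which perturbs a
  second pass only at the tied values);
- beyond the observed anchor range the terminal segments extend linearly,
  so strong peaks are rescaled rather than clipped;
- mapped values are clamped at 0; the map is monotone, so within-sample
  ranks are preserved;
- a sample whose anchor signal has no spread is refused by name, as is
  anchoring with fewer than 10 constant genes.

Cross-sample promoter comparisons refuse non-anchored tracks by default.

## Peak operations

Merging uses bedtools `-d` semantics (gap ≤ threshold merges, transitively;
book-ended intervals always merge) with the merged score the maximum of the
members, preserving top-N semantics. Top-N keeps the n highest scores with
ties broken by genomic order. Overlap counting is ≥ 1 bp against any peak
of the other set, reported per set with a base-pair Jaccard. FRiP is the
fraction of fragments overlapping ≥ 1 bp of any peak and is invariant under
peak merging.

The internal caller (`call_peaks_simple`) is test plumbing: per-bin
Poisson upper tail against the genome-wide mean rate, BH-adjusted, q ≤ 0.01
bins merged when adjacent, runs shorter than 2 bins dropped. It is
deliberately not a MACS2/SICER reimplementation (no local background, no
summit refinement); pipelines on real data should ingest externally called
peak files.

## Signal matrices

Reference-point matrices average signal in 50 bp bins over ±5 kb around an
anchor; scale-regions matrices rescale region bodies to 100 bins between
fixed flanks. Both integrate the piecewise-constant track exactly
(cumulative-sum integral), so results do not depend on the ratio of track
bin to profile bin. − strand rows are reversed so column 0 is always 5′;
the suite asserts the strand involution exactly. Flank positions off the
chromosome end are missing (NaN), not zero, to avoid edge artifacts in
group means. Expression strata are high (FPKM ≥ 10), medium (1 ≤ FPKM <
10), low (< 1), with boundary values landing exactly as written.
Metaprofiles are per-group column means with a seeded percentile bootstrap
band (default 1,000 resamples, 95%).

## Synthetic-data generator

The generator emulates the statistical structure of an INTACT + CUT&RUN
experiment on two neuronal subtypes; it is the ground truth against which
every downstream stage is tested.

- **Annotation**: non-overlapping genes (2–8 kb) placed one per
  equal-width slot with ≥ 10 kb guaranteed spacing, random strands; single
  chromosome by default, multi-chromosome supported.
- **States**: per-gene states drawn from configurable proportions
  (default K4only 0.40, bivalent 0.15, K27only 0.20, none 0.25); the
  second cell type shares the first's state with probability `coupling`
  (default 0.8, so most bivalent domains are shared). A
  `specific_gene_fraction` (default 0.05) of genes is overwritten with
  cell-type-specific configurations cycling through derepression
  (K4only vs bivalent), permissive_gain (K4only vs none) and both
  (K4only vs K27only), alternating the expressing cell type.
- **Expression**: log-normal FPKM driven by state, log2 means 4 / 1.5 /
  −1 / −2 for K4only / bivalent / K27only / none, sd 1.0 (in log2-FPKM),
  5 replicate libraries per cell type. With sd = 0 expression is an exact
  function of state. The differential table uses a label-permutation test
  (1,000 shuffles) on a studentized mean-difference with a SAM-style
  variance offset (s0 = median SE across genes), pooling the permuted
  statistics across genes into one empirical null; a per-gene permutation
  test with 5+5 replicates has a p-value floor of 2/C(10,5) ≈ 0.008 and
  could never clear a q < 0.05 gate, while the pooled null reaches
  p ≈ 1/(n_genes·n_perm). BH adjustment gives the q-values.
- **Fragments**: marked promoters receive fragments at `enrichment` ×
  background (default 20×), placed by a truncated normal centered on the
  promoter window; background is uniform. Fragment length ~ Normal(200,
  30) clipped to [50, 700] — mass deliberately on both sides of the
  150–500 retention window so the size filter is exercised. PCR
  duplicates are injected at rate 0.1 as exact coordinate copies (the
  base set is drawn collision-free, so the injected count is exactly the
  removable count); 10% of records get MAPQ < 20. The per-sample
  **efficiency** scalar (default A2a 1.5 vs D1 1.0, configurable)
  multiplies total depth *and* the enrichment excess
  (`e_eff = 1 + s·(e−1)`): a depth-only scalar would be cancelled exactly
  by CPM, whereas real capture-efficiency differences move the share of
  reads in peaks, which is the distortion invariant-gene anchoring
  exists to remove.
- **Manifest**: every parameter, seed and realized count (including the
  exact expected survivor count of the retention filters) is recorded;
  datasets regenerate byte-identically from (config, seed).

What the generator does **not** emulate: sequence-level reads (no FASTQ,
no alignment or mappability structure), nucleosome positioning, GC or
fragmentation bias, broad-domain K27me3 spreading beyond promoters, optical
duplicates, or biological replicate variability beyond Poisson sampling.
Passing recovery tests therefore demonstrates correctness of the
*computations* under the stated statistical model, not robustness to every
artifact of real libraries.

## Problem sizes and tolerances in the test suite

Tests run on genomes of 100–2,000 genes (1.2–80 Mb) at depths of
3,000–80,000 fragments per library — sizes chosen so the full suite runs in
seconds while leaving binomial/Poisson sampling error well inside the
asserted bounds. Stochastic assertions fix their seeds. Exact assertions
(filter bookkeeping, oracle equivalence, strand involution, idempotency at
1e-9) use constructions where exactness is provable: collision-free
duplicate injection, enumeration oracles ≤ 100 elements, knot-exact
quantile maps on tie-free tracks.

## Known limitations

- The caller's global-mean background under-calls peaks on genomes where
  enriched regions are a large fraction of bins (background estimate
  inflated); synthetic genomes keep promoter bp ≪ genome bp.
- Quantile anchoring assumes constant-gene promoters sample the signal
  range representatively; a mark absent at every constant gene anchors on
  background quantiles and relies on the linear tail extension for peaks.
- The MEI bootstrap treats genes as exchangeable; spatial correlation
  between neighboring promoters is not modeled (nor generated).
- Multi-set (3+) peak overlap categories are derived from pairwise
  overlaps only.
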