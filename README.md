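# bivalos

Promoter bivalency and cell-type-specific histone-mark analysis for
paired-end CUT&RUN fragment data.

## The problem

Two histone modifications jointly describe a promoter's regulatory state:
H3K4me3 (permissive, marks expressed genes) and H3K27me3 (repressive, marks
silenced genes). Promoters carrying **both** marks are *bivalent* and tend to
be expressed at an intermediate level. When the same two marks are profiled
in two related cell types — for example striatal A2a- and D1-type medium
spiny neurons isolated by affinity purification of tagged nuclei — the pair
of per-mark profiles can explain *why* a gene is expressed in one subtype
and not the other: the permissive mark may be gained in the expressing
subtype, or the repressive mark may be selectively lost there
(*de-repression*, the Egr3-style configuration), or both.

`bivalos` implements the downstream analysis for such an experiment, from
aligned fragment intervals to regulatory-pattern calls, together with a
ground-truth synthetic-data generator so every stage is testable offline:

1. **Fragment QC** — keep MAPQ ≥ 20, remove coordinate duplicates, keep
   inserts of 150–500 bp; INTACT cell-counting specificity/yield.
2. **Coverage & normalization** — fragment counts in fixed bins (1 kb
   default), counts-per-million (CPM), genome-wide replicate correlation,
   and *invariant-gene quantile anchoring*: samples are mapped onto a common
   scale using signal at transcriptionally constant genes (equal expression
   in both cell types ⇒ signal assumed equal), removing global
   efficiency/depth distortions that CPM cannot see.
3. **Peak operations** — merge within 5 kb, top-N by score, ≥ 1 bp overlap
   counting, FRiP, plus a minimal Poisson caller used only on synthetic data.
4. **Profiles** — reference-point (TSS ± 5 kb) and scale-regions signal
   matrices, stratified by expression (FPKM ≥ 10 / 1–10 / < 1).
5. **Bivalency** — four-way promoter states from peak overlap with the
   −2 kb/+1 kb TSS window; Wilcoxon rank-sum expression contrasts
   (BH-corrected); the **mutually exclusive index**

   `MEI = (p_K4 × p_K27) / p_both`

   the ratio of the co-occurrence expected under independence to the
   observed co-occurrence; 1.0 means no interaction, > 1 means the marks
   avoid each other (bivalency rarer than chance).
6. **Cell-type comparison** — cell-type-specific genes (q < 0.05,
   |log2FC| > 1), anchored promoter-signal log-ratios per mark, and the
   regulatory-pattern classifier (`derepression` / `permissive_gain` /
   `both` / `neither`, discordant configurations flagged).

## Worked example

Simulate a two-cell-type experiment with known promoter states, then run
the analysis for one cell type:

```python
import pandas as pd
from bivalos import *
from bivalos.synthetic import SimulationConfig

ds = simulate_dataset(SimulationConfig(n_genes=300, chrom_length=6_000_000,
                                       depth=30_000), seed=1)
ct = "A2a"
peaks = {}
for mark in ("H3K4me3", "H3K27me3"):
    frags = pd.concat([ds.fragments[(mark, ct, r)] for r in (1, 2)],
                      ignore_index=True)
    kept, counts = apply_retention_filters(frags)
    track = bin_coverage(kept, ds.genome, 500)
    peaks[mark] = call_peaks_simple(track)

states = classify_promoter_states(peaks["H3K4me3"], peaks["H3K27me3"],
                                  ds.genome, cell_type=ct)
mei = mutually_exclusive_index(states, n_boot=1000, seed=1)
tests = compare_expression_by_state(states, ds.expression.fpkm[ct])
```

Output:

```
H3K4me3: 90000 fragments -> 70179 after filtering
  169 peaks, FRiP = 0.724
H3K27me3: 90000 fragments -> 70050 after filtering
  102 peaks, FRiP = 0.612
state counts: {'K4only': 123, 'bivalent': 46, 'K27only': 56, 'none': 75}
mutually exclusive index = 1.25 (95% CI 1.07-1.53)
bivalent vs K4only: median 2.8 vs 16.0, W = 0, BH p = 3.35e-23
bivalent vs K27only: median 2.8 vs 0.5, W = 2576, BH p = 4.78e-18
```

Reading: roughly 22% of fragments were removed by the retention filters
(duplicates, low MAPQ, out-of-range inserts). Bivalent promoters sit at an
intermediate expression level — median FPKM 2.8, between the K4-only
(16.0) and K27-only (0.5) groups, both contrasts highly significant — and
the index of 1.25 (CI excluding 1.0) says the two marks co-occur somewhat
less often than independent placement would predict.

The same pipeline runs from the shell:

```sh
bivalos simulate --out data/ --seed 1
bivalos qc --in data/fragments/H3K4me3_A2a_rep1.bedpe --out filtered.bed
bivalos run --config pipeline.yaml          # full orchestration + report.md
```

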