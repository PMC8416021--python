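# dsbscreen

Quantification tools for two genomic readouts of DNA double-strand-break
(DSB) end protection in non-cycling cells:

1. **FACS-sorted pooled CRISPR screens.** Cells carrying a genome-wide
   guide library are irradiated and sorted on chromatin-bound RPA — a proxy
   for single-stranded DNA at resected break ends — into RPA-high (top 10%)
   and RPA-low (bottom 10%) gates. Guides knocking out end-protection
   factors accumulate in the RPA-high gate. `dsbscreen` extracts the
   19–20 nt spacer from each sequencing read using the fixed vector context
   around it, counts reads per guide, and scores enrichment between gates.

2. **End-seq resection profiling.** End sequencing maps the exact genomic
   position of every DSB end. Around a programmed cut (e.g. an AsiSI
   site), nucleolytic resection displaces the sequenced end away from the
   cut — rightwards on the + strand, leftwards on the − strand.
   `dsbscreen` aggregates strand-aware end records (BED) around known cut
   sites into binned distance profiles, per-site resection-extent
   estimates, and genome-wide heatmap matrices.

Both arms come with synthetic-data generators (with truth tables) so the
entire analysis is testable end to end without any external data.

## Model and scoring

Raw counts are normalized per sample to reads-per-million with a unit
pseudocount:

```
n_gs = c_gs / (Σ_g' c_g's) × 10⁶ + 1
```

where `c_gs` is the read count of guide *g* in sample *s*. Unobserved
guides sit exactly at 1, so every ratio is finite, and
`Σ_g (n_gs − 1) = 10⁶` in every sample. The enrichment score of a guide
for a sample pair (numerator, denominator — by default RPA-high over
RPA-low) is the ratio of its normalized abundances:

```
score_g = n_g,high / n_g,low
```

Genes are ranked by a summary of their guides' scores (median by default;
second-best and count-above-threshold are alternatives). No variance model
or p-value is attached — the screen ranks by fold enrichment.

Resection extent at a cut site is estimated per side as a high quantile
(default 0.95) of the absolute end-to-cut distances, with a minimum
support of 5 ends; sites are compared across genotypes (e.g. an
end-joining-deficient control with protected ends vs a resection-proficient
mutant) as per-site extent deltas.

## Worked example

Simulate a desk-scale sorted screen (120 genes × 5 guides, 2×10⁵ reads per
gate, six genes planted at 8-fold in the RPA-high gate), count the reads
and rank genes:

```python
from dsbscreen import (ScreenSimConfig, simulate_screen, count_reads, AnchorConfig,
                       normalize, enrichment, rank_genes)

cfg = ScreenSimConfig(samples=("high", "low"), seed=7)
sim = simulate_screen(cfg, "demo/sim")
counts = count_reads(sim.fastq_paths, sim.library,
                     AnchorConfig(spacer_length_range=(19, 19)))
scores = enrichment(normalize(counts), "high", "low")
summary = rank_genes(scores, sim.library, statistic="median")
print(summary[["n_guides", "median_score", "max_score"]].head(8).round(2))
print("planted:", sorted(cfg.planted_hits))
```

which prints

```
          n_guides  median_score  max_score
gene
gene0001         5          6.39       6.70
gene0005         5          6.26       7.17
gene0003         5          6.12       6.38
gene0004         5          5.98       6.71
gene0002         5          5.81       6.80
gene0006         5          5.72       6.11
gene0014         5          0.96       1.12
gene0049         5          0.93       0.98
planted: ['gene0001', 'gene0002', 'gene0003', 'gene0004', 'gene0005', 'gene0006']
```

All six planted genes rank on top, with median per-guide enrichment near
the planted 8-fold (attenuated slightly by within-sample renormalization
and sampling noise); unplanted genes sit at ~1.

The same stages are available from the shell:

```sh
dsbscreen simulate-screen --out-dir sim --seed 7
dsbscreen count --library sim/library.tsv --samples sheet.tsv \
    --spacer-min 19 --spacer-max 19 --out counts.tsv
dsbscreen score --counts counts.tsv --library sim/library.tsv \
    --num high --den low --out-dir results/
dsbscreen simulate-endseq --out-dir es --genotype resected --seed 7
dsbscreen resect --sites es/sites.bed --ends es/ends.bed --out-dir profiles/
```

and as one reproducible run (`dsbscreen run --config run.yaml`) that writes
a resolved config and a checksum manifest next to its outputs.

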