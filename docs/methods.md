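# Methods

## Screen quantification

### Read layout and spacer extraction

A pooled-screen amplicon read is assumed to have a fixed layout: constant
vector sequence (the end of the U6 promoter), the variable 19–20 nt
spacer, then the invariant gRNA scaffold. Extraction locates the upstream
anchor by a bounded-Hamming scan over all read offsets (no indels — the
amplicon layout is fixed, so substitutions are the only error mode worth
modelling), taking the occurrence with the fewest mismatches and the
leftmost on ties. The spacer is the following segment, trimmed at the
downstream anchor when it occurs within the allowed length window
(shortest placement wins); otherwise the next max-length bases are taken.
When the read ends inside the downstream anchor, a truncated prefix of at
least 3 bases still counts as an occurrence; fewer than 3 remaining bases
carry too little information to anchor on. `N` bases are kept in the
extracted spacer and simply fail the exact library lookup downstream.

Anchor sequences are configuration, not measured fact: sequencing setups
differ in where the read starts relative to the spacer. The defaults are
the canonical lentiviral-vector context — `TGGAAAGGACGAAACACCG` upstream
(U6/spacer junction) and `GTTTAAGAGCTAAGCTGGAA` downstream (scaffold
start) — with one tolerated mismatch.

### Counting

Extracted spacers are matched to the library exactly (no mismatch rescue
by default; a one-mismatch rescue mode exists for sensitivity analysis but
keeps counts auditable when off). Spacers carried by two or more guides
are tracked explicitly: the default `discard` policy drops such reads into
their own QC tally, preventing double counting; the `fractional` policy
credits 1/k to each of the k carriers. Every read lands in exactly one QC
tally, so

    total = extracted + no_anchor + bad_length
    extracted = matched + unmatched_spacer + ambiguous_discarded

hold for every sample, and counts are conserved end to end. Guides never
observed get an explicit zero.

### Normalization and enrichment

Counts are normalized per sample as reads-per-million plus a unit
pseudocount, `n = c / total × 10⁶ + 1`, so unobserved guides sit exactly
at 1 and `Σ(n − 1) = 10⁶` in every sample. A guide's enrichment score for
a sample pair is the ratio of its normalized abundances; the default pair
is RPA-high over RPA-low, and the inverted pair recovers guides depleted
for resection capacity (the mirrored screen design). The pseudocount
makes scores finite everywhere at the cost of compressing ratios for
low-abundance guides; with counts ≥100 the compression is under 2% and
scores become scale-invariant in the large-count limit.

No variance model is attached. The method ranks by fold enrichment, and
gene-level evidence is the consistency of a gene's guides: the default
gene statistic is the median guide score (robust to one noisy guide), with
`second_best` (demands two supporting guides) and `count_above` (default
threshold 4) as alternatives. Ranking is descending with a lexicographic
gene-name tie-break, so outputs are deterministic. Antisymmetry of the
score — `score(a,b) × score(b,a) = 1` — is an algebraic identity of the
ratio; in double precision the product is within a few ulp of 1, and the
tests assert it at 4·eps.

## End-seq resection profiling

This module starts from aligned, strand-aware end records (BED6), not raw
reads: the blunting/ligation chemistry and genome alignment upstream are
standard and out of scope, while the quantification downstream of
alignment is what the profiling figures embody. Coordinates are 0-based
half-open; a site's window is `[cut − W, cut + W)` with W = 5 kb by
default, comfortably containing ≤2 kb resection tracts, binned at 25 bp
for single-bin resolution near the cut. Site windows must not overlap
(closer than 2W is an error); each end is assigned to the unique window
containing it, with signed distance `end − cut`, and ends outside every
window are tallied, so assigned + unassigned equals the input.

Side semantics follow the strand: a `+` end is the right-moving
(top-strand) resection front, a `−` end the left-moving one. Per side,
**resection extent** is the 0.95 quantile of absolute distances, with a
minimum support of 5 ends (below which the extent is flagged undefined
rather than estimated). A pure maximum would be a single-read statistic;
a high quantile is robust to stray ends yet tracks the far edge of the
signal, and it is exactly equivariant under scaling and monotone in the
quantile level. Both the quantile and the support threshold are
configurable; the per-site maximum is available in the profile signal.

Heatmap matrices are sites × bins (left→right across the cut), rows
sorted by total signal or extent with site-id tie-break; `per_million`
normalization divides by total assigned ends / 10⁶, so the matrix sums to
10⁶ when every end is assigned. Genotype comparison requires identical
site sets and reports per-site extent deltas plus median extents.

## Synthetic data

The screen generator models sorting at the abundance level: baseline guide
abundances are log-normal (σ = 1), a planted gene multiplies its guides'
sampling probability by its fold change in the relevant gate
(renormalized), and each sample is one multinomial draw. Gate physics
(per-cell fluorescence, gating) is deliberately not simulated — the
pipeline under test begins at sequenced gDNA. Reads are the fixed vector
context around each spacer with i.i.d. substitution errors; quality
strings are constant because the pipeline is quality-agnostic. Defaults
are desk scale, chosen so the whole chain runs in seconds while leaving
sampling noise in play: 120 genes × 5 guides, 19 nt spacers, 2×10⁵ reads
per sample, 50 bp reads, 0.1% per-base error, six genes planted at
8-fold. Sequencing depth per sorted gate is a declared assumption (none
is published for this design); 2×10⁵ reads over 600 guides reproduces the
~300× mean coverage a real screen would target. The truth table (exact
per-guide probabilities and multinomial draws per sample) is written next
to every dataset and suffices to score recovery exactly.

The End-seq generator places sites on one synthetic chromosome at
11 kb spacing, draws a side per end with equal probability and a tract
length from the genotype's distribution: `protected` is uniform on
[0, 150 bp] (under the 200 bp ceiling of an end-joining-proficient
control), `resected` is exponential with mean 600 bp hard-truncated (by
rejection) at 2 kb. The truth table carries the closed-form 95th
percentile of each tract distribution — `0.95·L` for the uniform and
`−m·ln(1 − 0.95·(1 − e^{−c/m}))` for the truncated exponential — against
which the estimator is checked. An optional uniform background-end rate
(default 0) models nonspecific ends. Not modelled: PCR jackpots, indels,
chromatin accessibility bias, and inter-site variation in cutting
efficiency beyond multinomial noise — so passing tests demonstrate the
correctness of the computation under the stated statistical model, not
robustness to every artefact of real libraries.

## Numerical and design choices

- All randomness flows from one integer seed through a single
  `numpy.random.Generator`; identical config + seed gives byte-identical
  output files. Floats in reports are printed at fixed precision
  (`%.10g`) so reruns are byte-comparable.
- Quantiles use linear interpolation (numpy default); extent therefore
  interpolates between order statistics, which keeps it monotone in the
  quantile and exactly equivariant under scaling of distances.
- Ambiguous-spacer guide lists, gene rankings and profile orderings all
  carry deterministic lexicographic tie-breaks.
- Degenerate inputs fail loudly and specifically: zero-total samples,
  overlapping site windows, mismatched site sets, malformed FASTQ records
  (with record number) and invalid configs (naming the field) are hard
  errors; empty FASTQs, guides with zero reads and sites below the extent
  support threshold are valid data, not errors.
- The fold-enrichment denominator is configurable (RPA-low by default,
  unsorted supported) since both baselines are defensible.

## Known limitations

- Anchor search tolerates substitutions only; reads with indels inside
  the anchor are dropped to `no_anchor`.
- Exact spacer matching cannot rescue guides whose reads always carry a
  synthesis error; the one-mismatch rescue mode trades auditability for
  sensitivity and refuses to guess when two library spacers are equally
  close.
- The extent estimator reports the quantile of observed end positions; at
  low coverage it underestimates the true tract-length quantile, and the
  minimum-support rule leaves sparse sites undefined rather than noisy.
- Gene ranking carries no error model; two genes with near-identical
  statistics order lexicographically, and significance claims are outside
  scope.
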