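# hicarch

Comparative Hi-C analysis of chromatin architecture in two cell types, built
around the question of how topologically associating domains (TADs)
reorganize during differentiation — e.g. between *Drosophila* embryonic
(Kc167) and neuronal (BG3) cell lines. The package covers the full desk
side of such a study:

- **Restriction-fragment binning** — digest a genome with a 4-base cutter
  (DpnII, `GATC`), merge fragments closer than 150 bp, split fragments wider
  than 1 kb, and use the resulting bins as the contact-matrix coordinate
  system.
- **Contact matrices** — bin read pairs, merge replicates, down-sample
  libraries to matched depth (exact multivariate hypergeometric), distance
  decay curves, log2 ratio maps between cell types, observed/expected
  transforms and distance-stratified enriched contacts.
- **Correction** — coverage diagnostics in MAD units of log2 coverage,
  bin masking, and matrix balancing by iterative correction (ICE) or
  Knight–Ruiz (KR).
- **TAD borders** — multi-window diamond TAD-separation score on
  per-diagonal z-normalized counts; borders at significant local minima
  (delta ≥ 0.04, rank-sum p, FDR), graded strong (delta ≥ 0.08) or weak,
  and classified across cell types as conserved (identical coordinate),
  fuzzy (shifted < 2 kb) or cell-type-specific (≥ 2 kb from any counterpart).
- **Divergent transcription** — strand-specific signal profiles around
  borders, and the directionality score
  `D = log10(R+ / R−)` over 500-bp windows offset 500 bp from the border;
  `|D| < 0.47` (less than three-fold strand asymmetry) calls a border
  bidirectional. Mann–Whitney U and Kolmogorov–Smirnov comparisons between
  cell types use exact small-sample enumeration.
- **Loops and compartments** — a donut-filter loop caller (local annulus
  expectation, Poisson upper tail, Benjamini–Hochberg at FDR 0.05, 20-kb
  peak merging) with loop placement relative to TADs; A/B compartments from
  the leading eigenvector of the O/E Pearson correlation matrix,
  sign-oriented by GC content, with switch summaries between cell types.
- **Annotation statistics** — enhancer specificity classes (cell-specific
  vs common by mutual overlap), border–interval overlap tables, Fisher's
  exact test and a label-permutation test for differences between two
  proportions.
- **Synthetic data** — a generator that plants all of the above (power-law
  decay with within-TAD enrichment τ, shared/specific borders, GC-correlated
  checkerboard compartments, focal loops, multiplicative bin bias,
  divergent transcription tracks, border-linked annotations) with a full
  ground-truth record, so every stage is validated by parameter recovery.

## Worked example

Run the whole pipeline on a seeded standard simulation (two cell types,
500 bins × 2 kb, one million contacts each):

```sh
hicarch run --seed 1 --out demo_out
```

This writes per-stage outputs (COO matrices, border/loop/compartment
tables, truth JSON) under `demo_out/` and prints a summary; abridged:

```json
{
  "n_borders_A": 7,
  "border_classes_A": {"conserved": 4, "specific_A": 3},
  "loop_classes_A": {"within_tad": 8, "at_border": 2, "between_tads": 1},
  "compartment_switching": {"A_to_B": 0.002, "B_to_A": 0.19, "...": "..."},
  "percent_bidirectional_A": 100.0,
  "grb_fisher_p": 0.43,
  "border_recall_A": 1.0,
  "border_precision_A": 1.0,
  "compartment_accuracy_A": 0.994
}
```

Reading it: the caller found all 7 planted borders of cell A at the exact
bin (`border_recall_A`/`border_precision_A`), classified 4 of them as
conserved with cell B and 3 as A-specific, placed most loops inside TADs,
measured the planted compartment flip between the cell types
(`B_to_A = 0.19` of jointly classified bins), and found no significant
enhancer/GRB enrichment difference between border classes at this small
border count (`grb_fisher_p = 0.43`). All borders carry planted symmetric
divergent transcription, hence 100% bidirectional at the 0.47 cutoff.

Individual stages are available as library functions
(`hicarch.tad_separation_score`, `hicarch.call_loops_donut`, …) and as CLI
subcommands (`hicarch digest`, `hicarch matrix build|merge|downsample`,
`hicarch correct apply`, `hicarch simulate`).

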