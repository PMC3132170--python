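# hicbreaks

Tested, reusable pipeline for asking whether pairs of loci that are
genomically distant in one genome but adjacent in a second genome
("breakpoint pairs", the footprint of evolutionary rearrangements) show
elevated chromatin contact frequency in binned Hi-C data — controlling
for genomic distance, gene density, DNaseI sensitivity, and
segmental-duplication (SD) mapping bias.

## What it does

1. **Breakpoint detection and pairing** (`hicbreaks.breakpoints`) —
   breakpoints are regions between consecutive synteny blocks whose
   orthologous blocks are not consecutive (or not in the same relative
   orientation) on the partner genome; chromosome ends can be treated as
   telomere breakpoints.  Each partner-genome breakpoint links two
   breakpoints on the focal genome into a pair.  Pairs whose members
   belong to no other pair are *reciprocal* (single simple events);
   shared members mark *non-reciprocal* pairs (breakpoint re-use).  With
   an outgroup, each pair is assigned a lineage of origin when both
   members support the same, strictly parsimonious call.
2. **Hi-C processing** (`hicbreaks.hic`) — fixed 1-Mb windows on the
   autosomes; windows more than half covered by assembly gaps are
   discarded; read pairs are binned into unordered window pairs.
   Corrected counts discard SD-involved reads and rescale:
   `NRCSD = (NR - SDR) / ((1 - FSD1)(1 - FSD2))`.  Note: the published
   description of this correction omits the algebraic expression; the
   form above is the simple estimator implied by its stated assumption
   that read density inside SDs matches the surrounding sequence.
3. **Analysis table** (`hicbreaks.pair_table`) — per locus pair: counts,
   genomic distance, breakpoint-pair flag (breakpoints assigned to the
   window containing their midpoint), gene-density and DNase covariates
   as products of per-locus values, natural-log transforms.
4. **Association tests** (`hicbreaks.association`) — nested OLS models
   M0–M8 of log count on log distance, the breakpoint flag and
   covariates, compared by extra-sum-of-squares F tests; a two-sided
   rank-sum test for inter-chromosomal pairs; and a stratified
   resampling null (distance / gene-density / DNase classes, 500
   resamples by default, one-sided empirical p with the +1 correction).
5. **Synthetic data** (`hicbreaks.simulate`) — ground-truthed fixtures:
   two-lineage rearrangement histories (inversions, translocations) with
   known pairs and origins; contact counts with log-linear distance
   decay (slope −0.8, intercept 6 on the natural-log scale by default)
   plus an additive breakpoint effect; covariate tracks with optional
   enrichment at breakpoint loci; and an SD multi-mapping bias that
   relocates reads between SD copies while conserving totals.

All logarithms are natural logs.  All coordinates are 0-based half-open
internally; BED/bedGraph files are read and written in their native
conventions.

## CLI

```sh
# simulate a fixture bundle with known ground truth
hicbreaks generate demo/ --seed 1

# check the inputs, then run everything
hicbreaks validate demo/config.yaml
hicbreaks run-all demo/config.yaml
```

Other subcommands: `pairs` (breakpoint pairing from a block table),
`hic` (grid + corrected pair counts), `table`, `test`.  A run writes
`breakpoint_pairs.tsv`, `pair_table.tsv`, `locus_tracks.tsv`,
`report.tsv`/`report.txt` and a reproducibility `manifest.json` (config
hash, seeds, versions, record counts per stage) into the configured
output directory; reruns with the same config are byte-identical.

Input formats: synteny block table (TSV: `block_id`, then chrom / start /
end / strand for each genome), chrom.sizes, BED (gaps, SDs, genes),
bedGraph (DNase), and sparse count triples (`bin_i`, `bin_j`, `count`,
optional read-level `sdr`) with a companion bin BED.

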