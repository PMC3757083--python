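# crossonco

Cross-species comparative oncogenomics of tumor copy-number alterations
(CNAs): find candidate cancer driver genes inside large, gene-rich CNAs by
intersecting recurrence calls from two distantly related species.

Aneuploid tumors gain and lose whole chromosomes carrying hundreds of
genes, and recurrence analysis alone cannot say which of those genes drive
the tumor. If the same tumor type is profiled in a species whose genome is
heavily rearranged relative to human — zebrafish, separated by ~450 My and
one extra whole-genome duplication, with 90% of conserved synteny blocks
under 10 genes — then passengers co-amplified with a driver in one species
are usually *not* co-amplified in the other. Requiring a gene to be gained
(or lost) in **both** species filters out most passengers while keeping
conserved drivers. This package implements that comparison end to end, for
computational cancer biologists who have segmented copy-number profiles
(or binned tumor/normal counts) from two cohorts.

## What it computes

- **Recurrence** (GISTIC-style): per-gene G-scores
  `G(g) = (1/S) Σ_s max(0, ±v_gs − θ)` with θ = 0.2, permutation p-values
  (within-sample permutation null, pooled over genes), Benjamini–Hochberg
  Q-values, frequency tracks; binary region calls (chromosome-scale
  "large" vs sub-10-Mb "focal"), a focal mode with background removal and
  peel-off, sub-peak finding, and subgroup t-tests.
- **Segmentation**: circular binary segmentation of binned tumor/normal
  log2 ratios (permutation split test, outlier smoothing, undo.SD-style
  merge-back), or direct ingestion of externally segmented SEG files.
- **Orthology**: reciprocal best hits from a similarity table, refined by
  conserved synteny (100-gene ordinal windows) so that second fish
  paralogs from the teleost whole-genome duplication are kept; conserved
  synteny block chaining and size histograms.
- **Cross-species intersection**: per-gene concordance classification,
  region-level filtering summaries, focal∩focal and focal×large candidate
  lists, chromosome-by-chromosome intersection matrices.
- **miRNA families**: identifier-core family matching with the
  "same polarity in both species, no member opposite" exclusivity rule.
- **Chromothripsis flag**: per sample-chromosome detection of oscillation
  between two copy-number states.
- **Synthetic data**: a first-class generator producing genome pairs with
  known orthology and tumor cohorts with planted events, so every stage
  can be tested against ground truth.

## Worked example

`examples/` holds one short script per capability. Recurrence calling on
the default synthetic fish cohort (147 tumors, 25 chromosomes, planted
9 gained and 6 lost chromosomes):

```bash
$ python examples/02_recurrence.py
matrix: 5205 genes x 147 samples
large gains called on chromosomes:  ['3', '4', '5', '9', '10', '14', '16', '20', '24']
   (planted: ['3', '4', '5', '9', '10', '14', '16', '20', '24'])
large losses called on chromosomes: ['6', '8', '12', '15', '18', '21']
   (planted: ['6', '8', '12', '15', '18', '21'])
8 focal regions (< 10 Mb) — these hold the planted focal drivers plus any recurrent byproducts
```

Every planted whole-chromosome alteration is recovered and nothing else is
called at chromosome scale. The passenger filter itself
(`examples/04_cross_species_filter.py`) prints the per-region summary: how
many genes each human CNA holds, how many have a fish ortholog, and what
fraction the fish comparison filters out (typically half to two-thirds,
purely from broken synteny, when the species are simulated independently).

The same stages are available from the shell via the thin CLI
(`crossonco simulate|segment|recur|ortho|compare|mirna|chromothripsis|report`).

## Layout

```
src/crossonco/        library (model, io, simulate, segmentation, recurrence,
                      orthology, cross_species, mirna, chromothripsis, cli)
src/crossonco/data/   packaged worked-example tables
examples/             one narrative script per capability
tests/                pytest suite (unit, property, end-to-end)
docs/methods.md       models, assumptions, parameters, limitations
```
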