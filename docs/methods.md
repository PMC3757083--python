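# Methods

`crossonco` implements a cross-species comparative oncogenomics pipeline for
tumor copy-number alterations (CNAs): it calls recurrent gains and losses in
a zebrafish-like and a human-like tumor cohort, maps genes between the two
species, and keeps as candidate drivers only the genes altered in the same
direction in both — the rationale being that two genomes separated by ~450 My
and one whole-genome duplication are so rearranged that passengers linked to
a driver in one species are unlinked in the other.

## Copy-number representation

A tumor is a `SampleProfile`: non-overlapping segments per chromosome with a
mean log2 ratio relative to the sample's **baseline ploidy** (3N for the
near-triploid fish tumors, 2N for human). Value 0 therefore means "at the
tumor's modal state", not "diploid". Coordinates are 1-based inclusive, the
SEG-file convention; all interval logic goes through `Segment.contains` and
`GeneRecord.midpoint`.

A gene's value in a sample is the value of the segment containing the gene's
**midpoint**; genes straddling a breakpoint are thus valued unambiguously
(an open design point — the midpoint rule is this package's choice).
Midpoints not covered by any segment are gap-filled with 0.

## Recurrence (G-scores and permutation Q-values)

For cutoff θ (default 0.2) and polarity p:

    G_gain(g) = (1/S) Σ_s max(0, v_gs − θ)
    G_loss(g) = (1/S) Σ_s max(0, −v_gs − θ)

The null permutes each sample's gene values independently (preserving each
tumor's alteration burden, destroying locus identity) and pools null G over
genes and permutations: p(g) = (1 + #null ≥ G(g)) / (1 + N_null). Q-values
are Benjamini–Hochberg per polarity; thresholding Q < 0.25 is identical to
−log10 Q > 0.602. Normalizing G by sample count is a scale choice only; all
calls depend on ranks and Q.

**Focal mode** subtracts, per sample and chromosome, the sample's median
value on that chromosome — whole-chromosome events vanish, focal departures
survive — then finds peaks iteratively: score, take the top significant
gene, record the contiguous significant run around it, zero the supporting
samples' values over the run (peel-off), re-score. Because the maximal
overlap core of a recurrent focal event is a *plateau* of near-equal G, the
reported peak gene is the central gene of the ≥95%-of-max plateau (the
minimal-common-region midpoint), not the noise-determined argmax.

**Region calling**: maximal runs of ordinal-consecutive genes with Q below
the species cutoff (fish 0.25; human 10^−0.2 ≈ 0.63 — the human cohort has
only 23 samples, so its cutoff is deliberately permissive). A region is
*focal* if it spans under 10 Mb, or if a focal-mode peak covers at least
half of its genes; otherwise *large*. A small amplification riding inside a
whole-chromosome gain does not downgrade the chromosome-scale call. Gain
and loss regions may overlap (focal gains inside lost chromosomes are real
and expected). Repeat-rich regions one wishes to exclude are handled by
filtering the gene annotation before matrix construction.

**Sub-peaks** inside a region are local maxima of −log10 Q with a
prominence floor (scipy peak finding on a padded track, so boundary maxima
count and plateaus resolve to their leftmost gene).

**Subgroup tests**: per chromosome, each sample is summarized by its median
gene value; subgroups (initiating genotype, starting ploidy) are compared
with a two-tailed pooled-variance t-test.

## Segmentation

For binned paired tumor/normal counts: r_i = log2((t_i·s + c)/(n_i + c))
with library-size scale s and pseudocount c, median-centered genome-wide so
the modal state is 0 (this is what anchors a near-triploid tumor to its 3N
baseline). Circular binary segmentation then recursively takes the arc
maximizing the two-sample t-statistic against its complement, accepts the
split at within-segment permutation p < α (default 0.01, 1000 permutations
with early stopping), optionally shrinks isolated single-bin outliers
first, and finally merges adjacent segments whose means differ by less than
`undo_sd` (default 1) pooled within-segment standard deviations. Segment
means are exactly their member-bin means. Externally segmented SEG input
bypasses this module entirely.

## Orthology

The similarity table stands in for protein similarity-search bit scores.
Reciprocal best hits (RBH) give primary assignments; exact ties are kept as
ambiguous candidates. Each fish gene's candidate set is its hits within
`tie_ratio` (0.9) of its best hit. Unambiguous RBHs are accepted first;
remaining cases are arbitrated by **conserved synteny**: a candidate pair's
support is the number of context pairs within W = 100 ordinal positions in
*both* species on the same chromosomes. The context is the accepted pairs
plus every unresolved fish gene's provisional best hit — necessary so that
a block of co-retained second paralogs (post whole-genome duplication) can
support itself; with accepted-only context such blocks could never
bootstrap. The winner maximizes (support, score, lexicographic id) and is
accepted if it is an RBH or has positive support; the latter clause admits
second fish paralogs that are only one-way best hits to an already-claimed
human gene. Accepted pairs form a function fish→human; a human gene may
keep up to two fish paralogs. With no synteny information (single-gene
chromosomes) the result reduces to pure RBH.

Synteny blocks are greedy chains of accepted pairs along the human order:
a pair extends the block iff within W ordinals of the last pair in both
species on the same chromosome pair. Size-1 blocks are reported separately
from the 2–10 bin.

## Cross-species intersection

Every human protein-coding gene is classified: its human polarity/scope
from region membership (midpoint containment), its fish orthologs' states
likewise. A gene is *co-gained* iff it is in a human gain and ≥1 fish
ortholog is in a fish gain (symmetric for loss). An opposite-polarity fish
hit is recorded but does **not** veto — the veto is deliberately reserved
for the miRNA rule, which states it explicitly. Genes in both a gain and a
loss region carry both polarities and appear in both polarity summaries.

The region summary reports, per human region (focal regions pooled into
one "Focals" row per polarity) and per-polarity totals: gene count, genes
with an accepted ortholog (`n_in_table`), genes with a concordant fish hit
(`n_overlap`), and whole-percent `pct_in_table` and `pct_filtered`
(= 1 − n_overlap/n_in_table), rounded half-away-from-zero to match printed
tables. Totals de-duplicate genes shared between same-polarity regions.
Undefined percentages (empty denominators) are reported as missing, never 0.

## miRNA families

Families are keyed by the numeric core after the `mir`/`let` token
(`hsa-mir-10b` → "10"); families need members in both species to be
comparable. A family is called for polarity P iff ≥1 member per species is
in a recurrent region of P and *no* member of either species is in any
region of the opposite polarity. Gain and loss call sets are disjoint by
construction. "Altered" means membership in any recurrent region, focal or
large.

## Chromothripsis flag

Segments are discretized to {loss, neutral, gain} around δ = 0.2 and merged
into state runs. The oscillating window is the maximal chain of runs
alternating between exactly two states (run i equals run i−2); sparse
isolated events scattered along a chromosome break such chains, genuine
shattering patterns do not. Because flanking background merges into the
chain's end states, the two boundary runs contribute at most the chain's
median run length to the window span. Flag iff switches ≥ K = 6, distinct
window states within [2, max_states = 3], and span ≥ 30% of the chromosome.
These thresholds are this package's operationalization of a qualitative
signature; a profile toggling among three interleaved states would be seen
only through its two-state sub-chains — a known limitation. The detector is
deterministic and uses no rearrangement-junction evidence.

## Synthetic data: what it emulates, and what it does not

The generator fixes the study conditions: an ancestral genome (default
3,400 genes) cut into geometric blocks (mean 5 genes) scattered over 23
human / 25 fish chromosomes; a fish whole-genome duplication retaining the
second copy with probability 0.5 (fish:human gene ratio 1.5); 32% of
ancestral genes lack similarity evidence entirely (orphans), leaving about
two-thirds of human genes in the correspondence table. Similarity scores:
true pairs ~N(200, 8), second paralogs ×0.96, sparse background hits
~N(80, 15). Cohorts: 53 + 49 + 45 fish tumors (three genotype groups,
simulated identically — the study conditions include no group effect) and
23 human tumors. Planted events: 9 gained / 6 lost fish chromosomes and
5 / 13 human ones, each present per sample with probability 0.6 at
one-copy amplitude (fish gain log2(4/3) ≈ 0.415, loss log2(2/3) ≈ −0.585;
human 0.585 / −1); 14 + 3 fish and 13 + 7 human focal events (width
~N(2 Mb, 0.4 Mb), amplitude ±1, per-sample probability 0.3), a few riding
on altered chromosomes; Poisson(6) random passenger segments per sample
spanning 2–30% of a chromosome; chromothripsis windows (7–12 switches
between two states over ≥40% of a chromosome) at 1.3% of fish and 8.3% of
human sample-chromosomes; Gaussian segment noise (sd 0.05). Everything is
deterministic given the seed, and fixture output is byte-stable.

Not emulated: real read-depth noise structure (GC, mappability), germline
CNV, sequence-level similarity, arm-level events, fractional clonality, or
correlated fragile-site positions between species. Passing tests therefore
demonstrate the *algorithms* recover known structure under realistic event
geometry and noise amplitude — not that the pipeline is robust to every
artifact of real sequencing or array data.

## Numerical choices and problem sizes

Permutation counts: 200 for standard scoring, 100 per peel-off iteration
(the minimum pooled-null resolution is 1/(n_perm·n_genes+1), far below any
cutoff in use). Gene-ordinal ties break lexicographically; subpeak ties
break leftmost; ortholog arbitration ties break by score then id. Degenerate
inputs: empty similarity → empty table; empty cohorts → header-only files;
regions with no in-table genes → missing percentage markers. The multi-seed
recovery checks run 20 seeds at 120 permutations (large-region recovery,
type-I control, ortholog recovery) and 2 seeds for focal-mode localization;
these sizes are the package's chosen compromise between statistical
resolution and a test suite that runs in minutes.

## Known limitations

The human cohort's small size (23) genuinely limits sensitivity: with a
permissive cutoff, chromosomes whose sampled alteration frequency dips low
can be missed — the pipeline reports what the data support rather than the
planted truth, and downstream counts (e.g. concordant miRNA families) can
shift by one or two at some seeds. The focal-mode reconstruction is a
specified re-creation of peel-off peak finding, not a port of any existing
implementation; its parameterization (iteration cap, plateau fraction) is
documented above.
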