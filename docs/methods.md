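# Methods

## Model and procedure

The package treats a family of *k* species, each with diploid variant
calls (VCF) and a callable-region mask (BED) against one shared family
reference. All coordinates are normalized internally to 0-based half-open
intervals; VCF positions (1-based) are shifted on input.

### Conservation scan

For each autosome, windows of `bin_size` (default 100,000 bp) slide in
steps of `step_size` (default 10,000 bp), anchored at position 0; only
windows fully inside the contig are enumerated (count
`floor((L − B)/S) + 1` for contig length `L ≥ B`). Per position:

* **covered** — callable in every species (intersection of masks);
* **non-conserved** — covered and ≥ 1 species heterozygous for an SNV
  there ("zygosity" mode, the default). Homozygous-alternate calls do not
  break conservation: a difference fixed in all family members relative
  to the reference is still conserved *within* the family. An optional
  "identity" mode additionally breaks conservation where species'
  homozygous states disagree; indels are excluded from position counting
  by default because per-position semantics of multi-base events are
  ill-defined (`include_indels` counts a heterozygous indel at its anchor
  base).

A window is **usable** when covered positions exceed
`coverage_fraction × bin_size` (strict inequality; default 0.8 — a window
at exactly 80 % is excluded). Each usable window's
(conserved, non-conserved) counts are tested against the *chromosome's*
position-wise totals with a two-sided Fisher's exact test. Three choices
here were genuinely open and are recorded in output metadata:

* the test is two-sided, paired with a direction filter
  (`require_reduced`, default on) so only windows whose non-conserved
  fraction lies *below* the chromosome background can become HCRs;
* the chromosome background includes the tested window's own positions
  (no subtraction), and backgrounds are per-chromosome, not genome-wide;
* Benjamini–Hochberg correction is applied once across all usable
  autosomal windows of the family (a single significance rule), not per
  chromosome.

Windows with adjusted *P* < `alpha_adj` (default 10⁻⁴, strict) contribute
their middle tile `[s + (B−S)/2, s + (B+S)/2)`; tiles are merged
(overlaps and adjacencies coalesced), so the total HCR length is always a
multiple of `step_size` and invariant to window processing order. Both
the merged total and the unmerged per-window sum are reported, since they
differ whenever called windows are closer than one bin.

### Fisher's exact test

Implemented as a vectorized log-space hypergeometric summation: for row
margins (m, n) and column margin k, the probability of each table in the
support is computed via `gammaln`, normalized by the log-sum, and the
two-sided p-value sums all tables whose probability does not exceed the
observed one by more than a relative tolerance of 1e-7 (the standard tie
rule). Computing a whole margin family at once is what makes both the
genome scan (~2,000 tests on tables with margins in the millions) and
exhaustive validation sweeps tractable; the test suite checks it against
exact integer enumeration on every table with margins ≤ 60 and against an
independent implementation on large random tables. Degenerate tables (any
zero margin) return p = 1.0 so a scan never aborts on an empty window or
contig. BH adjustment delegates to the standard step-up implementation in
`statsmodels` and is validated against the direct
`q_(i) = min_{j≥i}(p_(j)·m/j)` formula.

### Diversity statistics

Per species, over autosomes only: nucleotide diversity
`π = n_het_SNV / genome_size` and genetic distance
`d = n_hom_SNV / genome_size / divergence_mya`. "Genome size" defaults to
the summed autosomal contig lengths and can be overridden per family in
configuration. Divergence times are configuration inputs; the shipped
defaults for the three reference families are Felidae 15.9, Hominidae
15.8 and Bovidae 26 MYA, and per-species overrides are accepted because a
species-to-reference split time is equally defensible. Heterozygous
indels are excluded from π by default (it is an SNV rate), with a flag to
include them. Family summaries are unweighted arithmetic means.

### AAC classification

Input is one consensus protein sequence per species per gene, aligned;
resolving within-species polymorphism happens upstream. A column is
skipped whenever any involved species shows a gap or a non-standard
residue — the definitions presume an aligned residue everywhere. A
group-specific AAC requires target unanimity for a residue absent from
every background species; a convergent AAC requires joint unanimity
across ≥ 2 disjoint clades, and by default the residue must also be
absent from the background (the stricter reading;
`require_absent_in_background=False` relaxes it). Function-altered genes
are computed purely from the upstream predictor table: any
"deleterious/damaging" call from either tool flags a (gene, species)
pair; a gene qualifies for a group when every group species is flagged
somewhere in it and no other-diet species is. Internally columns are
0-based; reports are 1-based.

## Synthetic data: what it emulates, and what it does not

`simulate_panel` draws every site independently per species: heterozygous
with rate *h*, homozygous-alternate with rate *q*, else reference (a
per-site multinomial, realized as exact multinomial counts over segments
plus uniform placement). Inside planted intervals the heterozygous rate
becomes `h·f` jointly in all species — the family-shared suppression the
scan targets. Masks drop a fixed fraction of fixed-size chunks at random
per species. Defaults (chosen once as this package's study conditions):

* `het_rate = 0.002` per site — inside the range family panels of this
  kind display (≈ 0.0004–0.0024);
* `hom_rate = 0.005` per site — a within-family divergence from the
  reference of the right order; the default scan mode is insensitive to
  it;
* `mask_dropout = 0.02` in 1-kb chunks — joint 5-species coverage ≈ 0.90,
  so the > 80 % rule keeps nearly all windows usable, as with
  high-coverage resequencing;
* simulation scale 5 species × one 20-Mb autosome (~1,991 windows) —
  large enough for a stable BH family and minutes-scale runs.

Not emulated: linkage disequilibrium (the scan statistic consumes only
per-position zygosity), mutation-rate heterogeneity, reference bias,
genotyping error, and demographic structure. Passing recovery tests
therefore demonstrates the statistical machinery — counting, exact test,
correction, tile extraction — under the model's own assumptions, not
robustness to artefacts of real callsets.

`simulate_protein_panel` gives every unplanted column one shared ancestral
residue with per-species substitution noise (default 0.01); planted
columns overwrite the involved rows with a residue the relevant
backgrounds cannot draw. The group layout nests a target family inside a
wider convergent clade set (plus two background diet groups), so planted
group-specific and convergent columns are mutually exclusive by
construction and exact-recovery comparisons are well-posed. Near-miss
decoys (a column one target short of unanimity; flag patterns one species
short of, or contaminated against, the function-altered definition) are
planted so that exact recovery is a discriminative check.

`score_recovery` is nucleotide-level: sensitivity `|called ∩ truth|/|truth|`,
precision `|called ∩ truth|/|called|`; precision of an empty call set is
undefined and reported as NaN.

## Numerical and degenerate-input choices

* Interval arithmetic is integer, on sorted numpy arrays; merging
  coalesces adjacency, is idempotent, and BED round-trips are
  byte-identical.
* Contigs shorter than one bin yield zero windows; contigs with no
  covered positions yield a (0, 0) background and their windows are not
  tested (p = NaN, never called), with a warning.
* Missing genotypes are "no call": coverage is defined by the mask alone.
  An absent mask file means fully callable, with a warning.
* Ties in BH follow the deterministic step-up min-cummin formulation.
* All generators are pure functions of (seed, parameters); reruns are
  byte-identical, with seeds handled through `numpy` `SeedSequence`
  spawning.

## Recovery behaviour and known limitations

On the default planted-recovery panel (20 × 200-kb intervals, f = 0.05)
the scan attains nucleotide-level sensitivity ≈ 0.99–1.0 and precision
≈ 0.84–0.85 (stable across seeds). The precision ceiling is intrinsic to
the window/tile geometry at this signal strength: a 100-kb window
overlapping a planted interval by only ~35 kb still carries a count
deficit of z ≈ 6, so its adjusted p-value clears 10⁻⁴ and its middle tile
can sit up to ~20 kb outside the true interval. Sharper boundaries would
require a much stricter threshold or smaller windows, both of which trade
away sensitivity to genuinely conserved 100-kb-scale regions; the
defaults keep the published procedure's geometry.

Other limitations: the scan assumes all species are mapped to one family
reference (no lift-over between families); gene-content comparison across
families relies on a user-supplied cross-family symbol; enrichment
analysis of HCR genes, demographic inference, and effect-predictor
execution are out of scope, their outputs being consumed as inputs where
relevant.
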