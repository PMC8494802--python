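# Methods notes

## Scope and data model

All genomic coordinates are 0-based, half-open, and every file the package
writes states so in a header comment. Chromosomes are modeled telocentric
(mouse): the centric fragment of a cut at `x` is always `[0, x)` and the
acentric fragment `[x, length)`. The cross is C57BL/6J (dam) × 129/SvJae
(sire); the reference allele of every panel SNP is carried by the maternal
(B6) haplotype, the alternate by the paternal (129) haplotype.

## The simulator

`realize_lineage` propagates a zygote karyotype through three cleavage
divisions. A karyotype is a per-chromosome list of segments with, per
haplotype, a *nuclear* copy count and a *micronuclear* copy count; copies
in micronuclei fail to replicate, so in a G2 harvest a nuclear copy
contributes 2 units of DNA mass and a micronuclear copy 1 (in G1 both
contribute 1). This single distinction generates the half-copy signature:
a cell whose acentric fragment (copy number 1) sits in a micronucleus
reads 0.5 on that haplotype relative to a disomic region when harvested in
G2.

Event mechanics conserve DNA at division: for every missegregation the
summed daughter copy number equals twice the mother's per segment.
The bridge-monosomy event implements the dicentric model — one daughter
receives all copies of the cut homolog (centric portion at CN 2; the
acentric portion either replicated or micronucleated, selectable via
`acentric_fate`) and the sister is left monosomic for the whole
chromosome. Cas9 cleavage can be placed at any division and on either
haplotype; at most one cut event per chromosome is accepted.

Count emission: expected reads per bin =
`mean_depth × bin_width / read_length × DNA mass × bias × timing
modulation`, drawn from a negative binomial with variance
`μ(1 + αμ)`. The count-noise family of real single-cell MDA libraries is
not identifiable from the outputs we emulate; negative binomial with
α = 0.05 is this package's choice (α = 0 gives Poisson), chosen to add
visible but mild overdispersion at deep coverage. Allelic depths are
Poisson per haplotype with mean `mean_depth × haplotype mass`, which makes
the alternate count conditionally binomial with success probability equal
to the local 129-haplotype mass fraction. Coverage defaults mirror the two
sequencing regimes analyzed: 0.15× (low-pass) and 9.45× (deep), with
100 bp reads.

The replication-timing surrogate is per-chromosome Gaussian noise smoothed
with a 50-bin kernel, standardized and clipped to ±3 — smooth,
autocorrelated, and bounded like an E/L timing statistic. Count bias
couples to it log-linearly (`exp(strength × value)`), so the injected bias
is strictly monotone in the track and its sign equals the sign of
`repli_bias_strength`.

What the simulator does **not** emulate: amplification artifacts of MDA
(allelic dropout, chimeras), GC-dependent bias (locus bias is represented
abstractly by `bias_profile`), read-level data, mappability structure, and
chromothripsis-style rearrangement graphs. Passing tests therefore
demonstrate correctness of the analysis logic under a clean generative
model, not robustness to every artifact of real libraries.

## Depth pipeline

Order of operations: per-sample median division → low-coverage bin
exclusion (bins below 25 % of the sample median in more than 80 % of
samples) → re-centering on the surviving bins (so the per-sample median of
unmasked values is exactly 1) → aggregation to the analysis bin size with
cross-sample median division per bin → LOESS correction of
replication-timing bias → segmentation. The LOESS (span 0.3 of points,
configurable) is fit per sample — samples differ in how strongly their
coverage couples to timing — and the corrected profile is re-centered to
median 1. A constant track triggers an identity transform with a warning.

Masked bins never enter any mean, median, MAD or segmentation statistic.

**A single-embryo caveat.** The cross-sample median steps assume most
samples are disomic at any locus. Within one 8-cell embryo that assumption
fails for alterations shared by half or all blastomeres: a gain carried by
4/8 cells is partly absorbed into the per-bin median, and an embryo-wide
trisomy is erased from the depth signal entirely. On a real cohort
(hundreds of cells from many embryos) the median is dominated by normal
cells and the issue disappears. Consequences inside this package:
(i) embryo-wide (meiotic) events are detected from the allelic-imbalance
ratio, which normalization cannot erase; (ii) the recovery studies plant
one-sided micronucleus events at divisions 2–3, where at most a quarter of
the embryo is affected and the median stays anchored.

## Segmentation

Circular binary segmentation: recursively locate the arc whose mean
differs most from its complement (max circular |t| over all arcs of length
≥ `min_width`), split if significant at `alpha` (default 0.01), recurse,
then re-test every adjacent pair of segments and drop boundaries that are
no longer significant. Ties in the statistic resolve to the shortest arc,
then the leftmost coordinate, so output is deterministic.

Two significance backends: an exact permutation test, and (the default) a
conservative Sidak-type bound over the number of candidate arcs using the
t tail probability. The bound is deliberately conservative — false splits
on flat profiles are rare — and costs nothing, while genuine CN steps at
the depths analyzed here produce |t| in the tens to hundreds and survive
any reasonable correction. The permutation backend is used in tests and
recommended for short vectors; note that its null is discrete: on a dozen
bins a short arc recurs contiguously by chance in a few percent of
permutations, so very small segments are undetectable *in principle* at
conventional alpha — a property of the test, not the implementation.

An exhaustive minimum-RSS search (`optimal_rss_breakpoints`) serves as an
independent oracle for breakpoint placement on small vectors.

## Haplotype copy number and ploidy

Bin VAF uses two-level aggregation: allelic depths are averaged within
5 kb micro-bins, micro-bin averages are summed across the CN bin, and
VAF = alt / (alt + ref). This prevents dense SNP clusters with correlated
coverage from dominating a bin. Ploidy: the statistic
`min(V̄, 1−V̄)^-1` over the per-sample mean bin VAF is compared to the
closed window [2.5, 3.5]; inside → triploid, copy number × 1.5; otherwise
diploid, untouched. Tetraploid and haploid regimes are deliberately outside
the rule and fall back to diploid with a logged warning. Blastomeres whose
call differs from the embryo's modal ploidy are flagged and excluded from
event inference; a modal tie marks the embryo indeterminate.

Haplotype CN is `VAF × total` and `(1−VAF) × total`, with total =
relative depth CN × 2 (diploid baseline) × ploidy factor, so a balanced
diploid bin reads (1, 1) and additivity `cn_129 + cn_b6 = total` holds
exactly wherever VAF is defined. Segment haplotype means average the
member bins; the half-copy flag fires when one haplotype mean is within
±0.15 of `k + ½` while the other is within ±0.15 of an integer. The ±0.15
window is this package's choice (no canonical value exists) and is
configurable; it is narrower than half the distance between adjacent
half-integer states, so the flag cannot fire on a clean integer segment.

**Panel provenance** (`panel_source`). The informative-SNP filter
(median per-sample VAF in the closed window [0.40, 0.60], at least 3
covered samples) is designed to run on a cohort, where most samples are
disomic at every site. Re-deriving the panel from a single aneuploid
embryo biases it — on a chromosome at 2:1 dosage every site's median VAF
is ~1/3 and the filter strips the chromosome. The pipeline therefore
accepts `panel_source: cohort` (use the known cross panel, as a cohort
derivation would produce) alongside the default `self`. The median is
taken over per-sample VAFs of covered samples, not over pooled reads, so
deeply covered cells cannot dominate the site statistic.

## Karyotype reconstruction

Per blastomere, haplotype segment means snap to the nearest half-integer
state. Whole-chromosome zero → monosomy; whole-chromosome baseline+1 →
trisomy; an arm-level (≥30 % of the chromosome — the term has no canonical
quantitative definition, so 30 % is configurable) distal gain/loss whose
boundary lies within tolerance of the cut site → a reciprocal-pattern
component, flagged `on_target`; a half-copy segment → micronucleus
signature (and is not double-reported as a gain/loss).

Embryo level: gains and losses of the same haplotype segment pair into one
missegregation, and with the full 8-cell complement the group size fixes
the division (4+4 → 1, 2+2 → 2, 1+1 → 3); with missing blastomeres the
division degrades to a range. The bridge rule requires a whole-chromosome
zero of the cut haplotype in some blastomere *and* a sibling whose centric
portion of the same haplotype carries ≥1 surplus copy; it runs before
reciprocal pairing and replaces the calls it explains (the most
parsimonious history), attaching the alternative ("independent loss and
gain") as an ambiguity note. A monosomy without sibling surplus keeps its
plain call with a flagged-for-review note. Alterations shared by every
blastomere are meiotic: a chromosome-wide ~2:1 allelic-imbalance ratio in
all cells (window 1.6–2.5) → meiotic trisomy; uniform triploid calls with
genome-wide maternal:paternal ≈ 2:1 → digyny. The imbalance-ratio form is
used because it survives the single-embryo normalization caveat above.

## SV genotyping

The four candidate filters (strain background, <3 supporting reads in the
discovery sample, no pair with MAPQ > 30, intra-chromosomal span ≤ 1 Mb)
are independent predicates, so they commute; survivor counts per filter
are logged. Inter-chromosomal junctions have no defined span and always
pass the distance filter. Joint genotyping marks a junction present in a
sample when split + discordant tallies reach the presence threshold
(default 1 read — tallying implies no stated cutoff, so the permissive
default is exposed as a parameter), and only junctions whose presence is
confined to one embryo are reported de novo. The 3-read support filter is
applied in the discovery sample.

## EdU quantification

Segmentation: Gaussian smoothing, Otsu threshold, distance-transform
watershed to split touching nuclei; the largest object is the primary
nucleus, smaller DAPI-positive objects are micronuclei. A mask-override
input replaces manual refinement and also covers the case where the best
focal planes of PN and MN differ. Densities are background-subtracted
(mean of a user-supplied rectangle that must not intersect any mask) and
normalized to DAPI; because the same background is subtracted from both
channels, a global additive offset cancels exactly. Negative
background-subtracted values are clamped to zero with a warning, so
densities and ratios are never negative. The ratio is reported only when
the primary nucleus is replicating (background-subtracted EdU ≥ 10 a.u.;
the a.u. scale is instrument-specific, so the gate is a parameter with 10
as the default on the synthetic scale, where foreground signals are in the
hundreds-to-thousands range).

## Problem sizes and defaults used in the shipped studies

The default desk-scale genome is 3 telocentric chromosomes of 50–60 Mb
with a heterozygous SNP roughly every 8 kb; whole-chromosome event studies
use 6 chromosomes of 20–30 Mb so that one chromosome is ≤20 % of the
genome and the triploidy statistic of a monosomic/trisomic cell stays
outside [2.5, 3.5], as it does on the real 19-autosome mouse genome. Deep
simulations run at 9.45×, low-pass at 0.15×. The recovery study spans 54
event embryos (9 per class, varying division, haplotype, lineage position
and cut site) plus 20 no-event controls; the headline micronucleus ratio
is computed from one G2 blastomere over 3300 unmasked 50 kb bins, and the
ploidy factor from 24 digynic blastomeres. These sizes were chosen so the
statistical targets (≥90 % recovery, ≥95 % specificity, ±0.05 on the
half-copy ratio) are well separated from their thresholds while each study
remains a desk-scale computation.

## Known limitations

* Detection of events shared by exactly half of one embryo's blastomeres
  is attenuated by the within-embryo cross-sample median (see above);
  cohort-scale input removes the limitation.
* The classifier emits the most parsimonious event history; genuinely
  ambiguous copy-number patterns carry an `ambiguous_alternatives` note
  rather than an enumeration of all consistent histories.
* G1 versus G2 cleavage of one or both sister chromatids often produces
  identical end-state copy numbers; the package reports the history
  class, not the chromatid-level mechanism, when the data cannot separate
  them.
* The EdU module works on single best-plane 2-D images; full confocal
  stacks and 3-D segmentation are out of scope.
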