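# Methods

This note documents the models, the defaults and why they were chosen, the
numerical conventions, and what the simulations do and do not show about
real RESCAN data.

## Simulation model

**Reference and founders.** The reference is i.i.d.-uniform over ACGT with
chromosomes `chr1..chrN`. Founder cultivars are fully homozygous and carry
`Binomial(L, snp_rate)` substitutions per chromosome, alternates uniform over
the three non-reference bases, founders mutually independent. The default
`snp_rate = 1e-4` (one SNP per 10 kb) is of the order of the divergence the
genotyping recovered between closely related temperate japonica cultivars and
their reference (tens of SNPs per sequenced 100 kb); it keeps multi-hit
collisions between founders negligible while giving enough covered loci to
exercise every downstream analysis. No indels and no heterozygotes are
simulated: the motivating panel is inbred cultivars analyzed as haplotypes,
and the caller's homozygous model is part of the design.

**Crosses.** A bi-parental inbred offspring is an alternating parental mosaic:
per chromosome, `Poisson(rate × L)` breakpoints (default 2 per Mb, a
plant-scale recombination density accumulated over the generations of
single-seed descent), first segment from a fair-coin parent, child allele
everywhere equal to the origin parent's allele, and the child fully
homozygous — i.e. the mosaic models the fixed product of inbreeding, not a
single F1 meiosis. The origin track is recorded as ground truth.

**Libraries and reads.** The cultivar genome (not the reference) is digested
at CATG occurrences, cutting after the site on the top strand, so planted
SNPs can create or destroy sites and genuinely perturb coverage. Retention is
an independent Bernoulli per fragment with probability given by the profile
(below) evaluated at the pre-ligation fragment length. Each retained fragment
emits `Poisson(mean_depth × n_ends)` reads split evenly between its
site-bearing ends (equal end sampling is an assumption; the chemistry gives
no reason to prefer an end). A read is
`barcode + CATG + (read_length − barcode − 4) genomic bases`; right-end reads
are the reverse complement of the preceding strand and begin with CATG again
because the site is its own reverse complement. Substitution errors are
i.i.d. over the whole read (barcode included, so demultiplexing loss under
error is represented) and the uniform per-base quality is
`Q = min(41, round(−10·log₁₀ ε))` — the quality filters only need a
consistent phred scale, not a learned error profile. Read ids encode
(cultivar, chromosome, site position, strand), which is what lets every
downstream statement be scored against truth.

**Retention profiles.** `sharp` is the indicator of `[low, high]`. `gel` and
`spri` are two-sided logistic curves with edge softness 5 bp and 40 bp —
a calibration expressing that electrophoretic fractionation cuts a much
steeper size band than SPRI beads, not a measurement. On an i.i.d.-uniform
genome these give in-window read fractions of roughly 94% (gel) and 49%
(spri) over a ~15% unselected baseline (6.2× and 3.2× enrichment). The
empirical contrast on a real rice library was 51% vs 27% over a ~13%
baseline (4× vs 2×): the *ordering* and the roughly-two-fold contrast
reproduce; the absolute fractions do not, because the real genome's
fragment-length distribution is far from the exponential-like distribution
of a uniform sequence. Only the ordering is asserted.

## Anchored alignment

Every valid read starts at a restriction site, so alignment reduces to
choosing among ≤ 2 anchors per reference site occurrence (forward: site +
following bases; reverse: reverse complement of the preceding bases + site).
Candidates are retrieved by exact 16-mers at read offsets 0/16/32 matched
against the same anchor offsets; the accepted placement is the unique
candidate with the fewest mismatches over the full overlap, subject to
`max_mismatch = 3` (generous for 0.5% error on 45 bases while keeping random
hits negligible). Ambiguous best hits are discarded and counted. Reads from
cultivar-only sites (a planted SNP creating a CATG) have no reference anchor
and are counted unaligned — the realistic fate of such reads under a
reference-anchored scheme.

## Calling and filters

Per sample and position, base counts and summed qualities feed a two-
hypothesis homozygous likelihood (reference base vs modal non-reference
base) with per-base error `e = max(10^(−q̄/10), 1e-3)`; the floor guards
against overconfident qualities. GQ is the phred-scaled likelihood ratio. A
sample call is MISSING when depth < 4, GQ < 20, or the two most frequent
bases both exceed 20% of reads (a mixed pileup cannot be a homozygote; this
also absorbs the depth-4-with-one-error case). A locus is emitted when some
sample is called ALT with a single alternate base panel-wide (sites with two
alternates are dropped and counted), the best ALT GQ reaches 20 (the proxy
for the original pipeline's site-level QUAL, which is not reproducible
without reimplementing its caller), and at least two genotype classes occur
across the panel ("two to three different genotypes" is ambiguous; ≥ 2 is the
default and configurable). "Sequenced breadth" is the count of reference
positions with depth ≥ 1; it is the denominator of SNPs per sequenced 100 kb,
consistent with the published table's arithmetic.

## Evaluation universes

Planted-SNP recovery is scored over pairs (cultivar, position) where the
carrier has depth ≥ 4 *and some non-carrier cultivar* has depth ≥ 4: the
panel filter needs a second genotype class, and size-selection asymmetry can
leave a variant covered only in carriers (e.g. when the variant merges two
fragments into the retained window), which no reference-panel caller could
emit. Under error-free reads at depth 20 precision and recall on this
universe are exactly 1.0. Genotype discordance compares every non-missing
call at emitted loci against the planted truth; at 0.5% read error with
default filters it stays well under the 2% bound established by independent
assay re-scoring of the original calls. Breakpoint recovery checks that
parental-origin labels switch exactly at the planted mosaic transitions;
localization is inherently limited to the bracketing inter-SNP interval.

## Distances and trees

Inbred calls make allele-frequency vectors unit vectors, so the per-locus
Cavalli-Sforza chord distance is 0 (concordant) or (2/π)√2 ≈ 0.9003
(discordant); pairwise distance is the mean over co-scored loci (pairwise
deletion). The cited implementation's exact missing-data convention is not
published, so this convention is stated explicitly and covered by
closed-form tests. Neighbor joining is the standard Q-criterion
agglomeration; ties are broken by the lexicographic order of each working
node's smallest leaf name, negative limb estimates are clamped to zero with
the deficit shifted to the sister limb, and the final three nodes join at a
trifurcating root (unrooted semantics). NJ is exact on additive matrices and
is property-tested against random additive trees and cross-checked against
an independent implementation.

A deliberate choice: the "cross children sit near their parents" check is
asserted on chord distances for both parents, but on the tree only as "the
nearest founder by path distance is a parent". A recombinant mosaic is an
admixed taxon and is not additively representable; when inheritance is
skewed toward one parent, the minor parent's patristic distance in the NJ
tree is legitimately distorted, so demanding the path-distance inequality
for both parents would test the tree for a property trees cannot have.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| enzyme site | CATG | — | NlaIII; self-reverse-complement |
| read_length / barcode | 50 / 5 | bp | read = barcode + site + 41 genomic bases |
| insert_window | 200–300 | bp | pre-ligation (350–450 after adapters) |
| gel / spri softness | 5 / 40 | bp | logistic edge; calibration, not ground truth |
| mean_depth | 20 | reads/end | per retained fragment end |
| snp_rate | 1e-4 | /bp | founder divergence |
| breakpoint_rate | 2 | /Mb | cross mosaics |
| min_depth / min GQ / min site Q | 4 / 20 / 20 | — / phred | the filter chain |
| ambiguity rule | 0.2 | fraction | two bases each > 20% ⇒ MISSING |
| bins | ≤15 / ≤30 | cultivars | rare / medium; closed-left edges |
| blocks | 3 SNPs, 500 kb | — / bp | block rule is a package definition |
| min_scored | 23 (of 45) | cultivars | informative-locus threshold |

## Problem sizes

Defaults were sized for a workstation: the acceptance runs use a 5 Mb,
2-chromosome genome with 6 cultivars (≈ 0.7 M reads, under a minute
end-to-end); the analysis drivers use 2 × 1 Mb; unit-test panels are
2 × 400 kb. Coverage structures are dense per-chromosome count arrays, so
memory scales as genome length × panel size (≈ 120 MB per cultivar at 5 Mb);
panels of dozens of cultivars on full genomes would need a sparse coverage
backend, which is a known limitation.

## What passing does and does not show

The simulations demonstrate internal correctness — coordinate arithmetic,
the filter chain, the estimators, and exact recovery under their own
generative model. They do not model PCR duplicates, adapter read-through,
quality decay along reads, partial digestion, indels, heterozygosity,
paralogy beyond exact duplications, or the fragment-length distribution of a
real genome; absolute quantities tied to those features (e.g. the 51%/27%
in-window fractions, genome-wide SNP totals) are expected to differ from any
real library, and the published-table arithmetic is validated directly from
the printed table instead.
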