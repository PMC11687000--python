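# Methods

This note documents the models, conventions and design choices behind
`targetsv`, and what the synthetic cohorts do and do not demonstrate.

## Coordinates and regions

All intervals are 0-based half-open internally. A target region is the lead
SNP's position ± `flank` (default 100,000 bp), stored as
`[pos − flank, pos + flank)` so its width is exactly `2 × flank` and the
stored numbers are also the pair printed in study-style tables (the SNP's
1-based coordinate ± flank). Building a region fails loudly when
`pos ≤ flank` (coordinate underflow) or `flank ≤ 0`. Chromosome labels are
accepted with or without the `chr` prefix and normalised to `chr` on output,
since VCF and BED sources mix conventions. Overlapping regions warn rather
than fail — the anchoring use case has disjoint regions, but the tool should
generalise. Conversion between genome assemblies is out of scope; all inputs
are assumed to share one assembly.

VCF input/output follows the anchor-base convention: POS names the base
before an indel, so the changed bases begin at POS+1. The readers convert to
the internal convention on the way in; the writers restore it. This is why
symbolic `<DEL>` records round-trip exactly through htslib, which recomputes
END from |SVLEN| under the same convention.

## Read quality and enrichment statistics

A read's quality is Phred of its mean per-base error probability,
Q = −10·log₁₀(p̄). The live sequencing filter removes reads below Q9 *or*
below 500 bp, read literally: Q ≥ 9 and length ≥ 500 are kept (boundaries
inclusive). Per-sample average quality converts the mean of per-read error
probabilities back to Phred — probability-space averaging, the platform
convention; an arithmetic mean of per-read Q is available via
`qual_aggregation="phred_mean"` because the choice changes the displayed
number by a few tenths.

Coverage is base-level and computed over *all* of a sample's reads:
on-target coverage is aligned bases falling inside the regions divided by
total region span, off-target coverage divides the bases falling outside by
(declared genome size − region span). A read straddling a region edge
therefore contributes its inside bases on-target and its outside bases
off-target, and the two scopes conserve total aligned bases exactly. The
off-target denominator is a configuration input (`genome_size`) and is
documented prominently because it scales the whole off-target coverage
column; with no genome size the column is reported as undefined rather than
guessed. Cohort summaries report per-column mean and SE = s/√n with the
n−1 sample standard deviation, and report tables round half-up to the
conventional printed precision (integer bp lengths, 1 dp quality and
coverage, 2 dp SEs).

## Cross-caller harmonisation

No published rule exists for deciding when two callers describe the same
variant, so the matcher uses common SV-merging practice, all thresholds
exposed in configuration: insertions match within 500 bp of breakpoint
distance; deletions additionally need ≥ 50 % reciprocal overlap; repeat and
transposable-element loci match anything class-compatible overlapping them
by ≥ 1 bp; SNVs match only identical position and allele. The class
compatibility matrix reflects how callers actually disagree: STR loci absorb
insertion/deletion reports (VCF callers see a repeat length change as a
plain indel), TE loci absorb insertions (no caller reports a composite
element as one unit), and SNVs never merge with anything else. Clustering is
single-linkage over this predicate; calls are canonically sorted first
(chromosome, start, end, class, caller, sample), making the partition
invariant to input order, and a sweep bound on start distance keeps it near
linear. Clusters spanning more than 100 kb are split at their largest
internal gap with a warning — a guard against pathological chains, not an
expected path. For ≤ 20 calls the partition provably equals the brute-force
transitive closure of the pairwise predicate (tested).

Presence is union-based: a variant is present for a sample if at least one
caller reports a non-reference genotype there or a human-curated alignment
inspection (the BAM-evidence table) flags a clear difference from the
reference. There is deliberately no majority vote or consensus genotype.
Genotypes a caller could not resolve (`./.`) are kept as `unresolved` and do
*not* count as presence by default; some callers coerce these to homozygous
reference, and `count_unresolved`/`coerce`-style switches let users mimic
that behaviour rather than having the loss imposed silently. Allele
distinctness is inequality of the (structural class, length, motif,
sequence) tuple — a 46 bp and a 47 bp insertion are two alleles; two
identical 47 bp insertions are one.

## Prioritisation cascade

Stage order is fixed (region → quality → class → impact/rsID → LD);
configuration can disable stages but not reorder them, keeping audit
semantics simple, and disabling any stage can only enlarge the output.
Choices worth stating:

* Quality is filtered on each caller's native scale with one threshold
  (≥ 9, inclusive), applied per call before clustering; sources that emit no
  quality (STR locus tables, alignment inspection) are exempt and flagged
  `qual-exempt` in the audit rather than dropped.
* The class stage removes SNVs and keeps indels only when strictly longer
  than 10 bp; STR and TE loci pass regardless of length. An indel locus's
  length is the largest reported allele length or reference span.
* "HIGH impact and no rsID" is conjunctive; "no rsID" means the record ID is
  absent and no annotation row carries one. A locus with *no* annotation row
  is quarantined into a `needs-annotation` bin, never silently lost.
* A target region that declares no LD blocks passes its loci with a
  `lenient` flag — mirroring the practice of relaxing the LD requirement in
  weak-signal regions instead of discarding everything.

Every stage writes `n_in`, `n_out` and one reason per excluded item;
conservation (`n_in = n_out + exclusions`) is asserted in code. The cascade
is seed-free and byte-deterministic given its inputs.

## Annotation windows

Features are intersected with `[locus.start − w, locus.end + w)` for
w = 2,500 bp, a plausible effect range for short structural variants acting
on nearby regulatory elements. Distances are signed gaps from the nearest
locus edge (0 iff overlapping; negative upstream in coordinate order); a
midpoint anchor is available because published "~x kb away" figures are
often midpoint-based. Strand is carried but ignored — the window is
symmetric. The feature vocabulary is closed (distal/proximal enhancer,
promoter, TFBS, CTCF, eQTL, TSS, miRNA site, GWAS hit) with an `other`
catch-all so novel track labels degrade gracefully.

## LD

r² is computed on phased biallelic haplotypes from the closed form
D²/(p_A(1−p_A)·p_B(1−p_B)); monomorphic sites raise rather than return 0,
because "no information" and "no association" are different answers. For
binary vectors the closed form equals the squared Pearson correlation, which
tests verify to 1e−12 as an independent route. LD blocks are maximal runs of
consecutive sites reaching the threshold (default 0.8, "high LD") against
the anchor: one below-threshold site breaks a run; an optional `max_gap`
additionally breaks runs across large positional gaps (default: none). Block
intervals span exactly the member sites, with no padding. This module exists
so the cascade's LD stage is testable hermetically; it does not attempt to
reproduce any external reference panel's estimates, and phasing itself is
assumed done upstream.

## Synthetic cohorts: what they emulate, and what they don't

The generator's defaults mirror the anchoring study's shape: 10 samples,
8 target regions of 200 kb (one per synthetic 1 Mb chromosome), and 120
truth variants — 60 SNVs and 60 non-SNVs (25 STR, 15 insertions, 15
deletions, 5 composite TEs), roughly the cohort's SNV/non-SNV mix — of which
20 "interesting" variants satisfy every cascade criterion. Each
non-interesting non-SNV carries exactly one planted failure mode (outside
the regions, all calls below Q9, indel ≤ 10 bp, non-HIGH impact, existing
rsID, or outside the LD cassette), so the audit can be checked exclusion by
exclusion. Read summaries plant 15× on-target and 3× off-target coverage on
a declared 8 Mb genome, with 10 % of reads planted below the Q9/500 bp
filter; ~190,000 reads per cohort. Haplotypes plant one perfect-LD cassette
(±30 kb) around each region's anchor, with background sites resampled below
r² 0.5 so any threshold between recovers the cassette exactly.

Caller emulation reproduces the *structure* of caller discordance: the STR
genotyper emits locus TSVs without quality; the VCF callers see repeat
length changes as plain indels and the composite TE as insertions inside its
VNTR; sensitivities differ per class and caller; breakpoints jitter;
genotypes flip (het↔hom) and occasionally come back unresolved; qualities
are log-normal with ~10 % below 9 on ordinary calls. Two planting
constraints keep truth recoverable rather than cosmetic: every carrier of an
interesting variant is guaranteed a call from at least one caller (the
presence rule is union-based, so this is the condition under which recall is
meaningful), and repeat observations are left-aligned with same-sign allele
spectra within a factor of two in length, so one underlying variant cannot
fragment into several loci purely by construction. Interesting variants are
emitted with quality ≥ 9 — they represent well-supported real variants —
while planted low-quality variants stay low in every noise regime.

What passing tests on these cohorts does **not** show: performance on real
nanopore error profiles (no sequence or signal simulation — the pipeline
consumes summaries, not reads), mapping artefacts, reference bias at
low-complexity loci, callers' correlated failure modes, or any biological
claim about the prioritised variants. The planted-recovery results are
statements about the pipeline's bookkeeping and logic, not about caller
accuracy.

## Numerical and size choices

Display rounding is half-up (`decimal`), matching how report tables are
printed; internal computation is never rounded. Acceptance-style property
suites run on scaled-down cohorts (4 samples, 3 regions, ~40 truth variants
per seed, 20 seeds) with the full 10-sample/8-region fixture exercised once
per suite; the enrichment-recovery check uses a single sample with ~5×10⁴
reads, where planted coverages come back within ±5 %. Ties in clustering are
broken by the canonical sort; quarantine, lenient and qual-exempt paths are
all represented in the audit rather than as silent behaviour. Known
limitations: the harmonised VCF encodes per-call provenance in one record
per (caller, locus, allele set), which is faithful but verbose; the LD
module assumes phased haplotypes and does not estimate D from unphased
genotypes; and the off-target coverage column depends entirely on the
declared genome size.
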