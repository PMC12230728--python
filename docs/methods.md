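# Methods

## Problem and model

CRISPR nucleases cut wherever the genome offers a protospacer-adjacent
motif (PAM) next to a sequence sufficiently similar to the guide spacer.
Off-target screens therefore enumerate every genomic window matching
`spacer + PAM` within a spacer-mismatch budget *k*, on both strands.
Screening only the reference assembly misses the fact that an
individual's variants can create PAMs and protospacers the reference
lacks, or destroy sites the reference has — and that the two (or more)
phased copies of each chromosome can differ from each other.

`allelescan` makes the screen haplotype-aware. Given a reference FASTA
and a *phased, single-sample* VCF it:

1. canonicalizes each VCF record into per-haplotype allelic primitives
   (multiallelic split by genotype index, end-anchored decomposition of
   MNPs/complex substitutions into SNVs plus at most one indel,
   leftmost parsimonious indel representation);
2. splices each haplotype's variants into the reference to produce
   allelic sequences plus an invertible coordinate map;
3. scans the reference and every allelic sequence with a
   degenerate-PAM, mismatch-tolerant kernel;
4. classifies each site as shared, reference-only, or allele-subset by
   merging hits on their lifted reference coordinates, and tabulates
   per-chromosome, per-allele counts.

## Matching semantics

The full pattern is `spacer ∥ PAM` (PAM downstream for SpCas9-class
three-prime motifs, upstream for Cas12a-class five-prime motifs). PAM
positions are matched degenerately with **zero tolerance**; the
mismatch budget applies to spacer positions only. This is the
convention implied by writing queries with a trailing PAM placeholder
of Ns and naming the PAM type separately.

IUPAC codes in the pattern denote base sets; a genome `N` is an
*unknown* base and matches only a pattern `N` (which asserts nothing).
Consequently windows that overlap reference N-runs fail concrete PAM
positions and accrue spacer mismatches — a deliberately conservative
choice with no window skipping, so the brute-force oracle can reproduce
it position by position.

Hits report the window start on the forward strand *in the scanned
sequence's own frame* (the reconstructed genome), with the lifted
reference coordinate as an extra column where the position is
collinear. Mismatched spacer bases are lowercased in the matched
sequence, which is always printed 5'→3' along the guide.

## Variant canonicalization

Coordinates are 0-based half-open everywhere internally; the 1-based
VCF `POS` is converted exactly once at the parser boundary. Missing or
half-missing genotypes are dropped with a counted warning rather than
treated as reference — silently filling reference alleles would
fabricate haplotypes. Unphased heterozygous genotypes are an error
unless `--assume-phased` is given; ploidy is inferred from the first
genotype and enforced. Symbolic ALTs (`<DEL>`, breakends, `*`) are
skipped with counted warnings: the model covers small variants only,
and structural variants are out of scope.

Because the internal representation is per-haplotype, the classical
split-primitives / split-multiallelics / re-merge cycle collapses to:
select each haplotype's ALT by genotype index, decompose that single
REF/ALT pair, left-align. Re-merging multiallelic records exists only
to keep VCFs well-formed; it cannot change the reconstructed sequence,
so it is intentionally omitted.

Decomposition trims the shared suffix then prefix (each allele keeps at
least one base), emits one SNV per differing position when the
remainders have equal length, and otherwise keeps the remainder as a
single anchored indel/block substitution. Left-alignment is the
standard shift-while-end-bases-match algorithm; it is idempotent and
sequence-equivalence preserving, and is verified in the tests against
an oracle that enumerates every equivalent anchored representation and
picks the leftmost.

Overlapping variants within one haplotype are rejected by default
(`--skip-overlaps` keeps the first and counts the rest); overlap across
haplotypes is of course legal.

## Coordinate map

The splice records collinear blocks `(ref_start, hap_start, length)`.
Substituted spans of equal length (SNVs, MNPs) stay collinear — the map
answers *where*, not *what* — and an indel's single shared anchor base
is collinear; only inserted/deleted tails are unmapped. Lookup is
binary search; `to_reference` and `from_reference` are mutually inverse
on all collinear positions (asserted exhaustively in the acceptance
tests). Chromosomes absent from the VCF pass through with identity
maps.

Site identity across sequences uses the strand-aware lifted reference
anchor, so a site downstream of a heterozygous deletion merges with its
reference counterpart even though its haplotype coordinate shifted.
Hits inside insertions have no reference image; they are keyed in their
own frame and never merged across alleles. Per-chromosome counts are
per-allele totals (a homozygous site counts once per allele), matching
the usual table semantics of haplotype-aware screens; the per-site
shared/gained/lost classification is an additional capability beyond
plain counting.

## Scan kernel

Sequences are byte-coded; each IUPAC pattern character becomes an
acceptance bitmask over `{A,C,G,T,N}` bits, and for each pattern offset
a vectorized AND over all windows accumulates spacer mismatches and PAM
failures. The reverse strand is scanned with the reverse-complemented
pattern over the same forward sequence, so positions are always
forward-strand window starts. Output is canonically sorted (position,
then `+` before `−`), making hit lists byte-reproducible regardless of
how work is partitioned.

The brute-force oracle (`simulate.brute_force_scan`) tests every window
by per-base set membership with no shared kernel machinery; the test
suite requires exact hit-list equality between the two on hundreds of
seeded instances. A uniformly random 15–25 nt spacer essentially never
matches random sequence within a small budget, so the equivalence
instances get windows planted at and just beyond the budget, with a
total-hit floor in the test guarding against vacuous comparisons.

## Synthetic fixtures

The generator emulates the study inputs at desk scale: a
multi-chromosome random reference (default 2 × 3 kb, GC 0.41 — a
plant-like genome-wide GC value), a phased diploid (or tetraploid) VCF
with SNPs (12), insertions and deletions (4 + 4, 1–20 bp), MNPs (2) and
multiallelic records (2), plus planted events covering each comparison
class: shared sites, PAM-creating and spacer-restoring SNP gains,
spacer-breaking SNP losses, spacer-truncating deletion losses, and
exact sites inside inserted sequence (unmappable gains). The default
query is a random 20-nt spacer with NGG and k = 2, matching common
SpCas9 screening practice.

Gain/loss events are constructed to sit exactly at the budget boundary:
the matching window carries exactly *k* mismatches so that one variant
base moves it across the threshold in the intended direction. The
deletion-loss planter additionally *verifies* its claim against a local
window check and redraws if a chance re-match survives the deletion, so
every emitted truth record is true by construction, not by probability.
Background variants and planted windows are kept apart by reserved
intervals with margins, so events never interact.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; identical specs produce byte-identical FASTA,
VCF and truth files.

What the fixtures do *not* emulate: realistic mutation-rate or linkage
structure, repeat families and segmental duplications, soft-masking,
real chromosome lengths, or sequencing artifacts. Passing the planted
suites therefore demonstrates correctness of the canonicalization /
reconstruction / scan / classification machinery, not calibrated
performance on real genomes — at multi-gigabase scale the same code
paths apply but runtimes and count magnitudes will differ.

## Numerical and interface choices

* Output coordinates default to 0-based half-open (search-tool
  convention); `--one-based` switches the dialect, which is stamped in
  every TSV header.
* `FILTER` is ignored by default (`--pass-only` restricts to PASS),
  matching permissive consensus-building practice.
* bgzip-compressed inputs are accepted but no tabix/faidx index is
  required; indexing is an I/O optimization, not semantics.
* FASTA headers for allelic records are `<chrom>_allele<k>`; the final
  `_allele<k>` suffix is the delimiter, so underscored chromosome names
  stay unambiguous. The header convention is this package's own; count
  tables, not header strings, are the comparison surface.
* Soft-masked bases are uppercased on load; scanning is
  case-insensitive and masking is not preserved.
* Test and acceptance problem sizes (kb-scale chromosomes, tens of
  variants, 50–200 instance sweeps) were chosen to exercise every code
  path and boundary with comfortable margins while keeping the suites
  quick to run.

## Known limitations

Small variants only (no structural variants); single-sample input (no
cohort handling, no phasing/imputation); no DNA/RNA bulge search; no
activity scoring (CFD/MIT); polyploid genotypes are supported
mechanically (one haplotype per phase index) but have only been
exercised on synthetic tetraploid fixtures.
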