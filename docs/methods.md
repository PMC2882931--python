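# Methods

This note records the models and procedures varkit implements, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data generators do and do not emulate.

## Data model and persistence

Coordinates are 1-based, fully-closed intervals everywhere; insertions
are represented with `start = end + 1` (the insertion point between the
two coordinates).  All variation features are stored on the forward
strand; alleles of reverse-strand mappings are reverse-complemented when
the feature is created, so every consumer sees one canonical
orientation.  Multi-allele strings use `/` with the reference allele
first; further alleles keep their import order (no canonical ordering of
alternates is imposed).

A dataset persists as a directory: one header + tab-separated-rows file
per table, a FASTA file for the reference, a binary sidecar of
concatenated genotype blobs addressed by offset and length, and a JSON
manifest with a format version.  Absent optional fields are written as
`\N`.  The store is inspectable and diff-able; loading verifies the
manifest version and table headers and reports corruption as a distinct
load error.  The contract is that load∘save is the identity on every
table, including blob bytes bit-for-bit.

Because compressed genotype rows are positional (they carry no variant
names), the dataset keeps a small `variant_positions` table
(name → region, position), populated at VCF import and at feature
creation.  The QC purge uses it to find and delete the genotypes of
failed variants; rows in affected windows are decoded, filtered and
re-encoded.

Population frequency inserts are validated: when a batch is declared
complete, each (population, variant, kind) group must sum to 1 within
1e-6 or the insert is rejected.

## Flank mapping and QC

The mapper performs an exact substring search of the composite
`5'flank + reference allele + 3'flank` over both strands of every
region.  Exact search is the desk-scale stand-in for a seeded aligner;
any mapping engine can replace it behind the same contract (hits
delimit the allele, are sorted by position, and are uncapped).
Overlapping occurrences count separately.  A palindromic composite that
matches itself reverse-complemented at the same locus is counted once,
on the forward strand, to avoid double-counting one physical site.

QC parameters: `max_mappings` N = 3 and `flank_min_len` = 20 bp.  Rules
are applied in order: zero hits → `NO_MAPPING`; more than N hits →
`TOO_MANY_MAPPINGS`; any hit whose reference bases (reverse-complemented
for reverse-strand hits) differ from the declared reference allele →
`ALLELE_MISMATCH`.  The allele check for a deletion compares the deleted
reference bases; for an insertion only flank adjacency is checked (an
insertion has no reference bases to compare).  The cap is applied
genome-wide, not per region.

Whitelisted variants (e.g. clinically significant ones) are never moved
to the failed set.  When a whitelisted variant over-maps, the N leftmost
hits (by region, then start) are materialised as features while
`map_weight` keeps the true hit count — bounding table growth without
losing the mapping multiplicity.

Flank compression replaces a raw flank by `(region, start, end, strand)`
when it equals the reference adjacent to the mapped allele.  The forward
orientation is tried first, then the reverse-complement of the opposite
side (covering variants originally mapped on the reverse strand); the
matching orientation is recorded in the pointer's strand, which is all
restoration needs.  A flank matching neither stays raw, so restoration
is always exact.

## Genotype compression codec

One row stores one individual's single-base genotypes within one fixed
genome window; the default window size is 100 kb.  Windows are
genome-anchored and 1-based — window k covers `[kW+1, (k+1)W]` — so a
region query touches only the rows of overlapping windows.  The blob is
a repeating triplet: distance in bp from the previous genotype, then two
ASCII allele bytes.  The first genotype's distance is zero by
construction and is not stored; decoding re-adds it at the row's start
position.  Distances are unsigned LEB128 (7 data bits per byte, high bit
continues); any fixed variable-length integer coding would satisfy the
contract, LEB128 is simply documented and bit-exact.  Consequences: with
all distances < 128 a row of n genotypes occupies exactly 3n − 1 bytes,
and never more than 4n bytes within a 100 kb window.  Missing alleles
are the in-alphabet sentinel `N`.  Decoding errors (truncation, invalid
allele byte, ULEB128 overrun) name the failing byte offset.  Multi-base
genotypes are rejected by the codec and live in a separate uncompressed
table; heterozygous allele pairs keep input order and are compared
order-insensitively.

## Linkage disequilibrium

Input is the 3×3 table n[i][j] of individuals with i copies of allele A
at locus 1 and j of allele B at locus 2 (biallelic loci only;
individuals missing either genotype are excluded pairwise; A/B label the
first-seen allele).  Every cell except the double heterozygote n[1][1]
contributes unambiguous haplotype counts.  EM starts at linkage
equilibrium (p_AB = p_A·p_B), weights each double heterozygote's
coupling phase by `p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB)`, renormalises
over 2N haplotypes, and stops when the largest frequency change drops
below `tol` = 1e-10 or after `max_iter` = 1000 iterations.  These two
constants, and the convention that D′ = 0 when D = 0 (including the
degenerate D_max = 0 case), are this package's declared choices.  A
consequence of the equilibrium start: the phase-uninformative
all-double-heterozygote table is a fixed point and reports D = 0, which
is the documented behaviour.  The implied allele frequencies always
equal the sample frequencies; correctness is tested against an
independent 1-D likelihood grid search over p_AB (marginals fixed at the
sample allele frequencies, where the MLE is known to lie) and against
simulation truth.  D′ is reported as |D|/D_max in [0, 1] (the Haploview
convention).  The whole-slice driver computes every eligible pair within
`max_distance` and logs (rather than raises) monomorphic or undefined
pairs.  The engine is pure Python/numpy; a compiled kernel would be an
optimisation, not a behavioural change.

## Consequence rules

Classification runs on the transcript's coding strand and returns the
union of applicable types for variants spanning multiple contexts; a
fixed severity order (stop gained > stop lost > frameshift >
non-synonymous > essential splice > splice region > synonymous > UTRs >
intronic > up/downstream > regulatory > non-coding gene > intergenic)
selects `most_severe`.  Declared distance constants: 5 kb for
upstream/downstream; essential splice = first/last 2 bp of an intron;
splice region = intronic 3–8 bp plus the terminal 3 exonic bases at a
junction.  CDS substitutions translate the reference and mutant codons
with the standard genetic code; indels whose net length change is not a
multiple of 3 are frameshifts, in-frame indels are classed
non-synonymous (they still alter the peptide).  Exonic positions outside
the CDS are 5′/3′ UTR by transcript orientation; intron interiors are
intronic; non-coding transcripts yield the non-coding-gene type;
`INTERGENIC` is returned only when nothing else applies and never
co-occurs.  Novel prediction classifies a bare (location, allele)
against every transcript within 5 kb, sorted most severe first.
Transcripts with incomplete CDS annotation are skipped with a warning at
import rather than special-cased.

## Resequencing views

Coverage levels are opaque positive classes (importers may bin real read
depths); intervals of the same (individual, region, level) merge when
they overlap or are adjacent.  Where different levels overlap, queries
report the maximum level — summing would be the plausible alternative,
and binning policy is upstream of this store.  Sequence reconstruction
is length-preserving: homozygous non-reference single-base genotypes
substitute their allele, heterozygous sites render as IUPAC ambiguity
codes, uncovered positions are lowercased, and multi-base genotypes in
the slice are an error directing to VCF export.

## Interchange formats

FASTA is read through Biopython (uppercased unless soft-masking is
requested; non-nucleotide characters rejected), GFF3 through gffutils
(mRNA/transcript with exon/CDS children; orphans and malformed
transcripts are warned about and skipped), VCF through pysam.  VCF is
the genotype interchange: single-base diploid GTs enter the compressed
store, records with any multi-base allele go to the multi-bp table with
their REF/ALT strings kept verbatim (so export→import is value-equal
without anchor-base rewriting); phased separators are accepted but
stored unphased, matching the LD engine's assumption.  Imported
variants' flanks are recorded directly as 20 bp coordinate pointers
around POS.

## Synthetic data

Generators are pure functions of their seed.  Toy genomes are uniform
i.i.d. A/C/G/T — no repeat structure, GC skew or gaps, so mapping tests
probe the counting rules, not aligner robustness on real repeats.
Variant planting embeds k non-overlapping copies of a randomly drawn
composite and verifies (re-drawing if needed) that the modified genome
contains exactly k occurrences over both strands, making the truth
record exact by construction.  Population genotypes are drawn by random
union of gametes from stated haplotype frequencies (HWE at the haplotype
level) — exactly the EM's likelihood model, which makes parameter
recovery a fair test of the estimator but says nothing about model
misspecification on real populations.  Default study conditions used by
the tests: two loci, 100 kb-window genotypes, 1,000 individuals and 200
replicates for parameter recovery, 10⁴ fuzzed rows for the codec round
trip, 1,000 random SNPs for the consequence oracle and 1,000 planted
variants for the flank round trip — sizes chosen so every distributional
claim has comfortable sampling margin at interactive runtimes.

## Known limitations

Exact-match mapping only (no mismatches or gaps); biallelic two-locus LD
only (no multi-locus haplotypes or phasing output); no protein-impact
scores or splicing-strength models; no assembly-exception (haplotype /
pseudo-autosomal) duplication bookkeeping; the file store is
single-writer and whole-dataset (no concurrent or incremental updates).
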