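# varkit

A self-contained toolkit for storing and analysing population variation,
dense genotyping and resequencing data on a reference genome.  It is
aimed at people who need the machinery of a genome-browser-style
variation resource — variant QC, compact genotype storage, on-the-fly
linkage disequilibrium, consequence annotation, per-individual sequence
views — at desk scale, without a database server.

## What it does

**Variation model.** A variant is assembly-independent: a name, a source,
at least one allele and its 5′/3′ flanking sequences.  Placements on a
reference live in separate *variation features* (with a map weight = the
number of genomic placements), so a new assembly only invalidates the
placements.  Structural variants carry bounded coordinates
(`outer_start ≤ inner_start ≤ inner_end ≤ outer_end`); population
allele/genotype frequencies, phenotype annotations and read-coverage
intervals round out the model.  Datasets persist as a directory of
tab-separated tables plus a binary blob sidecar.

**Flank mapping and QC.** Variants are anchored by exact search of the
composite `5'flank + reference allele + 3'flank` on both strands.  A
variant that maps nowhere, maps more than N = 3 times, or whose declared
reference allele disagrees with the genome at a mapped site is moved to
the failed set (`NO_MAPPING` / `TOO_MANY_MAPPINGS` / `ALLELE_MISMATCH`),
unless whitelisted.  Supplementary data of failed variants is purged.
Flanks that match the reference adjacent to a mapping are compressed to
coordinate pointers and restored on demand.

**Genotype compression.** Single-base genotypes are packed one row per
individual per fixed 100 kb genome window as a repeating triplet stream:
`ULEB128(distance from previous genotype)` + two allele bytes, with the
first genotype's zero distance left implicit (the row's start position
carries it).  With all distances < 128, n genotypes take exactly
3n − 1 bytes.  Multi-base genotypes go to a separate uncompressed table.

**Linkage disequilibrium.** For any two biallelic loci, unphased
genotypes are tabulated into a 3×3 table; an EM iteration resolves the
phase of double heterozygotes to maximum-likelihood haplotype
frequencies p_AB, p_Ab, p_aB, p_ab, from which

    D  = p_AB − p_A·p_B
    D′ = |D| / D_max
    r² = D² / (p_A(1−p_A) p_B(1−p_B))

are computed on the fly for every pair in a region.

**Consequences.** Each variant allele is classified against every
overlapping (or within 5 kb) transcript: stop gained/lost, frameshift,
(non-)synonymous by codon translation, essential splice site (intron
1–2 bp) and splice region, UTRs, intronic, up/downstream, non-coding
gene, regulatory region, intergenic — including novel variants given
only a location and an allele.

**Resequencing views.** Coverage intervals normalise by merging; an
individual's sequence over any slice is reconstructed from the reference
plus its genotypes (IUPAC codes at heterozygous sites) with uncovered
stretches masked to lowercase.

## Worked example

```python
from varkit.codec import encode_window, decode_window
from varkit.model import Genotype

gts = [Genotype("NA12878", "chr1", p, a1, a2)
       for p, (a1, a2) in zip((1000, 1030, 1055, 1375),
                              [("A","G"), ("C","C"), ("G","T"), ("A","A")])]
row = encode_window(gts)
print(row.start, row.blob.hex(), len(row.blob))
for g in decode_window(row):
    print(g.position, g.allele1, g.allele2)
```

prints

```
1000 41471e4343194754c0024141 12
1000 A G
1030 C C
1055 G T
1375 A A
```

The row's start (1000) anchors the first genotype, so its zero distance
is never stored: the 12-byte blob is `AG` ‖ `0x1E CC` ‖ `0x19 GT` ‖
`0xC0 0x02 AA` — distances 30, 25 and 320 bp (320 needs two ULEB128
bytes), each followed by the allele pair.  Decoding re-adds the implicit
zero and accumulates the distances back to absolute positions 1000,
1030, 1055, 1375.

The same dataset is reachable from a shell: `varkit import`, `varkit qc
--purge`, `varkit genotypes query`, `varkit ld --region chr1:1-100000`,
`varkit consequences`, `varkit individual-seq`, `varkit coverage`, and
`varkit fixtures` to generate seeded toy data (see `varkit --help`).

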