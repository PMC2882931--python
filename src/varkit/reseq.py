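"""Resequencing views: coverage intervals and individual sequences.

A resequenced individual is stored as (1) read-coverage intervals with
binned coverage levels and (2) its differences from the reference, held
as genotypes.  That is enough to reconstruct the individual's sequence
over any slice: start from the reference substring, substitute homozygous
non-reference bases, render heterozygous sites as IUPAC ambiguity codes,
and mask uncovered stretches to lowercase.  The contract is
length-preserving — indels are excluded and exported via VCF instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Data.IUPACData import ambiguous_dna_values

from .codec import CodecConfig, query_genotypes
from .model import Dataset, ReadCoverage, Slice

__all__ = [
    "LocusCall",
    "add_coverage",
    "coverage_at",
    "classify_loci",
    "individual_sequence",
    "iupac_code",
]

# invert Biopython's ambiguity table: unordered base pair -> one-letter code
_PAIR_TO_IUPAC: dict[frozenset[str], str] = {
    frozenset(bases): code
    for code, bases in ambiguous_dna_values.items()
    if len(bases) == 2
}


def iupac_code(allele1: str, allele2: str) -> str:
    """IUPAC one-letter code for an unordered pair of bases."""
    if allele1 == allele2:
        return allele1
    pair = frozenset((allele1.upper(), allele2.upper()))
    try:
        return _PAIR_TO_IUPAC[pair]
    except KeyError:
        raise ValueError(f"no IUPAC code for allele pair {allele1}/{allele2}") from None


@dataclass
class LocusCall:
    """Classification of one genotyped locus against the reference."""

    position: int
    ref_base: str
    allele1: str
    allele2: str
    status: str  # REFERENCE | HOMOZYGOUS_NONREF | HETEROZYGOUS
    covered: bool


def add_coverage(ds: Dataset, intervals: Iterable[ReadCoverage]) -> int:
    """Insert coverage intervals, merging overlaps and adjacencies.

    Intervals merge only within the same (individual, region, level) group;
    the store is kept sorted.  Returns the normalised interval count for
    the touched groups.
    """
    incoming = list(intervals)
    touched = {(c.individual_name, c.region_name, c.level) for c in incoming}
    pool = ds.coverage + incoming
    keep = [
        c for c in pool if (c.individual_name, c.region_name, c.level) not in touched
    ]
    merged_count = 0
    for key in sorted(touched):
        group = sorted(
            (
                c
                for c in pool
                if (c.individual_name, c.region_name, c.level) == key
            ),
            key=lambda c: (c.start, c.end),
        )
        merged: list[ReadCoverage] = []
        for c in group:
            if merged and c.start <= merged[-1].end + 1:  # overlap or adjacency
                if c.end > merged[-1].end:
                    merged[-1] = ReadCoverage(
                        c.individual_name, c.region_name, merged[-1].start, c.end, c.level
                    )
            else:
                merged.append(c)
        keep.extend(merged)
        merged_count += len(merged)
    keep.sort(key=lambda c: (c.individual_name, c.region_name, c.level, c.start))
    ds.coverage = keep
    return merged_count


def coverage_at(ds: Dataset, individual: str, sl: Slice) -> list[tuple[int, int, int]]:
    """Piecewise-constant maximum coverage level over a slice.

    Returns (start, end, level) pieces tiling the slice exactly; uncovered
    sub-intervals are reported with level 0.  Where intervals of different
    levels overlap the maximum level wins.
    """
    relevant = [
        c
        for c in ds.coverage
        if c.individual_name == individual
        and c.region_name == sl.region_name
        and c.start <= sl.end
        and sl.start <= c.end
    ]
    cuts = {sl.start, sl.end + 1}
    for c in relevant:
        cuts.add(max(c.start, sl.start))
        cuts.add(min(c.end, sl.end) + 1)
    edges = sorted(cuts)
    pieces: list[tuple[int, int, int]] = []
    for a, b in zip(edges, edges[1:]):
        lvl = max(
            (c.level for c in relevant if c.start <= a and b - 1 <= c.end), default=0
        )
        if pieces and pieces[-1][2] == lvl and pieces[-1][1] == a - 1:
            pieces[-1] = (pieces[-1][0], b - 1, lvl)
        else:
            pieces.append((a, b - 1, lvl))
    return pieces


def classify_loci(
    ds: Dataset, individual: str, sl: Slice, cfg: CodecConfig = CodecConfig()
) -> list[LocusCall]:
    """One call per stored genotype of the individual inside the slice."""
    cover = coverage_at(ds, individual, sl)

    def covered(pos: int) -> bool:
        return any(s <= pos <= e and lvl > 0 for s, e, lvl in cover)

    calls = []
    for g in query_genotypes(ds, sl, individuals=[individual], cfg=cfg):
        ref = ds.fetch_reference(sl.region_name, g.position, g.position).upper()
        a1, a2 = g.allele1.upper(), g.allele2.upper()
        if a1 == a2 == ref:
            status = "REFERENCE"
        elif a1 == a2:
            status = "HOMOZYGOUS_NONREF"
        else:
            status = "HETEROZYGOUS"
        calls.append(LocusCall(g.position, ref, a1, a2, status, covered(g.position)))
    return calls


def individual_sequence(
    ds: Dataset, individual: str, sl: Slice, cfg: CodecConfig = CodecConfig()
) -> str:
    """Reconstruct an individual's sequence over a slice.

    Reference bases are replaced by homozygous non-reference alleles and by
    IUPAC ambiguity codes at heterozygous sites; positions without a stored
    genotype keep the reference base.  Uncovered positions (coverage level
    0) are masked to lowercase.  Always returns exactly ``len(slice)``
    characters; multi-base genotypes in the slice are an error (export such
    loci via VCF instead).
    """
    for g in ds.multi_bp_genotypes:
        if (
            g.individual_name == individual
            and g.region_name == sl.region_name
            and sl.start <= g.position <= sl.end
        ):
            raise ValueError(
                f"multi-base genotype at {sl.region_name}:{g.position}; sequence "
                "reconstruction is length-preserving — export indels via VCF"
            )
    chars = list(ds.fetch_reference(sl.region_name, sl.start, sl.end).upper())
    for g in query_genotypes(ds, sl, individuals=[individual], cfg=cfg):
        chars[g.position - sl.start] = iupac_code(g.allele1, g.allele2)
    for s, e, lvl in coverage_at(ds, individual, sl):
        if lvl == 0:
            for pos in range(s, e + 1):
                chars[pos - sl.start] = chars[pos - sl.start].lower()
    return "".join(chars)
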