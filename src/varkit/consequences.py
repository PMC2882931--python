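"""Rule-based prediction of variant consequences on transcripts.

Each variant allele is classified against every transcript it overlaps
(or lies within 5 kb of) by asking what the allele changes in the
reference sequence: a substitution inside the CDS is translated codon by
codon (stop gained/lost, synonymous, non-synonymous); an indel whose
length is not a multiple of three shifts the reading frame; positions in
the first/last 2 bp of an intron hit the essential splice donor/acceptor
dinucleotides, with a wider splice-region window around each junction;
exonic positions outside the CDS are UTR; and so on down to intergenic.
The same machinery answers for novel variants given only a location and
an allele — no stored variant is required.

Severity ranking and the distance/window constants are declared here and
configurable; they follow genome-browser-era conventions (5 kb
up/downstream, 2 bp essential splice, 8 bp intronic / 3 bp exonic splice
region).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq, reverse_complement

from .model import Dataset, Slice, TranscriptModel, VariationFeature

__all__ = [
    "ConsequenceType",
    "ConsequenceCall",
    "VariantAllele",
    "classify",
    "predict_novel",
    "consequences_for_feature",
    "UPSTREAM_DOWNSTREAM_DISTANCE",
    "ESSENTIAL_SPLICE_INTRON_BP",
    "SPLICE_REGION_INTRON_BP",
    "SPLICE_REGION_EXON_BP",
]

UPSTREAM_DOWNSTREAM_DISTANCE = 5000
ESSENTIAL_SPLICE_INTRON_BP = 2
SPLICE_REGION_INTRON_BP = 8
SPLICE_REGION_EXON_BP = 3


class ConsequenceType(enum.Enum):
    """Consequence categories, declared most severe first."""

    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"
    FRAMESHIFT_CODING = "FRAMESHIFT_CODING"
    NON_SYNONYMOUS_CODING = "NON_SYNONYMOUS_CODING"
    ESSENTIAL_SPLICE_SITE = "ESSENTIAL_SPLICE_SITE"
    SPLICE_SITE = "SPLICE_SITE"
    SYNONYMOUS_CODING = "SYNONYMOUS_CODING"
    FIVE_PRIME_UTR = "5PRIME_UTR"
    THREE_PRIME_UTR = "3PRIME_UTR"
    INTRONIC = "INTRONIC"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    REGULATORY_REGION = "REGULATORY_REGION"
    WITHIN_NON_CODING_GENE = "WITHIN_NON_CODING_GENE"
    INTERGENIC = "INTERGENIC"

    @property
    def rank(self) -> int:
        return _SEVERITY_INDEX[self]


_SEVERITY_INDEX = {t: i for i, t in enumerate(ConsequenceType)}


@dataclass(frozen=True)
class VariantAllele:
    """One alternate allele at one reference location.

    Conventions: a SNP has start == end and a single-base ``alt``; a
    deletion removes reference bases [start, end] and has alt == "-"; an
    insertion has start == end + 1 (the insertion point between end and
    start) and ``alt`` is the inserted sequence.
    """

    region_name: str
    start: int
    end: int
    alt: str
    name: str = "novel"

    @property
    def is_insertion(self) -> bool:
        return self.start == self.end + 1

    @property
    def is_deletion(self) -> bool:
        return self.alt == "-" and not self.is_insertion

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic interval touched by the allele (closed)."""
        return (min(self.start, self.end), max(self.start, self.end))


@dataclass
class ConsequenceCall:
    variation_name: str
    transcript_name: Optional[str]
    types: tuple[ConsequenceType, ...]
    most_severe: ConsequenceType
    codon_change: Optional[str] = None
    peptide_change: Optional[str] = None
    cdna_position: Optional[int] = None
    protein_position: Optional[int] = None


def _genomic_exons(t: TranscriptModel) -> list[tuple[int, int]]:
    return sorted(t.exons)


def _introns(t: TranscriptModel) -> list[tuple[int, int]]:
    ex = _genomic_exons(t)
    return [
        (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(ex, ex[1:]) if s2 - e1 > 1
    ]


def _cds_intervals(t: TranscriptModel) -> list[tuple[int, int]]:
    if t.cds_start is None:
        return []
    out = []
    for s, e in _genomic_exons(t):
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if lo <= hi:
            out.append((lo, hi))
    return out


def _cds_sequence(t: TranscriptModel, reference: dict[str, str]) -> str:
    seq = reference[t.region_name]
    parts = [seq[s - 1 : e].upper() for s, e in _cds_intervals(t)]
    cds = "".join(parts)
    return reverse_complement(cds) if t.strand == -1 else cds


def _cds_offset(t: TranscriptModel, pos: int) -> Optional[int]:
    """0-based offset of a genomic position within the coding sequence."""
    ivals = _cds_intervals(t)
    if not any(s <= pos <= e for s, e in ivals):
        return None
    if t.strand == 1:
        off = 0
        for s, e in ivals:
            if pos > e:
                off += e - s + 1
            elif pos >= s:
                return off + (pos - s)
    else:
        off = 0
        for s, e in reversed(ivals):
            if pos < s:
                off += e - s + 1
            elif pos <= e:
                return off + (e - pos)
    return None


def _cdna_offset(t: TranscriptModel, pos: int) -> Optional[int]:
    off = 0
    for s, e in t.exons:  # transcript order
        if s <= pos <= e:
            return off + (pos - s if t.strand == 1 else e - pos)
        off += e - s + 1
    return None


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def classify(
    variant: VariantAllele,
    t: TranscriptModel,
    reference: dict[str, str],
    regulatory: Optional[Sequence[Slice]] = None,
) -> ConsequenceCall:
    """Consequence of one alt allele on one transcript.

    Applies the positional rules on the transcript's coding strand and
    returns the union of applicable types for variants spanning more than
    one context (e.g. a junction SNP can be both coding and splice-region).
    """
    seq = reference.get(variant.region_name)
    if seq is None:
        raise KeyError(f"unknown region {variant.region_name!r}")
    lo, hi = variant.footprint
    if lo < 1 or hi > len(seq):
        raise ValueError(
            f"variant {variant.region_name}:{lo}-{hi} outside reference"
        )
    is_snp = (
        variant.start == variant.end
        and len(variant.alt) == 1
        and variant.alt != "-"
    )
    if is_snp:
        ref_base = seq[variant.start - 1].upper()
        if variant.alt.upper() == ref_base:
            raise ValueError(
                f"alt allele equals the reference base {ref_base} at "
                f"{variant.region_name}:{variant.start}"
            )

    types: set[ConsequenceType] = set()
    codon_change = peptide_change = None
    cdna_position = protein_position = None

    if regulatory:
        for r in regulatory:
            if r.region_name == variant.region_name and r.start <= hi and lo <= r.end:
                types.add(ConsequenceType.REGULATORY_REGION)
                break

    if t.region_name == variant.region_name:
        t_lo, t_hi = t.span
        if hi < t_lo or lo > t_hi:
            # near but not overlapping: up/downstream by coding strand
            if hi < t_lo and t_lo - hi <= UPSTREAM_DOWNSTREAM_DISTANCE:
                types.add(
                    ConsequenceType.UPSTREAM if t.strand == 1 else ConsequenceType.DOWNSTREAM
                )
            elif lo > t_hi and lo - t_hi <= UPSTREAM_DOWNSTREAM_DISTANCE:
                types.add(
                    ConsequenceType.DOWNSTREAM if t.strand == 1 else ConsequenceType.UPSTREAM
                )
        else:
            types |= _overlap_types(variant, t)
            if _touches_cds(variant, t):
                if is_snp:
                    (
                        coding_type,
                        codon_change,
                        peptide_change,
                        cdna_position,
                        protein_position,
                    ) = _classify_coding_snp(variant, t, reference)
                    types.add(coding_type)
                else:
                    ref_len = 0 if variant.is_insertion else hi - lo + 1
                    alt_len = 0 if variant.alt == "-" else len(variant.alt)
                    if (alt_len - ref_len) % 3 != 0:
                        types.add(ConsequenceType.FRAMESHIFT_CODING)
                    else:
                        types.add(ConsequenceType.NON_SYNONYMOUS_CODING)
                    cdna_position = _first_cdna_position(variant, t)

    if not types:
        types.add(ConsequenceType.INTERGENIC)
    ordered = tuple(sorted(types, key=lambda c: c.rank))
    return ConsequenceCall(
        variation_name=variant.name,
        transcript_name=t.name if ordered[0] is not ConsequenceType.INTERGENIC else None,
        types=ordered,
        most_severe=ordered[0],
        codon_change=codon_change,
        peptide_change=peptide_change,
        cdna_position=cdna_position,
        protein_position=protein_position,
    )


def _overlap_types(variant: VariantAllele, t: TranscriptModel) -> set[ConsequenceType]:
    """Positional (non-codon) types for a variant overlapping the span."""
    types: set[ConsequenceType] = set()
    lo, hi = variant.footprint
    t_lo, t_hi = t.span
    exons = _genomic_exons(t)
    introns = _introns(t)
    coding = t.is_coding
    for pos in range(max(lo, t_lo), min(hi, t_hi) + 1):
        exon = next(((s, e) for s, e in exons if s <= pos <= e), None)
        if exon is not None:
            s, e = exon
            # exonic splice region: last bases of an exon at an intron junction
            if e < t_hi and pos > e - SPLICE_REGION_EXON_BP:
                types.add(ConsequenceType.SPLICE_SITE)
            if s > t_lo and pos < s + SPLICE_REGION_EXON_BP:
                types.add(ConsequenceType.SPLICE_SITE)
            if not coding:
                types.add(ConsequenceType.WITHIN_NON_CODING_GENE)
            elif pos < t.cds_start:
                types.add(
                    ConsequenceType.FIVE_PRIME_UTR
                    if t.strand == 1
                    else ConsequenceType.THREE_PRIME_UTR
                )
            elif pos > t.cds_end:
                types.add(
                    ConsequenceType.THREE_PRIME_UTR
                    if t.strand == 1
                    else ConsequenceType.FIVE_PRIME_UTR
                )
            # CDS positions get their coding type from the codon machinery
        else:
            intron = next(((s, e) for s, e in introns if s <= pos <= e), None)
            if intron is None:
                continue
            s, e = intron
            d = min(pos - s + 1, e - pos + 1)
            if d <= ESSENTIAL_SPLICE_INTRON_BP:
                types.add(ConsequenceType.ESSENTIAL_SPLICE_SITE)
            elif d <= SPLICE_REGION_INTRON_BP:
                types.add(ConsequenceType.SPLICE_SITE)
            else:
                types.add(ConsequenceType.INTRONIC)
    return types


def _touches_cds(variant: VariantAllele, t: TranscriptModel) -> bool:
    if not t.is_coding:
        return False
    lo, hi = variant.footprint
    if variant.is_insertion:
        # the insertion point must fall strictly inside the CDS
        return t.cds_start <= variant.end and variant.start <= t.cds_end and (
            _cds_offset(t, variant.end) is not None
            or _cds_offset(t, variant.start) is not None
        )
    return any(
        s <= hi and lo <= e for s, e in _cds_intervals(t)
    )


def _first_cdna_position(variant: VariantAllele, t: TranscriptModel) -> Optional[int]:
    lo, hi = variant.footprint
    for pos in range(lo, hi + 1):
        off = _cdna_offset(t, pos)
        if off is not None:
            return off + 1
    return None


def _classify_coding_snp(
    variant: VariantAllele, t: TranscriptModel, reference: dict[str, str]
) -> tuple[ConsequenceType, Optional[str], Optional[str], Optional[int], Optional[int]]:
    pos = variant.start
    cds_off = _cds_offset(t, pos)
    cds = _cds_sequence(t, reference)
    codon_idx = cds_off // 3
    within = cds_off % 3
    ref_codon = cds[3 * codon_idx : 3 * codon_idx + 3]
    cdna_pos = _cdna_offset(t, pos)
    cdna_pos = None if cdna_pos is None else cdna_pos + 1
    if len(ref_codon) < 3:
        # trailing partial codon on a CDS whose length is not a multiple of 3
        return (ConsequenceType.NON_SYNONYMOUS_CODING, None, None, cdna_pos, None)
    alt_base = variant.alt.upper()
    if t.strand == -1:
        alt_base = reverse_complement(alt_base)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        ctype = ConsequenceType.STOP_GAINED
    elif ref_aa == "*" and alt_aa != "*":
        ctype = ConsequenceType.STOP_LOST
    elif ref_aa == alt_aa:
        ctype = ConsequenceType.SYNONYMOUS_CODING
    else:
        ctype = ConsequenceType.NON_SYNONYMOUS_CODING
    return (
        ctype,
        f"{ref_codon}>{alt_codon}",
        f"{ref_aa}/{alt_aa}",
        cdna_pos,
        codon_idx + 1,
    )


def predict_novel(
    ds: Dataset,
    region_name: str,
    start: int,
    alt: str,
    end: Optional[int] = None,
    name: str = "novel",
    regulatory: Optional[Sequence[Slice]] = None,
) -> list[ConsequenceCall]:
    """Consequences of a (possibly novel) allele at a genomic location.

    Classifies against every transcript within the up/downstream distance;
    with no transcript in range a single INTERGENIC call is returned.  The
    variant need not exist in the dataset.  Results are sorted most severe
    first.
    """
    if end is None:
        end = start if alt != "-" else start
    variant = VariantAllele(region_name, start, end, alt, name=name)
    lo, hi = variant.footprint
    calls = []
    for t in ds.transcripts:
        if t.region_name != region_name:
            continue
        t_lo, t_hi = t.span
        if (
            lo <= t_hi + UPSTREAM_DOWNSTREAM_DISTANCE
            and hi >= t_lo - UPSTREAM_DOWNSTREAM_DISTANCE
        ):
            calls.append(classify(variant, t, ds.reference, regulatory=regulatory))
    if not calls:
        types = [ConsequenceType.INTERGENIC]
        if regulatory and any(
            r.region_name == region_name and r.start <= hi and lo <= r.end
            for r in regulatory
        ):
            types = [ConsequenceType.REGULATORY_REGION]
        ordered = tuple(sorted(types, key=lambda c: c.rank))
        calls = [
            ConsequenceCall(
                variation_name=name,
                transcript_name=None,
                types=ordered,
                most_severe=ordered[0],
            )
        ]
    calls.sort(key=lambda c: c.most_severe.rank)
    return calls


def consequences_for_feature(
    ds: Dataset,
    feature: VariationFeature,
    regulatory: Optional[Sequence[Slice]] = None,
) -> list[ConsequenceCall]:
    """Consequence calls for every alt allele of a stored mapped variant."""
    alleles = feature.allele_string.split("/")
    calls: list[ConsequenceCall] = []
    for alt in alleles[1:]:
        calls.extend(
            predict_novel(
                ds,
                feature.region_name,
                feature.start,
                alt,
                end=feature.end,
                name=feature.variation_name,
                regulatory=regulatory,
            )
        )
    return calls
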