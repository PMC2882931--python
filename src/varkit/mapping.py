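"""Flank-based variant mapping, QC rules, and flank compression.

A variant is anchored to the reference by aligning the composite
``5'flank + reference allele + 3'flank`` sequence to both strands.  Here
the aligner is an exact substring search — adequate for toy genomes and
simulated data; any real aligner can be swapped in behind
:func:`map_flanks`'s contract (hits delimit the allele, sorted by
position, uncapped).

QC then applies the classic failed-variation rules: a variant that maps
nowhere, maps more than N times (N = 3 by default), or whose declared
reference allele disagrees with the genome at a mapped location is moved
to the failed set — unless it is whitelisted (e.g. clinically
significant), in which case it is always retained.  All supplementary
data for failed variants is purged before release.

Finally, flanking sequences that exactly match the reference adjacent to
a mapped allele are compressed to coordinate pointers and restored on
demand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import reverse_complement

from .codec import CodecConfig, decode_window, encode_window
from .model import (
    Dataset,
    FailedReason,
    FlankRecord,
    Variation,
    VariationFeature,
)

__all__ = [
    "MappingHit",
    "QCConfig",
    "QCOutcome",
    "MappingError",
    "map_flanks",
    "apply_qc",
    "run_qc",
    "purge_failed",
    "compress_flank",
    "compress_variant_flanks",
    "restore_flank",
]


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class MappingHit:
    """One placement of a variant; coordinates delimit the allele itself.

    For an insertion (empty reference allele) ``start = end + 1``.
    """

    region_name: str
    start: int
    end: int
    strand: int


@dataclass(frozen=True)
class QCConfig:
    """QC thresholds: the mapping cap N and the minimum usable flank length."""

    max_mappings: int = 3
    flank_min_len: int = 20

    def __post_init__(self) -> None:
        if self.max_mappings < 1:
            raise ValueError("max_mappings must be >= 1")
        if self.flank_min_len < 1:
            raise ValueError("flank_min_len must be >= 1")


@dataclass
class QCOutcome:
    variation_name: str
    retained: bool
    failed_reason: Optional[FailedReason] = None
    features: list[VariationFeature] = field(default_factory=list)


def _ref_allele(v: Variation) -> str:
    allele = v.alleles[0]
    return "" if allele == "-" else allele


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based start offsets of every (possibly overlapping) occurrence."""
    return [m.start() for m in re.finditer(f"(?={re.escape(needle)})", haystack)]


def map_flanks(
    v: Variation, reference: dict[str, str], cfg: QCConfig = QCConfig()
) -> list[MappingHit]:
    """Every exact placement of flank_up + ref_allele + flank_down.

    Both strands are searched; a palindromic composite matching forward and
    reverse at the same locus counts once, on the forward strand.  No cap is
    applied — capping is QC's job.
    """
    for which, fr in (("5'", v.flank_up), ("3'", v.flank_down)):
        if fr is None or fr.raw_seq is None:
            raise MappingError(
                f"variant {v.name!r} has no raw {which} flanking sequence"
            )
        if len(fr.raw_seq) < cfg.flank_min_len:
            raise MappingError(
                f"variant {v.name!r}: {which} flank shorter than "
                f"{cfg.flank_min_len} bp"
            )
    up = v.flank_up.raw_seq.upper()
    down = v.flank_down.raw_seq.upper()
    allele = _ref_allele(v).upper()
    composite = up + allele + down
    rc = reverse_complement(composite)

    hits: list[MappingHit] = []
    seen: set[tuple[str, int, int]] = set()
    for region, seq in reference.items():
        seq = seq.upper()
        for off in _find_all(seq, composite):
            start = off + len(up) + 1
            end = start + len(allele) - 1  # end = start-1 for an insertion
            hits.append(MappingHit(region, start, end, 1))
            seen.add((region, start, end))
        for off in _find_all(seq, rc):
            # within the reverse-complemented composite the allele sits
            # after the reverse-complemented 3' flank
            start = off + len(down) + 1
            end = start + len(allele) - 1
            if (region, start, end) in seen:
                continue  # palindromic composite: one physical locus
            hits.append(MappingHit(region, start, end, -1))
    hits.sort(key=lambda h: (h.region_name, h.start, h.end, -h.strand))
    return hits


def _hit_ref_allele(hit: MappingHit, reference: dict[str, str]) -> str:
    """Reference bases under a hit, in the variant's orientation."""
    seq = reference.get(hit.region_name)
    if seq is None:
        raise KeyError(f"hit references unknown region {hit.region_name!r}")
    if hit.end < hit.start:  # insertion point: no reference bases
        return ""
    if hit.start < 1 or hit.end > len(seq):
        raise MappingError(
            f"hit {hit.region_name}:{hit.start}-{hit.end} outside reference"
        )
    bases = seq[hit.start - 1 : hit.end].upper()
    return reverse_complement(bases) if hit.strand == -1 else bases


def _forward_allele_string(v: Variation, strand: int) -> str:
    """Allele string for a feature stored on the forward strand."""
    alleles = v.alleles
    if strand == -1:
        alleles = [a if a == "-" else reverse_complement(a) for a in alleles]
    return "/".join(alleles)


def apply_qc(
    v: Variation,
    hits: list[MappingHit],
    reference: dict[str, str],
    cfg: QCConfig = QCConfig(),
) -> QCOutcome:
    """Apply the failed-variation rules to one variant's mapping hits.

    Outcomes, in rule order: no hits -> NO_MAPPING; more than N hits ->
    TOO_MANY_MAPPINGS; a hit whose reference bases differ from the declared
    reference allele -> ALLELE_MISMATCH.  Otherwise the variant is retained
    with one forward-strand feature per hit and map_weight = hit count.
    A whitelisted variant is never failed; when it over-maps, only the N
    leftmost hits are materialised but map_weight keeps the true count.
    """
    is_insertion = v.alleles[0] == "-"
    declared = "" if is_insertion else v.alleles[0].upper()

    failed: Optional[FailedReason] = None
    if not hits:
        failed = FailedReason.NO_MAPPING
    elif len(hits) > cfg.max_mappings:
        failed = FailedReason.TOO_MANY_MAPPINGS
    else:
        for h in hits:
            if not is_insertion and _hit_ref_allele(h, reference) != declared:
                failed = FailedReason.ALLELE_MISMATCH
                break

    if failed is not None and not v.whitelisted:
        return QCOutcome(v.name, retained=False, failed_reason=failed)

    kept = hits
    if len(hits) > cfg.max_mappings:  # whitelisted over-mapper: leftmost N
        kept = sorted(hits, key=lambda h: (h.region_name, h.start))[: cfg.max_mappings]
    features = [
        VariationFeature(
            variation_name=v.name,
            region_name=h.region_name,
            start=h.start,
            end=h.end,
            strand=1,
            allele_string=_forward_allele_string(v, h.strand),
            map_weight=len(hits),
        )
        for h in kept
    ]
    # unknown-region hits must error even when the allele check is skipped
    for h in kept:
        if h.region_name not in reference:
            raise KeyError(f"hit references unknown region {h.region_name!r}")
    return QCOutcome(v.name, retained=True, features=features)


def run_qc(ds: Dataset, cfg: QCConfig = QCConfig()) -> list[QCOutcome]:
    """Map and QC every variant that still carries raw flanks.

    Retained variants gain features in the dataset; failed ones get their
    failed_reason set (purge is a separate, explicit step).
    """
    outcomes = []
    for v in ds.variations.values():
        if v.flank_up is None or v.flank_up.raw_seq is None:
            continue
        hits = map_flanks(v, ds.reference, cfg)
        out = apply_qc(v, hits, ds.reference, cfg)
        if out.retained:
            ds.variation_features.extend(out.features)
            if out.features and v.name not in ds.variant_positions:
                f = out.features[0]
                ds.variant_positions[v.name] = (f.region_name, f.start)
        else:
            v.failed_reason = out.failed_reason
        outcomes.append(out)
    return outcomes


def purge_failed(ds: Dataset, cfg: CodecConfig = CodecConfig()) -> dict[str, int]:
    """Delete all supplementary data of failed variants.

    Failed variants keep only (name, source, failed_reason); their features,
    alleles, flanks, frequencies, annotations and genotypes (compressed and
    multi-bp) are removed.  Idempotent.  Returns removed-record counts.
    """
    failed = {name for name, v in ds.variations.items() if v.failed_reason is not None}
    counts = {"features": 0, "alleles": 0, "frequencies": 0, "annotations": 0, "genotypes": 0}
    if not failed:
        return counts

    before = len(ds.variation_features)
    ds.variation_features = [
        f for f in ds.variation_features if f.variation_name not in failed
    ]
    counts["features"] = before - len(ds.variation_features)

    before = len(ds.frequencies)
    ds.frequencies = [f for f in ds.frequencies if f.variation_name not in failed]
    counts["frequencies"] = before - len(ds.frequencies)

    before = len(ds.annotations)
    ds.annotations = [a for a in ds.annotations if a.variation_name not in failed]
    counts["annotations"] = before - len(ds.annotations)

    before = len(ds.multi_bp_genotypes)
    ds.multi_bp_genotypes = [
        g for g in ds.multi_bp_genotypes if g.variation_name not in failed
    ]
    counts["genotypes"] += before - len(ds.multi_bp_genotypes)

    # compressed genotypes are positional: drop those at failed variants' loci
    failed_loci = {
        ds.variant_positions[name] for name in failed if name in ds.variant_positions
    }
    if failed_loci:
        new_rows = []
        for row in ds.genotype_rows:
            gts = decode_window(row)
            kept = [g for g in gts if (g.region_name, g.position) not in failed_loci]
            counts["genotypes"] += len(gts) - len(kept)
            if kept:
                new_rows.append(encode_window(kept, cfg))
        ds.genotype_rows = new_rows

    for name in failed:
        v = ds.variations[name]
        counts["alleles"] += len(v.alleles)
        v.alleles = []
        v.flank_up = None
        v.flank_down = None
        v.ancestral_allele = None
        ds.variant_positions.pop(name, None)
    return counts


def compress_flank(
    v: Variation,
    feature: VariationFeature,
    reference: dict[str, str],
    which: str = "up",
) -> FlankRecord:
    """Replace one raw flank by reference coordinates when it matches.

    ``which`` selects the 5' ("up") or 3' ("down") flank.  The raw flank is
    compared against the reference adjacent to the mapped allele, first in
    forward orientation and then as the reverse complement of the opposite
    side (a variant originally mapped on the reverse strand); a match yields
    a coord_ref whose strand records the orientation.  A flank that matches
    neither is returned unchanged as a raw record.
    """
    if which not in ("up", "down"):
        raise ValueError("which must be 'up' or 'down'")
    fr = v.flank_up if which == "up" else v.flank_down
    if fr is None:
        raise MappingError(f"variant {v.name!r} has no {which} flank")
    if fr.raw_seq is None:
        return fr  # already compressed
    seq = reference.get(feature.region_name)
    if seq is None:
        raise KeyError(f"unknown region {feature.region_name!r}")
    if feature.start < 1 or feature.end > len(seq) or feature.start > len(seq) + 1:
        raise MappingError(
            f"feature {feature.region_name}:{feature.start}-{feature.end} "
            "outside reference"
        )
    raw = fr.raw_seq.upper()
    L = len(raw)

    def window(s: int, e: int) -> Optional[str]:
        if s < 1 or e > len(seq):
            return None
        return seq[s - 1 : e].upper()

    # forward orientation: 5' flank precedes the allele, 3' flank follows
    if which == "up":
        fwd = (feature.start - L, feature.start - 1)
        rev = (feature.end + 1, feature.end + L)
    else:
        fwd = (feature.end + 1, feature.end + L)
        rev = (feature.start - L, feature.start - 1)
    cand = window(*fwd)
    if cand is not None and cand == raw:
        return FlankRecord(coord_ref=(feature.region_name, fwd[0], fwd[1], 1))
    cand = window(*rev)
    if cand is not None and reverse_complement(cand) == raw:
        return FlankRecord(coord_ref=(feature.region_name, rev[0], rev[1], -1))
    return fr


def compress_variant_flanks(
    v: Variation, feature: VariationFeature, reference: dict[str, str]
) -> None:
    """Compress both flanks of a variant in place (where they match)."""
    v.flank_up = compress_flank(v, feature, reference, "up")
    v.flank_down = compress_flank(v, feature, reference, "down")


def restore_flank(fr: FlankRecord, reference: dict[str, str]) -> str:
    """The flanking sequence, restored from coordinates when compressed."""
    if fr.raw_seq is not None:
        return fr.raw_seq
    region, start, end, strand = fr.coord_ref
    seq = reference.get(region)
    if seq is None:
        raise KeyError(f"unknown region {region!r}")
    if start < 1 or end > len(seq):
        raise MappingError(f"coord_ref {region}:{start}-{end} outside reference")
    sub = seq[start - 1 : end].upper()
    return reverse_complement(sub) if strand == -1 else sub
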