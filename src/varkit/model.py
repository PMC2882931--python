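"""Core domain types for population-variation data.

The model mirrors the classic two-table-set design for genome variation
resources: assembly-independent records (a variant's name, source, alleles
and flanking sequences) are kept separate from their placements on a
reference assembly (variation features), so that a new assembly only
invalidates the placements.  Around these sit tables for structural
variants with bounded (outer/inner) coordinates, population allele and
genotype frequencies, phenotype annotations, read-coverage intervals and
the compressed genotype store.

Coordinates are 1-based, fully-closed throughout.  Insertions are
represented with ``start = end + 1`` (the insertion point lies between
``end`` and ``start``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "Slice",
    "FailedReason",
    "FlankRecord",
    "Variation",
    "VariationFeature",
    "StructuralVariation",
    "PopulationFrequency",
    "VariationAnnotation",
    "Individual",
    "Genotype",
    "GenotypeRow",
    "MultiBpGenotype",
    "ReadCoverage",
    "TranscriptModel",
    "Dataset",
    "ValidationError",
    "slices_overlap",
    "query_structural",
    "query_phenotype",
]

FREQ_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """An object or insert violates a model invariant."""


class FailedReason(str, Enum):
    """Why a variant was moved to the failed set during QC."""

    NO_MAPPING = "NO_MAPPING"
    TOO_MANY_MAPPINGS = "TOO_MANY_MAPPINGS"
    ALLELE_MISMATCH = "ALLELE_MISMATCH"


@dataclass(frozen=True)
class Slice:
    """A contiguous region of one reference sequence (1-based, closed)."""

    region_name: str
    start: int
    end: int
    strand: int = 1

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"slice start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"slice end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in (1, -1):
            raise ValidationError(f"strand must be +1 or -1, got {self.strand}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class FlankRecord:
    """One flanking sequence, stored raw or as reference coordinates.

    Before a variant is mapped the raw sequence is held verbatim.  After
    QC, a flank that exactly matches the reference adjacent to the mapped
    allele is compressed to a ``(region, start, end, strand)`` pointer and
    the raw sequence dropped; the sequence is then restored on demand.
    """

    raw_seq: Optional[str] = None
    coord_ref: Optional[tuple[str, int, int, int]] = None

    def __post_init__(self) -> None:
        if (self.raw_seq is None) == (self.coord_ref is None):
            raise ValidationError(
                "exactly one of raw_seq / coord_ref must be set on a flank"
            )


@dataclass
class Variation:
    """An assembly-independent sequence variant.

    Defined by its two flanking sequences plus at least one allele; the
    placement(s) on a reference live in :class:`VariationFeature`.
    """

    name: str
    source: str
    alleles: list[str]
    flank_up: Optional[FlankRecord] = None
    flank_down: Optional[FlankRecord] = None
    ancestral_allele: Optional[str] = None
    whitelisted: bool = False
    failed_reason: Optional[FailedReason] = None

    def __post_init__(self) -> None:
        if not self.alleles and self.failed_reason is None:
            raise ValidationError(f"variant {self.name!r} must have >= 1 allele")

    @property
    def allele_string(self) -> str:
        return "/".join(self.alleles)


@dataclass
class VariationFeature:
    """One mapping of a variant onto the reference (forward strand).

    ``map_weight`` is the total number of genomic placements of the
    variant; it equals the number of stored features except for
    whitelisted variants mapping more than the QC cap, where only the
    leftmost hits are materialised.

    For an insertion ``start = end + 1``.
    """

    variation_name: str
    region_name: str
    start: int
    end: int
    strand: int
    allele_string: str
    map_weight: int = 1

    def __post_init__(self) -> None:
        if self.map_weight < 1:
            raise ValidationError("map_weight must be >= 1")
        if self.end < self.start - 1:
            raise ValidationError(
                f"feature end ({self.end}) must be >= start-1 ({self.start - 1})"
            )
        if self.strand not in (1, -1):
            raise ValidationError("feature strand must be +1 or -1")


@dataclass
class StructuralVariation:
    """A structural variant with fuzzy boundaries.

    The location is a range between a minimum (outer) and maximum (inner)
    bound at each end: outer_start <= inner_start <= inner_end <= outer_end.
    """

    name: str
    region_name: str
    outer_start: int
    inner_start: int
    inner_end: int
    outer_end: int
    sv_class: str = "CNV"

    def __post_init__(self) -> None:
        if not (
            self.outer_start <= self.inner_start <= self.inner_end <= self.outer_end
        ):
            raise ValidationError(
                f"structural variant {self.name!r}: bounds must satisfy "
                "outer_start <= inner_start <= inner_end <= outer_end"
            )


@dataclass
class PopulationFrequency:
    """An observed allele or genotype frequency in one population."""

    population: str
    variation_name: str
    kind: str  # "allele" | "genotype"
    state: str
    frequency: float
    sample_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("allele", "genotype"):
            raise ValidationError(f"frequency kind must be allele/genotype, got {self.kind!r}")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValidationError(f"frequency must lie in [0,1], got {self.frequency}")


@dataclass
class VariationAnnotation:
    """A phenotype/association annotation attached to a variant."""

    variation_name: str
    phenotype_description: str
    risk_allele: Optional[str] = None
    p_value: Optional[float] = None
    study_source: str = ""

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value must lie in (0,1], got {self.p_value}")


@dataclass
class Individual:
    name: str
    population_names: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Genotype:
    """One individual's unphased allele pair at a single base position."""

    individual_name: str
    region_name: str
    position: int
    allele1: str
    allele2: str

    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele1, self.allele2))


@dataclass
class GenotypeRow:
    """One individual x one fixed genome window of packed genotypes.

    The blob is a delta-encoded triplet stream; see :mod:`varkit.codec`.
    """

    individual_name: str
    region_name: str
    window_index: int
    start: int
    blob: bytes

    def __post_init__(self) -> None:
        if self.window_index < 0:
            raise ValidationError("window_index must be >= 0")


@dataclass
class MultiBpGenotype:
    """An uncompressed genotype for indels / multi-base alleles."""

    individual_name: str
    region_name: str
    position: int
    allele1: str
    allele2: str
    variation_name: Optional[str] = None


@dataclass
class ReadCoverage:
    """A read-coverage interval at one binned coverage level."""

    individual_name: str
    region_name: str
    start: int
    end: int
    level: int

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise ValidationError(f"coverage level must be positive, got {self.level}")
        if self.end < self.start:
            raise ValidationError("coverage end must be >= start")


@dataclass
class TranscriptModel:
    """A transcript: exon structure plus optional CDS bounds.

    ``exons`` are (start, end) pairs in transcript (5'->3') order — ascending
    genomic coordinates on the forward strand, descending on the reverse.
    ``cds_start``/``cds_end`` are genomic bounds (cds_start <= cds_end)
    irrespective of strand; absent for non-coding transcripts.
    """

    name: str
    region_name: str
    strand: int
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValidationError("transcript strand must be +1 or -1")
        if not self.exons:
            raise ValidationError(f"transcript {self.name!r} has no exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValidationError(f"transcript {self.name!r}: exons overlap")
        expected = genomic if self.strand == 1 else genomic[::-1]
        if list(self.exons) != expected:
            raise ValidationError(
                f"transcript {self.name!r}: exons not in transcript order"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            if self.cds_start > self.cds_end:
                raise ValidationError("cds_start must be <= cds_end")
            if not any(s <= self.cds_start <= e for s, e in genomic) or not any(
                s <= self.cds_end <= e for s, e in genomic
            ):
                raise ValidationError("CDS bounds must lie inside the exon union")

    @property
    def span(self) -> tuple[int, int]:
        genomic = sorted(self.exons)
        return genomic[0][0], genomic[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding" and self.cds_start is not None


@dataclass
class Dataset:
    """In-memory container for one variation dataset.

    Persistence (a directory of tab-separated tables plus a binary blob
    sidecar) lives in :mod:`varkit.persist`.
    """

    reference: dict[str, str] = field(default_factory=dict)
    variations: dict[str, Variation] = field(default_factory=dict)
    variation_features: list[VariationFeature] = field(default_factory=list)
    genotype_rows: list[GenotypeRow] = field(default_factory=list)
    multi_bp_genotypes: list[MultiBpGenotype] = field(default_factory=list)
    coverage: list[ReadCoverage] = field(default_factory=list)
    structural_variations: list[StructuralVariation] = field(default_factory=list)
    frequencies: list[PopulationFrequency] = field(default_factory=list)
    annotations: list[VariationAnnotation] = field(default_factory=list)
    individuals: dict[str, Individual] = field(default_factory=dict)
    transcripts: list[TranscriptModel] = field(default_factory=list)
    # name -> (region, position): where a variant's genotypes live; QC purge
    # uses this to delete genotypes of failed variants.
    variant_positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def add_variation(self, v: Variation) -> None:
        if v.name in self.variations:
            raise ValidationError(f"duplicate variant name {v.name!r}")
        self.variations[v.name] = v

    def add_individual(self, ind: Individual) -> None:
        if ind.name not in self.individuals:
            self.individuals[ind.name] = ind

    def add_frequencies(
        self, freqs: list[PopulationFrequency], complete: bool = True
    ) -> None:
        """Insert a batch of frequencies.

        When ``complete`` is true each (population, variation, kind) group in
        the batch is taken to be the full observed set and must sum to 1
        within ``FREQ_SUM_TOL``; otherwise the insert is rejected.
        """
        if complete:
            groups: dict[tuple[str, str, str], float] = {}
            for f in freqs:
                key = (f.population, f.variation_name, f.kind)
                groups[key] = groups.get(key, 0.0) + f.frequency
            for key, total in groups.items():
                if abs(total - 1.0) > FREQ_SUM_TOL:
                    raise ValidationError(
                        f"frequencies for {key} sum to {total:.8f}, not 1"
                    )
        self.frequencies.extend(freqs)

    def region_length(self, region_name: str) -> int:
        try:
            return len(self.reference[region_name])
        except KeyError:
            raise KeyError(f"unknown region {region_name!r}") from None

    def fetch_reference(self, region_name: str, start: int, end: int) -> str:
        """Reference bases for a 1-based closed interval."""
        seq = self.reference.get(region_name)
        if seq is None:
            raise KeyError(f"unknown region {region_name!r}")
        if start < 1 or end > len(seq):
            raise ValueError(
                f"{region_name}:{start}-{end} outside reference (length {len(seq)})"
            )
        return seq[start - 1 : end]


def slices_overlap(a: Slice, b: Slice) -> bool:
    """True iff the two slices share a region and their closed intervals
    intersect; strand is ignored."""
    return (
        a.region_name == b.region_name and a.start <= b.end and b.start <= a.end
    )


def query_structural(ds: Dataset, sl: Slice) -> list[StructuralVariation]:
    """Structural variants whose outer bounds overlap the slice."""
    if sl.region_name not in ds.reference:
        raise KeyError(f"unknown region {sl.region_name!r}")
    return [
        sv
        for sv in ds.structural_variations
        if sv.region_name == sl.region_name
        and sv.outer_start <= sl.end
        and sl.start <= sv.outer_end
    ]


def query_phenotype(ds: Dataset, text: str) -> list[VariationAnnotation]:
    """Case-insensitive substring search over phenotype descriptions."""
    if not text:
        raise ValueError("phenotype query string must be non-empty")
    needle = text.lower()
    return [a for a in ds.annotations if needle in a.phenotype_description.lower()]
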