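"""Dataset persistence: a directory of tab-separated tables.

One file per schema table (header row + data rows), a FASTA file for the
reference, a binary sidecar holding the concatenated genotype blobs
(referenced by offset + length from the genotype row table), and a JSON
manifest recording the format version.  The layout is deliberately
inspectable and diff-able; the only binary artefact is the blob sidecar,
whose contents round-trip bit-for-bit.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Dataset,
    FailedReason,
    FlankRecord,
    GenotypeRow,
    Individual,
    MultiBpGenotype,
    PopulationFrequency,
    ReadCoverage,
    StructuralVariation,
    TranscriptModel,
    Variation,
    VariationAnnotation,
    VariationFeature,
)

__all__ = ["save_dataset", "load_dataset", "DatasetLoadError", "FORMAT_VERSION"]

FORMAT_VERSION = 1
_NULL = "\\N"  # sentinel for absent optional fields


class DatasetLoadError(RuntimeError):
    """The on-disk store is corrupt, incomplete, or of an unsupported version."""


def _opt(v) -> str:
    return _NULL if v is None else str(v)


def _unopt(s: str) -> Optional[str]:
    return None if s == _NULL else s


def _write_table(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def _read_table(path: Path, expected_header: list[str]) -> list[list[str]]:
    if not path.exists():
        raise DatasetLoadError(f"missing table file {path.name}")
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        try:
            header = next(r)
        except StopIteration:
            raise DatasetLoadError(f"{path.name} is empty") from None
        if header != expected_header:
            raise DatasetLoadError(
                f"{path.name}: unexpected header {header!r}"
            )
        rows = list(r)
    for row in rows:
        if len(row) != len(expected_header):
            raise DatasetLoadError(f"{path.name}: ragged row {row!r}")
    return rows


def _flank_fields(fr: Optional[FlankRecord]) -> list[str]:
    if fr is None:
        return [_NULL] * 5
    if fr.raw_seq is not None:
        return [fr.raw_seq, _NULL, _NULL, _NULL, _NULL]
    region, s, e, strand = fr.coord_ref
    return [_NULL, region, str(s), str(e), str(strand)]


def _flank_from_fields(fields: list[str]) -> Optional[FlankRecord]:
    raw, region, s, e, strand = fields
    if raw != _NULL:
        return FlankRecord(raw_seq=raw)
    if region == _NULL:
        return None
    return FlankRecord(coord_ref=(region, int(s), int(e), int(strand)))


_VARIATION_HEADER = (
    ["name", "source", "alleles", "ancestral_allele", "whitelisted", "failed_reason"]
    + [f"flank_up_{c}" for c in ("raw", "region", "start", "end", "strand")]
    + [f"flank_down_{c}" for c in ("raw", "region", "start", "end", "strand")]
)


def save_dataset(ds: Dataset, path) -> None:
    """Write a dataset to a directory (created if needed)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in ds.reference.items()
    ]
    SeqIO.write(records, root / "reference.fa", "fasta")

    _write_table(
        root / "variations.tsv",
        _VARIATION_HEADER,
        [
            [
                v.name,
                v.source,
                ",".join(v.alleles),
                _opt(v.ancestral_allele),
                "1" if v.whitelisted else "0",
                _opt(v.failed_reason.value if v.failed_reason else None),
            ]
            + _flank_fields(v.flank_up)
            + _flank_fields(v.flank_down)
            for v in ds.variations.values()
        ],
    )
    _write_table(
        root / "variation_features.tsv",
        ["variation_name", "region_name", "start", "end", "strand", "allele_string", "map_weight"],
        [
            [f.variation_name, f.region_name, str(f.start), str(f.end), str(f.strand), f.allele_string, str(f.map_weight)]
            for f in ds.variation_features
        ],
    )

    blob_rows = []
    with open(root / "genotype_blobs.bin", "wb") as bh:
        offset = 0
        for r in ds.genotype_rows:
            bh.write(r.blob)
            blob_rows.append(
                [r.individual_name, r.region_name, str(r.window_index), str(r.start), str(offset), str(len(r.blob))]
            )
            offset += len(r.blob)
    _write_table(
        root / "genotype_rows.tsv",
        ["individual_name", "region_name", "window_index", "start", "offset", "length"],
        blob_rows,
    )

    _write_table(
        root / "multi_bp_genotypes.tsv",
        ["individual_name", "region_name", "position", "allele1", "allele2", "variation_name"],
        [
            [g.individual_name, g.region_name, str(g.position), g.allele1, g.allele2, _opt(g.variation_name)]
            for g in ds.multi_bp_genotypes
        ],
    )
    _write_table(
        root / "coverage.tsv",
        ["individual_name", "region_name", "start", "end", "level"],
        [[c.individual_name, c.region_name, str(c.start), str(c.end), str(c.level)] for c in ds.coverage],
    )
    _write_table(
        root / "structural_variations.tsv",
        ["name", "region_name", "outer_start", "inner_start", "inner_end", "outer_end", "sv_class"],
        [
            [s.name, s.region_name, str(s.outer_start), str(s.inner_start), str(s.inner_end), str(s.outer_end), s.sv_class]
            for s in ds.structural_variations
        ],
    )
    _write_table(
        root / "frequencies.tsv",
        ["population", "variation_name", "kind", "state", "frequency", "sample_count"],
        [
            [f.population, f.variation_name, f.kind, f.state, repr(f.frequency), _opt(f.sample_count)]
            for f in ds.frequencies
        ],
    )
    _write_table(
        root / "annotations.tsv",
        ["variation_name", "phenotype_description", "risk_allele", "p_value", "study_source"],
        [
            [a.variation_name, a.phenotype_description, _opt(a.risk_allele), _NULL if a.p_value is None else repr(a.p_value), a.study_source]
            for a in ds.annotations
        ],
    )
    _write_table(
        root / "individuals.tsv",
        ["name", "population_names"],
        [[i.name, ",".join(i.population_names)] for i in ds.individuals.values()],
    )
    _write_table(
        root / "transcripts.tsv",
        ["name", "region_name", "strand", "exons", "cds_start", "cds_end", "biotype"],
        [
            [
                t.name,
                t.region_name,
                str(t.strand),
                ";".join(f"{s}-{e}" for s, e in t.exons),
                _opt(t.cds_start),
                _opt(t.cds_end),
                t.biotype,
            ]
            for t in ds.transcripts
        ],
    )
    _write_table(
        root / "variant_positions.tsv",
        ["variation_name", "region_name", "position"],
        [[name, region, str(pos)] for name, (region, pos) in ds.variant_positions.items()],
    )

    with open(root / "manifest.json", "w") as fh:
        json.dump({"format": "varkit-dataset", "version": FORMAT_VERSION}, fh)


def load_dataset(path) -> Dataset:
    """Read a dataset directory written by :func:`save_dataset`."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise DatasetLoadError(f"{root}: not a dataset directory (no manifest)")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise DatasetLoadError(f"corrupt manifest: {exc}") from exc
    if manifest.get("format") != "varkit-dataset":
        raise DatasetLoadError("manifest does not describe a varkit dataset")
    if manifest.get("version") != FORMAT_VERSION:
        raise DatasetLoadError(
            f"unsupported store version {manifest.get('version')!r} "
            f"(this build reads version {FORMAT_VERSION})"
        )

    try:
        ds = Dataset()
        for rec in SeqIO.parse(root / "reference.fa", "fasta"):
            ds.reference[rec.id] = str(rec.seq)

        for row in _read_table(root / "variations.tsv", _VARIATION_HEADER):
            name, source, alleles, ancestral, wl, failed = row[:6]
            v = Variation(
                name=name,
                source=source,
                alleles=[a for a in alleles.split(",") if a] if alleles else [],
                ancestral_allele=_unopt(ancestral),
                whitelisted=wl == "1",
                failed_reason=None if failed == _NULL else FailedReason(failed),
                flank_up=_flank_from_fields(row[6:11]),
                flank_down=_flank_from_fields(row[11:16]),
            )
            ds.variations[v.name] = v

        for row in _read_table(
            root / "variation_features.tsv",
            ["variation_name", "region_name", "start", "end", "strand", "allele_string", "map_weight"],
        ):
            ds.variation_features.append(
                VariationFeature(row[0], row[1], int(row[2]), int(row[3]), int(row[4]), row[5], int(row[6]))
            )

        blob_path = root / "genotype_blobs.bin"
        blobs = blob_path.read_bytes() if blob_path.exists() else b""
        for row in _read_table(
            root / "genotype_rows.tsv",
            ["individual_name", "region_name", "window_index", "start", "offset", "length"],
        ):
            offset, length = int(row[4]), int(row[5])
            if offset + length > len(blobs):
                raise DatasetLoadError("genotype blob sidecar is truncated")
            ds.genotype_rows.append(
                GenotypeRow(row[0], row[1], int(row[2]), int(row[3]), blobs[offset : offset + length])
            )

        for row in _read_table(
            root / "multi_bp_genotypes.tsv",
            ["individual_name", "region_name", "position", "allele1", "allele2", "variation_name"],
        ):
            ds.multi_bp_genotypes.append(
                MultiBpGenotype(row[0], row[1], int(row[2]), row[3], row[4], _unopt(row[5]))
            )
        for row in _read_table(
            root / "coverage.tsv",
            ["individual_name", "region_name", "start", "end", "level"],
        ):
            ds.coverage.append(ReadCoverage(row[0], row[1], int(row[2]), int(row[3]), int(row[4])))
        for row in _read_table(
            root / "structural_variations.tsv",
            ["name", "region_name", "outer_start", "inner_start", "inner_end", "outer_end", "sv_class"],
        ):
            ds.structural_variations.append(
                StructuralVariation(row[0], row[1], int(row[2]), int(row[3]), int(row[4]), int(row[5]), row[6])
            )
        for row in _read_table(
            root / "frequencies.tsv",
            ["population", "variation_name", "kind", "state", "frequency", "sample_count"],
        ):
            ds.frequencies.append(
                PopulationFrequency(
                    row[0], row[1], row[2], row[3], float(row[4]),
                    None if row[5] == _NULL else int(row[5]),
                )
            )
        for row in _read_table(
            root / "annotations.tsv",
            ["variation_name", "phenotype_description", "risk_allele", "p_value", "study_source"],
        ):
            ds.annotations.append(
                VariationAnnotation(
                    row[0], row[1], _unopt(row[2]),
                    None if row[3] == _NULL else float(row[3]), row[4],
                )
            )
        for row in _read_table(root / "individuals.tsv", ["name", "population_names"]):
            ds.individuals[row[0]] = Individual(
                row[0], [p for p in row[1].split(",") if p]
            )
        for row in _read_table(
            root / "transcripts.tsv",
            ["name", "region_name", "strand", "exons", "cds_start", "cds_end", "biotype"],
        ):
            exons = [
                (int(a), int(b))
                for a, b in (pair.split("-") for pair in row[3].split(";") if pair)
            ]
            ds.transcripts.append(
                TranscriptModel(
                    row[0], row[1], int(row[2]), exons,
                    None if row[4] == _NULL else int(row[4]),
                    None if row[5] == _NULL else int(row[5]),
                    row[6],
                )
            )
        for row in _read_table(
            root / "variant_positions.tsv", ["variation_name", "region_name", "position"]
        ):
            ds.variant_positions[row[0]] = (row[1], int(row[2]))
        return ds
    except DatasetLoadError:
        raise
    except Exception as exc:  # corrupt rows, bad ints, invariant violations
        raise DatasetLoadError(f"corrupt dataset store at {root}: {exc}") from exc
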