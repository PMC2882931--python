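"""Readers and writers for the interchange formats.

FASTA references, GFF3 transcript models, VCF variants/genotypes and BED
regulatory regions.  VCF is the import/export interchange: single-base
unphased genotypes go to the compressed store, everything else to the
multi-base-pair genotype table.  Phase in the input ("|") is accepted but
not preserved — the store, like the LD engine, is unphased.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codec import CodecConfig, query_genotypes, store_genotypes
from .model import (
    Dataset,
    FlankRecord,
    Genotype,
    Individual,
    MultiBpGenotype,
    Slice,
    TranscriptModel,
    Variation,
    VariationFeature,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_transcripts",
    "read_bed",
    "import_vcf",
    "export_vcf",
]

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
DEFAULT_IMPORT_FLANK = 20


def read_fasta(path, keep_softmask: bool = False) -> dict[str, str]:
    """Read a nucleotide FASTA into a region -> sequence mapping.

    Sequences are uppercased unless ``keep_softmask``; duplicate record
    names and non-nucleotide characters are rejected.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq)
        bad = set(seq.upper()) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )
        out[rec.id] = seq if keep_softmask else seq.upper()
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _precheck_gff(path) -> None:
    """Cheap structural validation so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns"
                )


def read_transcripts(path) -> list[TranscriptModel]:
    """Assemble transcript models from a GFF3 (or GTF) subset.

    Recognises mRNA/transcript features with exon and CDS children.
    Transcripts without exons, and exons without a resolvable parent, are
    skipped with a logged warning rather than failing the whole file.
    """
    _precheck_gff(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_parents = {
        f.id for f in db.all_features() if f.featuretype in ("mRNA", "transcript")
    }
    for exon in db.features_of_type(("exon", "CDS")):
        parents = exon.attributes.get("Parent", [])
        if not parents or not any(p in known_parents for p in parents):
            log.warning(
                "%s feature at %s:%d-%d has no transcript parent; skipped",
                exon.featuretype, exon.seqid, exon.start, exon.end,
            )

    out: list[TranscriptModel] = []
    for tf in db.features_of_type(("mRNA", "transcript")):
        exons = sorted(
            (e.start, e.end) for e in db.children(tf, featuretype="exon")
        )
        if not exons:
            log.warning("transcript %s has no exons; skipped", tf.id)
            continue
        cds = [(c.start, c.end) for c in db.children(tf, featuretype="CDS")]
        strand = 1 if tf.strand != "-" else -1
        biotype = tf.attributes.get("biotype", ["protein_coding" if cds else "non_coding"])[0]
        try:
            out.append(
                TranscriptModel(
                    name=tf.id,
                    region_name=tf.seqid,
                    strand=strand,
                    exons=exons if strand == 1 else exons[::-1],
                    cds_start=min(s for s, _ in cds) if cds else None,
                    cds_end=max(e for _, e in cds) if cds else None,
                    biotype=biotype,
                )
            )
        except ValueError as exc:
            log.warning("malformed transcript %s skipped: %s", tf.id, exc)
    return out


def read_bed(path) -> list[Slice]:
    """Read BED intervals (0-based half-open on disk) as 1-based slices."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            out.append(Slice(fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


def import_vcf(
    path,
    ds: Dataset,
    source: str = "vcf",
    flank_len: int = DEFAULT_IMPORT_FLANK,
    cfg: CodecConfig = CodecConfig(),
) -> dict[str, int]:
    """Import variants and GT genotypes from a VCF 4.x file.

    REF/ALT strings become allele strings verbatim (reference allele
    first).  Single-base diploid genotypes enter the compressed store;
    records with any multi-base allele go to the multi-bp genotype table.
    Flanks are recorded as reference coordinate pointers around POS.
    Returns import counts.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for s in samples:
        ds.add_individual(Individual(s))

    counts = {"variants": 0, "snp_genotypes": 0, "multibp_genotypes": 0,
              "individuals": len(samples)}
    pending: list[Genotype] = []
    for rec in vf.fetch() if vf.index is not None else vf:
        chrom = rec.chrom
        if chrom not in ds.reference:
            raise KeyError(f"VCF record references unknown region {chrom!r}")
        ref = rec.ref.upper()
        alts = [a.upper() for a in (rec.alts or ())]
        name = rec.id or f"{chrom}_{rec.pos}_{ref}"
        alleles = [ref] + alts
        is_snv = all(len(a) == 1 for a in alleles)

        pos = rec.pos
        up_s, up_e = max(1, pos - flank_len), pos - 1
        dn_s = pos + len(ref)
        dn_e = min(len(ds.reference[chrom]), dn_s + flank_len - 1)
        v = Variation(
            name=name,
            source=source,
            alleles=alleles,
            flank_up=FlankRecord(coord_ref=(chrom, up_s, up_e, 1)) if up_e >= up_s else None,
            flank_down=FlankRecord(coord_ref=(chrom, dn_s, dn_e, 1)) if dn_e >= dn_s else None,
        )
        ds.add_variation(v)
        ds.variation_features.append(
            VariationFeature(
                variation_name=name,
                region_name=chrom,
                start=pos,
                end=pos + len(ref) - 1,
                strand=1,
                allele_string="/".join(alleles),
                map_weight=1,
            )
        )
        ds.variant_positions[name] = (chrom, pos)
        counts["variants"] += 1

        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                continue
            if len(gt) != 2:
                raise ValueError(
                    f"non-diploid genotype for sample {s!r} at {chrom}:{pos}"
                )
            if any(a is None for a in gt):
                continue
            a1, a2 = alleles[gt[0]], alleles[gt[1]]
            if is_snv:
                pending.append(Genotype(s, chrom, pos, a1, a2))
                counts["snp_genotypes"] += 1
            else:
                ds.multi_bp_genotypes.append(
                    MultiBpGenotype(s, chrom, pos, a1, a2, variation_name=name)
                )
                counts["multibp_genotypes"] += 1
    if pending:
        store_genotypes(ds, pending, cfg)
    return counts


def export_vcf(
    ds: Dataset, sl: Optional[Slice], path, cfg: CodecConfig = CodecConfig()
) -> int:
    """Write variants and genotypes (optionally restricted to a slice) as VCF.

    Genotypes are emitted unphased ("/") regardless of how they were
    imported.  Returns the number of records written.
    """
    individuals = sorted(ds.individuals)
    lines = ["##fileformat=VCFv4.2"]
    for region, seq in ds.reference.items():
        lines.append(f"##contig=<ID={region},length={len(seq)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
    lines.append("\t".join(header[:-1] + ["INFO", "FORMAT"] + individuals))

    records = []
    for name, (region, pos) in ds.variant_positions.items():
        v = ds.variations.get(name)
        if v is None or v.failed_reason is not None or not v.alleles:
            continue
        if sl is not None and not (
            region == sl.region_name and sl.start <= pos <= sl.end
        ):
            continue
        records.append((region, pos, v))
    records.sort(key=lambda r: (r[0], r[1]))

    n = 0
    for region, pos, v in records:
        ref = v.alleles[0]
        alts = v.alleles[1:]
        allele_index = {a: i for i, a in enumerate(v.alleles)}
        is_snv = all(len(a) == 1 for a in v.alleles)
        gts = {}
        if is_snv:
            here = Slice(region, pos, pos)
            for g in query_genotypes(ds, here, cfg=cfg):
                gts[g.individual_name] = (g.allele1, g.allele2)
        else:
            for g in ds.multi_bp_genotypes:
                if g.variation_name == v.name or (
                    g.variation_name is None
                    and g.region_name == region
                    and g.position == pos
                ):
                    gts[g.individual_name] = (g.allele1, g.allele2)
        cols = [
            region, str(pos), v.name, ref,
            ",".join(alts) if alts else ".", ".", ".", ".", "GT",
        ]
        for ind in individuals:
            pair = gts.get(ind)
            if pair is None or pair[0] not in allele_index or pair[1] not in allele_index:
                cols.append("./.")
            else:
                cols.append(f"{allele_index[pair[0]]}/{allele_index[pair[1]]}")
        lines.append("\t".join(cols))
        n += 1

    Path(path).write_text("\n".join(lines) + "\n")
    return n
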