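"""Deterministic generators of toy genomes, variants, transcripts and
population genotypes.

Everything downstream is exercised against data built here: uniform
random genomes, variants planted as flank+allele+flank composites at a
known number of copies (the substrate for mapping QC), random coding
transcripts for the consequence rules, and two-locus genotype samples
drawn by random union of gametes from stated haplotype frequencies — the
exact population model the EM likelihood assumes, which makes parameter
recovery a fair test.  All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio.Seq import reverse_complement

from .model import (
    Dataset,
    FlankRecord,
    Genotype,
    Individual,
    TranscriptModel,
    Variation,
)

__all__ = [
    "SimSpec",
    "make_genome",
    "plant_variant",
    "variation_from_truth",
    "simulate_genotypes",
    "true_freq_for_labels",
    "random_coding_transcript",
    "build_fixture_dataset",
    "write_gff3",
    "write_fixture_bundle",
]

_BASES = np.array(list("ACGT"))
HAPLOTYPES = (("A", "B"), ("A", "b"), ("a", "B"), ("a", "b"))


@dataclass
class SimSpec:
    """Specification of a simulated study.

    ``haplotype_freqs`` gives (p_AB, p_Ab, p_aB, p_ab) for one locus pair;
    ``loci`` are (position, (allele_A, allele_a)) for locus 1 and 2;
    ``plantings`` are (flank_len, copies) variant-planting requests.
    """

    seed: int = 0
    genome_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 50_000})
    n_individuals: int = 100
    loci: list[tuple[int, tuple[str, str]]] = field(
        default_factory=lambda: [(1_000, ("A", "G")), (2_000, ("C", "T"))]
    )
    haplotype_freqs: tuple[float, float, float, float] = (0.4, 0.1, 0.1, 0.4)
    plantings: list[tuple[int, int]] = field(default_factory=lambda: [(20, 1)])

    def __post_init__(self) -> None:
        if abs(sum(self.haplotype_freqs) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")


def _rng(seed_or_rng: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def make_genome(
    lengths: Union[int, dict[str, int]], seed: Union[int, np.random.Generator] = 0
) -> dict[str, str]:
    """Uniform-random A/C/G/T sequences, one per region; seed-reproducible."""
    rng = _rng(seed)
    if isinstance(lengths, int):
        lengths = {"chr1": lengths}
    out = {}
    for name, n in lengths.items():
        if n < 1:
            raise ValueError("genome length must be >= 1")
        out[name] = "".join(_BASES[rng.integers(0, 4, size=n)])
    return out


def plant_variant(
    genome: str,
    flank_len: int,
    k: int,
    alleles: Sequence[str] = ("A", "G"),
    seed: Union[int, np.random.Generator] = 0,
    max_tries: int = 50,
) -> tuple[str, dict]:
    """Embed k non-overlapping copies of a unique composite into a genome.

    The composite is 5'flank + reference allele + 3'flank with randomly
    drawn flanks, re-drawn until it occurs exactly k times in the modified
    genome (counting both strands) — so truth equals what a mapper must
    find.  Returns the modified genome and a truth record with the flanks,
    alleles, and the 1-based allele positions of every copy.
    """
    rng = _rng(seed)
    ref_allele = "" if alleles[0] == "-" else alleles[0]
    comp_len = 2 * flank_len + len(ref_allele)
    if k * comp_len > len(genome):
        raise ValueError(f"genome too short for {k} non-overlapping copies")

    for _ in range(max_tries):
        up = "".join(_BASES[rng.integers(0, 4, size=flank_len)])
        down = "".join(_BASES[rng.integers(0, 4, size=flank_len)])
        composite = up + ref_allele + down
        # k non-overlapping slots, left to right
        n_slots = len(genome) // comp_len
        if n_slots < k:
            raise ValueError("genome too short for requested copies")
        slot_ids = rng.choice(n_slots, size=k, replace=False)
        chars = list(genome)
        starts = []
        for sid in sorted(slot_ids):
            off = sid * comp_len
            chars[off : off + comp_len] = composite
            starts.append(off + flank_len + 1)  # 1-based allele start
        new_genome = "".join(chars)
        fwd = _count_occurrences(new_genome, composite)
        rc = reverse_complement(composite)
        rev = 0 if rc == composite else _count_occurrences(new_genome, rc)
        if fwd + rev == k:
            return new_genome, {
                "flank_up": up,
                "flank_down": down,
                "ref_allele": alleles[0],
                "alleles": list(alleles),
                "composite": composite,
                "positions": starts,
                "k": k,
            }
    raise RuntimeError("could not plant a unique composite; genome too repetitive")


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def variation_from_truth(name: str, truth: dict, source: str = "fixtures") -> Variation:
    """A mapper-ready variant (raw flanks) from a planting truth record."""
    return Variation(
        name=name,
        source=source,
        alleles=list(truth["alleles"]),
        flank_up=FlankRecord(raw_seq=truth["flank_up"]),
        flank_down=FlankRecord(raw_seq=truth["flank_down"]),
    )


def simulate_genotypes(
    freqs: Sequence[float],
    n_individuals: int,
    seed: Union[int, np.random.Generator] = 0,
    region: str = "chr1",
    positions: tuple[int, int] = (1_000, 2_000),
    allele_pairs: tuple[tuple[str, str], tuple[str, str]] = (("A", "G"), ("C", "T")),
) -> tuple[list[Genotype], list[Genotype], dict]:
    """Unphased two-locus genotypes by random union of gametes.

    Each individual receives two haplotypes drawn i.i.d. from the four
    classes (AB, Ab, aB, ab) at the stated frequencies; the first allele of
    each pair plays A (resp. B).  Returns genotype lists per locus plus a
    truth record holding the input frequencies and the realised haplotype
    draw counts.
    """
    if len(freqs) != 4 or abs(sum(freqs) - 1.0) > 1e-9:
        raise ValueError("need four haplotype frequencies summing to 1")
    rng = _rng(seed)
    (a_hi, a_lo), (b_hi, b_lo) = allele_pairs
    draws = rng.choice(4, size=(n_individuals, 2), p=np.asarray(freqs, dtype=float))
    gts1: list[Genotype] = []
    gts2: list[Genotype] = []
    for i in range(n_individuals):
        h1, h2 = HAPLOTYPES[draws[i, 0]], HAPLOTYPES[draws[i, 1]]
        name = f"ind{i:04d}"
        a1 = a_hi if h1[0] == "A" else a_lo
        a2 = a_hi if h2[0] == "A" else a_lo
        b1 = b_hi if h1[1] == "B" else b_lo
        b2 = b_hi if h2[1] == "B" else b_lo
        gts1.append(Genotype(name, region, positions[0], a1, a2))
        gts2.append(Genotype(name, region, positions[1], b1, b2))
    counts = np.bincount(draws.ravel(), minlength=4)
    truth = {
        "freqs": tuple(float(f) for f in freqs),
        "draw_counts": counts.tolist(),
        "n_individuals": n_individuals,
        "allele_pairs": allele_pairs,
    }
    return gts1, gts2, truth


def true_freq_for_labels(
    truth: dict, a_label: str, b_label: str
) -> tuple[float, float]:
    """(p_AB, p_A-ish marginals aside) the true haplotype frequency for the
    label pair a table assigned, plus the true p_A for that label.

    The two-locus counter labels A/B by first-seen allele, which may be
    either member of each pair; this maps the stated truth onto those
    labels so estimates and truth are comparable.
    """
    p_AB, p_Ab, p_aB, p_ab = truth["freqs"]
    (a_hi, _a_lo), (b_hi, _b_lo) = truth["allele_pairs"]
    a_is_A = a_label == a_hi
    b_is_B = b_label == b_hi
    if a_is_A and b_is_B:
        return p_AB, p_AB + p_Ab
    if a_is_A and not b_is_B:
        return p_Ab, p_AB + p_Ab
    if not a_is_A and b_is_B:
        return p_aB, p_aB + p_ab
    return p_ab, p_aB + p_ab


def random_coding_transcript(
    region_name: str,
    genome_len: int,
    seed: Union[int, np.random.Generator] = 0,
    strand: Optional[int] = None,
    name: str = "tx1",
) -> TranscriptModel:
    """A random multi-exon protein-coding transcript inside a toy genome.

    Exon and intron sizes are drawn so the CDS length is a multiple of 3;
    the CDS starts/ends inside the terminal exons leaving UTR room.
    """
    rng = _rng(seed)
    if strand is None:
        strand = int(rng.choice([1, -1]))
    n_exons = int(rng.integers(1, 4))
    exon_lens = [int(rng.integers(30, 90)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(20, 60)) for _ in range(n_exons - 1)]
    total = sum(exon_lens) + sum(intron_lens)
    if total + 20 > genome_len:
        raise ValueError("genome too short for a random transcript")
    t_start = int(rng.integers(10, genome_len - total - 10))
    exons = []
    pos = t_start
    for i, L in enumerate(exon_lens):
        exons.append((pos, pos + L - 1))
        pos += L
        if i < n_exons - 1:
            pos += intron_lens[i]
    # UTRs: trim a few bases off each end of the exon union for the CDS
    utr5 = int(rng.integers(3, 12))
    utr3 = int(rng.integers(3, 12))
    exonic = [p for s, e in exons for p in range(s, e + 1)]
    cds_positions = exonic[utr5 : len(exonic) - utr3]
    excess = len(cds_positions) % 3
    if excess:
        cds_positions = cds_positions[:-excess]
    if len(cds_positions) < 6:
        raise ValueError("transcript too small for a CDS")
    cds_start, cds_end = cds_positions[0], cds_positions[-1]
    return TranscriptModel(
        name=name,
        region_name=region_name,
        strand=strand,
        exons=exons if strand == 1 else exons[::-1],
        cds_start=cds_start,
        cds_end=cds_end,
        biotype="protein_coding",
    )


def build_fixture_dataset(spec: SimSpec) -> tuple[Dataset, dict]:
    """A complete toy dataset from a SimSpec, plus its truth record.

    Builds the genome, plants the requested variants, simulates the
    two-locus population genotypes and stores everything in a Dataset;
    truth is sufficient to recompute every expected downstream answer.
    """
    from .codec import store_genotypes  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    ds = Dataset(reference=make_genome(dict(spec.genome_lengths), rng))
    truth: dict = {"seed": spec.seed, "plantings": [], "genotypes": None}

    region = next(iter(ds.reference))
    for i, (flank_len, k) in enumerate(spec.plantings):
        genome, t = plant_variant(ds.reference[region], flank_len, k, seed=rng)
        ds.reference[region] = genome
        name = f"planted{i}"
        ds.add_variation(variation_from_truth(name, t))
        truth["plantings"].append({"name": name, **t})

    if spec.loci and spec.n_individuals:
        (p1, pair1), (p2, pair2) = spec.loci[0], spec.loci[1]
        gts1, gts2, gt_truth = simulate_genotypes(
            spec.haplotype_freqs,
            spec.n_individuals,
            seed=rng,
            region=region,
            positions=(p1, p2),
            allele_pairs=(tuple(pair1), tuple(pair2)),
        )
        for g in gts1:
            ds.add_individual(Individual(g.individual_name, ["POP1"]))
        store_genotypes(ds, gts1 + gts2)
        truth["genotypes"] = gt_truth
    return ds, truth


def write_gff3(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as a minimal GFF3 (gene/mRNA/exon/CDS)."""
    lines = ["##gff-version 3"]
    for t in transcripts:
        lo, hi = t.span
        strand = "+" if t.strand == 1 else "-"
        lines.append(
            f"{t.region_name}\tvarkit\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID=gene:{t.name}"
        )
        lines.append(
            f"{t.region_name}\tvarkit\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\t"
            f"ID={t.name};Parent=gene:{t.name};biotype={t.biotype}"
        )
        for s, e in sorted(t.exons):
            lines.append(
                f"{t.region_name}\tvarkit\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={t.name}"
            )
        if t.cds_start is not None:
            for s, e in sorted(t.exons):
                cs, ce = max(s, t.cds_start), min(e, t.cds_end)
                if cs <= ce:
                    lines.append(
                        f"{t.region_name}\tvarkit\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\tParent={t.name}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_bundle(spec: SimSpec, out_dir) -> dict:
    """Materialise a fixture dataset as FASTA + GFF3 + VCF + truth JSON."""
    from .io import export_vcf, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = build_fixture_dataset(spec)
    write_fasta(ds.reference, out / "reference.fa")
    region = next(iter(ds.reference))
    try:
        tx = random_coding_transcript(
            region, len(ds.reference[region]), seed=spec.seed, name="fixture_tx1"
        )
        ds.transcripts.append(tx)
    except ValueError:
        pass  # genome too small for a transcript; bundle ships without one
    write_gff3(ds.transcripts, out / "genes.gff3")
    # register simulated loci so the VCF exporter can see them
    region = next(iter(ds.reference))
    if truth["genotypes"] is not None:
        for idx, (pos, pair) in enumerate(spec.loci[:2]):
            name = f"simlocus{idx}"
            ds.add_variation(
                Variation(name=name, source="fixtures", alleles=list(pair))
            )
            ds.variant_positions[name] = (region, pos)
    export_vcf(ds, None, out / "genotypes.vcf")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
    return truth
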