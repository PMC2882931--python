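"""Consequence rules versus a brute-force translate-and-diff oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq, reverse_complement

from varkit.consequences import (
    ConsequenceType as CT,
    VariantAllele,
    classify,
    predict_novel,
)
from varkit.fixtures import make_genome, random_coding_transcript
from varkit.model import Dataset, Slice, TranscriptModel

CODING_TYPES = {CT.STOP_GAINED, CT.STOP_LOST, CT.SYNONYMOUS_CODING, CT.NON_SYNONYMOUS_CODING}


@pytest.fixture
def stop_gain_setup():
    """30 bp chromosome; forward CDS 11-19 reading ATG TGG TAA."""
    seq = "CCCCCCCCCC" + "ATGTGGTAA" + "CCCCCCCCCCC"
    assert len(seq) == 30
    ref = {"chr1": seq}
    t = TranscriptModel("t1", "chr1", 1, [(5, 25)], cds_start=11, cds_end=19)
    return ref, t


class TestCodingSnp:
    def test_stop_gained_with_codon_and_peptide(self, stop_gain_setup):
        ref, t = stop_gain_setup
        call = classify(VariantAllele("chr1", 15, 15, "A"), t, ref)
        assert call.most_severe is CT.STOP_GAINED
        assert call.codon_change == "TGG>TAG"
        assert call.peptide_change == "W/*"
        assert call.protein_position == 2

    def test_stop_lost(self, stop_gain_setup):
        ref, t = stop_gain_setup
        # TAA -> CAA at position 17
        call = classify(VariantAllele("chr1", 17, 17, "C"), t, ref)
        assert call.most_severe is CT.STOP_LOST

    def test_synonymous(self, stop_gain_setup):
        ref, t = stop_gain_setup
        # TGG -> TGG is impossible; use third codon base wobble:
        # codon 2 TGG has no synonym, so test codon 3 TAA -> TGA (both stop)
        call = classify(VariantAllele("chr1", 18, 18, "G"), t, ref)
        assert call.most_severe is CT.SYNONYMOUS_CODING
        assert call.peptide_change == "*/*"

    def test_alt_equal_ref_rejected(self, stop_gain_setup):
        ref, t = stop_gain_setup
        with pytest.raises(ValueError):
            classify(VariantAllele("chr1", 15, 15, "G"), t, ref)

    def test_position_outside_reference_rejected(self, stop_gain_setup):
        ref, t = stop_gain_setup
        with pytest.raises(ValueError):
            classify(VariantAllele("chr1", 40, 40, "A"), t, ref)


class TestIndels:
    def test_single_base_deletion_is_frameshift(self, stop_gain_setup):
        ref, t = stop_gain_setup
        call = classify(VariantAllele("chr1", 14, 14, "-"), t, ref)
        assert CT.FRAMESHIFT_CODING in call.types

    def test_in_frame_deletion_is_non_synonymous(self, stop_gain_setup):
        ref, t = stop_gain_setup
        call = classify(VariantAllele("chr1", 12, 14, "-"), t, ref)
        assert CT.FRAMESHIFT_CODING not in call.types
        assert CT.NON_SYNONYMOUS_CODING in call.types

    def test_two_base_insertion_in_cds_is_frameshift(self, stop_gain_setup):
        ref, t = stop_gain_setup
        call = classify(VariantAllele("chr1", 15, 14, "AG"), t, ref)
        assert CT.FRAMESHIFT_CODING in call.types


class TestLocationTypes:
    @pytest.fixture
    def two_exon(self):
        genome = make_genome({"chr1": 2_000}, seed=13)
        # exon1 100-199, intron 200-399, exon2 400-499; CDS 120-479
        t = TranscriptModel(
            "t2e", "chr1", 1, [(100, 199), (400, 499)], cds_start=120, cds_end=479
        )
        return genome, t

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (200, CT.ESSENTIAL_SPLICE_SITE),  # intron base 1 (donor)
            (201, CT.ESSENTIAL_SPLICE_SITE),  # intron base 2
            (202, CT.SPLICE_SITE),  # intron base 3
            (207, CT.SPLICE_SITE),  # intron base 8
            (208, CT.INTRONIC),  # intron base 9
            (300, CT.INTRONIC),  # deep intron
            (398, CT.ESSENTIAL_SPLICE_SITE),  # acceptor side, 2 bp from end
            (392, CT.SPLICE_SITE),  # 8 bp from intron end
        ],
    )
    def test_intronic_splice_windows(self, two_exon, pos, expected):
        genome, t = two_exon
        alt = "A" if genome["chr1"][pos - 1] != "A" else "C"
        call = classify(VariantAllele("chr1", pos, pos, alt), t, genome)
        assert call.most_severe is expected

    def test_exonic_junction_base_is_splice_and_coding(self, two_exon):
        genome, t = two_exon
        pos = 199  # last exon base before the intron, inside CDS
        alt = "A" if genome["chr1"][pos - 1] != "A" else "C"
        call = classify(VariantAllele("chr1", pos, pos, alt), t, genome)
        assert CT.SPLICE_SITE in call.types
        assert CODING_TYPES & set(call.types)

    @pytest.mark.parametrize("pos,expected", [(110, CT.FIVE_PRIME_UTR), (490, CT.THREE_PRIME_UTR)])
    def test_utr_by_orientation_forward(self, two_exon, pos, expected):
        genome, t = two_exon
        alt = "A" if genome["chr1"][pos - 1] != "A" else "C"
        call = classify(VariantAllele("chr1", pos, pos, alt), t, genome)
        assert expected in call.types

    def test_utr_flips_on_reverse_strand(self, two_exon):
        genome, _ = two_exon
        t = TranscriptModel(
            "t2r", "chr1", -1, [(400, 499), (100, 199)], cds_start=120, cds_end=479
        )
        alt = "A" if genome["chr1"][109] != "A" else "C"
        call = classify(VariantAllele("chr1", 110, 110, alt), t, genome)
        assert CT.THREE_PRIME_UTR in call.types

    @pytest.mark.parametrize(
        "pos,strand,expected",
        [
            (50, 1, CT.UPSTREAM),
            (600, 1, CT.DOWNSTREAM),
            (50, -1, CT.DOWNSTREAM),
            (600, -1, CT.UPSTREAM),
        ],
    )
    def test_upstream_downstream_by_strand(self, two_exon, pos, strand, expected):
        genome, _ = two_exon
        exons = [(100, 199), (400, 499)]
        t = TranscriptModel(
            "t", "chr1", strand,
            exons if strand == 1 else exons[::-1], cds_start=120, cds_end=479,
        )
        alt = "A" if genome["chr1"][pos - 1] != "A" else "C"
        call = classify(VariantAllele("chr1", pos, pos, alt), t, genome)
        assert call.most_severe is expected

    def test_far_variant_is_intergenic(self, two_exon):
        genome, t = two_exon
        genome = {"chr1": genome["chr1"] * 10}  # room for a 10 kb offset
        alt = "A" if genome["chr1"][10_000 - 1] != "A" else "C"
        call = classify(VariantAllele("chr1", 10_000, 10_000, alt), t, genome)
        assert call.types == (CT.INTERGENIC,)

    def test_non_coding_gene(self, two_exon):
        genome, _ = two_exon
        t = TranscriptModel("nc", "chr1", 1, [(100, 199)], biotype="non_coding")
        alt = "A" if genome["chr1"][149] != "A" else "C"
        call = classify(VariantAllele("chr1", 150, 150, alt), t, genome)
        assert CT.WITHIN_NON_CODING_GENE in call.types

    def test_regulatory_region_added(self, two_exon):
        genome, t = two_exon
        reg = [Slice("chr1", 140, 160)]
        alt = "A" if genome["chr1"][149] != "A" else "C"
        call = classify(
            VariantAllele("chr1", 150, 150, alt), t, genome, regulatory=reg
        )
        assert CT.REGULATORY_REGION in call.types


class TestPredictNovel:
    @pytest.fixture
    def ds(self):
        ds = Dataset(reference=make_genome({"chr1": 3_000}, seed=21))
        ds.transcripts = [
            TranscriptModel("tA", "chr1", 1, [(100, 399)], cds_start=150, cds_end=359),
            TranscriptModel("tB", "chr1", 1, [(200, 599)], cds_start=240, cds_end=539),
        ]
        return ds

    def test_two_overlapping_transcripts_two_calls(self, ds):
        alt = "A" if ds.reference["chr1"][299] != "A" else "C"
        calls = predict_novel(ds, "chr1", 300, alt)
        assert {c.transcript_name for c in calls} == {"tA", "tB"}
        # sorted most severe first
        ranks = [c.most_severe.rank for c in calls]
        assert ranks == sorted(ranks)

    def test_no_transcript_gives_single_intergenic_call(self, ds):
        ds.transcripts = []
        calls = predict_novel(ds, "chr1", 300, "A" if ds.reference["chr1"][299] != "A" else "C")
        assert len(calls) == 1 and calls[0].types == (CT.INTERGENIC,)

    def test_novel_matches_stored_variant_path(self, ds):
        from varkit.consequences import consequences_for_feature
        from varkit.model import VariationFeature

        pos = 250
        ref_base = ds.reference["chr1"][pos - 1]
        alt = "A" if ref_base != "A" else "C"
        feat = VariationFeature("rsX", "chr1", pos, pos, 1, f"{ref_base}/{alt}", 1)
        stored = consequences_for_feature(ds, feat)
        novel = predict_novel(ds, "chr1", pos, alt)
        assert [(c.transcript_name, c.types) for c in stored] == [
            (c.transcript_name, c.types) for c in novel
        ]


def oracle_coding_type(genome: str, t: TranscriptModel, pos: int, alt: str) -> CT:
    """Independent oracle: rebuild the mutant CDS, translate both, diff."""

    def cds_of(seq: str) -> str:
        ivals = []
        for s, e in sorted(t.exons):
            lo, hi = max(s, t.cds_start), min(e, t.cds_end)
            if lo <= hi:
                ivals.append(seq[lo - 1 : hi])
        cds = "".join(ivals)
        return reverse_complement(cds) if t.strand == -1 else cds

    mutant = genome[: pos - 1] + alt + genome[pos:]
    ref_prot = str(Seq(cds_of(genome)).translate())
    alt_prot = str(Seq(cds_of(mutant)).translate())
    if ref_prot == alt_prot:
        return CT.SYNONYMOUS_CODING
    diffs = [(a, b) for a, b in zip(ref_prot, alt_prot) if a != b]
    ref_aa, alt_aa = diffs[0]
    if alt_aa == "*":
        return CT.STOP_GAINED
    if ref_aa == "*":
        return CT.STOP_LOST
    return CT.NON_SYNONYMOUS_CODING


def test_coding_classification_matches_translate_and_diff_oracle():
    """1,000 random CDS SNPs over random transcripts on both strands."""
    rng = np.random.default_rng(99)
    checked = 0
    tx_seed = 0
    while checked < 1000:
        tx_seed += 1
        genome = make_genome({"chr1": 1_500}, seed=tx_seed)["chr1"]
        try:
            t = random_coding_transcript("chr1", 1_500, seed=tx_seed)
        except ValueError:
            continue
        cds_positions = [
            p
            for s, e in sorted(t.exons)
            for p in range(max(s, t.cds_start), min(e, t.cds_end) + 1)
        ]
        for pos in rng.choice(cds_positions, size=min(25, len(cds_positions)), replace=False):
            pos = int(pos)
            ref_base = genome[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            call = classify(VariantAllele("chr1", pos, pos, str(alt)), t, {"chr1": genome})
            got = CODING_TYPES & set(call.types)
            assert len(got) == 1
            assert got.pop() is oracle_coding_type(genome, t, pos, str(alt))
            checked += 1


def test_strand_symmetry_of_consequences():
    """Mirroring the genome and annotations preserves consequence types."""
    rng = np.random.default_rng(7)
    L = 1_500
    genome = make_genome({"chr1": L}, seed=5)["chr1"]
    t = random_coding_transcript("chr1", L, seed=5, strand=1)
    mirror_genome = reverse_complement(genome)
    m_exons = sorted(((L - e + 1, L - s + 1) for s, e in t.exons))
    mt = TranscriptModel(
        "mt", "chr1", -1, m_exons[::-1],
        cds_start=L - t.cds_end + 1, cds_end=L - t.cds_start + 1,
    )
    t_lo, t_hi = t.span
    for _ in range(150):
        pos = int(rng.integers(max(1, t_lo - 100), min(L, t_hi + 100)))
        ref_base = genome[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        call = classify(VariantAllele("chr1", pos, pos, alt), t, {"chr1": genome})
        m_pos = L - pos + 1
        m_alt = reverse_complement(alt)
        m_call = classify(
            VariantAllele("chr1", m_pos, m_pos, m_alt), mt, {"chr1": mirror_genome}
        )
        assert set(call.types) == set(m_call.types), (pos, call.types, m_call.types)


def test_every_variant_gets_a_type_and_intergenic_is_exclusive():
    rng = np.random.default_rng(17)
    genome = make_genome({"chr1": 2_000}, seed=3)
    t = random_coding_transcript("chr1", 2_000, seed=3)
    for _ in range(200):
        pos = int(rng.integers(1, 2_001))
        ref_base = genome["chr1"][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        call = classify(VariantAllele("chr1", pos, pos, alt), t, genome)
        assert len(call.types) >= 1
        if CT.INTERGENIC in call.types:
            assert call.types == (CT.INTERGENIC,)
        assert call.most_severe is call.types[0]
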