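"""EM haplotype estimation and LD statistics, checked against an
independent 1-D likelihood grid-search oracle and simulation truth."""

import numpy as np
import pytest

from varkit.codec import store_genotypes
from varkit.fixtures import simulate_genotypes, true_freq_for_labels
from varkit.ld import (
    LDUndefinedError,
    TwoLocusTable,
    count_two_locus,
    em_haplotypes,
    ld_for_table,
    ld_stats,
    pairwise_ld,
)
from varkit.model import Dataset, Genotype, Slice


def grid_mle_p_ab(t: TwoLocusTable, resolution=1e-5):
    """Oracle: maximise the two-locus likelihood over p_AB by brute grid.

    With the haplotype marginals fixed at the sample allele frequencies
    (where the full MLE is known to sit), the likelihood is a function of
    p_AB alone; scan it at the given resolution.
    """
    p_a, p_b = t.p_a, t.p_b
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.arange(lo, hi + resolution, resolution)
    p_ab_ = grid
    p_Ab = p_a - grid
    p_aB = p_b - grid
    p_ab = 1.0 - p_a - p_b + grid
    eps = 1e-300

    def hap_prob(i, j):
        # P(genotype cell i,j) under random union of gametes
        if (i, j) == (1, 1):
            return 2 * p_ab_ * p_ab + 2 * p_Ab * p_aB

        def hap(ai, bj):
            if ai == 1 and bj == 1:
                return p_ab_
            if ai == 1 and bj == 0:
                return p_Ab
            if ai == 0 and bj == 1:
                return p_aB
            return p_ab
        # decompose (i, j) into two gametes
        a_alleles = [1] * i + [0] * (2 - i)
        b_alleles = [1] * j + [0] * (2 - j)
        h1 = hap(a_alleles[0], b_alleles[0])
        h2 = hap(a_alleles[1], b_alleles[1])
        same = (a_alleles[0], b_alleles[0]) == (a_alleles[1], b_alleles[1])
        return h1 * h2 * (1 if same else 2)

    ll = np.zeros_like(grid)
    for i in range(3):
        for j in range(3):
            if t.n[i][j]:
                ll = ll + t.n[i][j] * np.log(np.maximum(hap_prob(i, j), eps))
    return float(grid[int(np.argmax(ll))])


def random_polymorphic_table(rng) -> TwoLocusTable:
    while True:
        n = rng.integers(0, 20, size=(3, 3)).tolist()
        t = TwoLocusTable(n=n)
        if t.n_total and 0.0 < t.p_a < 1.0 and 0.0 < t.p_b < 1.0:
            return t


class TestCountTwoLocus:
    def test_all_homozygous_single_cell(self):
        g1 = [Genotype(f"i{k}", "chr1", 10, "A", "A") for k in range(10)]
        g2 = [Genotype(f"i{k}", "chr1", 20, "C", "C") for k in range(10)]
        t = count_two_locus(g1, g2)
        assert t.n[2][2] == 10 and t.n_total == 10

    def test_individual_missing_one_locus_excluded(self):
        g1 = [Genotype("a", "chr1", 10, "A", "G"), Genotype("b", "chr1", 10, "A", "A")]
        g2 = [Genotype("a", "chr1", 20, "C", "C")]
        t = count_two_locus(g1, g2)
        assert t.n_total == 1

    def test_mixed_toy_set_matches_hand_tally(self):
        # six individuals, tallied by hand:
        #   i0 AA/BB -> n[2][2], i1 AB(het)/BB -> n[1][2], i2 het/het -> n[1][1]
        #   i3 aa/bb -> n[0][0], i4 AA/het -> n[2][1], i5 het/bb -> n[1][0]
        def pair(ind, pos, x, y, hi, lo):
            a1 = hi if x else lo
            a2 = hi if y else lo
            return Genotype(ind, "chr1", pos, a1, a2)

        g1 = [
            pair("i0", 10, 1, 1, "A", "G"), pair("i1", 10, 1, 0, "A", "G"),
            pair("i2", 10, 1, 0, "A", "G"), pair("i3", 10, 0, 0, "A", "G"),
            pair("i4", 10, 1, 1, "A", "G"), pair("i5", 10, 1, 0, "A", "G"),
        ]
        g2 = [
            pair("i0", 20, 1, 1, "C", "T"), pair("i1", 20, 1, 1, "C", "T"),
            pair("i2", 20, 1, 0, "C", "T"), pair("i3", 20, 0, 0, "C", "T"),
            pair("i4", 20, 1, 0, "C", "T"), pair("i5", 20, 0, 0, "C", "T"),
        ]
        t = count_two_locus(g1, g2)
        assert t.allele_a == "A" and t.allele_b == "C"
        expected = [[0] * 3 for _ in range(3)]
        expected[2][2], expected[1][2], expected[1][1] = 1, 1, 1
        expected[0][0], expected[2][1], expected[1][0] = 1, 1, 1
        assert t.n == expected

    def test_triallelic_locus_rejected(self):
        g1 = [
            Genotype("a", "chr1", 10, "A", "G"),
            Genotype("b", "chr1", 10, "C", "C"),
        ]
        g2 = [Genotype(i, "chr1", 20, "C", "T") for i in ("a", "b")]
        with pytest.raises(ValueError, match="biallelic"):
            count_two_locus(g1, g2)


class TestEM:
    def test_phase_unambiguous_counts_directly(self):
        # 50 AA/BB + 50 aa/bb: no double heterozygotes, EM = direct count
        n = [[50, 0, 0], [0, 0, 0], [0, 0, 50]]
        p_AB, p_Ab, p_aB, p_ab, iters, conv = em_haplotypes(TwoLocusTable(n=n))
        assert conv and iters <= 2
        assert p_AB == pytest.approx(0.5, abs=1e-12)
        assert p_ab == pytest.approx(0.5, abs=1e-12)
        assert p_Ab == pytest.approx(0.0, abs=1e-12)

    def test_multiplicative_independence_is_fixed_point(self):
        # HWE expected counts at p_A = p_B = 0.5, independent loci
        n = [[4, 8, 4], [8, 16, 8], [4, 8, 4]]
        p_AB, *_rest = em_haplotypes(TwoLocusTable(n=n))
        D, dp, r2 = ld_stats(p_AB, *_rest[:3])
        assert p_AB == pytest.approx(0.25, abs=1e-9)
        assert D == pytest.approx(0.0, abs=1e-9)

    def test_all_double_heterozygotes_reports_equilibrium(self):
        n = [[0, 0, 0], [0, 40, 0], [0, 0, 0]]
        p_AB, p_Ab, p_aB, p_ab, iters, conv = em_haplotypes(TwoLocusTable(n=n))
        assert conv and iters == 1  # equilibrium start is a fixed point
        assert p_AB == pytest.approx(0.25, abs=1e-12)
        D, dp, r2 = ld_stats(p_AB, p_Ab, p_aB, p_ab)
        assert D == 0.0 and dp == 0.0

    def test_monomorphic_locus_undefined(self):
        n = [[0, 0, 0], [0, 0, 0], [5, 5, 0]]  # locus 1 fixed for A
        with pytest.raises(LDUndefinedError):
            em_haplotypes(TwoLocusTable(n=n))

    def test_empty_table_errors(self):
        with pytest.raises(LDUndefinedError):
            em_haplotypes(TwoLocusTable(n=[[0] * 3] * 3))

    def test_em_matches_grid_search_oracle(self, rng):
        """Converged p_AB maximises the likelihood (100+ random tables)."""
        for _ in range(120):
            t = random_polymorphic_table(rng)
            p_AB, *_ = em_haplotypes(t)
            assert p_AB == pytest.approx(grid_mle_p_ab(t), abs=1e-3)

    def test_implied_allele_frequencies_match_sample(self, rng):
        for _ in range(50):
            t = random_polymorphic_table(rng)
            p_AB, p_Ab, p_aB, p_ab, *_ = em_haplotypes(t)
            assert p_AB + p_Ab == pytest.approx(t.p_a, abs=1e-9)
            assert p_AB + p_aB == pytest.approx(t.p_b, abs=1e-9)
            assert p_AB + p_Ab + p_aB + p_ab == pytest.approx(1.0, abs=1e-9)


class TestLDStats:
    def test_perfect_coupling(self):
        D, dp, r2 = ld_stats(0.5, 0.0, 0.0, 0.5)
        assert (D, dp, r2) == (pytest.approx(0.25), pytest.approx(1.0), pytest.approx(1.0))

    def test_equilibrium_is_zero(self):
        D, dp, r2 = ld_stats(0.25, 0.25, 0.25, 0.25)
        assert D == 0.0 and dp == 0.0 and r2 == 0.0

    def test_hand_computed_intermediate_case(self):
        # p_A = p_B = 0.5, D = 0.4 - 0.25 = 0.15, D_max = 0.25,
        # D' = 0.6, r2 = 0.15^2 / 0.5^4 = 0.36
        D, dp, r2 = ld_stats(0.4, 0.1, 0.1, 0.4)
        assert D == pytest.approx(0.15)
        assert dp == pytest.approx(0.6)
        assert r2 == pytest.approx(0.36)

    def test_bounds_hold_on_fuzzed_tables(self, rng):
        for _ in range(200):
            t = random_polymorphic_table(rng)
            res = ld_for_table(t)
            assert 0.0 <= res.r2 <= 1.0 + 1e-12
            assert 0.0 <= res.D_prime <= 1.0 + 1e-12
            if res.r2 > 1.0 - 1e-9:
                assert res.D_prime == pytest.approx(1.0, abs=1e-6)


def test_em_parameter_recovery_within_binomial_error(rng):
    """Estimates from 1,000 simulated individuals fall within 3 binomial SE
    of the true haplotype frequency in >= 95% of 200 replicates."""
    n_ind = 1000
    hits = 0
    reps = 200
    for _ in range(reps):
        f = rng.dirichlet(np.ones(4) * 5)
        f = 0.9 * f + 0.025  # keep all classes away from the boundary
        gts1, gts2, truth = simulate_genotypes(tuple(f), n_ind, seed=rng)
        t = count_two_locus(gts1, gts2)
        try:
            p_AB, *_ = em_haplotypes(t)
        except LDUndefinedError:
            continue
        p_true, _ = true_freq_for_labels(truth, t.allele_a, t.allele_b)
        se = np.sqrt(p_true * (1 - p_true) / (2 * n_ind))
        if abs(p_AB - p_true) <= 3 * se:
            hits += 1
    assert hits / reps >= 0.95


def test_degenerate_support_gives_perfect_d_prime():
    gts1, gts2, truth = simulate_genotypes((0.5, 0.0, 0.0, 0.5), 100, seed=11)
    t = count_two_locus(gts1, gts2)
    res = ld_for_table(t)
    assert res.D_prime == pytest.approx(1.0)


class TestPairwise:
    @pytest.fixture
    def ds(self):
        ds = Dataset(reference={"chr1": "A" * 300_000})
        gts = []
        rng = np.random.default_rng(3)
        for pos in (1_000, 2_000, 3_000):
            for i in range(40):
                a1, a2 = rng.choice(list("AG"), size=2)
                gts.append(Genotype(f"i{i}", "chr1", pos, str(a1), str(a2)))
        store_genotypes(ds, gts)
        return ds

    def test_three_loci_three_pairs(self, ds):
        results = pairwise_ld(ds, Slice("chr1", 1, 10_000))
        assert len(results) == 3

    def test_max_distance_skips_far_pairs(self, ds):
        store_genotypes(
            ds,
            [
                Genotype(f"i{i}", "chr1", 200_000, "A" if i % 2 else "G", "G")
                for i in range(40)
            ],
        )
        results = pairwise_ld(ds, Slice("chr1", 1, 300_000), max_distance=100_000)
        pairs = {(r.locus1[1], r.locus2[1]) for r in results}
        assert (1_000, 200_000) not in pairs
        assert (1_000, 2_000) in pairs

    def test_pairwise_matches_single_pair_path(self, ds):
        results = pairwise_ld(ds, Slice("chr1", 1, 10_000))
        from varkit.codec import query_genotypes

        for r in results:
            g1 = query_genotypes(ds, Slice("chr1", r.locus1[1], r.locus1[1]))
            g2 = query_genotypes(ds, Slice("chr1", r.locus2[1], r.locus2[1]))
            direct = ld_for_table(count_two_locus(g1, g2))
            assert r.r2 == pytest.approx(direct.r2, abs=1e-12)

    def test_unknown_population_errors(self, ds):
        with pytest.raises(KeyError):
            pairwise_ld(ds, Slice("chr1", 1, 10_000), population="NOPE")
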