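"""On-the-fly pairwise linkage disequilibrium from unphased genotypes.

For two biallelic loci the unphased data reduce to a 3x3 table n[i][j] of
individuals carrying i copies of allele A at locus 1 and j copies of
allele B at locus 2.  Every cell except the double heterozygote n[1][1]
contributes unambiguous haplotype counts; the double heterozygotes are
split between the coupling (AB/ab) and repulsion (Ab/aB) phases by an EM
iteration that starts at linkage equilibrium and reweights with

    w = p_AB p_ab / (p_AB p_ab + p_Ab p_aB)

until the haplotype frequencies stabilise.  From the converged
frequencies the standard summaries follow:

    D  = p_AB - p_A p_B
    D' = |D| / D_max          (Lewontin; D_max given the allele freqs)
    r2 = D^2 / (p_A(1-p_A) p_B(1-p_B))

Computing pairs on demand replaces a precomputed all-pairs table; the
whole-slice driver :func:`pairwise_ld` is what a browser-style LD
triangle is built from.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .codec import CodecConfig, query_genotypes
from .model import Dataset, Genotype, Slice

__all__ = [
    "TwoLocusTable",
    "LDResult",
    "LDUndefinedError",
    "count_two_locus",
    "em_haplotypes",
    "ld_stats",
    "pairwise_ld",
]

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


class LDUndefinedError(ValueError):
    """LD is undefined for the given input (e.g. a monomorphic locus)."""


@dataclass
class TwoLocusTable:
    """Genotype counts for two biallelic loci.

    ``n[i][j]`` = number of individuals with i copies of allele A at locus 1
    and j copies of allele B at locus 2.  ``allele_a``/``allele_b`` record
    which observed allele was labelled A/B (first seen wins).
    """

    n: list[list[int]]
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if len(self.n) != 3 or any(len(r) != 3 for r in self.n):
            raise ValueError("two-locus table must be 3x3")
        if any(c < 0 for row in self.n for c in row):
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return sum(sum(row) for row in self.n)

    @property
    def p_a(self) -> float:
        n = self.n_total
        if n == 0:
            raise LDUndefinedError("empty two-locus table")
        return sum((i * sum(self.n[i])) for i in range(3)) / (2 * n)

    @property
    def p_b(self) -> float:
        n = self.n_total
        if n == 0:
            raise LDUndefinedError("empty two-locus table")
        return sum(j * sum(self.n[i][j] for i in range(3)) for j in range(3)) / (2 * n)


@dataclass
class LDResult:
    locus1: tuple[str, int]
    locus2: tuple[str, int]
    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    p_A: float
    p_B: float
    D: float
    D_prime: float
    r2: float
    n_individuals: int
    iterations: int
    converged: bool


def count_two_locus(
    genotypes1: Sequence[Genotype], genotypes2: Sequence[Genotype]
) -> TwoLocusTable:
    """Tabulate unphased genotypes at two loci into a 3x3 count table.

    Individuals missing either genotype are excluded pairwise.  Allele A/B
    labels are assigned to the first allele seen at each locus; more than
    two distinct alleles at a locus is an error.
    """

    def by_individual(gs: Sequence[Genotype], locus: str) -> dict[str, Genotype]:
        out: dict[str, Genotype] = {}
        for g in gs:
            if g.individual_name in out:
                raise ValueError(
                    f"individual {g.individual_name!r} has two genotypes at {locus}"
                )
            out[g.individual_name] = g
        return out

    g1 = by_individual(genotypes1, "locus 1")
    g2 = by_individual(genotypes2, "locus 2")

    def labels(gs: dict[str, Genotype], locus: str) -> list[str]:
        seen: list[str] = []
        for g in gs.values():
            for a in (g.allele1, g.allele2):
                if a not in seen:
                    seen.append(a)
        if len(seen) > 2:
            raise ValueError(f"{locus} has {len(seen)} alleles; LD requires biallelic loci")
        return seen

    seen1 = labels(g1, "locus 1")
    seen2 = labels(g2, "locus 2")
    a_label = seen1[0] if seen1 else "A"
    b_label = seen2[0] if seen2 else "B"

    n = [[0, 0, 0], [0, 0, 0], [0, 0, 0]]
    for ind in g1.keys() & g2.keys():
        i = (g1[ind].allele1 == a_label) + (g1[ind].allele2 == a_label)
        j = (g2[ind].allele1 == b_label) + (g2[ind].allele2 == b_label)
        n[i][j] += 1
    return TwoLocusTable(n=n, allele_a=a_label, allele_b=b_label)


def em_haplotypes(
    t: TwoLocusTable,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[float, float, float, float, int, bool]:
    """Maximum-likelihood two-locus haplotype frequencies via EM.

    Returns (p_AB, p_Ab, p_aB, p_ab, iterations, converged).  Requires both
    loci polymorphic in the table.  Initialised at linkage equilibrium
    p_AB = p_A p_B; consequently a table consisting purely of double
    heterozygotes — which is phase-uninformative — sits at the equilibrium
    fixed point and reports D = 0.
    """
    N = t.n_total
    if N == 0:
        raise LDUndefinedError("empty two-locus table")
    p_a, p_b = t.p_a, t.p_b
    if not (0.0 < p_a < 1.0) or not (0.0 < p_b < 1.0):
        raise LDUndefinedError("monomorphic locus: LD undefined")

    n = t.n
    # unambiguous haplotype counts from the eight phase-known cells
    k_AB = 2 * n[2][2] + n[2][1] + n[1][2]
    k_Ab = 2 * n[2][0] + n[2][1] + n[1][0]
    k_aB = 2 * n[0][2] + n[0][1] + n[1][2]
    k_ab = 2 * n[0][0] + n[0][1] + n[1][0]
    dh = n[1][1]
    total = 2 * N

    p_AB = p_a * p_b
    p_Ab = p_a * (1 - p_b)
    p_aB = (1 - p_a) * p_b
    p_ab = (1 - p_a) * (1 - p_b)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        denom = p_AB * p_ab + p_Ab * p_aB
        w = 0.5 if denom == 0.0 else p_AB * p_ab / denom
        new_AB = (k_AB + w * dh) / total
        new_Ab = (k_Ab + (1 - w) * dh) / total
        new_aB = (k_aB + (1 - w) * dh) / total
        new_ab = (k_ab + w * dh) / total
        delta = max(
            abs(new_AB - p_AB), abs(new_Ab - p_Ab),
            abs(new_aB - p_aB), abs(new_ab - p_ab),
        )
        p_AB, p_Ab, p_aB, p_ab = new_AB, new_Ab, new_aB, new_ab
        if delta < tol:
            converged = True
            break
    return p_AB, p_Ab, p_aB, p_ab, iterations, converged


def ld_stats(
    p_AB: float, p_Ab: float, p_aB: float, p_ab: float
) -> tuple[float, float, float]:
    """D, D' and r2 from four haplotype frequencies.

    D' follows the Haploview convention |D|/D_max in [0,1]; when D = 0
    (including the degenerate D_max = 0 case) D' is reported as 0.
    """
    p_A = p_AB + p_Ab
    p_B = p_AB + p_aB
    if not (0.0 < p_A < 1.0) or not (0.0 < p_B < 1.0):
        raise LDUndefinedError("monomorphic locus: LD undefined")
    D = p_AB - p_A * p_B
    if D > 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    d_prime = 0.0 if D == 0.0 or d_max == 0.0 else abs(D) / d_max
    r2 = D * D / (p_A * (1 - p_A) * p_B * (1 - p_B))
    return D, d_prime, r2


def ld_for_table(
    t: TwoLocusTable,
    locus1: tuple[str, int] = ("", 0),
    locus2: tuple[str, int] = ("", 0),
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LDResult:
    """Full EM + summary pipeline for one counted locus pair."""
    p_AB, p_Ab, p_aB, p_ab, iters, conv = em_haplotypes(t, tol, max_iter)
    D, d_prime, r2 = ld_stats(p_AB, p_Ab, p_aB, p_ab)
    return LDResult(
        locus1=locus1,
        locus2=locus2,
        p_AB=p_AB,
        p_Ab=p_Ab,
        p_aB=p_aB,
        p_ab=p_ab,
        p_A=p_AB + p_Ab,
        p_B=p_AB + p_aB,
        D=D,
        D_prime=d_prime,
        r2=r2,
        n_individuals=t.n_total,
        iterations=iters,
        converged=conv,
    )


def pairwise_ld(
    ds: Dataset,
    sl: Slice,
    population: Optional[str] = None,
    individuals: Optional[Iterable[str]] = None,
    max_distance: Optional[int] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    cfg: CodecConfig = CodecConfig(),
) -> list[LDResult]:
    """LD for every eligible locus pair inside a slice.

    Eligible loci are biallelic, polymorphic single-base positions with
    stored genotypes; pairs further apart than ``max_distance`` are skipped.
    Monomorphic or otherwise undefined pairs are skipped with a logged
    reason rather than raising.
    """
    if population is not None:
        if individuals is not None:
            raise ValueError("give either population or individuals, not both")
        members = [
            name
            for name, ind in ds.individuals.items()
            if population in ind.population_names
        ]
        if not members:
            raise KeyError(f"unknown or empty population {population!r}")
        individuals = members

    gts = query_genotypes(ds, sl, individuals=individuals, cfg=cfg)
    by_pos: dict[int, list[Genotype]] = {}
    for g in gts:
        by_pos.setdefault(g.position, []).append(g)

    results: list[LDResult] = []
    for p1, p2 in itertools.combinations(sorted(by_pos), 2):
        if max_distance is not None and p2 - p1 > max_distance:
            continue
        try:
            t = count_two_locus(by_pos[p1], by_pos[p2])
            results.append(
                ld_for_table(
                    t,
                    locus1=(sl.region_name, p1),
                    locus2=(sl.region_name, p2),
                    tol=tol,
                    max_iter=max_iter,
                )
            )
        except (LDUndefinedError, ValueError) as exc:
            log.info("skipping pair %d-%d: %s", p1, p2, exc)
    return results
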