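"""Per-pair probability model and log-likelihood ratio.

For a pair of single-base observations A and B at two linked SNPs, two
models are compared. If the reads came from two independent individuals
the observations are independent draws from the population:

    P2(A ^ B) = f(A) f(B)

If both reads came from one diploid individual, each read landed on one of
that individual's two chromosomes with equal probability, so half the time
the two observations lie on the same chromosome (probability given by the
population haplotype frequency f(AB)) and half the time on different
chromosomes (independent draws):

    P1(A ^ B) = 1/2 f(AB) + 1/2 f(A) f(B)

The evidence in one pair is the log-likelihood ratio in bits:

    gamma(A, B) = log2( P1 / P2 )

gamma is bounded below by -1 (P1 >= P2/2 always) and equals 0 exactly when
the two sites are in linkage equilibrium in the panel (f(AB) = f(A) f(B)).

Frequencies come from integer haplotype counts in the reference panel and
are divided out at the last step, so the normalisation identities
(sum of P over the four allele combinations = 1) hold to the last bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .panel import ReferencePanel


@dataclass(frozen=True)
class PairComparison:
    """One compared pair of observations at two linked panel sites."""

    site_i: int
    site_j: int
    allele_a: int
    allele_b: int
    distance_bp: int
    llr: float  # bits


def p_two_individuals(fA: float, fB: float) -> float:
    """P2: probability of the pair under the two-individuals model."""
    _check_freq(fA, "fA")
    _check_freq(fB, "fB")
    return fA * fB


def p_one_individual(fA: float, fB: float, fAB: float) -> float:
    """P1: probability of the pair under the single-diploid-individual model.

    ``fAB`` is the population frequency of the A-B haplotype; it may be 0
    (P1 stays positive through the independent-chromosomes term) but cannot
    exceed either marginal frequency.
    """
    _check_freq(fA, "fA")
    _check_freq(fB, "fB")
    if not 0.0 <= fAB <= min(fA, fB) + 1e-12:
        raise ValueError(
            f"inconsistent frequencies: fAB={fAB} > min(fA={fA}, fB={fB})"
        )
    return 0.5 * fAB + 0.5 * fA * fB


def llr_pair(
    panel: ReferencePanel,
    site_i: int,
    allele_a: int,
    site_j: int,
    allele_b: int,
) -> PairComparison:
    """gamma for one observation pair, with frequencies from ``panel``.

    Computed from integer counts: with panel size N, allele counts cA, cB
    and haplotype count cAB,

        gamma = log2( (N * cAB + cA * cB) / (2 * cA * cB) )

    which is finite for every pair the panel invariants admit.
    """
    si, sj = panel.sites[site_i], panel.sites[site_j]
    if si.chrom != sj.chrom:
        raise ValueError(
            f"pair spans chromosomes {si.chrom} and {sj.chrom}; "
            "linked pairs must share a chromosome"
        )
    if site_i == site_j:
        raise ValueError("pair requires two distinct sites")
    n = panel.n_haplotypes
    cA = panel.allele_count(site_i, allele_a)
    cB = panel.allele_count(site_j, allele_b)
    cAB = panel.haplotype_count(site_i, allele_a, site_j, allele_b)
    # single division keeps the boundary cases exact: the integer ratio is
    # exactly 0.5 when cAB = 0 (gamma = -1) and exactly 1 at equilibrium
    gamma = math.log2((n * cAB + cA * cB) / (2 * cA * cB))
    return PairComparison(
        site_i=site_i,
        site_j=site_j,
        allele_a=allele_a,
        allele_b=allele_b,
        distance_bp=abs(sj.pos - si.pos),
        llr=gamma,
    )


def enumeration_oracle_p1(
    panel: ReferencePanel,
    site_i: int,
    allele_a: int,
    site_j: int,
    allele_b: int,
) -> float:
    """Brute-force P1 by exhaustive enumeration, for verification only.

    Forms every ordered pair of panel haplotypes (h1, h2) as a candidate
    diploid (sampling with replacement), lets each of the two reads pick
    either chromosome independently, and averages the indicator that the
    reads show (allele_a, allele_b). Quadratic in panel size; intended for
    panels of at most a few dozen haplotypes.
    """
    H = panel.haplotypes
    n = H.shape[0]
    hits = 0
    for h1 in range(n):
        for h2 in range(n):
            for o1 in (h1, h2):
                for o2 in (h1, h2):
                    if H[o1, site_i] == allele_a and H[o2, site_j] == allele_b:
                        hits += 1
    return hits / (n * n * 4)


def _check_freq(f: float, name: str) -> None:
    if not 0.0 < f < 1.0:
        raise ValueError(f"{name} must be strictly between 0 and 1, got {f}")
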