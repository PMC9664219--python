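"""Transmission of nonadditive effects under a sire-with-many-dams system.

Additive effects are transmitted directly: each parent passes one allele per
locus.  Dominance and epistasis effects live on allele *combinations*, which
are reassembled every generation, so their inheritance is "indirect": a sire
cannot transmit a heterozygous genotype, but his transmitted allele changes
the genotype frequencies among his daughters.

With dams modeled as an infinite random-mating pool at allele frequencies
(p, q) for (A, a), a sire's daughters have heterozygote frequency q, 1/2 or
p for sire genotypes AA, Aa, aa.  The excess over the population
heterozygosity 2pq is the *daughter difference*, and relative to 2pq it is
the *relative daughter difference*

    lambda = (het_freq(daughters) - 2 p q) / (2 p q).

A homozygous sire for the rarer allele maximizes lambda; at p = q = 1/2 all
sire genotypes give lambda = 0, so indirect inheritance vanishes.

For an A×A effect on two unlinked loci in linkage equilibrium, a favorable
allelic combination (say AB) is transmitted *directly* when the sire can
pass an intact AB gamete with both component alleles fixed in him (AABB),
*indirectly* when he cannot pass AB but still raises its genotype frequency
in daughters through allele pairing, by *both* routes for AABb/AaBB, and
not at all for the double heterozygote AaBb, which leaves daughter gametic
and genotypic frequencies unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = [
    "DaughterArray",
    "TransmissionClass",
    "daughter_genotype_array",
    "daughter_difference",
    "relative_daughter_difference",
    "classify_two_locus_transmission",
]

SIRE_GENOTYPES = ("AA", "Aa", "aa")
TWO_LOCUS_GENOTYPES = tuple(
    g1 + g2 for g1, g2 in product(("AA", "Aa", "aa"), ("BB", "Bb", "bb"))
)
FAVORABLE_COMBOS = ("AB", "Ab", "aB", "ab")


@dataclass
class DaughterArray:
    """Genotype distribution of a sire's daughters at one biallelic locus."""

    sire_genotype: str
    p: float
    probs: dict[str, float]

    @property
    def het_freq(self) -> float:
        return self.probs["Aa"]


@dataclass
class TransmissionClass:
    """How a sire genotype transmits a favorable two-locus allele combination."""

    sire_two_locus_genotype: str
    favorable_combo: str
    transmission: str  # direct | indirect | mixed | none


def _check_p(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency p={p} must be strictly inside (0, 1)")


def _sire_allele_probs(sire: str) -> dict[str, float]:
    if sire not in SIRE_GENOTYPES:
        raise ValueError(f"sire genotype must be one of {SIRE_GENOTYPES}, got {sire!r}")
    return {"A": sire.count("A") / 2.0, "a": sire.count("a") / 2.0}


def daughter_genotype_array(sire: str, p: float) -> DaughterArray:
    """Daughter genotype distribution for a sire mated to the dam pool.

    The sire transmits A with probability 1, 1/2 or 0 for AA, Aa, aa; the
    dam allele is drawn at the population frequency p of A.  The daughter
    heterozygote frequency is therefore q, 1/2 and p for sires AA, Aa, aa.
    """
    _check_p(p)
    sp = _sire_allele_probs(sire)
    dp = {"A": p, "a": 1.0 - p}
    probs = {"AA": 0.0, "Aa": 0.0, "aa": 0.0}
    for s_allele, s_prob in sp.items():
        for d_allele, d_prob in dp.items():
            geno = "".join(sorted(s_allele + d_allele))  # 'Aa' ordering
            if geno == "aA":
                geno = "Aa"
            probs[geno] += s_prob * d_prob
    return DaughterArray(sire, p, probs)


def daughter_difference(sire: str, p: float) -> float:
    """Daughter heterozygosity minus population heterozygosity 2pq."""
    arr = daughter_genotype_array(sire, p)
    return arr.het_freq - 2.0 * p * (1.0 - p)


def relative_daughter_difference(sire: str, p: float) -> float:
    """Relative daughter difference lambda = (het_daughters - 2pq) / 2pq."""
    return daughter_difference(sire, p) / (2.0 * p * (1.0 - p))


def _sire_gamete_probs(genotype: str) -> dict[str, float]:
    """Gamete distribution of a two-locus sire genotype, loci unlinked."""
    locus1, locus2 = genotype[:2], genotype[2:]
    g1 = {al: locus1.count(al) / 2.0 for al in set(locus1)}
    g2 = {al: locus2.count(al) / 2.0 for al in set(locus2)}
    return {
        a1 + a2: p1 * p2 for a1, p1 in g1.items() for a2, p2 in g2.items() if p1 * p2 > 0
    }


def classify_two_locus_transmission(sire: str, favorable: str = "AB") -> TransmissionClass:
    """Classify a sire's transmission of a favorable allelic combination.

    direct   — every sire gamete carries the favorable combination intact
               (both favorable alleles fixed in the sire, e.g. AABB for AB);
    indirect — the sire is fixed for exactly one favorable allele but cannot
               transmit the pair intact with certainty beyond population
               expectation at the other locus; he raises the frequency of
               daughters carrying the combination only through allele
               pairing with dam gametes;
    mixed    — one favorable allele fixed, the other heterozygous (AABb,
               AaBB for AB): part of the gametes transmit the combination
               intact and the fixed allele also acts indirectly;
    none     — the double heterozygote: daughter gametic and genotypic
               frequencies are unchanged relative to the population.

    Classification rule (unlinked loci, linkage equilibrium): with the
    sire's allele dose x in {0, 1, 2} of the favorable allele at locus 1 and
    y at locus 2, the pair (x, y) maps to direct (2,2), mixed ({2,1} in
    either order), none for (1,1) and (0,0) — the double heterozygote
    guarantees neither allele, and a sire with neither favorable allele has
    no pairing route either (he is direct for the opposite combination) —
    and indirect otherwise; this reproduces the gamete enumeration over all
    nine genotypes.
    """
    if sire not in TWO_LOCUS_GENOTYPES:
        raise ValueError(f"malformed two-locus genotype {sire!r}; expected e.g. 'AaBB'")
    if favorable not in FAVORABLE_COMBOS:
        raise ValueError(f"favorable combination must be one of {FAVORABLE_COMBOS}")
    x = sire[:2].count(favorable[0])
    y = sire[2:].count(favorable[1])
    if (x, y) == (2, 2):
        cls = "direct"
    elif (x, y) in ((1, 1), (0, 0)):
        cls = "none"
    elif {x, y} == {1, 2}:
        cls = "mixed"
    else:
        cls = "indirect"
    return TransmissionClass(sire, favorable, cls)
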