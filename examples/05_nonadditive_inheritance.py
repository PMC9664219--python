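"""Transmission of nonadditive effects from a sire to his daughters.

Prints daughter genotype arrays and the relative daughter difference
(lambda) for each sire genotype at a biallelic locus, and the two-locus
transmission classification of a favorable allele combination.
"""

import epiblup as eb

p = 0.9  # frequency of allele A in the dam population
print(f"dam-population allele frequency p(A) = {p}, heterozygosity 2pq = {2*p*(1-p):.2f}")
for sire in ("AA", "Aa", "aa"):
    arr = eb.daughter_genotype_array(sire, p)
    lam = eb.relative_daughter_difference(sire, p)
    probs = ", ".join(f"{g}:{v:.2f}" for g, v in arr.probs.items())
    print(f"  sire {sire}: daughters {{{probs}}}  het={arr.het_freq:.2f}  lambda={lam:+.2f}")

print("\ntwo-locus transmission of the favorable combination AB:")
for sire in ("AABB", "AABb", "AAbb", "AaBB", "AaBb", "Aabb", "aaBB", "aaBb", "aabb"):
    cls = eb.classify_two_locus_transmission(sire, "AB")
    print(f"  sire {sire}: {cls.transmission}")

# A homozygous sire for the rare allele (aa at p=0.9) maximizes daughter
# heterozygosity (lambda = 4): dominance is inherited only indirectly,
# through allele pairing. A two-locus combination is transmitted directly
# only when both favorable alleles are fixed in the sire; the double
# heterozygote leaves daughter genotype frequencies unchanged.
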