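"""Synthetic genotypes and phenotypes with additive and epistatic architecture.

The generator emulates the statistical structure the prediction pipeline
assumes: n individuals genotyped at m biallelic SNPs spread over several
chromosomes, and phenotypic residuals

    y = mu + a + aa_intra + aa_inter + d + e

with user-specified variance fractions per component.  Genotypes come from
Hardy-Weinberg draws at frequencies sampled from ``maf_dist`` (unrelated
mode), or from a half-sib design (each sire mated to unrelated dams drawn
from the population pool), which produces the classical expected additive
relationship of 1/4 — and A×A relationship of ~1/16 — between half sibs.
In family mode parents are phased and transmit recombinant chromosome
haplotypes (crossovers at rate ``chrom_length_morgans`` per chromosome),
so linked loci co-segregate: sibs share parental chromosome segments,
which both spreads the realized relationships around their pedigree
expectations and gives intra-chromosome locus pairs the elevated,
distance-dependent co-inheritance that makes intra- vs inter-chromosome
epistasis distinguishable (and lets intra-chromosome A×A signal
masquerade as additive signal, as it does in real livestock data).
Founder haplotypes are drawn independently per locus, so the population
itself is in linkage equilibrium.

Genetic values are built from Gaussian per-locus (additive, dominance) and
per-locus-pair (A×A) effects on the centered codes, each component rescaled
empirically so its realized sample variance hits the requested fraction of
a unit phenotypic variance; the residual takes the remaining fraction.
Epistatic pairs are sampled (default 5,000) rather than exhaustive —
intra-chromosome fractions use within-chromosome pairs, inter-chromosome
fractions use cross-chromosome pairs — so the inter-only confounding
experiment (inter-chromosome signal, zero intra) is directly runnable.

Loci are in linkage equilibrium; there is no LD map, no selection, no
genotyping error, and effects are Gaussian.  Defaults are a desk-scale
stand-in for a dairy-cattle reference-population design: n = 1,000
individuals, m = 2,000 SNPs on 5 chromosomes, additive fraction 0.15 and
inter-chromosome A×A fraction 0.25 (an additive-plus-epistasis trait with
epistasis carrying more variance than the additive part).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .io import GenotypeMatrix, PhenotypeTable

__all__ = ["SimulationConfig", "simulate_genotypes", "simulate_phenotypes", "simulate_dataset"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study population.

    h2 maps component name ('additive', 'dominance', 'aa', 'aa_intra',
    'aa_inter' — 'aa' samples locus pairs anywhere, the intra/inter variants
    restrict to within- or cross-chromosome pairs)
    to its target fraction of the phenotypic variance; fractions must sum to
    less than one, the residual takes the rest.  ``family=(n_sires,
    daughters_per_sire)`` switches to the half-sib design (n is then
    n_sires * daughters_per_sire); each sire's mates default to an infinite
    unrelated dam pool, while ``dams_per_sire`` draws that many explicit
    dams per sire so families mix full sibs (shared dam) and half sibs —
    the two relatedness levels (1/2 and 1/4) that make additive and A-by-A
    variance separable in a single-generation design.  ``n_outliers``
    plants that many extreme phenotypes (8 clean-data SDs from the mean)
    for exercising the 4-SD phenotype filter.
    """

    n: int = 1000
    m: int = 2000
    n_chrom: int = 5
    maf_range: tuple[float, float] = (0.05, 0.95)
    h2: dict[str, float] = dc_field(
        default_factory=lambda: {"additive": 0.15, "aa_inter": 0.25}
    )
    family: tuple[int, int] | None = None
    dams_per_sire: int | None = None
    chrom_length_morgans: float = 1.0
    founder_ld_rho: float = 0.0
    n_pairs: int = 5000
    mu: float = 0.0
    n_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.m, self.n_chrom) < 1:
            raise ValueError("n, m and n_chrom must be at least 1")
        known = {"additive", "dominance", "aa", "aa_intra", "aa_inter"}
        bad = set(self.h2) - known
        if bad:
            raise ValueError(f"unknown variance components {sorted(bad)}")
        if any(v < 0 for v in self.h2.values()) or sum(self.h2.values()) >= 1:
            raise ValueError("variance fractions must be nonnegative and sum to < 1")
        if self.family is not None and self.family[0] * self.family[1] != self.n:
            raise ValueError("family design (n_sires * daughters_per_sire) must equal n")


def _chromosome_blocks(m: int, n_chrom: int) -> np.ndarray:
    """Contiguous chromosome labels 1..n_chrom over m SNPs."""
    sizes = np.full(n_chrom, m // n_chrom)
    sizes[: m % n_chrom] += 1
    return np.repeat(np.arange(1, n_chrom + 1), sizes)


def _founder_haplotypes(
    rng: np.random.Generator, n_hap: int, p: np.ndarray, chrom: np.ndarray, rho: float
) -> np.ndarray:
    """Founder haplotypes; adjacent within-chromosome alleles correlated.

    rho = 0 draws each locus independently (linkage equilibrium).  rho > 0
    uses an AR(1) Gaussian copula along each chromosome — latent
    u_k = rho u_{k-1} + sqrt(1-rho^2) eps, allele = [u_k < Phi^-1(p_k)] —
    which gives block-correlated haplotypes with marginal frequency p_k.
    """
    from scipy.stats import norm

    if rho == 0.0:
        return rng.binomial(1, p, size=(n_hap, len(p))).astype(np.int8)
    u = np.empty((n_hap, len(p)))
    eps = rng.standard_normal((n_hap, len(p)))
    scale = np.sqrt(1.0 - rho**2)
    prev_chrom = None
    for k in range(len(p)):
        if chrom[k] != prev_chrom:
            u[:, k] = eps[:, k]
            prev_chrom = chrom[k]
        else:
            u[:, k] = rho * u[:, k - 1] + scale * eps[:, k]
    return (u < norm.ppf(p)).astype(np.int8)


def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw a genotype panel; HWE unrelated or half-sib families."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p = rng.uniform(*cfg.maf_range, size=cfg.m)
    if cfg.family is None:
        chrom = _chromosome_blocks(cfg.m, cfg.n_chrom)
        haps = _founder_haplotypes(rng, 2 * cfg.n, p, chrom, cfg.founder_ld_rho)
        codes = haps[::2] + haps[1::2]
        sample_ids = np.array([f"ind{i:05d}" for i in range(cfg.n)])
    else:
        n_sires, per_sire = cfg.family
        chrom = _chromosome_blocks(cfg.m, cfg.n_chrom)

        def gametes(parent_haps: np.ndarray, parent_of: np.ndarray) -> np.ndarray:
            # recombinant parental haplotypes: SNPs evenly spaced on a
            # chromosome of cfg.chrom_length_morgans, crossovers between
            # adjacent SNPs w.p. length/(m_c - 1), so linked loci tend to be
            # co-transmitted and sibs share chromosome segments
            out = np.empty((len(parent_of), cfg.m), dtype=np.int8)
            G = len(parent_of)
            for c in range(1, cfg.n_chrom + 1):
                block = np.flatnonzero(chrom == c)
                mc = len(block)
                r = cfg.chrom_length_morgans / max(mc - 1, 1)
                cross = rng.random((G, mc)) < r
                cross[:, 0] = rng.integers(0, 2, size=G).astype(bool)
                path = np.cumsum(cross, axis=1) % 2  # haplotype index per SNP
                hap0 = parent_haps[parent_of, 0][:, block]
                hap1 = parent_haps[parent_of, 1][:, block]
                out[:, block] = np.where(path == 0, hap0, hap1)
            return out

        sire_haps = _founder_haplotypes(
            rng, 2 * n_sires, p, chrom, cfg.founder_ld_rho
        ).reshape(n_sires, 2, cfg.m)
        sire_of = np.repeat(np.arange(n_sires), per_sire)
        sire_gam = gametes(sire_haps, sire_of)
        if cfg.dams_per_sire is None:
            # infinite unrelated dam pool: pure half-sib families
            dam_gam = _founder_haplotypes(rng, cfg.n, p, chrom, cfg.founder_ld_rho)
        else:
            # explicit dams reused within a sire family: full + half sibs
            n_dams = n_sires * cfg.dams_per_sire
            dam_haps = _founder_haplotypes(
                rng, 2 * n_dams, p, chrom, cfg.founder_ld_rho
            ).reshape(n_dams, 2, cfg.m)
            dam_of = np.concatenate(
                [
                    s * cfg.dams_per_sire + (np.arange(per_sire) % cfg.dams_per_sire)
                    for s in range(n_sires)
                ]
            )
            dam_gam = gametes(dam_haps, dam_of)
        codes = sire_gam + dam_gam
        sample_ids = np.array(
            [f"s{s:04d}_d{d:03d}" for s in range(n_sires) for d in range(per_sire)]
        )
    return GenotypeMatrix(
        codes.astype(np.int8),
        sample_ids,
        np.array([f"snp{j:05d}" for j in range(cfg.m)]),
        _chromosome_blocks(cfg.m, cfg.n_chrom),
    )


def _scale_to(x: np.ndarray, target_var: float) -> np.ndarray:
    v = np.var(x)
    if v == 0:
        if target_var > 0:
            raise ValueError("component has zero realized variance; cannot scale")
        return x
    return x * np.sqrt(target_var / v)


def _sample_pairs(
    rng: np.random.Generator, chrom: np.ndarray, n_pairs: int, same_chrom: bool | None
) -> np.ndarray:
    """Sample distinct locus pairs: within chromosomes (True), across (False)
    or anywhere (None).  The count is capped at the number of available pairs."""
    m = len(chrom)
    if same_chrom is True and np.all(np.bincount(chrom)[1:] <= 1):
        raise ValueError("aa_intra requested but every chromosome has a single SNP")
    if same_chrom is False and len(np.unique(chrom)) < 2:
        raise ValueError("aa_inter requested but the panel has a single chromosome")
    counts = np.bincount(chrom)
    within = int(sum(c * (c - 1) // 2 for c in counts))
    total = m * (m - 1) // 2
    available = {True: within, False: total - within, None: total}[same_chrom]
    n_pairs = min(n_pairs, available)
    pairs = set()
    while len(pairs) < n_pairs:
        k = rng.integers(0, m, size=2 * (n_pairs - len(pairs)))
        l = rng.integers(0, m, size=len(k))
        ok = k != l
        if same_chrom is not None:
            ok &= (chrom[k] == chrom[l]) == same_chrom
        for a, b in zip(k[ok], l[ok]):
            pairs.add((min(a, b), max(a, b)))
            if len(pairs) == n_pairs:
                break
    return np.array(sorted(pairs))


def simulate_phenotypes(
    geno: GenotypeMatrix, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[PhenotypeTable, dict[str, np.ndarray]]:
    """Simulate phenotypes on an existing panel; returns (table, truth).

    ``truth`` maps each nonzero component ('additive', 'dominance',
    'aa_intra', 'aa_inter'), plus 'total_genetic' and 'residual', to its
    per-individual value vector, for recovery and accuracy checks.
    Phenotypic variance is 1 by construction (before any planted outliers).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n = geno.n_individuals
    p = geno.allele_freq
    Z = geno.codes - 2.0 * p
    truth: dict[str, np.ndarray] = {}

    if cfg.h2.get("additive", 0) > 0:
        g = Z @ rng.standard_normal(geno.n_snps)
        truth["additive"] = _scale_to(g, cfg.h2["additive"])
    if cfg.h2.get("dominance", 0) > 0:
        q = 1.0 - p
        W = np.where(geno.codes == 1, 2 * p * q, np.where(geno.codes == 2, -2 * p**2, -2 * q**2))
        g = W @ rng.standard_normal(geno.n_snps)
        truth["dominance"] = _scale_to(g, cfg.h2["dominance"])
    for comp, same in (("aa", None), ("aa_intra", True), ("aa_inter", False)):
        if cfg.h2.get(comp, 0) > 0:
            pairs = _sample_pairs(rng, geno.chromosome, cfg.n_pairs, same)
            g = np.zeros(n)
            beta = rng.standard_normal(len(pairs))
            for lo in range(0, len(pairs), 10_000):  # chunked: pairs can be many
                sl = slice(lo, min(lo + 10_000, len(pairs)))
                g += (Z[:, pairs[sl, 0]] * Z[:, pairs[sl, 1]]) @ beta[sl]
            truth[comp] = _scale_to(g, cfg.h2[comp])

    total_g = np.sum(list(truth.values()), axis=0) if truth else np.zeros(n)
    resid = rng.standard_normal(n) * np.sqrt(max(1.0 - sum(cfg.h2.values()), 0.0))
    truth["total_genetic"] = total_g
    truth["residual"] = resid
    y = cfg.mu + total_g + resid

    if cfg.n_outliers:
        sd = y.std()
        idx = rng.choice(n, size=cfg.n_outliers, replace=False)
        signs = rng.choice((-1.0, 1.0), size=cfg.n_outliers)
        y[idx] = y.mean() + signs * 8.0 * sd
        truth["outlier_idx"] = idx
    return PhenotypeTable(geno.sample_ids, y), truth


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, dict[str, np.ndarray]]:
    """Convenience wrapper: genotypes + phenotypes from one seeded config."""
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(cfg, rng)
    pheno, truth = simulate_phenotypes(geno, cfg, rng)
    return geno, pheno, truth
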