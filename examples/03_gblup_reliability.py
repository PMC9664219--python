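"""GBLUP prediction with per-individual reliabilities.

Holds out 20% of individuals as a validation set (phenotypes masked),
solves the additive + A-by-A mixed model on the training records, and
prints predictions and reliabilities for a few validation individuals.
"""

import numpy as np

import epiblup as eb

cfg = eb.SimulationConfig(
    n=400, m=800, n_chrom=4, h2={"additive": 0.2, "aa": 0.25},
    family=(40, 10), dams_per_sire=3, n_pairs=50_000, seed=3,
)
geno, pheno, truth = eb.simulate_dataset(cfg)
A = eb.build_additive_grm(geno).values
AA = eb.build_pairwise_epistasis_grm(gm=geno, kind="AA", method="exact").values
kernels = {"A": A, "AA": AA}

rng = np.random.default_rng(0)
train = np.ones(400, dtype=bool)
train[rng.choice(400, 80, replace=False)] = False

vc, _ = eb.fit_greml(pheno.y[train], {k: K[np.ix_(np.flatnonzero(train), np.flatnonzero(train))] for k, K in kernels.items()})
fit = eb.solve_mixed_model(pheno.y, kernels, vc, train=train, sample_ids=geno.sample_ids)
recs = eb.reliability(kernels, vc, train, sample_ids=geno.sample_ids)

val = np.flatnonzero(~train)
acc = np.corrcoef(fit.total_g[val], truth["total_genetic"][val])[0, 1]
print(f"validation accuracy corr(GBLUP total, true genetic value) = {acc:.3f}")
print("first five validation individuals:")
print(f"{'id':>12} {'ghat_A':>8} {'ghat_AA':>8} {'total':>8} {'rel_A':>6} {'rel_AA':>7} {'rel_tot':>8}")
for i in val[:5]:
    r = recs[i]
    print(f"{str(r.id):>12} {fit.gblup['A'][i]:8.3f} {fit.gblup['AA'][i]:8.3f} "
          f"{fit.total_g[i]:8.3f} {r.rel['A']:6.3f} {r.rel['AA']:7.3f} {r.rel['total']:8.3f}")

# Reliability is the squared accuracy of each genetic-value prediction;
# the A x A reliability is much smaller than the additive one because
# epistatic relationships are roughly the square of additive ones.
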