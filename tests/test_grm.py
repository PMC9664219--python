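"""Relationship-matrix builders against brute-force and model-matrix oracles."""

import itertools

import numpy as np
import pytest

from epiblup.grm import (
    build_additive_grm,
    build_dominance_grm,
    build_pairwise_epistasis_grm,
    build_third_order_grm,
    centered_additive_codes,
    dominance_codes,
    load_grm_hdf5,
    partition_intra_inter,
    read_gcta_grm,
    save_grm_hdf5,
    write_gcta_grm,
    RelationshipMatrix,
)
from epiblup.io import GenotypeMatrix
from epiblup.simulate import SimulationConfig, simulate_genotypes


def brute_force_additive(gm):
    """Element-by-element A_ij = sum_k (g_ik - 2p_k)(g_jk - 2p_k) / sum 2pq."""
    n, m = gm.codes.shape
    p = gm.codes.mean(axis=0) / 2.0
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = sum(
                (gm.codes[i, k] - 2 * p[k]) * (gm.codes[j, k] - 2 * p[k]) for k in range(m)
            )
    return A / sum(2 * pk * (1 - pk) for pk in p)


def brute_force_dominance(gm):
    n, m = gm.codes.shape
    p = gm.codes.mean(axis=0) / 2.0
    w_of = lambda g, pk: {2: -2 * pk**2, 1: 2 * pk * (1 - pk), 0: -2 * (1 - pk) ** 2}[g]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = sum(
                w_of(gm.codes[i, k], p[k]) * w_of(gm.codes[j, k], p[k])
                for k in range(m)
                if 0 < p[k] < 1
            )
    return D / sum((2 * pk * (1 - pk)) ** 2 for pk in p)


def pairwise_model_matrix_aa(gm, pair_filter=None):
    """Explicit interaction model matrix: columns z_.k * z_.l over k < l,
    normalized to mean diagonal one (the construction the exact A-by-A
    matrix must reproduce)."""
    Z = centered_additive_codes(gm)
    cols = [
        Z[:, k] * Z[:, l]
        for k, l in itertools.combinations(range(gm.n_snps), 2)
        if pair_filter is None or pair_filter(k, l)
    ]
    M = np.column_stack(cols)
    raw = M @ M.T
    return raw / np.mean(np.diag(raw))


class TestAdditive:
    def test_duplicate_rows_share_relationship(self):
        gm = GenotypeMatrix(
            np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]]),
            np.array(list("abc")),
            np.array(["s1", "s2", "s3"]),
            np.ones(3, int),
        )
        A = build_additive_grm(gm).values
        assert A[0, 1] == pytest.approx(A[0, 0], abs=1e-12)

    def test_matches_brute_force(self, random_genotypes):
        A = build_additive_grm(random_genotypes)
        np.testing.assert_allclose(A.values, brute_force_additive(random_genotypes), atol=1e-12)
        assert 0.5 < A.mean_diag() < 2.0

    def test_monomorphic_panel_rejected(self):
        gm = GenotypeMatrix(
            np.full((3, 2), 2), np.array(list("abc")), np.array(["s1", "s2"]), np.ones(2, int)
        )
        with pytest.raises(ValueError, match="monomorphic"):
            build_additive_grm(gm)

    def test_symmetry(self, random_genotypes):
        A = build_additive_grm(random_genotypes).values
        assert np.max(np.abs(A - A.T)) < 1e-10 * np.max(np.abs(A))


class TestDominance:
    def test_all_heterozygous_rank_one(self):
        # every individual het at every SNP: identical w rows -> rank-1 D
        gm = GenotypeMatrix(
            np.vstack([np.ones(4, int)] * 3 + [np.array([0, 2, 0, 2])]),
            np.array(list("abcd")),
            np.array([f"s{k}" for k in range(4)]),
            np.ones(4, int),
        )
        D = build_dominance_grm(gm).values
        assert np.linalg.matrix_rank(D[:3, :3], tol=1e-10) == 1

    def test_hand_calculation_p_half(self):
        """p = 0.5 everywhere: w is +-0.5; D on 2 individuals by hand."""
        gm = GenotypeMatrix(
            np.array([[1, 1], [2, 0], [0, 2], [1, 1]]),
            np.array(list("abcd")),
            np.array(["s1", "s2"]),
            np.ones(2, int),
        )
        D = build_dominance_grm(gm)
        # normalizer = 2 * (2*0.5*0.5)^2 = 0.5; w rows: a=(0.5,0.5), b=(-0.5,-0.5)
        assert D.normalizer == pytest.approx(0.5)
        assert D.values[0, 0] == pytest.approx((0.25 + 0.25) / 0.5)
        assert D.values[0, 1] == pytest.approx(-(0.25 + 0.25) / 0.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        gm = GenotypeMatrix(
            rng.integers(0, 3, size=(6, 10)),
            np.array([f"i{k}" for k in range(6)]),
            np.array([f"s{k}" for k in range(10)]),
            np.ones(10, int),
        )
        D = build_dominance_grm(gm)
        np.testing.assert_allclose(D.values, brute_force_dominance(gm), atol=1e-12)


class TestPairwiseEpistasis:
    def test_hadamard_square_identity(self):
        ident = RelationshipMatrix(np.eye(4), "A")
        AA = build_pairwise_epistasis_grm(A=ident, kind="AA", method="approximate")
        np.testing.assert_allclose(AA.values, np.eye(4))

    def test_squaring_rule_before_rescaling(self, random_genotypes):
        """Approximate (aa)_ij = (a_ij)^2 on the unnormalized scale: a cell
        with a_ij = 1/2 maps to 1/4."""
        A = build_additive_grm(random_genotypes)
        AA = build_pairwise_epistasis_grm(A=A, kind="AA", method="approximate")
        np.testing.assert_allclose(AA.values * AA.normalizer, A.values**2, rtol=1e-14)
        a = RelationshipMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), "A")
        aa = build_pairwise_epistasis_grm(A=a, kind="AA", method="approximate")
        assert (aa.values * aa.normalizer)[0, 1] == pytest.approx(0.25)

    def test_exact_aa_equals_model_matrix_oracle(self):
        gm = simulate_genotypes(SimulationConfig(n=5, m=4, n_chrom=2, seed=9))
        AA = build_pairwise_epistasis_grm(gm=gm, kind="AA", method="exact")
        np.testing.assert_allclose(AA.values, pairwise_model_matrix_aa(gm), atol=1e-10)

    def test_exact_ad_dd_match_model_matrix_oracle(self, random_genotypes):
        Z = centered_additive_codes(random_genotypes)
        W = dominance_codes(random_genotypes)
        m = random_genotypes.n_snps
        for kind, U, T in (("AD", Z, W), ("DD", W, W)):
            if kind == "AD":
                # ordered cross-locus pairs k != l of (additive_k, dominance_l)
                cols = [U[:, k] * T[:, l] for k in range(m) for l in range(m) if k != l]
            else:
                cols = [U[:, k] * T[:, l] for k, l in itertools.combinations(range(m), 2)]
            M = np.column_stack(cols)
            raw = M @ M.T
            oracle = raw / np.mean(np.diag(raw))
            built = build_pairwise_epistasis_grm(gm=random_genotypes, kind=kind, method="exact")
            np.testing.assert_allclose(built.values, oracle, atol=1e-10)

    def test_exact_below_approximate_unnormalized(self, random_genotypes):
        """The intra-locus term subtracted by the exact method is a sum of
        squares, so exact <= approximate elementwise before rescaling."""
        Z = centered_additive_codes(random_genotypes)
        approx_raw = (Z @ Z.T) ** 2
        exact_raw = approx_raw - (Z * Z) @ (Z * Z).T
        assert np.all(exact_raw <= approx_raw + 1e-12)

    def test_negative_entries_exact_only(self):
        """A panel with negative additive relationships: the approximate
        Hadamard square is elementwise nonnegative while the exact matrix
        can carry small negative entries."""
        gm = simulate_genotypes(SimulationConfig(n=40, m=60, n_chrom=2, seed=21))
        A = build_additive_grm(gm)
        assert (A.values < 0).any()
        approx = build_pairwise_epistasis_grm(A=A, kind="AA", method="approximate")
        exact = build_pairwise_epistasis_grm(gm=gm, kind="AA", method="exact")
        assert np.all(approx.values >= 0)
        neg = exact.values[exact.values < 0]
        assert neg.size > 0
        assert np.max(np.abs(neg)) < 0.1  # very small absolute values


class TestThirdOrder:
    def test_identity_and_cube_rule(self, random_genotypes):
        ident = RelationshipMatrix(np.eye(5), "A")
        AAA = build_third_order_grm(ident, kind="AAA")
        np.testing.assert_allclose(AAA.values, np.eye(5))
        A = build_additive_grm(random_genotypes)
        built = build_third_order_grm(A, kind="AAA")
        np.testing.assert_allclose(built.values * built.normalizer, A.values**3, rtol=1e-14)

    def test_loop_oracle_all_kinds(self, random_genotypes):
        A = build_additive_grm(random_genotypes)
        D = build_dominance_grm(random_genotypes)
        vals = {"A": A.values, "D": D.values}
        for kind in ("AAA", "AAD", "ADD", "DDD"):
            built = build_third_order_grm(A, D, kind=kind)
            n = A.n
            raw = np.array(
                [
                    [np.prod([vals[ch][i, j] for ch in kind]) for j in range(n)]
                    for i in range(n)
                ]
            )
            np.testing.assert_allclose(built.values, raw / np.mean(np.diag(raw)), atol=1e-12)


class TestIntraInterPartition:
    def test_single_chromosome_inter_is_zero(self):
        gm = simulate_genotypes(SimulationConfig(n=6, m=8, n_chrom=1, seed=2))
        for method in ("exact", "approximate"):
            intra, inter = partition_intra_inter(gm, method=method)
            np.testing.assert_allclose(inter.values, 0.0, atol=1e-12)

    def test_one_snp_per_chromosome_intra_is_zero(self):
        gm = simulate_genotypes(SimulationConfig(n=6, m=8, n_chrom=8, seed=2))
        intra, inter = partition_intra_inter(gm, method="exact")
        np.testing.assert_allclose(intra.values, 0.0, atol=1e-12)

    def test_exact_split_matches_model_matrix_oracle(self):
        gm = simulate_genotypes(SimulationConfig(n=6, m=8, n_chrom=2, seed=13))
        intra, inter = partition_intra_inter(gm, method="exact")
        total = build_pairwise_epistasis_grm(gm=gm, kind="AA", method="exact")
        chrom = gm.chromosome
        # oracle split by pair location, renormalized by the shared total scale
        Z = centered_additive_codes(gm)
        raw = {"intra": np.zeros((6, 6)), "inter": np.zeros((6, 6))}
        for k, l in itertools.combinations(range(8), 2):
            col = np.outer(Z[:, k] * Z[:, l], Z[:, k] * Z[:, l])
            raw["intra" if chrom[k] == chrom[l] else "inter"] += col
        norm = np.mean(np.diag(raw["intra"] + raw["inter"]))
        np.testing.assert_allclose(intra.values, raw["intra"] / norm, atol=1e-10)
        np.testing.assert_allclose(inter.values, raw["inter"] / norm, atol=1e-10)
        np.testing.assert_allclose(
            intra.values + inter.values, total.values, atol=1e-10
        )

    @pytest.mark.parametrize("method", ["exact", "approximate"])
    def test_parts_sum_to_total(self, method):
        gm = simulate_genotypes(SimulationConfig(n=12, m=30, n_chrom=3, seed=17))
        intra, inter = partition_intra_inter(gm, method=method)
        if method == "exact":
            total = build_pairwise_epistasis_grm(gm=gm, kind="AA", method="exact")
        else:
            A = build_additive_grm(gm)
            total = build_pairwise_epistasis_grm(A=A, kind="AA", method="approximate")
        np.testing.assert_allclose(
            intra.values + inter.values, total.values, atol=1e-10
        )
        assert intra.normalizer == inter.normalizer


class TestSerialization:
    def test_hdf5_round_trip(self, tmp_path, random_genotypes):
        A = build_additive_grm(random_genotypes)
        save_grm_hdf5(A, tmp_path / "a.h5")
        back = load_grm_hdf5(tmp_path / "a.h5")
        np.testing.assert_array_equal(back.values, A.values)
        assert back.kind == "A" and back.normalizer == A.normalizer
        np.testing.assert_array_equal(back.sample_ids, A.sample_ids)

    def test_gcta_round_trip(self, tmp_path, random_genotypes):
        A = build_additive_grm(random_genotypes)
        write_gcta_grm(A, tmp_path / "a", n_snps=random_genotypes.n_snps)
        back = read_gcta_grm(tmp_path / "a")
        np.testing.assert_allclose(back.values, A.values, atol=1e-6)  # float32 storage
        np.testing.assert_array_equal(back.sample_ids, A.sample_ids)
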