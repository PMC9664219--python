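"""Genomic relationship matrices: additive, dominance, epistasis.

The additive matrix follows the centered-allele-count construction
A = Z Z' / sum_k 2 p_k q_k with z_ik = g_ik - 2 p_k.  Dominance uses the
HWE-orthogonal coding w = (-2p^2, 2pq, -2q^2) for codes (2, 1, 0) with
normalizer sum_k (2 p_k q_k)^2, so the dominance component is uncorrelated
with the additive one under Hardy-Weinberg proportions.

Pairwise epistasis matrices come in two flavours:

* ``approximate`` — Hadamard products of the additive/dominance matrices,
  AA = A ∘ A, AD = A ∘ D, DD = D ∘ D.  The Hadamard square implicitly
  contains "self-interaction" of each locus with itself.
* ``exact`` — the intra-locus term is removed so only cross-locus pair
  products remain.  For A×A the unnormalized entry is
  (sum_k z_ik z_jk)^2 - sum_k (z_ik z_jk)^2, which equals (twice) the
  pairwise-interaction model matrix product with columns z_.k ∘ z_.l over
  locus pairs k < l; AD and DD subtract the analogous single sums with the
  dominance codes.  The exact matrix can carry small negative entries (it
  is no longer an elementwise square); the approximate one cannot.

Every epistasis matrix is rescaled to mean diagonal one; the applied scalar
is recorded in ``normalizer`` so the unnormalized matrix is recoverable.
Variance components absorb the scale, so estimates are invariant to this
convention, but it keeps heritabilities directly comparable across kernels.

A×A additionally partitions into intra- and inter-chromosome parts by
whether the two loci share a chromosome; the parts share one normalizer so
AA_intra + AA_inter equals AA elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "build_additive_grm",
    "build_dominance_grm",
    "build_pairwise_epistasis_grm",
    "build_third_order_grm",
    "partition_intra_inter",
    "centered_additive_codes",
    "dominance_codes",
    "save_grm_hdf5",
    "load_grm_hdf5",
    "write_gcta_grm",
    "read_gcta_grm",
]

PAIRWISE_KINDS = ("AA", "AD", "DD")
THIRD_ORDER_KINDS = ("AAA", "AAD", "ADD", "DDD")


@dataclass
class RelationshipMatrix:
    """A labeled n x n genomic relationship matrix.

    ``normalizer`` is the positive scalar the raw cross-product matrix was
    divided by; ``values * normalizer`` recovers the unnormalized matrix.
    """

    values: np.ndarray
    kind: str
    method: str = "n/a"  # exact | approximate | n/a
    normalizer: float = 1.0
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids)
            if len(self.sample_ids) != self.values.shape[0]:
                raise ValueError("sample_ids length does not match matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def mean_diag(self) -> float:
        return float(np.mean(np.diag(self.values)))


def centered_additive_codes(gm: GenotypeMatrix) -> np.ndarray:
    """Column-centered allele counts z_ik = g_ik - 2 p_k (monomorphic -> 0)."""
    return gm.codes - 2.0 * gm.allele_freq


def dominance_codes(gm: GenotypeMatrix) -> np.ndarray:
    """HWE-orthogonal dominance codes: -2p^2, 2pq, -2q^2 for codes 2, 1, 0."""
    p = gm.allele_freq
    q = 1.0 - p
    w = np.empty(gm.codes.shape, dtype=float)
    codes = gm.codes
    w[codes == 2] = (-2.0 * p**2 * np.ones_like(w))[codes == 2]
    w[codes == 1] = (2.0 * p * q * np.ones_like(w))[codes == 1]
    w[codes == 0] = (-2.0 * q**2 * np.ones_like(w))[codes == 0]
    # monomorphic SNPs carry no dominance information
    w[:, (p == 0) | (p == 1)] = 0.0
    return w


def _check_polymorphic(gm: GenotypeMatrix) -> None:
    p = gm.allele_freq
    if not np.any((p > 0) & (p < 1)):
        raise ValueError("all SNPs are monomorphic; relationship normalizer is zero")
    if gm.n_individuals < 2:
        raise ValueError("need at least two individuals")


def build_additive_grm(gm: GenotypeMatrix) -> RelationshipMatrix:
    """Additive GRM A = Z Z' / sum_k 2 p_k q_k from centered codes."""
    _check_polymorphic(gm)
    Z = centered_additive_codes(gm)
    p = gm.allele_freq
    norm = float(np.sum(2.0 * p * (1.0 - p)))
    return RelationshipMatrix(Z @ Z.T / norm, "A", "n/a", norm, gm.sample_ids)


def build_dominance_grm(gm: GenotypeMatrix) -> RelationshipMatrix:
    """Dominance GRM D = W W' / sum_k (2 p_k q_k)^2."""
    _check_polymorphic(gm)
    W = dominance_codes(gm)
    p = gm.allele_freq
    norm = float(np.sum((2.0 * p * (1.0 - p)) ** 2))
    return RelationshipMatrix(W @ W.T / norm, "D", "n/a", norm, gm.sample_ids)


def _pair_code_matrices(gm: GenotypeMatrix, kind: str) -> tuple[np.ndarray, np.ndarray]:
    if kind == "AA":
        Z = centered_additive_codes(gm)
        return Z, Z
    if kind == "AD":
        return centered_additive_codes(gm), dominance_codes(gm)
    if kind == "DD":
        W = dominance_codes(gm)
        return W, W
    raise ValueError(f"unknown pairwise kind {kind!r}")


def _normalize(raw: np.ndarray, kind: str, method: str, ids) -> RelationshipMatrix:
    norm = float(np.mean(np.diag(raw)))
    if norm <= 0:
        raise ValueError(f"{kind} matrix has nonpositive mean diagonal; degenerate panel")
    return RelationshipMatrix(raw / norm, kind, method, norm, ids)


def build_pairwise_epistasis_grm(
    A: RelationshipMatrix | None = None,
    D: RelationshipMatrix | None = None,
    gm: GenotypeMatrix | None = None,
    kind: str = "AA",
    method: str = "exact",
) -> RelationshipMatrix:
    """Pairwise epistasis relationship matrix (AA, AD or DD).

    ``method="approximate"`` forms the Hadamard product of the supplied A/D
    matrices (built from ``gm`` when not supplied).  ``method="exact"``
    requires ``gm`` and removes the intra-locus term, keeping only genuine
    cross-locus pair products.  The result is rescaled to mean diagonal one.
    """
    if kind not in PAIRWISE_KINDS:
        raise ValueError(f"kind must be one of {PAIRWISE_KINDS}")
    if method == "approximate":
        if "A" in kind and A is None:
            if gm is None:
                raise ValueError("approximate method needs A (or a GenotypeMatrix)")
            A = build_additive_grm(gm)
        if "D" in kind and D is None:
            if gm is None:
                raise ValueError("approximate method needs D (or a GenotypeMatrix)")
            D = build_dominance_grm(gm)
        first = A if kind[0] == "A" else D
        second = A if kind[1] == "A" else D
        if first.n != second.n:
            raise ValueError("mismatched sample sets between A and D")
        raw = first.values * second.values
        ids = first.sample_ids if first.sample_ids is not None else second.sample_ids
        return _normalize(raw, kind, "approximate", ids)
    if method == "exact":
        if gm is None:
            raise ValueError("exact method requires the genotype matrix")
        if A is not None and A.n != gm.n_individuals:
            raise ValueError("mismatched sample sets between A and genotypes")
        U, T = _pair_code_matrices(gm, kind)
        raw = (U @ U.T) * (T @ T.T) - (U * T) @ (U * T).T
        return _normalize(raw, kind, "exact", gm.sample_ids)
    raise ValueError(f"unknown method {method!r}")


def build_third_order_grm(
    A: RelationshipMatrix, D: RelationshipMatrix | None = None, kind: str = "AAA"
) -> RelationshipMatrix:
    """Third-order epistasis matrix by triple Hadamard products.

    Only the approximate (Hadamard) construction is provided at third
    order; the intra-locus correction is not applied (its effect on
    pairwise matrices is already at the third decimal on realistic panels).
    """
    if kind not in THIRD_ORDER_KINDS:
        raise ValueError(f"kind must be one of {THIRD_ORDER_KINDS}")
    n_d = kind.count("D")
    if n_d and D is None:
        raise ValueError(f"{kind} requires the dominance matrix")
    raw = np.ones_like(A.values)
    for ch in kind:
        raw = raw * (A.values if ch == "A" else D.values)
    if D is not None and D.n != A.n:
        raise ValueError("mismatched sample sets between A and D")
    return _normalize(raw, kind, "approximate", A.sample_ids)


def partition_intra_inter(
    gm: GenotypeMatrix, method: str = "exact"
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Split the A×A matrix into intra- and inter-chromosome parts.

    The intra part aggregates locus pairs on the same chromosome, the inter
    part the cross-chromosome pairs.  Both are divided by the mean diagonal
    of the total raw A×A matrix, so ``AA_intra + AA_inter`` equals the total
    A×A matrix (same method, same normalizer) elementwise.
    """
    Z = centered_additive_codes(gm)
    if method == "exact":
        total_raw = (Z @ Z.T) ** 2 - (Z * Z) @ (Z * Z).T
        intra_raw = np.zeros_like(total_raw)
        for c in gm.chromosomes():
            Zc = Z[:, gm.chromosome == c]
            intra_raw += (Zc @ Zc.T) ** 2 - (Zc * Zc) @ (Zc * Zc).T
    elif method == "approximate":
        p = gm.allele_freq
        norm_a = np.sum(2.0 * p * (1.0 - p))
        total_raw = ((Z @ Z.T) / norm_a) ** 2
        intra_raw = np.zeros_like(total_raw)
        for c in gm.chromosomes():
            Zc = Z[:, gm.chromosome == c]
            intra_raw += ((Zc @ Zc.T) / norm_a) ** 2
    else:
        raise ValueError(f"unknown method {method!r}")
    inter_raw = total_raw - intra_raw
    norm = float(np.mean(np.diag(total_raw)))
    if norm <= 0:
        raise ValueError("degenerate panel: total A×A mean diagonal is nonpositive")
    intra = RelationshipMatrix(intra_raw / norm, "AA_intra", method, norm, gm.sample_ids)
    inter = RelationshipMatrix(inter_raw / norm, "AA_inter", method, norm, gm.sample_ids)
    return intra, inter


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_grm_hdf5(rm: RelationshipMatrix, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=rm.values)
        f.attrs["kind"] = rm.kind
        f.attrs["method"] = rm.method
        f.attrs["normalizer"] = rm.normalizer
        if rm.sample_ids is not None:
            f.create_dataset("sample_ids", data=np.asarray(rm.sample_ids, dtype="S"))


def load_grm_hdf5(path: str | Path) -> RelationshipMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        ids = None
        if "sample_ids" in f:
            ids = np.array([s.decode() for s in f["sample_ids"][()]])
        return RelationshipMatrix(
            f["values"][()], f.attrs["kind"], f.attrs["method"], float(f.attrs["normalizer"]), ids
        )


def write_gcta_grm(rm: RelationshipMatrix, prefix: str | Path, n_snps: int = 0) -> None:
    """Write GCTA-compatible binary triplet: .grm.bin, .grm.N.bin, .grm.id."""
    prefix = str(prefix)
    n = rm.n
    tri = rm.values[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix + ".grm.bin")
    np.full(tri.shape, n_snps, dtype="<f4").tofile(prefix + ".grm.N.bin")
    ids = rm.sample_ids if rm.sample_ids is not None else np.arange(1, n + 1)
    with open(prefix + ".grm.id", "w") as fh:
        for s in ids:
            fh.write(f"{s}\t{s}\n")


def read_gcta_grm(prefix: str | Path, kind: str = "A") -> RelationshipMatrix:
    prefix = str(prefix)
    with open(prefix + ".grm.id") as fh:
        ids = np.array([line.split()[1] for line in fh if line.strip()])
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if len(tri) != n * (n + 1) // 2:
        raise ValueError("GRM binary size does not match id count")
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = tri
    values = values + np.tril(values, -1).T
    return RelationshipMatrix(values, kind, "n/a", 1.0, ids)
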