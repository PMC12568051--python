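"""Genomic relationship matrices: additive (G), dominance (D), combined (Gt).

G follows VanRaden: Z = M - 2p columnwise, G = ZZ' / (2 sum p_i q_i).
D uses the heterozygosity indicator h in {0,1} centred by its
Hardy-Weinberg expectation 2 p_j q_j with denominator 4 sum p_j^2 q_j^2
(the "hybrid" coding; see the package methods note).  A pure
dominance-deviation coding (Vitezica-style, denominator sum (2 p q)^2) is
available via ``coding="dominance_deviation"``.

Allele frequencies are always taken from the full genotype sample, never
from an individual subset, so matrices built for training subsets stay
compatible with whole-population matrices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "build_additive_grm",
    "build_dominance_grm",
    "combine_matrices",
    "regularize",
    "write_relationship_matrix",
    "read_relationship_matrix",
]


class MatrixAlignmentError(ValueError):
    """Raised when two relationship matrices index different individuals."""


@dataclasses.dataclass
class RelationshipMatrix:
    """Symmetric individual-by-individual relationship matrix.

    ``scaling_denominator`` keeps the constant the cross-product was divided
    by (2*sum(p*q) for additive, 4*sum(p^2*q^2) for dominance), which makes
    the unscaled cross-products recoverable for subset-additivity checks.
    """

    individual_ids: list
    values: np.ndarray
    kind: str  # additive | dominance | combined
    scaling_denominator: float
    ridge_added: float = 0.0
    source_snp_set: object = "all"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match individual ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def align(self, ids) -> np.ndarray:
        """Submatrix for ``ids`` in that order."""
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        idx = np.array([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]


def _freqs_for(geno: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    p = geno.allele_freq[cols]
    if np.all((p <= 0.0) | (p >= 1.0)):
        raise ZeroDivisionError(
            "all selected SNPs are monomorphic; relationship denominator is zero"
        )
    return p


def build_additive_grm(geno: GenotypeMatrix, snp_set="all") -> RelationshipMatrix:
    """VanRaden additive GRM from a SNP subset (default: whole panel)."""
    cols = geno.snp_indexer(snp_set)
    if cols.size == 0:
        raise ValueError("empty SNP set")
    p = _freqs_for(geno, cols)
    M = geno.codes[:, cols]
    Z = M - 2.0 * p[None, :]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    values = (Z @ Z.T) / denom
    return RelationshipMatrix(
        individual_ids=list(geno.individual_ids),
        values=values,
        kind="additive",
        scaling_denominator=denom,
        source_snp_set=snp_set if isinstance(snp_set, str) else list(snp_set),
    )


def build_dominance_grm(
    geno: GenotypeMatrix, snp_set="all", coding: str = "hybrid"
) -> RelationshipMatrix:
    """Dominance GRM from the heterozygosity indicator.

    coding="hybrid" (default): V = h - 2pq, D = VV' / (4 sum p^2 q^2).
    coding="dominance_deviation": genotype classes scored (-2p^2, 2pq, -2q^2)
    for 0/1/2 copies, D = VV' / sum (2pq)^2; its diagonal averages 1 under
    Hardy-Weinberg proportions.
    """
    cols = geno.snp_indexer(snp_set)
    if cols.size == 0:
        raise ValueError("empty SNP set")
    p = _freqs_for(geno, cols)
    q = 1.0 - p
    codes = geno.codes[:, cols]
    het = (codes == 1.0).astype(float)
    # fractional (imputed) codes: use the HWE expectation so the centred
    # entry contributes nothing
    frac = ~np.isin(codes, (0.0, 1.0, 2.0))
    if frac.any():
        het[frac] = np.broadcast_to(2.0 * p * q, het.shape)[frac]
    if coding == "hybrid":
        V = het - 2.0 * p * q
        denom = 4.0 * float(np.sum(p**2 * q**2))
    elif coding == "dominance_deviation":
        V = np.where(
            codes == 1.0,
            2.0 * p * q,
            np.where(codes >= 1.0, -2.0 * q**2, -2.0 * p**2),
        )
        V[frac] = 0.0
        denom = float(np.sum((2.0 * p * q) ** 2))
    else:
        raise ValueError(f"unknown dominance coding {coding!r}")
    if denom <= 0.0:
        raise ZeroDivisionError("dominance denominator is zero (monomorphic set)")
    values = (V @ V.T) / denom
    return RelationshipMatrix(
        individual_ids=list(geno.individual_ids),
        values=values,
        kind="dominance",
        scaling_denominator=denom,
        source_snp_set=snp_set if isinstance(snp_set, str) else list(snp_set),
    )


def combine_matrices(
    A: RelationshipMatrix, B: RelationshipMatrix, tau: float
) -> RelationshipMatrix:
    """Convex combination tau*A + (1-tau)*B (the trait-specific Gt)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    if A.individual_ids != B.individual_ids:
        raise MatrixAlignmentError("matrices index different individuals")
    if A.kind != B.kind:
        raise MatrixAlignmentError(f"cannot combine kinds {A.kind!r} and {B.kind!r}")
    return RelationshipMatrix(
        individual_ids=list(A.individual_ids),
        values=tau * A.values + (1.0 - tau) * B.values,
        kind="combined",
        scaling_denominator=tau * A.scaling_denominator
        + (1.0 - tau) * B.scaling_denominator,
        source_snp_set="combined",
    )


def regularize(A: RelationshipMatrix, ridge_factor: float = 1e-6) -> RelationshipMatrix:
    """Add ridge_factor * mean(diag) * I; needed before inverting subset GRMs."""
    if ridge_factor < 0.0:
        raise ValueError("ridge_factor must be non-negative")
    if ridge_factor == 0.0:
        return A
    ridge = ridge_factor * float(np.mean(np.diag(A.values)))
    out = dataclasses.replace(A, values=A.values + ridge * np.eye(A.n))
    out.ridge_added = A.ridge_added + ridge
    return out


def write_relationship_matrix(A: RelationshipMatrix, path) -> None:
    """Id-indexed CSV; scaling metadata in a JSON-ish header comment line."""
    path = Path(path)
    df = pd.DataFrame(A.values, index=A.individual_ids, columns=A.individual_ids)
    with open(path, "w") as fh:
        fh.write(
            f"# kind={A.kind} scaling_denominator={A.scaling_denominator!r} "
            f"ridge_added={A.ridge_added!r}\n"
        )
        df.to_csv(fh)


def read_relationship_matrix(path) -> RelationshipMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, index_col=0)
    meta = dict(
        item.split("=", 1) for item in header.lstrip("# ").split() if "=" in item
    )
    return RelationshipMatrix(
        individual_ids=list(df.index.astype(str)),
        values=df.to_numpy(),
        kind=meta.get("kind", "additive"),
        scaling_denominator=float(meta.get("scaling_denominator", "nan")),
        ridge_added=float(meta.get("ridge_added", "0.0")),
    )


def write_relationship_matrix_binary(A: RelationshipMatrix, path) -> None:
    """Compact bit-exact format: JSON header line + row-major float64."""
    import json

    header = {
        "individual_ids": list(map(str, A.individual_ids)),
        "kind": A.kind,
        "scaling_denominator": A.scaling_denominator,
        "ridge_added": A.ridge_added,
    }
    with open(Path(path), "wb") as fh:
        fh.write(json.dumps(header).encode() + b"\n")
        fh.write(np.ascontiguousarray(A.values, dtype="<f8").tobytes())


def read_relationship_matrix_binary(path) -> RelationshipMatrix:
    import json

    with open(Path(path), "rb") as fh:
        header = json.loads(fh.readline().decode())
        n = len(header["individual_ids"])
        values = np.frombuffer(fh.read(), dtype="<f8").reshape(n, n)
    return RelationshipMatrix(
        individual_ids=header["individual_ids"],
        values=values.copy(),
        kind=header["kind"],
        scaling_denominator=header["scaling_denominator"],
        ridge_added=header["ridge_added"],
    )
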