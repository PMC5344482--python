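"""Additive relationship matrices: pedigree-based A and SNP-based G.

The pedigree numerator relationship matrix A is built with the tabular
method (Emik & Terrill recursion), so diagonals equal 1 + F with F the
inbreeding coefficient. The genomic relationship matrix G follows VanRaden's
first method: centered dosages W = M - 2P scaled by twice the sum of
heterozygosities, G = WW' / (2 * sum_j p_j (1 - p_j)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree


class KinshipError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray = field(repr=False)
    kind: str = "pedigree"            # "pedigree" or "genomic"
    stabilized: bool = False
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if arr.shape != (n, n):
            raise KinshipError(f"matrix shape {arr.shape} != ({n}, {n})")
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise KinshipError("relationship matrix is not symmetric")
        self.values = (arr + arr.T) / 2.0

    def subset(self, ids) -> "RelationshipMatrix":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [index[str(i)] for i in ids]
        return RelationshipMatrix([self.ids[r] for r in rows],
                                  self.values[np.ix_(rows, rows)],
                                  kind=self.kind, stabilized=self.stabilized,
                                  epsilon=self.epsilon)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def pedigree_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    For individual j with parents s, d (processed parents-first):
    ``a_jj = 1 + 0.5 * a_sd`` and ``a_ij = 0.5 * (a_is + a_id)`` for earlier
    i; unknown parents contribute zero. Founders form an identity block.
    """
    ids = pedigree.ids
    n = len(ids)
    pos = {i: k for k, i in enumerate(ids)}
    A = np.zeros((n, n))
    for j, row in enumerate(pedigree.table.itertuples()):
        s = pos[row.sire] if row.sire is not None else None
        d = pos[row.dam] if row.dam is not None else None
        if j > 0:
            left = A[:j, s] if s is not None else 0.0
            right = A[:j, d] if d is not None else 0.0
            A[:j, j] = 0.5 * (left + right)
            A[j, :j] = A[:j, j]
        A[j, j] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None
                         else 0.0)
    return RelationshipMatrix(ids, A, kind="pedigree")


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per SNP from non-missing dosages."""
    dos = genotypes.dosages
    n_obs = np.isfinite(dos).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [genotypes.snp_ids[j] for j in np.nonzero(n_obs == 0)[0]]
        raise KinshipError(f"SNP(s) with no non-missing calls: {bad[:5]}")
    with np.errstate(invalid="ignore"):
        return np.nanmean(dos, axis=0) / 2.0


def genomic_relationship(genotypes: GenotypeMatrix,
                         freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Missing dosages are mean-imputed to ``2 p_j`` (so they contribute zero
    after centering). Raises if the panel is entirely monomorphic, which
    zeroes the scaling denominator.
    """
    if freqs is None:
        freqs = allele_frequencies(genotypes)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (genotypes.n_snps,):
        raise KinshipError("frequency vector is not aligned with SNP columns")
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0.0:
        raise KinshipError("all SNPs monomorphic: VanRaden denominator is zero")
    W = genotypes.dosages - 2.0 * freqs
    W = np.where(np.isfinite(W), W, 0.0)
    G = (W @ W.T) / denom
    return RelationshipMatrix(list(genotypes.ids), G, kind="genomic")


def stabilize(matrix: RelationshipMatrix,
              epsilon: float = 1e-6) -> RelationshipMatrix:
    """Return a Cholesky-factorizable copy, ridging the diagonal if needed.

    If the input already factorizes it is returned unchanged (flag False).
    Otherwise ``epsilon * mean(diag)`` is added to the diagonal, escalating
    epsilon tenfold up to 1e-2 before giving up.
    """
    vals = matrix.values
    try:
        linalg.cholesky(vals, lower=True)
        return matrix
    except linalg.LinAlgError:
        pass
    mean_diag = float(np.mean(np.diag(vals)))
    eps = epsilon
    while eps <= 1e-2:
        ridged = vals + eps * mean_diag * np.eye(len(matrix.ids))
        try:
            linalg.cholesky(ridged, lower=True)
            return RelationshipMatrix(list(matrix.ids), ridged,
                                      kind=matrix.kind, stabilized=True,
                                      epsilon=eps)
        except linalg.LinAlgError:
            eps *= 10.0
    raise KinshipError("matrix not factorizable even with ridge 1e-2")
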