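"""Assembly of the heterogeneous bilayer network adjacency matrix.

The disease similarity network, the lncRNA similarity network and the
disease-lncRNA association network are joined into one symmetric
(m+n) x (m+n) block matrix

    A = [[DS, DL],
         [DL.T, LS]]

with diseases occupying rows/columns 0..m-1 and lncRNAs m..m+n-1.  The
observed-entry index set Phi contains every similarity-block position
(similarity entries are all computed, hence known — zeros included)
plus exactly the positions of the 1-entries in the association blocks,
so |Phi| = m^2 + n^2 + 2*nnz(DL).  Positive semi-definiteness of A is
never assumed: integrated similarities need not be PSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix

__all__ = [
    "HeterogeneousAdjacency",
    "build_adjacency",
    "observed_index_set",
    "project_observed",
    "extract_association_block",
]


@dataclass
class HeterogeneousAdjacency:
    """The bilayer adjacency matrix with its label bookkeeping."""

    values: np.ndarray
    disease_ids: list[str]
    lncrna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = len(self.disease_ids), len(self.lncrna_ids)
        if self.values.shape != (m + n, m + n):
            raise ValueError("adjacency must be (m+n) x (m+n)")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("adjacency must be symmetric")

    @property
    def m(self) -> int:
        return len(self.disease_ids)

    @property
    def n(self) -> int:
        return len(self.lncrna_ids)

    @property
    def size(self) -> int:
        return self.m + self.n


def build_adjacency(
    DS: SimilarityMatrix, LS: SimilarityMatrix, DL: AssociationMatrix
) -> HeterogeneousAdjacency:
    """Stack [[DS, DL], [DL.T, LS]] after verifying label alignment."""
    if DS.ids != DL.disease_ids:
        raise ValueError("disease similarity ids do not match association rows")
    if LS.ids != DL.lncrna_ids:
        raise ValueError("lncRNA similarity ids do not match association columns")
    A = np.block([[DS.values, DL.values], [DL.values.T, LS.values]])
    return HeterogeneousAdjacency(A, list(DL.disease_ids), list(DL.lncrna_ids))


def observed_index_set(A: HeterogeneousAdjacency, DL: AssociationMatrix | None = None) -> np.ndarray:
    """Boolean mask of the known entries Phi of the adjacency matrix.

    All similarity-block entries are observed; within the association
    blocks only the 1-entries are (zeros are unknown, not negative).
    When ``DL`` is omitted the association block is taken from ``A``
    itself.  The mask is closed under transposition by construction.
    """
    m, n = A.m, A.n
    mask = np.zeros((m + n, m + n), dtype=bool)
    mask[:m, :m] = True
    mask[m:, m:] = True
    block = A.values[:m, m:] if DL is None else DL.values
    known = block != 0
    mask[:m, m:] = known
    mask[m:, :m] = known.T
    return mask


def project_observed(M: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Orthogonal projector P_Phi: zero every entry outside the mask."""
    M = np.asarray(M, dtype=float)
    return np.where(mask, M, 0.0)


def extract_association_block(
    A_star: np.ndarray, m: int, n: int
) -> np.ndarray:
    """Prediction scores: the averaged mirrored association blocks of A*.

    Averaging the top-right block with the transposed bottom-left block
    guards against the tiny asymmetries a floating-point iteration can
    introduce.
    """
    A_star = np.asarray(A_star, dtype=float)
    if A_star.shape != (m + n, m + n):
        raise ValueError("completed matrix has wrong shape")
    return (A_star[:m, m:] + A_star[m:, :m].T) / 2.0
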