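"""Per-source similarity measures and their weighted integration.

Disease similarity can come from a term-overlap Jaccard index, from a
DAG-based semantic kernel, or from the cosine of binary interaction
profiles; lncRNA similarity from global sequence alignment, expression
rank correlation, disease-set functional similarity, or again profile
cosine.  An integrated similarity is the convex combination
``w * S_source + (1 - w) * S_cosine``; the weight is tuned on a grid by
cross-validation AUC.

Degenerate-input rules (all deliberate, so every output is a valid
``SimilarityMatrix``):

* cosine similarity of an all-zero profile is 0 to everything,
  including its own diagonal (0/0 carries no information);
* Jaccard of two empty term sets is 0 (no evidence), not 1;
* a constant expression row has similarity 0 off-diagonal, 1 to itself;
* raw negative alignment cross-scores are clamped to 0 before the
  normalization so sequence similarity stays in [0, 1];
* a lncRNA with no associated disease gets functional similarity 0
  off-diagonal and 1 on the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .alignment import AlignmentScoring, needleman_wunsch_score
from .containers import (
    AnnotationSets,
    AssociationMatrix,
    OntologyDag,
    SequenceSet,
    SimilarityMatrix,
)

__all__ = [
    "IntegrationWeights",
    "jaccard_similarity",
    "cosine_profile_similarity",
    "sequence_similarity",
    "expression_similarity",
    "semantic_similarity_dag",
    "lncrna_functional_similarity",
    "integrate",
    "tune_weight_grid",
]


@dataclass
class IntegrationWeights:
    """Convex-combination weights for disease (w_d) and lncRNA (w_l) blocks."""

    w_d: float
    w_l: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_d <= 1.0 and 0.0 <= self.w_l <= 1.0):
            raise ValueError("weights must lie in [0, 1]")


def jaccard_similarity(ann: AnnotationSets, ids: Sequence[str]) -> SimilarityMatrix:
    """Term-set Jaccard index |G_i & G_j| / |G_i | G_j| over ``ids``."""
    sets = [frozenset(ann.get(i)) for i in ids]
    n = len(ids)
    S = np.zeros((n, n))
    for i in range(n):
        if sets[i]:
            S[i, i] = 1.0
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            S[i, j] = S[j, i] = len(sets[i] & sets[j]) / union if union else 0.0
    return SimilarityMatrix(S, list(ids), "jaccard")


def cosine_profile_similarity(
    M: AssociationMatrix, axis: str = "diseases"
) -> SimilarityMatrix:
    """Cosine of the angle between binary interaction profiles.

    ``axis='diseases'`` compares rows of the association matrix,
    ``axis='lncrnas'`` columns.  All-zero profiles get similarity 0 to
    everything, including themselves.
    """
    if axis == "diseases":
        P, ids = M.values, M.disease_ids
    elif axis == "lncrnas":
        P, ids = M.values.T, M.lncrna_ids
    else:
        raise ValueError("axis must be 'diseases' or 'lncrnas'")
    norms = np.linalg.norm(P, axis=1)
    G = P @ P.T
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(S, list(ids), "cosine")


def sequence_similarity(
    seqs: SequenceSet,
    scoring: AlignmentScoring | None = None,
    ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Normalized global-alignment similarity between lncRNA sequences.

    S(i, j) = NW(i, j) / sqrt(NW(i, i) * NW(j, j)) with negative raw
    cross-scores clamped to 0 first, so the result lies in [0, 1] with
    an exact unit diagonal.  The geometric-mean denominator is what
    makes self-similarity exactly 1.
    """
    scoring = scoring or AlignmentScoring()
    ids = list(ids) if ids is not None else list(seqs.records)
    n = len(ids)
    self_scores = np.array(
        [needleman_wunsch_score(seqs.records[i], seqs.records[i], scoring) for i in ids]
    )
    if (self_scores <= 0).any():
        raise ValueError("non-positive self-alignment score")
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            raw = needleman_wunsch_score(seqs.records[ids[i]], seqs.records[ids[j]], scoring)
            raw = max(raw, 0.0)
            S[i, j] = S[j, i] = raw / np.sqrt(self_scores[i] * self_scores[j])
    return SimilarityMatrix(np.clip(S, 0.0, 1.0), ids, "sequence")


def expression_similarity(E) -> SimilarityMatrix:
    """Absolute Spearman rank correlation between expression profiles.

    Ties get average ranks.  A constant row correlates with nothing:
    similarity 0 off-diagonal, 1 on the diagonal.
    """
    values, ids = E.values, E.lncrna_ids
    if values.shape[1] < 2:
        raise ValueError("at least 2 samples required")
    constant = values.std(axis=1) == 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = np.asarray(stats.spearmanr(values, axis=1).statistic, dtype=float)
    if rho.ndim == 0:  # scipy collapses the 2-row case to a scalar
        r = float(rho) if np.isfinite(rho) else 0.0
        rho = np.array([[1.0, r], [r, 1.0]])
    S = np.abs(np.nan_to_num(rho, nan=0.0))
    S[constant, :] = 0.0
    S[:, constant] = 0.0
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(S, list(ids), "expression")


def _semantic_contributions(
    dag: OntologyDag, terms: Iterable[str]
) -> dict[str, float]:
    """Contribution of every DAG node to one disease's semantic profile.

    Annotated nodes contribute 1; a node k edges above any annotated
    node contributes decay**k, taking the maximum over annotated nodes
    and paths (with decay <= 1 that maximum is attained along a shortest
    upward path).
    """
    contrib: dict[str, float] = {}
    for t in terms:
        for node, depth in dag.ancestors_with_depth(t).items():
            val = dag.decay**depth
            if val > contrib.get(node, 0.0):
                contrib[node] = val
    return contrib


def semantic_similarity_dag(
    dag: OntologyDag,
    disease_terms: AnnotationSets | Mapping[str, Iterable[str]],
    ids: Sequence[str],
) -> SimilarityMatrix:
    """DAG-based semantic similarity with depth-decayed term contributions.

    Each disease's profile is its annotated nodes plus all their
    ancestors, a node's semantic contribution decaying by ``dag.decay``
    per edge upward; similarity is the contribution mass on shared
    nodes divided by the two total semantic values (the standard
    semantic-value formulation for MeSH-style disease DAGs).
    """
    getter = disease_terms.get if isinstance(disease_terms, AnnotationSets) else (
        lambda d: disease_terms.get(d, set())
    )
    profiles = []
    for d in ids:
        terms = list(getter(d))
        if not terms:
            raise ValueError(f"disease {d!r} maps to no DAG node")
        profiles.append(_semantic_contributions(dag, terms))
    totals = [sum(p.values()) for p in profiles]
    n = len(ids)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            common = profiles[i].keys() & profiles[j].keys()
            num = sum(profiles[i][t] + profiles[j][t] for t in common)
            S[i, j] = S[j, i] = num / (totals[i] + totals[j])
    return SimilarityMatrix(np.clip(S, 0.0, 1.0), list(ids), "semantic")


def lncrna_functional_similarity(
    DS_sem: SimilarityMatrix, assoc: AssociationMatrix
) -> SimilarityMatrix:
    """Functional similarity of lncRNAs via their associated disease sets.

    For lncRNAs with disease sets D_i, D_j:

        S(i, j) = [ sum_{d in D_i} max_{d' in D_j} DS(d, d')
                  + sum_{d in D_j} max_{d' in D_i} DS(d, d') ] / (|D_i| + |D_j|)

    lncRNAs associated with no disease get similarity 0 off-diagonal and
    1 on the diagonal (the ratio is undefined for empty sets).
    """
    if DS_sem.ids != assoc.disease_ids:
        raise ValueError("disease similarity and association labels disagree")
    D = DS_sem.values
    n = assoc.n_lncrnas
    disease_sets = [np.flatnonzero(assoc.values[:, j]) for j in range(n)]
    S = np.eye(n)
    for i in range(n):
        Di = disease_sets[i]
        for j in range(i + 1, n):
            Dj = disease_sets[j]
            if len(Di) == 0 or len(Dj) == 0:
                S[i, j] = S[j, i] = 0.0
                continue
            block = D[np.ix_(Di, Dj)]
            num = block.max(axis=1).sum() + block.max(axis=0).sum()
            S[i, j] = S[j, i] = num / (len(Di) + len(Dj))
    return SimilarityMatrix(np.clip(S, 0.0, 1.0), list(assoc.lncrna_ids), "functional")


def integrate(S1: SimilarityMatrix, S2: SimilarityMatrix, w: float) -> SimilarityMatrix:
    """Entrywise convex combination w*S1 + (1-w)*S2 of two aligned blocks."""
    if S1.ids != S2.ids:
        raise ValueError("cannot integrate similarity matrices with different ids")
    if not (0.0 <= w <= 1.0):
        raise ValueError("weight must lie in [0, 1]")
    return SimilarityMatrix(w * S1.values + (1.0 - w) * S2.values, list(S1.ids), "integrated")


def tune_weight_grid(
    evaluate: Callable[[float, float], float],
    grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10)),
) -> tuple[IntegrationWeights, list[tuple[float, float, float]]]:
    """Grid-search the integration weights (w_d, w_l) by AUC.

    ``evaluate(w_d, w_l)`` must return the cross-validation AUC of the
    full pipeline under a fixed seed.  Returns the argmax pair plus the
    full (w_d, w_l, auc) table for reporting.  Ties break toward the
    larger weights, i.e. more mass on the non-cosine source.
    """
    table: list[tuple[float, float, float]] = []
    best: tuple[float, float, float] | None = None
    for w_d in grid:
        for w_l in grid:
            try:
                auc = float(evaluate(w_d, w_l))
            except Exception as exc:  # surface grid context with the failure
                raise RuntimeError(f"weight evaluation failed at (w_d={w_d}, w_l={w_l})") from exc
            table.append((float(w_d), float(w_l), auc))
            key = (auc, w_d, w_l)
            if best is None or key > (best[2], best[0], best[1]):
                best = (float(w_d), float(w_l), auc)
    assert best is not None
    return IntegrationWeights(best[0], best[1]), table
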