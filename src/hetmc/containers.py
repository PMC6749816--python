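"""Labelled matrix containers shared by every stage of the pipeline.

All containers are thin, validated wrappers around numpy arrays plus
ordered identifier lists.  Keeping the labels attached to the values is
what lets every downstream matrix (similarity blocks, the bilayer
adjacency, prediction scores) stay aligned to disease / lncRNA ids
without positional bookkeeping in user code.

A ``0`` in an association matrix means *unknown or uncertain*, never a
verified negative: absence of evidence for a disease-lncRNA link is not
evidence of absence, and the completion model treats those cells as
blanks to be filled in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "SequenceSet",
    "ExpressionMatrix",
    "AnnotationSets",
    "OntologyDag",
    "RankedPredictions",
    "EvalResult",
]

SYMMETRY_TOL = 1e-10


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    if not ids:
        raise ValueError(f"empty {what} identifier list")
    return ids


@dataclass
class AssociationMatrix:
    """Binary disease x lncRNA association matrix DL.

    Rows are diseases, columns are lncRNAs; row ``i`` is the interaction
    profile of disease ``d_i`` and column ``j`` the profile of lncRNA
    ``l_j``.  Entries are 0/1 where 1 is an experimentally supported
    association and 0 means unknown/uncertain.
    """

    values: np.ndarray
    disease_ids: list[str]
    lncrna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.lncrna_ids = _check_unique(self.lncrna_ids, "lncRNA")
        m, n = len(self.disease_ids), len(self.lncrna_ids)
        if self.values.shape != (m, n):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"{m} diseases x {n} lncRNAs"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_known(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.disease_ids), list(self.lncrna_ids)
        )


@dataclass
class SimilarityMatrix:
    """Symmetric similarity block with values in [0, 1].

    ``source_tag`` records which measure produced the block (semantic,
    jaccard, cosine, sequence, expression, functional or integrated).
    The diagonal is 1 for every entity with non-degenerate input; an
    all-zero interaction profile yields a 0 diagonal under the cosine
    measure (a deliberate degenerate-case rule, see the cosine op).
    """

    values: np.ndarray
    ids: list[str]
    source_tag: str = "integrated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = _check_unique(self.ids, "similarity")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over its ids")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite values")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"similarity matrix asymmetric (max dev {asym:.3g})")
        self.values = (self.values + self.values.T) / 2.0
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Reorder to ``ids``, erroring on identifiers missing here."""
        pos = {v: k for k, v in enumerate(self.ids)}
        try:
            idx = [pos[i] for i in ids]
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} missing from similarity matrix")
        return SimilarityMatrix(
            self.values[np.ix_(idx, idx)], list(ids), self.source_tag
        )


@dataclass
class SequenceSet:
    """Nucleotide sequences keyed by lncRNA id (uppercase, U kept as given)."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty sequence set")
        for k, v in self.records.items():
            if not v:
                raise ValueError(f"empty sequence for id {k!r}")


@dataclass
class ExpressionMatrix:
    """Real lncRNA x sample expression table (no missing values)."""

    values: np.ndarray
    lncrna_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lncrna_ids = _check_unique(self.lncrna_ids, "lncRNA")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.lncrna_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape does not match its labels")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if len(self.sample_ids) < 2:
            raise ValueError("at least 2 samples required for correlation")


@dataclass
class AnnotationSets:
    """Entity -> set of annotation-term ids (e.g. disease -> GO terms)."""

    sets: dict[str, set[str]] = field(default_factory=dict)

    def get(self, entity_id: str) -> set[str]:
        return self.sets.get(entity_id, set())


@dataclass
class OntologyDag:
    """Directed acyclic term graph given as child -> parent edges.

    ``decay`` is the per-edge contribution factor used by the semantic
    similarity kernel: a term ``k`` edges above an annotated node
    contributes ``decay**k``.
    """

    edges: list[tuple[str, str]]
    decay: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.decay <= 1.0):
            raise ValueError("decay must be in (0, 1]")
        import networkx as nx

        g = nx.DiGraph()
        nodes = {t for e in self.edges for t in e}
        g.add_nodes_from(nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("cycle detected in ontology DAG")
        self._graph = g

    @property
    def graph(self):
        return self._graph

    def ancestors_with_depth(self, node: str) -> dict[str, int]:
        """Map of node and its ancestors to shortest upward edge distance."""
        import networkx as nx

        if node not in self._graph:
            raise KeyError(f"term {node!r} not in DAG")
        return nx.single_source_shortest_path_length(self._graph, node)


@dataclass
class RankedPredictions:
    """Scored candidate disease-lncRNA pairs with per-disease and global ranks.

    Sorted by score descending; ties broken lexicographically by
    (disease_id, lncrna_id) so emitted files are deterministic.
    """

    entries: list[tuple[str, str, float, bool]]  # (disease, lncrna, score, is_known)
    per_disease_rank: list[int] = field(default_factory=list)
    global_rank: list[int] = field(default_factory=list)

    @classmethod
    def from_scores(
        cls,
        scores: np.ndarray,
        disease_ids: Sequence[str],
        lncrna_ids: Sequence[str],
        known: np.ndarray | None = None,
        exclude_known: bool = False,
    ) -> "RankedPredictions":
        m, n = scores.shape
        if known is None:
            known = np.zeros_like(scores, dtype=bool)
        known = np.asarray(known, dtype=bool)
        rows = []
        for i in range(m):
            for j in range(n):
                if exclude_known and known[i, j]:
                    continue
                rows.append(
                    (disease_ids[i], lncrna_ids[j], float(scores[i, j]), bool(known[i, j]))
                )
        rows.sort(key=lambda r: (-r[2], r[0], r[1]))
        global_rank = list(range(1, len(rows) + 1))
        counter: dict[str, int] = {}
        per_disease = []
        for d, _, _, _ in rows:
            counter[d] = counter.get(d, 0) + 1
            per_disease.append(counter[d])
        return cls(rows, per_disease, global_rank)


@dataclass
class EvalResult:
    """ROC/PR summary of a ranking experiment."""

    auc: float
    aupr: float
    roc_points: np.ndarray  # (fpr, tpr) rows
    pr_points: np.ndarray  # (recall, precision) rows
    precision_at: dict[int, float] = field(default_factory=dict)
    recall_at: dict[int, float] = field(default_factory=dict)
    n_test: int = 0
    n_candidates: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0) or not (0.0 <= self.aupr <= 1.0):
            raise ValueError("AUC/AUPR must lie in [0, 1]")
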