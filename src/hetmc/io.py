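"""Readers and writers for every external file format.

All tabular inputs are plain delimited text (tab or comma, auto-detected
unless a delimiter is forced); sequences are FASTA.  Readers own the
label bookkeeping: identifier order is fixed at first appearance in the
association file and similarity inputs are reindexed to that order,
erroring on missing ids rather than silently dropping them.

A 0 in the association file's implied matrix encodes "unknown or
uncertain", never a verified negative.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    AnnotationSets,
    AssociationMatrix,
    ExpressionMatrix,
    OntologyDag,
    RankedPredictions,
    SequenceSet,
    SimilarityMatrix,
)

__all__ = [
    "read_associations",
    "read_similarity_matrix",
    "read_fasta",
    "read_expression",
    "read_annotations",
    "read_dag",
    "write_predictions",
    "write_similarity_matrix",
]

#: asymmetry larger than this in a similarity input is an error,
#: smaller deviations are silently symmetrized as (S + S.T)/2
ASYMMETRY_TOL = 1e-8


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    sample = Path(path).read_text().splitlines()
    for line in sample:
        if line.strip() and not line.startswith("#"):
            return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: empty file")


def read_associations(path, delimiter: str | None = None) -> AssociationMatrix:
    """Read disease-lncRNA pairs (two columns) into a binary matrix.

    Duplicate pairs collapse to a single 1; identifier order is first
    appearance.  An optional header row is detected and skipped when its
    two fields reappear nowhere else as a pair.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or not "".join(row).strip() or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(row)}")
            d, l = row[0].strip(), row[1].strip()
            if not d or not l:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            pairs.append((d, l))
    if not pairs:
        raise ValueError(f"{path}: no association rows")
    # header heuristic: first row looks like column names if its disease id
    # never recurs and common header words are present
    first = pairs[0]
    if first[0].lower() in {"disease", "disease_id", "diseases"} or first[1].lower() in {
        "lncrna",
        "lncrna_id",
        "lncrnas",
    }:
        pairs = pairs[1:]
        if not pairs:
            raise ValueError(f"{path}: header only, no association rows")
    disease_ids: list[str] = []
    lncrna_ids: list[str] = []
    dpos: dict[str, int] = {}
    lpos: dict[str, int] = {}
    for d, l in pairs:
        if d not in dpos:
            dpos[d] = len(disease_ids)
            disease_ids.append(d)
        if l not in lpos:
            lpos[l] = len(lncrna_ids)
            lncrna_ids.append(l)
    values = np.zeros((len(disease_ids), len(lncrna_ids)))
    for d, l in pairs:
        values[dpos[d], lpos[l]] = 1.0
    return AssociationMatrix(values, disease_ids, lncrna_ids)


def read_similarity_matrix(
    path, delimiter: str | None = None, source_tag: str = "integrated"
) -> SimilarityMatrix:
    """Read a labelled square similarity matrix.

    Values must lie in [0, 1].  Asymmetry up to 1e-8 is symmetrized
    silently; anything larger is an error.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, index_col=0, comment="#")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-numeric or missing similarity value")
    if values.min() < 0 or values.max() > 1:
        raise ValueError(f"{path}: similarity values outside [0, 1]")
    asym = np.abs(values - values.T).max()
    if asym > ASYMMETRY_TOL:
        raise ValueError(f"{path}: asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOL}")
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, [str(i) for i in df.index], source_tag)


def read_fasta(path) -> SequenceSet:
    """Read nucleotide FASTA; sequences upper-cased, ids must be unique."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return SequenceSet(records)


def read_expression(path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a lncRNA x sample expression table with a header row."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, index_col=0, comment="#")
    values = df.to_numpy(dtype=object)
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    if np.isnan(numeric).any():
        bad = int(np.argwhere(np.isnan(numeric))[0][0]) // df.shape[1]
        raise ValueError(
            f"{path}: non-numeric expression value in row {df.index[bad]!r}"
        )
    return ExpressionMatrix(
        numeric.reshape(df.shape),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def read_annotations(path, delimiter: str | None = None) -> AnnotationSets:
    """Read entity -> term annotations, one (entity, term) pair per row."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or not "".join(row).strip() or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected entity,term")
            sets.setdefault(row[0].strip(), set()).add(row[1].strip())
    return AnnotationSets(sets)


def read_dag(path, delimiter: str | None = None, decay: float = 0.5) -> OntologyDag:
    """Read child,parent term edges into a DAG (cycles are an error)."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or not "".join(row).strip() or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected child,parent")
            edges.append((row[0].strip(), row[1].strip()))
    return OntologyDag(edges, decay=decay)


def write_predictions(preds: RankedPredictions, path, header: Iterable[str] = ()) -> None:
    """Write ranked predictions as tab-delimited text.

    Columns: disease_id, lncrna_id, score, rank_within_disease,
    global_rank.  Rows are sorted by score descending with deterministic
    lexicographic tie-breaking (already enforced by RankedPredictions).
    Extra ``header`` lines (e.g. provenance) are written as ``#`` comments.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["disease_id", "lncrna_id", "score", "rank_within_disease", "global_rank"])
        for (d, l, s, _), pr, gr in zip(
            preds.entries, preds.per_disease_rank, preds.global_rank
        ):
            w.writerow([d, l, f"{s:.10g}", pr, gr])


def write_similarity_matrix(sim: SimilarityMatrix, path, delimiter: str = "\t") -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        path, sep=delimiter, float_format="%.10g"
    )
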