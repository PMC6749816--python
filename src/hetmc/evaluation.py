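"""Ranking-based validation of association predictions.

The protocols mirror how link-prediction methods are scored in this
field: each experimentally supported association is hidden in turn
(LOOCV) or in equal folds (k-fold CV), the model is re-run on the
reduced training matrix, and the hidden pair is ranked against the
candidate pairs without known evidence.  "Global" protocols rank
against all unknown pairs of the whole matrix, "local" against the
unknown pairs of the held-out pair's own disease only.

Fold ranks are pooled into one list by converting every fold's scores
to normalized average ranks (rank / #scored); AUC and AUPR are then
computed on the pooled list.  A model whose score equals the hidden
truth therefore attains AUC exactly 1, and random scores hover at 0.5.

The permutation contribution test randomizes one input matrix at a time
(symmetric label permutation for similarity blocks, a reshuffle of the
1-positions for the association matrix) and records how far the AUC
collapses toward 0.5: the matrix whose permutation hurts most is the
one the model leans on most.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn import metrics

from .containers import AssociationMatrix, EvalResult, RankedPredictions

__all__ = [
    "roc_pr_from_scores",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "precision_recall_at_ranks",
    "permutation_contribution",
    "matrix_sparsity",
    "truncate_significant",
]

ModelCallback = Callable[[np.ndarray], np.ndarray]
"""Retrains/rescores on a reduced binary training matrix (m x n) and
returns a full score matrix of the same shape."""


def roc_pr_from_scores(pos_scores, neg_scores) -> EvalResult:
    """ROC and PR summaries from positive- and negative-class scores.

    AUC is the rank statistic (ties counted half, equivalent to
    trapezoidal ROC integration); AUPR uses step-wise precision
    interpolation at each positive.
    """
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    auc = float(metrics.roc_auc_score(y, s))
    aupr = float(metrics.average_precision_score(y, s))
    fpr, tpr, _ = metrics.roc_curve(y, s)
    prec, rec, _ = metrics.precision_recall_curve(y, s)
    return EvalResult(
        auc=auc,
        aupr=aupr,
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec, prec]),
        n_test=int(pos.size),
        n_candidates=int(neg.size),
    )


def _pool_fold(pos_score: float, neg_scores: np.ndarray) -> tuple[float, np.ndarray]:
    """Normalized average ranks of one fold's positive and negatives."""
    all_scores = np.concatenate([[pos_score], neg_scores])
    r = rankdata(all_scores, method="average") / all_scores.size
    return float(r[0]), r[1:]


def _loocv(assoc: AssociationMatrix, model_callback: ModelCallback, local: bool) -> EvalResult:
    DL = assoc.values
    known = np.argwhere(DL == 1)
    if known.shape[0] < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    pooled_pos: list[float] = []
    pooled_neg: list[np.ndarray] = []
    for i, j in known:
        train = DL.copy()
        train[i, j] = 0.0
        S = model_callback(train)
        if S.shape != DL.shape:
            raise ValueError("model callback returned wrong-shaped scores")
        if local:
            # candidates: unknown pairs of this disease only
            neg = S[i][(train[i] == 0) & (np.arange(DL.shape[1]) != j)]
        else:
            mask = train == 0
            mask[i, j] = False
            neg = S[mask]
        if neg.size == 0:
            continue
        u_pos, u_neg = _pool_fold(float(S[i, j]), neg)
        pooled_pos.append(u_pos)
        pooled_neg.append(u_neg)
    res = roc_pr_from_scores(np.asarray(pooled_pos), np.concatenate(pooled_neg))
    res.extra["protocol"] = "local-loocv" if local else "global-loocv"
    return res


def global_loocv(assoc: AssociationMatrix, model_callback: ModelCallback, seed=None) -> EvalResult:
    """Hide each known pair in turn; rank it against all unknown pairs."""
    return _loocv(assoc, model_callback, local=False)


def local_loocv(assoc: AssociationMatrix, model_callback: ModelCallback, seed=None) -> EvalResult:
    """Hide each known pair in turn; rank it within its own disease only."""
    return _loocv(assoc, model_callback, local=True)


def make_folds(n_known: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled disjoint covering folds with sizes differing by <= 1."""
    if not (2 <= k <= n_known):
        raise ValueError("k must be between 2 and the number of known pairs")
    perm = rng.permutation(n_known)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def kfold_cv(
    assoc: AssociationMatrix,
    model_callback: ModelCallback,
    k: int = 5,
    repeats: int = 1,
    seed: int | None = None,
) -> EvalResult:
    """Global k-fold CV over the known associations, pooled ranking.

    Each fold's hidden pairs are scored after retraining without the
    whole fold; every hidden pair is ranked against the unknown pairs of
    the training matrix, excluding the other hidden pairs of the same
    fold.  With ``repeats > 1`` the per-repeat AUC spread is reported in
    ``extra['auc_per_repeat']``.
    """
    DL = assoc.values
    known = np.argwhere(DL == 1)
    rng = np.random.default_rng(seed)
    per_repeat_auc: list[float] = []
    pooled_pos_all: list[float] = []
    pooled_neg_all: list[np.ndarray] = []
    for _ in range(repeats):
        folds = make_folds(known.shape[0], k, rng)
        pooled_pos: list[float] = []
        pooled_neg: list[np.ndarray] = []
        for fold in folds:
            test_pairs = known[fold]
            train = DL.copy()
            train[test_pairs[:, 0], test_pairs[:, 1]] = 0.0
            S = model_callback(train)
            cand = train == 0
            cand[test_pairs[:, 0], test_pairs[:, 1]] = False  # drop all test pairs
            neg = S[cand]
            for i, j in test_pairs:
                u_pos, u_neg = _pool_fold(float(S[i, j]), neg)
                pooled_pos.append(u_pos)
                pooled_neg.append(u_neg)
        rep = roc_pr_from_scores(np.asarray(pooled_pos), np.concatenate(pooled_neg))
        per_repeat_auc.append(rep.auc)
        pooled_pos_all.extend(pooled_pos)
        pooled_neg_all.extend(pooled_neg)
    res = roc_pr_from_scores(np.asarray(pooled_pos_all), np.concatenate(pooled_neg_all))
    res.extra["protocol"] = f"global-{k}fold"
    res.extra["auc_per_repeat"] = per_repeat_auc
    res.extra["auc_mean"] = float(np.mean(per_repeat_auc))
    res.extra["auc_sd"] = float(np.std(per_repeat_auc, ddof=1)) if repeats > 1 else 0.0
    return res


def precision_recall_at_ranks(
    preds: RankedPredictions,
    truth: Iterable[tuple[str, str]] | None = None,
    cutoffs: Sequence[int] = (20, 40, 60, 80, 100, 120, 140),
) -> tuple[dict[int, float], dict[int, float]]:
    """Precision@k and recall@k over the pooled ranked prediction list.

    ``truth`` is a set of (disease_id, lncrna_id) pairs that are real
    associations; if ``None``, the ``is_known`` flag carried by the
    predictions is used.
    """
    if truth is None:
        flags = [e[3] for e in preds.entries]
    else:
        truth = set(truth)
        flags = [(d, l) in truth for d, l, _, _ in preds.entries]
    flags = np.asarray(flags, dtype=bool)
    total_pos = int(flags.sum())
    precision_at: dict[int, float] = {}
    recall_at: dict[int, float] = {}
    for c in cutoffs:
        top = flags[:c]
        tp = int(top.sum())
        precision_at[c] = tp / c
        recall_at[c] = tp / total_pos if total_pos else 0.0
    return precision_at, recall_at


def permutation_contribution(
    DS: np.ndarray,
    LS: np.ndarray,
    DL: np.ndarray,
    which: str,
    evaluator: Callable[[np.ndarray, np.ndarray, np.ndarray], float],
    n_reps: int = 20,
    seed: int | None = None,
) -> dict:
    """Randomize one input matrix ``n_reps`` times and record the AUC.

    Similarity blocks are permuted symmetrically (rows and columns by
    the same label permutation, preserving symmetry and the unit
    diagonal); the association matrix has its 1-positions reshuffled
    uniformly over the grid (count preserved, degree structure not).
    ``evaluator(DS, LS, DL) -> AUC`` reruns the pipeline.
    """
    if which not in ("DS", "LS", "DL"):
        raise ValueError("which must be one of 'DS', 'LS', 'DL'")
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_reps):
        ds, ls, dl = DS, LS, DL
        if which == "DS":
            p = rng.permutation(DS.shape[0])
            ds = DS[np.ix_(p, p)]
        elif which == "LS":
            p = rng.permutation(LS.shape[0])
            ls = LS[np.ix_(p, p)]
        else:
            m, n = DL.shape
            nnz = int(DL.sum())
            cells = rng.choice(m * n, size=nnz, replace=False)
            dl = np.zeros_like(DL)
            dl.flat[cells] = 1.0
        aucs.append(float(evaluator(ds, ls, dl)))
    aucs = np.asarray(aucs)
    return {
        "which": which,
        "auc_mean": float(aucs.mean()),
        "auc_sd": float(aucs.std(ddof=1)) if n_reps > 1 else 0.0,
        "auc_values": aucs.tolist(),
    }


def truncate_significant(x: float, sig: int = 4) -> float:
    """Truncate (not round) ``x`` to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    import math

    e = math.floor(math.log10(abs(x)))
    f = 10.0 ** (e - sig + 1)
    return math.floor(x / f) * f


def matrix_sparsity(DL: AssociationMatrix | np.ndarray, truncate: bool = True) -> float:
    """Density nnz(DL) / (m*n), truncated to 4 significant figures.

    Truncation (rather than rounding) matches the convention used when
    such densities are tabulated to four figures.
    """
    values = DL.values if isinstance(DL, AssociationMatrix) else np.asarray(DL)
    density = float((values != 0).sum()) / values.size
    return truncate_significant(density, 4) if truncate else density
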