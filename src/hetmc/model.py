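"""End-to-end link predictor: similarities + associations -> ranked scores.

``BilayerLinkPredictor`` is the estimator users actually fit: it stacks
the disease-similarity, lncRNA-similarity and association blocks into
the bilayer adjacency matrix, runs singular-value-thresholding
completion over the observed entries, and exposes the completed
association block (mirrored-average, clipped to [0, 1]) as prediction
scores.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, clone

from .completion import CompletionConfig, SVTCompleter
from .containers import AssociationMatrix, RankedPredictions, SimilarityMatrix
from .network import build_adjacency, extract_association_block, observed_index_set

__all__ = ["BilayerLinkPredictor", "make_completion_callback"]


class BilayerLinkPredictor(BaseEstimator):
    """Predict disease-lncRNA associations by bilayer matrix completion.

    Parameters
    ----------
    completer : SVTCompleter or None
        The completion engine; cloned at fit time.  ``None`` means a
        default :class:`SVTCompleter` (clipping enabled).
    random_state : int or None
        Overrides the completer's ``random_state`` when given.

    Attributes
    ----------
    scores_ : ndarray of shape (m, n)
        Completed association block, clipped to [0, 1].
    adjacency_, mask_, completer_ : fitted internals.
    """

    def __init__(self, completer: SVTCompleter | None = None, random_state: int | None = None):
        self.completer = completer
        self.random_state = random_state

    def fit(
        self,
        assoc: AssociationMatrix,
        disease_sim: SimilarityMatrix,
        lncrna_sim: SimilarityMatrix,
    ) -> "BilayerLinkPredictor":
        A = build_adjacency(disease_sim, lncrna_sim, assoc)
        mask = observed_index_set(A)
        completer = clone(self.completer) if self.completer is not None else SVTCompleter()
        if self.random_state is not None:
            completer.set_params(random_state=self.random_state)
        completer.fit(A.values, mask=mask)
        self.adjacency_ = A
        self.mask_ = mask
        self.completer_ = completer
        self.scores_ = np.clip(
            extract_association_block(completer.raw_completed_, A.m, A.n), 0.0, 1.0
        )
        self.assoc_ = assoc
        return self

    def predict(self) -> np.ndarray:
        """The (m, n) score matrix for all disease-lncRNA pairs."""
        if not hasattr(self, "scores_"):
            raise AttributeError("BilayerLinkPredictor is not fitted yet")
        return self.scores_

    def ranked_predictions(self, exclude_known: bool = True) -> RankedPredictions:
        """Deterministically ranked candidate pairs (known pairs optional)."""
        return RankedPredictions.from_scores(
            self.predict(),
            self.assoc_.disease_ids,
            self.assoc_.lncrna_ids,
            known=self.assoc_.values.astype(bool),
            exclude_known=exclude_known,
        )


def make_completion_callback(
    DS: np.ndarray, LS: np.ndarray, config: CompletionConfig | None = None
):
    """Model callback for the CV harness: train matrix -> score matrix.

    Fixes the similarity blocks and re-runs completion for any binary
    training association matrix handed in by a cross-validation
    protocol.  The returned callable is what ``global_loocv`` /
    ``kfold_cv`` expect.
    """
    DS = np.asarray(DS, dtype=float)
    LS = np.asarray(LS, dtype=float)
    cfg = config or CompletionConfig()
    m, n = DS.shape[0], LS.shape[0]
    disease_ids = [f"d{i}" for i in range(m)]
    lncrna_ids = [f"l{j}" for j in range(n)]
    ds = SimilarityMatrix(DS, disease_ids, "integrated")
    ls = SimilarityMatrix(LS, lncrna_ids, "integrated")

    def callback(train: np.ndarray) -> np.ndarray:
        assoc = AssociationMatrix(np.asarray(train, dtype=float), disease_ids, lncrna_ids)
        est = BilayerLinkPredictor(
            completer=SVTCompleter(
                tau=cfg.tau,
                delta=cfg.delta,
                c0=cfg.c0,
                epsilon=cfg.epsilon,
                p=cfg.p,
                max_iter=cfg.max_iter,
                rank_start=cfg.rank_start,
                rank_increment=cfg.rank_increment,
                rank_cap=cfg.rank_cap,
                oversampling=cfg.oversampling,
                backend=cfg.backend,
                norm=cfg.norm,
                stop_rule=cfg.stop_rule,
                adaptive_p=cfg.adaptive_p,
                random_state=cfg.seed,
            )
        )
        est.fit(assoc, ds, ls)
        return est.scores_

    return callback
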