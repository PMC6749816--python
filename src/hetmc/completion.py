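"""Singular-value-thresholding matrix completion with a randomized
block-Krylov partial SVD and subspace reuse.

The nuclear-norm relaxation of the rank-minimization completion problem

    min ||X||_*   s.t.   P_Phi(X) = P_Phi(A)

is solved by the linearized Bregman (SVT) iteration

    X_i = shrink(Y_{i-1}, tau)
    Y_i = Y_{i-1} + delta * P_Phi(A - X_i),        Y_0 = c * delta * P_Phi(A)

where shrink soft-thresholds the singular values: every sigma_j >= tau
contributes (sigma_j - tau) u_j v_j^T.  Default parameters follow the
faster-SVT parameterization for a square N x N matrix with observed set
Phi:

    delta = N / |Phi|
    tau   = ||P_Phi(A)||_F * N / |Phi|
    c     = ceil( tau / (delta * ||P_Phi(A)||_2) )

(the norm in c is the spectral norm by default; Frobenius selectable).
Iteration stops when the relative Frobenius residual on Phi falls below
epsilon (mean-absolute-error on Phi selectable), or at ``max_iter``.

The inner partial SVD is either exact (reference backend) or the
randomized block-Krylov scheme ``rsvd_bki``: project onto the subspace
spanned by [M Omega, (M M^T) M Omega, ..., (M M^T)^p M Omega] for a
Gaussian test matrix Omega, then solve the small projected SVD.  Across
SVT iterations the right singular basis found at iteration i seeds the
test matrix at iteration i+1 (subspace reuse), which is what makes the
randomized path cheap without losing accuracy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CompletionConfig",
    "CompletionState",
    "SVDTriplet",
    "default_svt_parameters",
    "exact_truncated_svd",
    "rsvd_bki",
    "shrink",
    "SVTCompleter",
    "fsvt_complete",
]


@dataclass
class SVDTriplet:
    """Top-k singular triplet (U orthonormal, s non-increasing, V orthonormal)."""

    U: np.ndarray
    s: np.ndarray
    V: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.s) @ self.V.T


@dataclass
class CompletionConfig:
    """SVT parameters; ``None`` for tau/delta/c0 means use the defaults
    computed from the observed data by :func:`default_svt_parameters`."""

    tau: float | None = None
    delta: float | None = None
    c0: int | None = None
    epsilon: float = 0.4
    p: int = 2
    max_iter: int = 5000
    rank_start: int = 10
    rank_increment: int = 5
    rank_cap: int | None = None
    oversampling: int = 10
    backend: str = "rsvd_bki"
    norm: str = "spectral"  # norm in the c formula: spectral | frobenius
    stop_rule: str = "residual"  # residual (relative Frobenius on Phi) | mae
    adaptive_p: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.rank_start < 1:
            raise ValueError("rank_start must be >= 1")
        if self.backend not in ("exact", "rsvd_bki"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class CompletionState:
    """Iteration trace: residuals, final rank, reused subspace."""

    residual_history: list[float] = field(default_factory=list)
    iter: int = 0
    converged: bool = False
    rank: int = 0
    Q_prev: np.ndarray | None = None
    p_used: int = 2


def default_svt_parameters(
    A_observed: np.ndarray,
    mask: np.ndarray,
    epsilon: float = 0.4,
    p: int = 2,
    norm: str = "spectral",
    **overrides,
) -> CompletionConfig:
    """Data-driven SVT defaults for a square observed matrix.

    ``A_observed`` may be the full matrix (entries outside ``mask`` are
    ignored).  Raises on an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("observed index set is empty")
    A_obs = np.where(mask, np.asarray(A_observed, dtype=float), 0.0)
    N = A_obs.shape[0]
    if A_obs.shape[0] != A_obs.shape[1]:
        raise ValueError("completion operates on square matrices")
    delta = N / n_obs
    fro = float(np.linalg.norm(A_obs))
    tau = fro * N / n_obs
    if norm == "spectral":
        denom_norm = float(np.linalg.norm(A_obs, 2))
    elif norm == "frobenius":
        denom_norm = fro
    else:
        raise ValueError("norm must be 'spectral' or 'frobenius'")
    c0 = math.ceil(tau / (delta * denom_norm)) if denom_norm > 0 else 1
    cfg = CompletionConfig(
        tau=tau, delta=delta, c0=c0, epsilon=epsilon, p=p, norm=norm
    )
    return replace(cfg, **overrides) if overrides else cfg


def exact_truncated_svd(M: np.ndarray, k: int) -> SVDTriplet:
    """Exact top-k SVD (reference backend and test oracle)."""
    M = np.asarray(M, dtype=float)
    k = min(k, min(M.shape))
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return SVDTriplet(U[:, :k], s[:k], Vt[:k].T)


def _orth(M: np.ndarray) -> np.ndarray:
    Q, _ = linalg.qr(M, mode="economic")
    return Q


def rsvd_bki(
    M,
    k: int,
    p: int = 2,
    oversampling: int = 10,
    seed=None,
    Q_init: np.ndarray | None = None,
) -> SVDTriplet:
    """Randomized partial SVD via block-Krylov iteration.

    Builds the Krylov block [M Omega, (M M^T) M Omega, ..., (M M^T)^p
    M Omega] from a (k + oversampling)-column Gaussian test matrix Omega
    (each block re-orthonormalized for stability), orthonormalizes the
    union, and solves the projected small SVD.  When ``Q_init`` is
    given, its columns replace the leading random columns of Omega —
    this is the subspace-reuse hook.  Deterministic given ``seed`` (an
    int or a ``numpy.random.Generator``).
    """
    M = np.asarray(M, dtype=float)
    m, n = M.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(m, n):
        warnings.warn(
            f"requested rank {k} exceeds min dimension {min(m, n)}; clamping",
            RuntimeWarning,
            stacklevel=2,
        )
        k = min(m, n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    l = min(k + max(oversampling, 0), min(m, n))
    Omega = rng.standard_normal((n, l))
    if Q_init is not None and Q_init.size:
        q = min(Q_init.shape[1], l)
        Omega[:, :q] = Q_init[:, :q]
    Q = _orth(M @ Omega)
    blocks = [Q]
    for _ in range(p):
        Q = _orth(M @ (M.T @ Q))
        blocks.append(Q)
    Qk = _orth(np.hstack(blocks))
    B = Qk.T @ M
    Ub, s, Vt = np.linalg.svd(B, full_matrices=False)
    U = Qk @ Ub
    return SVDTriplet(U[:, :k], s[:k], Vt[:k].T)


def shrink(
    Y: np.ndarray,
    tau: float,
    backend: str = "exact",
    rank_start: int = 10,
    rank_increment: int = 5,
    rank_cap: int | None = None,
    oversampling: int = 10,
    p: int = 2,
    seed=None,
    Q_init: np.ndarray | None = None,
) -> tuple[np.ndarray, SVDTriplet]:
    """Singular-value soft-thresholding X = sum_{sigma_j >= tau} (sigma_j - tau) u_j v_j^T.

    The partial SVD rank adapts: compute ``s`` values, and while the
    smallest computed value still clears tau, grow ``s`` by
    ``rank_increment`` and recompute, until a value falls below tau or
    ``s`` hits the cap.  Returns the thresholded matrix together with
    the retained (un-shrunk) triplet.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    Y = np.asarray(Y, dtype=float)
    cap = min(Y.shape)
    if rank_cap is not None:
        cap = min(cap, max(1, rank_cap))
    s_try = min(max(1, rank_start), cap)
    while True:
        if backend == "exact":
            trip = exact_truncated_svd(Y, cap)
        elif backend == "rsvd_bki":
            trip = rsvd_bki(Y, s_try, p=p, oversampling=oversampling, seed=seed, Q_init=Q_init)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        if backend == "exact" or trip.s[-1] < tau or s_try >= cap:
            break
        s_try = min(s_try + max(1, rank_increment), cap)
    keep = trip.s >= tau
    r = int(keep.sum())
    kept = SVDTriplet(trip.U[:, :r], trip.s[:r], trip.V[:, :r])
    if r == 0:
        X = np.zeros_like(Y)
    else:
        X = (kept.U * (kept.s - tau)) @ kept.V.T
    return X, kept


class SVTCompleter(TransformerMixin, BaseEstimator):
    """Low-rank matrix completion by faster singular value thresholding.

    scikit-learn style estimator: ``fit(X, mask=...)`` runs the SVT
    iteration on the square matrix ``X`` whose known entries are flagged
    by the boolean ``mask`` (if omitted, non-NaN entries of ``X`` are
    treated as observed); ``transform`` returns the completed matrix.

    Parameters default to the data-driven SVT values (see
    :func:`default_svt_parameters`) when left as ``None``.  The
    ``rsvd_bki`` backend reuses the singular basis from the previous
    iteration to seed the next randomized projection.

    Attributes (after fit): ``completed_`` (clipped to [0, 1] when
    ``clip``), ``raw_completed_``, ``residual_history_``, ``n_iter_``,
    ``converged_``, ``rank_``, ``config_``.
    """

    def __init__(
        self,
        tau: float | None = None,
        delta: float | None = None,
        c0: int | None = None,
        epsilon: float = 0.4,
        p: int = 2,
        max_iter: int = 5000,
        rank_start: int = 10,
        rank_increment: int = 5,
        rank_cap: int | None = None,
        oversampling: int = 10,
        backend: str = "rsvd_bki",
        norm: str = "spectral",
        stop_rule: str = "residual",
        adaptive_p: bool = False,
        clip: bool = True,
        random_state: int | None = None,
    ) -> None:
        self.tau = tau
        self.delta = delta
        self.c0 = c0
        self.epsilon = epsilon
        self.p = p
        self.max_iter = max_iter
        self.rank_start = rank_start
        self.rank_increment = rank_increment
        self.rank_cap = rank_cap
        self.oversampling = oversampling
        self.backend = backend
        self.norm = norm
        self.stop_rule = stop_rule
        self.adaptive_p = adaptive_p
        self.clip = clip
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _resolve_config(self, A: np.ndarray, mask: np.ndarray) -> CompletionConfig:
        cfg = default_svt_parameters(
            A, mask, epsilon=self.epsilon, p=self.p, norm=self.norm
        )
        return replace(
            cfg,
            tau=self.tau if self.tau is not None else cfg.tau,
            delta=self.delta if self.delta is not None else cfg.delta,
            c0=self.c0 if self.c0 is not None else cfg.c0,
            max_iter=self.max_iter,
            rank_start=self.rank_start,
            rank_increment=self.rank_increment,
            rank_cap=self.rank_cap,
            oversampling=self.oversampling,
            backend=self.backend,
            stop_rule=self.stop_rule,
            adaptive_p=self.adaptive_p,
            seed=self.random_state,
        )

    def fit(self, X, y=None, mask: np.ndarray | None = None) -> "SVTCompleter":
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("SVTCompleter expects a square matrix")
        if mask is None:
            mask = ~np.isnan(A)
            A = np.nan_to_num(A, nan=0.0)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != A.shape:
            raise ValueError("mask shape must match the matrix")
        cfg = self._resolve_config(A, mask)
        N = A.shape[0]
        cap = cfg.rank_cap if cfg.rank_cap is not None else max(1, int(0.5 * N))
        rng = np.random.default_rng(cfg.seed)

        A_obs = np.where(mask, A, 0.0)
        obs_fro = float(np.linalg.norm(A_obs))
        if obs_fro == 0:
            raise ValueError("observed entries are all zero; nothing to complete")
        n_obs = int(mask.sum())

        Y = cfg.c0 * cfg.delta * A_obs
        state = CompletionState(p_used=cfg.p)
        Xc = np.zeros_like(A)
        rank_guess = cfg.rank_start
        prev_sigma_min: float | None = None
        p_eff = cfg.p
        for it in range(1, cfg.max_iter + 1):
            Xc, trip = shrink(
                Y,
                cfg.tau,
                backend=cfg.backend,
                rank_start=rank_guess,
                rank_increment=cfg.rank_increment,
                rank_cap=cap,
                oversampling=cfg.oversampling,
                p=p_eff,
                seed=rng,
                Q_init=state.Q_prev,
            )
            if not np.isfinite(Xc).all():
                raise FloatingPointError(f"non-finite iterate at iteration {it}")
            R = np.where(mask, A - Xc, 0.0)
            if cfg.stop_rule == "mae":
                resid = float(np.abs(R[mask]).mean()) if n_obs else 0.0
            else:
                resid = float(np.linalg.norm(R)) / obs_fro
            state.residual_history.append(resid)
            state.iter = it
            state.rank = trip.s.size
            state.Q_prev = trip.V if trip.s.size else None
            rank_guess = max(cfg.rank_start, trip.s.size + cfg.rank_increment)
            if cfg.adaptive_p and trip.s.size:
                smin = float(trip.s[-1])
                if prev_sigma_min is not None and prev_sigma_min > 0:
                    if abs(smin - prev_sigma_min) / prev_sigma_min > 0.01:
                        p_eff = min(p_eff * 2, 16)
                prev_sigma_min = smin
            if resid <= cfg.epsilon:
                state.converged = True
                break
            Y = Y + cfg.delta * R

        self.config_ = cfg
        self.state_ = state
        self.mask_ = mask
        self.raw_completed_ = Xc
        self.completed_ = np.clip(Xc, 0.0, 1.0) if self.clip else Xc
        self.residual_history_ = np.asarray(state.residual_history)
        self.n_iter_ = state.iter
        self.converged_ = state.converged
        self.rank_ = state.rank
        return self

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "completed_"):
            raise AttributeError("SVTCompleter is not fitted yet")
        return self.completed_

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).transform()


def fsvt_complete(
    A: np.ndarray, mask: np.ndarray, config: CompletionConfig | None = None
) -> tuple[np.ndarray, CompletionState]:
    """Functional wrapper: complete ``A`` over observed set ``mask``.

    Returns the completed matrix (clipped to [0, 1] for scoring) and the
    iteration state.
    """
    config = config or CompletionConfig()
    est = SVTCompleter(
        tau=config.tau,
        delta=config.delta,
        c0=config.c0,
        epsilon=config.epsilon,
        p=config.p,
        max_iter=config.max_iter,
        rank_start=config.rank_start,
        rank_increment=config.rank_increment,
        rank_cap=config.rank_cap,
        oversampling=config.oversampling,
        backend=config.backend,
        norm=config.norm,
        stop_rule=config.stop_rule,
        adaptive_p=config.adaptive_p,
        clip=True,
        random_state=config.seed,
    )
    est.fit(A, mask=mask)
    return est.completed_, est.state_
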