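"""Independent reference implementations used only as test oracles.

Each function here is deliberately naive (quadratic DP, explicit
double loops, exhaustive enumeration) and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import numpy as np


def gotoh_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_ext: float = 0.5,
) -> float:
    """Three-matrix affine-gap global alignment DP (end gaps penalized).

    A gap of length L costs gap_open + gap_ext * L.
    """
    NEG = float("-inf")
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -(gap_open + gap_ext * i)
    for j in range(1, lb + 1):
        Y[0][j] = -(gap_open + gap_ext * j)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_ext,
                X[i - 1][j] - gap_ext,
                Y[i - 1][j] - gap_open - gap_ext,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_ext,
                Y[i][j - 1] - gap_ext,
                X[i][j - 1] - gap_open - gap_ext,
            )
    return max(M[la][lb], X[la][lb], Y[la][lb])


def spearman_abs(x: np.ndarray, y: np.ndarray) -> float:
    """|Spearman rho| via the explicit Pearson-of-average-ranks formula."""

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(np.asarray(x)), avg_ranks(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0
    return abs(float((rx * ry).sum() / denom))


def functional_similarity_bruteforce(DS: np.ndarray, assoc: np.ndarray) -> np.ndarray:
    """Double-loop implementation of the disease-set functional similarity."""
    m, n = assoc.shape
    out = np.eye(n)
    for i in range(n):
        Di = [d for d in range(m) if assoc[d, i]]
        for j in range(i + 1, n):
            Dj = [d for d in range(m) if assoc[d, j]]
            if not Di or not Dj:
                out[i, j] = out[j, i] = 0.0
                continue
            total = sum(max(DS[d, dp] for dp in Dj) for d in Di)
            total += sum(max(DS[d, dp] for dp in Di) for d in Dj)
            out[i, j] = out[j, i] = total / (len(Di) + len(Dj))
    return out


def auc_pair_counting(pos, neg) -> float:
    """Concordant-pair fraction with ties counted half."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def semantic_similarity_enumeration(
    edges: list[tuple[str, str]],
    decay: float,
    terms_i: set[str],
    terms_j: set[str],
) -> float:
    """Exhaustive-path semantic similarity on a tiny DAG."""
    parents: dict[str, list[str]] = {}
    nodes = set()
    for c, p in edges:
        parents.setdefault(c, []).append(p)
        nodes.update((c, p))

    def contributions(terms: set[str]) -> dict[str, float]:
        contrib: dict[str, float] = {}

        def walk(node: str, value: float) -> None:
            if value > contrib.get(node, 0.0):
                contrib[node] = value
                for par in parents.get(node, []):
                    walk(par, value * decay)

        for t in terms:
            walk(t, 1.0)
        return contrib

    ci, cj = contributions(terms_i), contributions(terms_j)
    common = set(ci) & set(cj)
    num = sum(ci[t] + cj[t] for t in common)
    return num / (sum(ci.values()) + sum(cj.values()))


def svt_reference(A_obs: np.ndarray, mask: np.ndarray, tau: float, delta: float,
                  c0: int, n_iter: int) -> list[np.ndarray]:
    """Plain-loop textbook SVT: full SVD + soft threshold each step.

    Returns the list of primal iterates X_1 .. X_{n_iter}.
    """
    Y = c0 * delta * np.where(mask, A_obs, 0.0)
    out = []
    for _ in range(n_iter):
        U, s, Vt = np.linalg.svd(Y, full_matrices=False)
        keep = np.maximum(s - tau, 0.0)
        X = (U * keep) @ Vt
        out.append(X)
        Y = Y + delta * np.where(mask, A_obs - X, 0.0)
    return out
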