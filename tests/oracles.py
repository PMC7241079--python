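"""Independent brute-force oracles used by the tests.

Each oracle is written against the mathematical definition, avoiding the
package's own implementation path, so agreement is evidence and not
tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import special


def knn_impute_oracle(X: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive feature-neighbor imputation: rank every candidate feature
    by Euclidean distance on co-observed rows, average the top k values."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    out = X.copy()
    for j in range(p):
        for i in range(n):
            if not np.isnan(X[i, j]):
                continue
            cands = []
            for l in range(p):
                if l == j or np.isnan(X[i, l]):
                    continue
                shared = ~np.isnan(X[:, j]) & ~np.isnan(X[:, l])
                if not shared.any():
                    continue
                d = math.sqrt(float(np.sum((X[shared, j] - X[shared, l]) ** 2)))
                cands.append((d, l))
            if not cands:
                out[i, j] = np.nanmean(X[:, j])
                continue
            cands.sort()
            chosen = [l for _, l in cands[:k]]
            out[i, j] = float(np.mean([X[i, l] for l in chosen]))
    return out


def project_oracle(v: np.ndarray, c: float, n_grid: int = 20000) -> np.ndarray:
    """Dense scan over the soft-threshold parameter: evaluate the
    renormalized soft-thresholded vector on a fine delta grid, keep the
    feasible candidate with the largest objective w'v."""
    v = np.asarray(v, dtype=float)
    best_w, best_obj = np.zeros_like(v), -np.inf
    for delta in np.linspace(0.0, np.max(np.abs(v)), n_grid, endpoint=False):
        w = np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)
        norm = np.linalg.norm(w)
        if norm == 0:
            continue
        w = w / norm
        if np.abs(w).sum() <= c + 1e-9:
            obj = float(w @ v)
            if obj > best_obj:
                best_obj, best_w = obj, w
    return best_w


def sphere_grid(p: int, step: float = 0.05, c: float | None = None) -> np.ndarray:
    """All coordinate-grid points in [-1,1]^p normalized to the unit sphere,
    optionally filtered to the L1 ball of radius c. Deduplicated."""
    axis = np.arange(-1.0, 1.0 + step / 2, step)
    pts = np.array(list(itertools.product(axis, repeat=p)))
    norms = np.linalg.norm(pts, axis=1)
    pts = pts[norms > 1e-9] / norms[norms > 1e-9, None]
    if c is not None:
        pts = pts[np.abs(pts).sum(axis=1) <= c + 1e-9]
    return np.unique(np.round(pts, 12), axis=0)


def _pair_max(W1, W2, S12, s1y, s2y, s, chunk=512):
    """Max and argmax of the bilinear objective over all grid pairs."""
    base = W1 @ s1y * s  # per-w1 constant
    T = W1 @ S12 + s * s2y[None, :]  # per-w1 linear form in w2
    best, arg = -np.inf, (0, 0)
    for start in range(0, W1.shape[0], chunk):
        block = T[start : start + chunk] @ W2.T + base[start : start + chunk, None]
        i, j = np.unravel_index(np.argmax(block), block.shape)
        if block[i, j] > best:
            best, arg = float(block[i, j]), (start + int(i), int(j))
    return best, arg


def _local_grid(w: np.ndarray, step: float, c: float | None) -> np.ndarray:
    """Coordinate perturbations of w on the sphere (nested grid refinement)."""
    offsets = np.array(list(itertools.product((-step, 0.0, step), repeat=w.size)))
    pts = w[None, :] + offsets
    norms = np.linalg.norm(pts, axis=1)
    pts = pts[norms > 1e-9] / norms[norms > 1e-9, None]
    if c is not None:
        pts = pts[np.abs(pts).sum(axis=1) <= c + 1e-9]
    return pts


def grid_search_smcca(
    S12: np.ndarray,
    s1y: np.ndarray,
    s2y: np.ndarray,
    s: float,
    c1: float,
    c2: float,
    step: float = 0.05,
    n_refine: int = 6,
) -> float:
    """Brute-force maximum of w1'S12 w2 + s(w1's1y + w2's2y): a global
    0.05-step grid of unit-norm feasible pairs, then nested local grid
    refinements around the argmax (step shrinking threefold each pass)."""
    W1 = sphere_grid(S12.shape[0], step, c1)
    W2 = sphere_grid(S12.shape[1], step, c2)
    best, (i, j) = _pair_max(W1, W2, S12, s1y, s2y, s)
    w1, w2 = W1[i], W2[j]
    local_step = step
    for _ in range(n_refine):
        local_step /= 3.0
        L1 = _local_grid(w1, local_step, c1)
        L2 = _local_grid(w2, local_step, c2)
        cand, (i, j) = _pair_max(L1, L2, S12, s1y, s2y, s)
        if cand > best:
            best, w1, w2 = cand, L1[i], L2[j]
    return best


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p: hypergeometric upper tail computed
    from factorials directly."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def log_hyper(x: int) -> float:
        return (
            special.gammaln(row1 + 1)
            - special.gammaln(x + 1)
            - special.gammaln(row1 - x + 1)
            + special.gammaln(n - row1 + 1)
            - special.gammaln(col1 - x + 1)
            - special.gammaln(n - row1 - (col1 - x) + 1)
            - (special.gammaln(n + 1) - special.gammaln(col1 + 1) - special.gammaln(n - col1 + 1))
        )

    hi = min(row1, col1)
    lo = max(0, col1 - (n - row1))
    return float(sum(math.exp(log_hyper(x)) for x in range(a, hi + 1) if x >= lo))


def bh_adjust_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the textbook definition: sort, scale by m/i,
    enforce monotonicity from the largest p down."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def anova_permutation_p(samples: list, n_perm: int = 10000, seed: int = 0) -> float:
    """Permutation p-value for the one-way ANOVA F statistic."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    obs = stats.f_oneway(*samples).statistic
    pooled = np.concatenate(samples)
    sizes = [len(s) for s in samples]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts, start = [], 0
        for sz in sizes:
            parts.append(perm[start : start + sz])
            start += sz
        if stats.f_oneway(*parts).statistic >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
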