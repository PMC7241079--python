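"""Sparse multiple canonical correlation with a phenotype block.

The objective couples two omics blocks X1 (n x p1), X2 (n x p2) and a
phenotype vector y (all column-standardized) through

    J(w1, w2) = w1' S12 w2 + s * (w1' s1y + w2' s2y)

where S12 = X1'X2/(n-1) and sky = Xk'y/(n-1) are Pearson correlation
matrices, and s >= 0 is the scaling constant that prioritizes the
omics-phenotype terms over the omics-omics term. Each weight vector is
constrained to the intersection of the unit L2 ball and an L1 ball of
radius c_k = l_k * sqrt(p_k); the block update is the classic
soft-threshold-and-renormalize projection, so alternating maximization is
monotone in J.

Networks come from averaging |w w'| over feature subsamples: features that
co-occur with large weights across many refits earn a large similarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------
@dataclass
class ScalingScheme:
    """Weight on the omics-phenotype correlation terms (between-omics = 1)."""

    s: float = 1.0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"scaling constant must be >= 0, got {self.s}")


@dataclass
class PenaltyPair:
    """Sparsity fractions per block; effective L1 budget is l_k * sqrt(p_k)."""

    l1: float
    l2: float

    def __post_init__(self) -> None:
        for name, val in (("l1", self.l1), ("l2", self.l2)):
            if not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {val}")


@dataclass
class SubsampleScheme:
    fraction_1: float = 0.7
    fraction_2: float = 0.7
    n_subsamples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("fraction_1", self.fraction_1), ("fraction_2", self.fraction_2)):
            if not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {val}")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")


@dataclass
class CanonicalWeights:
    w1: np.ndarray
    w2: np.ndarray
    objective_value: float
    n_iterations: int
    converged: bool

    def support_1(self, tol: float = 1e-10) -> np.ndarray:
        return np.where(np.abs(self.w1) > tol)[0]

    def support_2(self, tol: float = 1e-10) -> np.ndarray:
        return np.where(np.abs(self.w2) > tol)[0]


@dataclass
class CVResult:
    grid: list
    mean_errors: np.ndarray
    chosen: PenaltyPair
    fold_assignments: np.ndarray


@dataclass
class SimilarityMatrix:
    """Subsampling-averaged |ww'| association matrix, max-normalized.

    ``values`` is (p1+p2) x (p1+p2), symmetric, in [0,1] with zero diagonal;
    ``signs`` carries the sign of the plain Pearson correlation between each
    feature pair (negative associations render as grey/negative edges
    downstream).
    """

    values: np.ndarray
    feature_ids: list
    kinds: list
    signs: np.ndarray


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------
def correlation_range_report(X1: np.ndarray, X2: np.ndarray, y: np.ndarray) -> dict:
    """Min/max pairwise Pearson correlations between blocks and with y.

    Recommends raising the scaling constant when the omics-omics range
    strictly contains the omics-phenotype range — the situation in which an
    unscaled objective is dominated by between-omics correlation.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    if keep.sum() < 3 or X1.shape[0] < 3:
        raise ValueError("need at least 3 subjects")

    def _stdz(M: np.ndarray) -> np.ndarray:
        M = M - M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return M / sd

    n = X1.shape[0]
    Z1, Z2 = _stdz(X1), _stdz(X2)
    cross = Z1.T @ Z2 / (n - 1)

    ny = keep.sum()
    Z1y, Z2y = _stdz(X1[keep]), _stdz(X2[keep])
    yz = (y[keep] - y[keep].mean()) / y[keep].std(ddof=1)
    r1y = Z1y.T @ yz / (ny - 1)
    r2y = Z2y.T @ yz / (ny - 1)

    omics = (float(cross.min()), float(cross.max()))
    x1y = (float(r1y.min()), float(r1y.max()))
    x2y = (float(r2y.min()), float(r2y.max()))
    pheno_lo = min(x1y[0], x2y[0])
    pheno_hi = max(x1y[1], x2y[1])
    recommend = omics[0] < pheno_lo and omics[1] > pheno_hi
    return {
        "omics_omics": omics,
        "omics1_phenotype": x1y,
        "omics2_phenotype": x2y,
        "recommend_increase_scaling": bool(recommend),
    }


# --------------------------------------------------------------------------
# the sparse projection
# --------------------------------------------------------------------------
def _soft(v: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)


def project_l1_l2(v: np.ndarray, c: float, tol: float = 1e-10) -> np.ndarray:
    """argmax of w'v over the unit L2 ball intersected with the L1 ball of
    radius c, via soft-thresholding and renormalization.

    The maximizer is S(v, d)/||S(v, d)||_2 with S the soft-threshold
    operator and d the smallest threshold making the result L1-feasible
    (d = 0 when v/||v||_2 is already feasible). The threshold is located by
    walking the sorted support breakpoints and solving the feasibility
    equation in closed form on the bracketing interval, which stays exact
    even when components of |v| are tied to machine precision. c must be
    >= 1 (below 1 no maximizer attains the unit sphere); c = 1 returns the
    one-hot vector at the largest |v_i| (ties to the lowest index). An
    all-zero v returns the zero vector with a warning.
    """
    v = np.asarray(v, dtype=float)
    if c < 1.0:
        raise ValueError(f"L1 budget c must be >= 1, got {c}")
    if not np.any(v):
        warnings.warn("projection target is the zero vector", RuntimeWarning)
        return np.zeros_like(v)
    if c == 1.0:
        w = np.zeros_like(v)
        i = int(np.argmax(np.abs(v)))
        w[i] = np.sign(v[i]) if v[i] != 0 else 1.0
        return w

    u = v / np.linalg.norm(v)
    if np.abs(u).sum() <= c + tol:
        return u

    # Magnitudes within a relative 1e-6 band are collapsed into tie groups;
    # the group-mass problem (maximize sum t_g M_g subject to sum M_g <= c,
    # sum M_g^2 / n_g <= 1) is then solved exactly. With distinct group
    # values the soft-threshold feasibility equation is well conditioned,
    # and exactly tied components (where no single threshold can meet the
    # L1 budget) receive equal within-group mass, which is optimal there.
    order = np.argsort(-np.abs(v), kind="stable")
    mag = np.abs(v)[order]
    gap_tol = 1e-6 * mag[0]
    boundaries = [0]
    for i in range(1, mag.size):
        if mag[boundaries[-1]] - mag[i] > gap_tol:
            boundaries.append(i)
    t_vals = np.array([mag[b:e].mean() for b, e in zip(boundaries, boundaries[1:] + [mag.size])])
    n_vals = np.array(
        [e - b for b, e in zip(boundaries, boundaries[1:] + [mag.size])], dtype=float
    )

    x_sorted = np.zeros(mag.size)
    if c * c <= n_vals[0]:
        # budget fits inside the top tie group: all mass there, equal split
        b0, e0 = boundaries[0], boundaries[1] if len(boundaries) > 1 else mag.size
        x_sorted[b0:e0] = c / n_vals[0]
    else:
        A_pre = np.cumsum(n_vals * t_vals)
        B_pre = np.cumsum(n_vals * t_vals**2)
        N_pre = np.cumsum(n_vals)

        def _f(g: int, mu: float) -> float:
            num = A_pre[g] - N_pre[g] * mu
            den = math.sqrt(
                max(B_pre[g] - 2 * A_pre[g] * mu + N_pre[g] * mu * mu, 0.0)
            )
            return num / den if den > 0 else math.sqrt(N_pre[g])

        G = t_vals.size
        mu_star = 0.0
        for g in range(G - 1, -1, -1):
            lo = t_vals[g + 1] if g < G - 1 else 0.0
            hi = t_vals[g]
            if not (_f(g, lo) >= c >= _f(g, hi)):
                continue
            A, B, N = A_pre[g], B_pre[g], N_pre[g]
            if abs(N - c * c) < 1e-12:
                mu_star = lo
            else:
                qa = N * (N - c * c)
                qb = -2 * A * (N - c * c)
                qc = A * A - c * c * B
                disc = max(qb * qb - 4 * qa * qc, 0.0)
                roots = [
                    min(max((-qb + sgn * math.sqrt(disc)) / (2 * qa), lo), hi)
                    for sgn in (1.0, -1.0)
                ]
                mu_star = min(roots, key=lambda r: abs(_f(g, r) - c))
            break
        for g, (b, e) in enumerate(zip(boundaries, boundaries[1:] + [mag.size])):
            x_sorted[b:e] = max(t_vals[g] - mu_star, 0.0)
        norm = np.linalg.norm(x_sorted)
        if norm > 0:
            x_sorted /= norm

    w = np.zeros_like(v)
    w[order] = x_sorted * np.sign(v[order])
    return w


# --------------------------------------------------------------------------
# objective and solver
# --------------------------------------------------------------------------
def weighted_objective(
    w1: np.ndarray,
    w2: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    scheme: ScalingScheme,
) -> float:
    """J = w1' S12 w2 + s (w1' s1y + w2' s2y) on standardized inputs."""
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X1.shape[0]
    if X2.shape[0] != n or y.shape[0] != n:
        raise ValueError("X1, X2 and y must share the subject dimension")
    if w1.shape[0] != X1.shape[1] or w2.shape[0] != X2.shape[1]:
        raise ValueError("weight lengths must match feature counts")
    cross = (X1 @ w1) @ (X2 @ w2) / (n - 1)
    pheno = ((X1 @ w1) @ y + (X2 @ w2) @ y) / (n - 1)
    return float(cross + scheme.s * pheno)


def _effective_budget(l: float, p: int) -> float:
    # grid fractions below 1/sqrt(p) would give an infeasible budget; clamp
    # to the fully-sparse corner c = 1 (one active feature)
    return max(1.0, l * math.sqrt(p))


def fit_smcca(
    X1: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    scheme: ScalingScheme,
    penalties: PenaltyPair,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> CanonicalWeights:
    """Block coordinate ascent for the sparse weighted objective.

    Each half-step solves its block exactly via :func:`project_l1_l2`, so the
    objective is non-decreasing; iteration stops when the largest component
    change falls below ``tol``. Initialization is deterministic: w2 starts at
    the unit-normalized column sums of |S12|.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p1 = X1.shape
    p2 = X2.shape[1]
    if n < 3:
        raise ValueError("need at least 3 subjects")

    S12 = X1.T @ X2 / (n - 1)
    s1y = X1.T @ y / (n - 1)
    s2y = X2.T @ y / (n - 1)
    c1 = _effective_budget(penalties.l1, p1)
    c2 = _effective_budget(penalties.l2, p2)

    colsum = np.abs(S12).sum(axis=0)
    w2 = colsum / np.linalg.norm(colsum) if np.any(colsum) else np.full(p2, p2**-0.5)
    w1 = np.zeros(p1)

    obj_prev = -np.inf
    converged = False
    it = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-target projections
        for it in range(1, max_iter + 1):
            w1_new = project_l1_l2(S12 @ w2 + scheme.s * s1y, c1)
            w2_new = project_l1_l2(S12.T @ w1_new + scheme.s * s2y, c2)
            obj = float(
                w1_new @ S12 @ w2_new + scheme.s * (w1_new @ s1y + w2_new @ s2y)
            )
            # tolerance covers the tie-collapse approximation in the projection
            if obj < obj_prev - 1e-4 * max(1.0, abs(obj_prev)):
                raise AssertionError(
                    f"objective decreased at iteration {it}: {obj_prev} -> {obj}"
                )
            delta = max(
                np.max(np.abs(w1_new - w1)) if p1 else 0.0,
                np.max(np.abs(w2_new - w2)) if p2 else 0.0,
            )
            w1, w2, obj_prev = w1_new, w2_new, obj
            if delta < tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"SmCCA did not converge in {max_iter} iterations", RuntimeWarning
        )
    if not np.any(w1) and not np.any(w2):
        raise ValueError("degenerate solution: both weight vectors all-zero")
    return CanonicalWeights(w1, w2, obj_prev, it, converged)


# --------------------------------------------------------------------------
# cross-validated penalty selection
# --------------------------------------------------------------------------
def _standardize_cols(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0
    return M / sd


def cv_select_penalties(
    X1: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    scheme: ScalingScheme,
    grid_values: Sequence[float] = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55),
    k_folds: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_repeats: int = 1,
) -> CVResult:
    """Grid search over all l1 x l2 pairs with k-fold CV.

    Prediction error for a pair is the relative generalization gap
    |J_train - J_test| / |J_train| averaged over folds, both objectives
    evaluated with the trained weights on independently standardized
    splits. (The relative scaling matters: the raw objective grows with the
    L1 budget, so an absolute gap would always favor the sparsest pair
    regardless of fit.) With ``n_repeats`` > 1 the error is further
    averaged over independent fold splits, which flattens fold-assignment
    noise on an otherwise shallow error surface. The chosen pair minimizes
    mean error; ties break to smaller l1+l2, then smaller l1.
    ``fold_assignments`` reports the first repeat's split.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X1.shape[0]
    if n < k_folds:
        raise ValueError("need at least k_folds subjects")
    pairs = [PenaltyPair(a, b) for a in grid_values for b in grid_values]
    mean_errors = np.zeros(len(pairs))
    first_folds = None
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for f, idx in enumerate(np.array_split(perm, k_folds)):
            folds[idx] = f
            if idx.size < 3:
                raise ValueError(f"fold {f} has fewer than 3 subjects")
        if first_folds is None:
            first_folds = folds
        splits = []
        for f in range(k_folds):
            tr, te = folds != f, folds == f
            Z1tr, Z2tr = _standardize_cols(X1[tr]), _standardize_cols(X2[tr])
            ytr = (y[tr] - y[tr].mean()) / max(y[tr].std(ddof=1), 1e-12)
            Z1te, Z2te = _standardize_cols(X1[te]), _standardize_cols(X2[te])
            yte = (y[te] - y[te].mean()) / max(y[te].std(ddof=1), 1e-12)
            splits.append((Z1tr, Z2tr, ytr, Z1te, Z2te, yte))
        for k, pair in enumerate(pairs):
            errs = []
            for Z1tr, Z2tr, ytr, Z1te, Z2te, yte in splits:
                fit = fit_smcca(Z1tr, Z2tr, ytr, scheme, pair, max_iter, tol)
                j_tr = weighted_objective(fit.w1, fit.w2, Z1tr, Z2tr, ytr, scheme)
                j_te = weighted_objective(fit.w1, fit.w2, Z1te, Z2te, yte, scheme)
                errs.append(abs(j_tr - j_te) / max(abs(j_tr), 1e-12))
            mean_errors[k] += np.mean(errs)
    mean_errors /= n_repeats
    folds = first_folds

    best = min(
        range(len(pairs)),
        key=lambda k: (mean_errors[k], pairs[k].l1 + pairs[k].l2, pairs[k].l1),
    )
    return CVResult(pairs, mean_errors, pairs[best], folds)


# --------------------------------------------------------------------------
# consensus similarity via feature subsampling
# --------------------------------------------------------------------------
def build_similarity(
    X1: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    scheme: ScalingScheme,
    penalties: PenaltyPair,
    subsampling: SubsampleScheme,
    feature_ids_1: Optional[Sequence] = None,
    feature_ids_2: Optional[Sequence] = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> SimilarityMatrix:
    """Average |w w'| over feature subsamples into a consensus similarity.

    Each replicate fits SmCCA on ceil(fraction_k * p_k) features drawn
    without replacement per block; weights are embedded into full-length
    vectors (zeros elsewhere) and the outer-product magnitudes accumulated.
    The average is normalized so its largest off-diagonal entry is 1 and the
    diagonal is zeroed. Edge signs come from plain Pearson correlations of
    the full data.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float)
    p1, p2 = X1.shape[1], X2.shape[1]
    m1 = math.ceil(subsampling.fraction_1 * p1)
    m2 = math.ceil(subsampling.fraction_2 * p2)
    if m1 < 2 or m2 < 2:
        raise ValueError(
            f"subsample sizes must be >= 2 per block, got {m1} and {m2}"
        )
    rng = np.random.default_rng(subsampling.seed)
    p = p1 + p2
    acc = np.zeros((p, p))
    for _ in range(subsampling.n_subsamples):
        idx1 = np.sort(rng.choice(p1, m1, replace=False))
        idx2 = np.sort(rng.choice(p2, m2, replace=False))
        fit = fit_smcca(
            X1[:, idx1], X2[:, idx2], y, scheme, penalties, max_iter, tol
        )
        w = np.zeros(p)
        w[idx1] = fit.w1
        w[p1 + idx2] = fit.w2
        acc += np.abs(np.outer(w, w))
    acc /= subsampling.n_subsamples
    np.fill_diagonal(acc, 0.0)
    peak = acc.max()
    if peak > 0:
        acc /= peak
    acc = 0.5 * (acc + acc.T)  # exact symmetry against float noise

    full = np.hstack([X1, X2])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(full, rowvar=False)
    signs = np.where(np.nan_to_num(corr) < 0, -1, 1)
    np.fill_diagonal(signs, 1)

    if feature_ids_1 is None:
        feature_ids_1 = [f"x1_{j}" for j in range(p1)]
    if feature_ids_2 is None:
        feature_ids_2 = [f"x2_{j}" for j in range(p2)]
    ids = list(feature_ids_1) + list(feature_ids_2)
    kinds = ["protein"] * p1 + ["metabolite"] * p2
    return SimilarityMatrix(acc, ids, kinds, signs)
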