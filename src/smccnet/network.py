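"""From a similarity matrix to trimmed, phenotype-summarized networks.

Modules are found by average-linkage hierarchical clustering on the
dissimilarity 1 - similarity, cutting the tree just below 1 so any connected
structure separates from the unconnected bulk. A module is trimmed at an
edge threshold tau, summarized by the first principal component of its
feature submatrix, and scored by the Pearson correlation of that PC1 with
the phenotype. The hyperparameter sweep reproduces the manual diagnostics
table: one row per (scaling constant, tau) with the correlation, node
counts, kind ratio and edge-weight summary, and a rule-based selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .smcca import (
    PenaltyPair,
    ScalingScheme,
    SimilarityMatrix,
    SubsampleScheme,
    build_similarity,
)


@dataclass
class NetworkModule:
    """A candidate feature module (indices into the similarity matrix)."""

    indices: np.ndarray
    feature_ids: list
    kinds: list

    def __post_init__(self) -> None:
        if len(self.indices) < 2:
            raise ValueError("a module needs at least 2 features")
        if len(set(self.indices.tolist())) != len(self.indices):
            raise ValueError("module indices must be unique")


@dataclass
class TrimmedNetwork:
    """A module after edge thresholding: signed edge list, degrees, counts."""

    node_indices: np.ndarray
    node_ids: list
    node_kinds: list
    edges: list  # (i, j, weight, sign) with i, j global similarity indices
    tau: float
    degrees: dict  # feature id -> degree
    n_proteins: int
    n_metabolites: int


@dataclass
class NetworkSummary:
    pc1_scores: np.ndarray
    rho: float
    p_value: float
    n_used: int
    variance_explained: float
    loadings: np.ndarray = field(default=None)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t transform,
    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


# --------------------------------------------------------------------------
# module extraction
# --------------------------------------------------------------------------
def extract_modules(
    sim: SimilarityMatrix,
    cut_height: float = 0.999,
    method: str = "average",
) -> tuple[list[NetworkModule], NetworkModule | list]:
    """Hierarchical clustering of features on D = 1 - similarity.

    Clusters of size >= 2 below the cut height become modules; everything
    else goes to the complement set. With a max-normalized similarity a cut
    just below 1 isolates any connected structure from the zero-similarity
    bulk. Deterministic for a fixed matrix.
    """
    S = sim.values
    p = S.shape[0]
    off = S[~np.eye(p, dtype=bool)]
    if not np.any(off):
        warnings.warn("all-zero similarity: no modules", RuntimeWarning)
        return [], list(range(p))
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=cut_height, criterion="distance")

    modules = []
    complement: list[int] = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if idx.size >= 2:
            modules.append(
                NetworkModule(
                    idx,
                    [sim.feature_ids[i] for i in idx],
                    [sim.kinds[i] for i in idx],
                )
            )
        else:
            complement.extend(idx.tolist())
    return modules, sorted(complement)


def trim_edges(module: NetworkModule, sim: SimilarityMatrix, tau: float) -> TrimmedNetwork:
    """Keep within-module edges with weight >= tau; drop isolated nodes."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    idx = module.indices
    S = sim.values
    edges = []
    max_avail = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = int(idx[a]), int(idx[b])
            w = float(S[i, j])
            max_avail = max(max_avail, w)
            if w >= tau:
                edges.append((i, j, w, int(sim.signs[i, j])))
    if not edges:
        raise ValueError(
            f"tau={tau} removes every edge (max available weight {max_avail:.6g})"
        )
    deg: dict[int, int] = {}
    for i, j, _, _ in edges:
        deg[i] = deg.get(i, 0) + 1
        deg[j] = deg.get(j, 0) + 1
    keep = np.array(sorted(deg), dtype=int)
    ids = [sim.feature_ids[i] for i in keep]
    kinds = [sim.kinds[i] for i in keep]
    return TrimmedNetwork(
        node_indices=keep,
        node_ids=ids,
        node_kinds=kinds,
        edges=edges,
        tau=tau,
        degrees={sim.feature_ids[i]: deg[i] for i in keep},
        n_proteins=sum(k == "protein" for k in kinds),
        n_metabolites=sum(k == "metabolite" for k in kinds),
    )


# --------------------------------------------------------------------------
# PC1 summary and per-node correlations
# --------------------------------------------------------------------------
def _pc1(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of a column-centered matrix.

    Returns (scores, loadings, variance fraction); the loading with largest
    magnitude (ties to lowest index) is made positive to fix the sign.
    """
    Xc = X - X.mean(axis=0)
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[0]
    i_star = int(np.argmax(np.abs(loadings)))
    if loadings[i_star] < 0:
        loadings = -loadings
        U = U.copy()
        U[:, 0] = -U[:, 0]
    scores = U[:, 0] * svals[0]
    var_frac = float(svals[0] ** 2 / np.sum(svals**2))
    return scores, loadings, var_frac


def summarize_network(
    net_or_features,
    X: pd.DataFrame,
    phenotype: pd.Series,
) -> NetworkSummary:
    """PC1 of the network's feature submatrix, correlated with the phenotype.

    Accepts a TrimmedNetwork, a NetworkModule, or a plain feature-id list.
    Subjects with missing phenotype are dropped pairwise from the
    correlation but still receive PC1 scores.
    """
    if isinstance(net_or_features, TrimmedNetwork):
        feats = net_or_features.node_ids
    elif isinstance(net_or_features, NetworkModule):
        feats = net_or_features.feature_ids
    else:
        feats = list(net_or_features)
    if len(feats) < 2:
        raise ValueError("need at least 2 network features")
    sub = X[feats].to_numpy(dtype=float)
    scores, loadings, var_frac = _pc1(sub)
    y = phenotype.reindex(X.index).to_numpy(dtype=float)
    keep = ~np.isnan(y)
    n_used = int(keep.sum())
    if n_used < 3:
        raise ValueError("fewer than 3 subjects with non-missing phenotype")
    r = float(np.corrcoef(scores[keep], y[keep])[0, 1])
    return NetworkSummary(
        pc1_scores=scores,
        rho=r,
        p_value=correlation_pvalue(r, n_used),
        n_used=n_used,
        variance_explained=var_frac,
        loadings=loadings,
    )


def node_correlations(
    net: TrimmedNetwork, X: pd.DataFrame, phenotype: pd.Series
) -> pd.DataFrame:
    """Per-node Pearson correlation with the phenotype (two-sided p)."""
    y = phenotype.reindex(X.index).to_numpy(dtype=float)
    keep = ~np.isnan(y)
    n_used = int(keep.sum())
    if n_used < 3:
        raise ValueError("fewer than 3 subjects with non-missing phenotype")
    rows = []
    for fid, kind in zip(net.node_ids, net.node_kinds):
        x = X[fid].to_numpy(dtype=float)[keep]
        r = float(np.corrcoef(x, y[keep])[0, 1])
        rows.append(
            {
                "feature_id": fid,
                "kind": kind,
                "r": r,
                "p_value": correlation_pvalue(r, n_used),
                "degree": net.degrees[fid],
            }
        )
    return pd.DataFrame(rows)


def hub_report(net: TrimmedNetwork) -> dict:
    """Nodes ranked by degree (descending, ties by feature id) and the
    single strongest edge."""
    if not net.edges:
        raise ValueError("empty network")
    ranked = sorted(net.degrees.items(), key=lambda kv: (-kv[1], str(kv[0])))
    i, j, w, sign = max(net.edges, key=lambda e: e[2])
    return {
        "ranked_nodes": ranked,
        "strongest_edge": {
            "source": net.node_ids[list(net.node_indices).index(i)],
            "target": net.node_ids[list(net.node_indices).index(j)],
            "weight": w,
            "sign": sign,
        },
    }


# --------------------------------------------------------------------------
# hyperparameter sweep (diagnostics table)
# --------------------------------------------------------------------------
@dataclass
class SweepResult:
    table: pd.DataFrame
    selected: Optional[tuple]  # (s, tau) or None
    similarity_by_s: dict
    module_by_s: dict
    complement_by_s: dict


def hyperparameter_sweep(
    X1: pd.DataFrame,
    X2: pd.DataFrame,
    y: pd.Series,
    s_values: Sequence[float],
    tau_values: Sequence[float],
    penalties: PenaltyPair,
    subsampling: SubsampleScheme,
    cut_height: float = 0.999,
    min_abs_rho: float = 0.20,
    ratio_band: tuple = (0.25, 4.0),
    rho_tolerance: float = 0.01,
) -> SweepResult:
    """Diagnostics over the (scaling constant, edge threshold) grid.

    For each s, a consensus similarity is built and the module with the
    largest untrimmed |PC1 correlation| is carried through every tau. The
    selected pair maximizes |rho| among rows with |rho| >= ``min_abs_rho``,
    both feature kinds present, and protein:metabolite ratio inside
    ``ratio_band``. Rows whose |rho| is within ``rho_tolerance`` of the
    maximum count as tied (differences far below the sampling error of a
    correlation cannot be ranked); among tied rows the selection prefers
    the longest plateau of constant node count across adjacent tau values
    (stability under adjacent hyperparameters), then larger tau (the
    sparser, stronger-edged network), then smaller s. Returns the full
    table even when nothing passes (with a warning).
    """
    if len(list(s_values)) == 0 or len(list(tau_values)) == 0:
        raise ValueError("both grids must be nonempty")
    combined = pd.concat([X1, X2], axis=1)
    rows = []
    sim_by_s: dict = {}
    mod_by_s: dict = {}
    comp_by_s: dict = {}
    yv = y.reindex(X1.index)
    for s in s_values:
        sim = build_similarity(
            X1.to_numpy(dtype=float),
            X2.to_numpy(dtype=float),
            np.nan_to_num(
                ((yv - yv.mean()) / yv.std(ddof=1)).to_numpy(dtype=float), nan=0.0
            ),
            ScalingScheme(s),
            penalties,
            subsampling,
            feature_ids_1=list(X1.columns),
            feature_ids_2=list(X2.columns),
        )
        sim_by_s[s] = sim
        modules, complement = extract_modules(sim, cut_height)
        comp_by_s[s] = complement
        if not modules:
            continue
        best_mod = max(
            modules,
            key=lambda m: abs(summarize_network(m, combined, yv).rho),
        )
        mod_by_s[s] = best_mod
        for tau in tau_values:
            try:
                net = trim_edges(best_mod, sim, tau)
            except ValueError:
                rows.append(
                    {
                        "s": s,
                        "tau": tau,
                        "rho": np.nan,
                        "abs_rho": np.nan,
                        "n_nodes": 0,
                        "n_proteins": 0,
                        "n_metabolites": 0,
                        "ratio": np.nan,
                        "n_edges": 0,
                        "min_edge": np.nan,
                        "median_edge": np.nan,
                        "max_edge": np.nan,
                    }
                )
                continue
            summ = summarize_network(net, combined, yv)
            weights = np.array([e[2] for e in net.edges])
            ratio = (
                net.n_proteins / net.n_metabolites
                if net.n_proteins and net.n_metabolites
                else np.nan
            )
            rows.append(
                {
                    "s": s,
                    "tau": tau,
                    "rho": summ.rho,
                    "abs_rho": abs(summ.rho),
                    "n_nodes": len(net.node_ids),
                    "n_proteins": net.n_proteins,
                    "n_metabolites": net.n_metabolites,
                    "ratio": ratio,
                    "n_edges": len(net.edges),
                    "min_edge": float(weights.min()),
                    "median_edge": float(np.median(weights)),
                    "max_edge": float(weights.max()),
                }
            )
    table = pd.DataFrame(rows)
    selected = None
    if len(table):
        ok = table[
            (table["abs_rho"] >= min_abs_rho)
            & (table["n_proteins"] > 0)
            & (table["n_metabolites"] > 0)
            & (table["ratio"] >= ratio_band[0])
            & (table["ratio"] <= ratio_band[1])
        ]
        if len(ok):
            # plateau length: consecutive taus (per s) with equal node count
            run_len = pd.Series(0, index=table.index)
            for s in table["s"].unique():
                sub = table[table["s"] == s].sort_values("tau")
                block = (sub["n_nodes"].diff() != 0).cumsum()
                sizes = block.map(block.value_counts())
                run_len.loc[sub.index] = sizes.to_numpy()
            near_best = ok[
                ok["abs_rho"] >= ok["abs_rho"].max() - rho_tolerance
            ].copy()
            near_best["run_len"] = run_len.loc[near_best.index]
            near_best = near_best.sort_values(
                ["run_len", "tau", "s"], ascending=[False, False, True]
            )
            best = near_best.iloc[0]
            selected = (float(best["s"]), float(best["tau"]))
    if selected is None:
        warnings.warn("no (s, tau) configuration passed the acceptance rules")
    return SweepResult(table, selected, sim_by_s, mod_by_s, comp_by_s)
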