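"""Clinical grading, sensitivity comparison and subgroup statistics.

Covers the downstream questions asked of a fitted network: GOLD/PRISm
spirometry grading and emphysema-severity binning of subjects; Fisher's
exact test for node overlap between the covariate-adjusted and unadjusted
networks; the dual per-feature significance rule (|r| > 0.15 and
Benjamini-Hochberg adjusted p < 0.001); and one-way ANOVA with Tukey's HSD
on the network PC1 across cohort subgroups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import correlation_pvalue

GOLD_STAGES = ("GOLD0", "GOLD1", "GOLD2", "GOLD3", "GOLD4", "PRISm", "MISSING")
EMPHYSEMA_BINS = ("control", "mild", "moderate", "severe")


# --------------------------------------------------------------------------
# clinical grading
# --------------------------------------------------------------------------
def classify_gold(fev1_pct: Optional[float], ratio: Optional[float]) -> str:
    """Spirometry grade from FEV1 percent-predicted and FEV1/FVC.

    GOLD0: FEV1 >= 80 and ratio >= 0.7 (no COPD); GOLD1-4 stratify FEV1
    (>=80, [50,80), [30,50), <30) at ratio < 0.7; PRISm is reduced FEV1
    (< 80) with preserved ratio (>= 0.7). Missing input gives MISSING.
    """
    if fev1_pct is None or ratio is None:
        return "MISSING"
    fev1_pct = float(fev1_pct)
    ratio = float(ratio)
    if math.isnan(fev1_pct) or math.isnan(ratio):
        return "MISSING"
    if ratio >= 0.7:
        return "GOLD0" if fev1_pct >= 80 else "PRISm"
    if fev1_pct >= 80:
        return "GOLD1"
    if fev1_pct >= 50:
        return "GOLD2"
    if fev1_pct >= 30:
        return "GOLD3"
    return "GOLD4"


def classify_gold_series(fev1_pct: pd.Series, ratio: pd.Series) -> pd.Series:
    aligned = ratio.reindex(fev1_pct.index)
    return pd.Series(
        [classify_gold(f, r) for f, r in zip(fev1_pct, aligned)],
        index=fev1_pct.index,
        name="gold_stage",
    )


def classify_emphysema_severity(pct: float) -> str:
    """Emphysema severity bins: [0,5) control, [5,10) mild, [10,20]
    moderate, (20, inf) severe — boundaries 5 and 10 go upward, 20 stays
    moderate so 'more than 20%' is strict."""
    pct = float(pct)
    if math.isnan(pct):
        raise ValueError("percent emphysema is missing")
    if pct < 0:
        raise ValueError(f"percent emphysema must be >= 0, got {pct}")
    if pct < 5:
        return "control"
    if pct < 10:
        return "mild"
    if pct <= 20:
        return "moderate"
    return "severe"


def heart_disease_composite(
    clinical: pd.DataFrame, indicator_columns: Sequence[str]
) -> pd.Series:
    """Boolean OR over the available self-report/CAC indicator columns;
    columns absent from the table are treated as false with a warning."""
    present = [c for c in indicator_columns if c in clinical.columns]
    absent = [c for c in indicator_columns if c not in clinical.columns]
    if absent:
        warnings.warn(f"missing heart-disease indicator columns: {absent}")
    if not present:
        return pd.Series(False, index=clinical.index, name="heart_disease")
    return clinical[present].fillna(0).astype(bool).any(axis=1)


# --------------------------------------------------------------------------
# adjusted vs unadjusted network overlap
# --------------------------------------------------------------------------
@dataclass
class OverlapTable:
    in_both: int
    adjusted_only: int
    unadjusted_only: int
    neither: int
    odds_ratio: float
    p_value: float
    alternative: str = "greater"

    @property
    def universe_size(self) -> int:
        return self.in_both + self.adjusted_only + self.unadjusted_only + self.neither


def compare_networks(
    adjusted_nodes: set, unadjusted_nodes: set, universe: set,
    alternative: str = "greater",
) -> OverlapTable:
    """2x2 node-overlap table with a one-sided Fisher enrichment test.

    The background universe is the set of features that entered the
    canonical-correlation stage; both node sets must be subsets of it.
    """
    adjusted_nodes = set(adjusted_nodes)
    unadjusted_nodes = set(unadjusted_nodes)
    universe = set(universe)
    outside = (adjusted_nodes | unadjusted_nodes) - universe
    if outside:
        raise ValueError(f"nodes outside the universe: {sorted(outside)}")
    a = len(adjusted_nodes & unadjusted_nodes)
    b = len(adjusted_nodes - unadjusted_nodes)
    c = len(unadjusted_nodes - adjusted_nodes)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return OverlapTable(a, b, c, d, float(odds), float(p), alternative)


# --------------------------------------------------------------------------
# per-feature significance with FDR
# --------------------------------------------------------------------------
def feature_significance(
    r_values: Sequence[float],
    n: int,
    feature_ids: Optional[Sequence] = None,
    r_threshold: float = 0.15,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Dual significance rule on per-feature phenotype correlations.

    Two-sided p from the t transform, Benjamini-Hochberg adjustment across
    features, significant iff |r| > r_threshold AND adjusted p < alpha.
    """
    r = np.asarray(r_values, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    p = np.array([correlation_pvalue(v, n) for v in r])
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    sig = (np.abs(r) > r_threshold) & (p_adj < alpha)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(r.size)]
    return pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "r": r,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": sig,
        }
    )


# --------------------------------------------------------------------------
# subgroup PC1 analysis
# --------------------------------------------------------------------------
@dataclass
class SubgroupResult:
    group_sizes: dict
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # one row per group pair: difference, adjusted p


def subgroup_pc1_analysis(
    pc1_scores: Sequence[float], group_labels: Sequence
) -> SubgroupResult:
    """One-way ANOVA on network PC1 across subgroups, then Tukey HSD.

    With exactly two groups the pairwise test is the pooled two-sample
    t-test (to which Tukey's HSD reduces); with more, adjusted pairwise
    p-values come from the studentized range distribution.
    """
    scores = np.asarray(pc1_scores, dtype=float)
    labels = pd.Series(list(group_labels))
    keep = ~np.isnan(scores) & labels.notna().to_numpy()
    scores, labels = scores[keep], labels[keep]
    groups = sorted(labels.unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [scores[(labels == g).to_numpy()] for g in groups]
    sizes = {g: int(s.size) for g, s in zip(groups, samples)}
    small = [g for g, s in zip(groups, samples) if s.size < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")

    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        f_stat, p = 0.0, 1.0  # all values identical: no between- or within-variance
    else:
        f_stat, p = stats.f_oneway(*samples)

    rows = []
    if len(groups) == 2:
        t, pt = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        rows.append(
            {
                "group_a": groups[0],
                "group_b": groups[1],
                "difference": float(np.mean(samples[0]) - np.mean(samples[1])),
                "p_adjusted": float(pt),
            }
        )
    else:
        res = stats.tukey_hsd(*samples)
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                rows.append(
                    {
                        "group_a": groups[a],
                        "group_b": groups[b],
                        "difference": float(
                            np.mean(samples[a]) - np.mean(samples[b])
                        ),
                        "p_adjusted": float(res.pvalue[a, b]),
                    }
                )
    return SubgroupResult(sizes, float(f_stat), float(p), pd.DataFrame(rows))
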