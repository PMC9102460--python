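"""Pairwise stage differential expression on raw counts.

Replicates of each stage are pooled by summation and compared with a
two-proportion z-test under the pooled binomial null, the modelling
assumption of count-sampling DE tools for unreplicated library pairs.
Benjamini-Hochberg controls the FDR within each comparison; the screen
keeps transcripts with fold change >= fc_min and adjusted p <= alpha.
An exact binomial test is available for small pooled counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .types import ExpressionMatrix


@dataclass
class DEResult:
    transcript_id: str
    comparison: tuple[int, int]
    log2fc: float
    z: float
    p: float
    p_adj: float
    direction: str
    significant: bool


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-dimensional")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def de_test(counts: ExpressionMatrix, a: int, b: int, fc_min: float = 2.0,
            alpha: float = 0.001, pseudocount: float = 1.0,
            exact: bool = False) -> list[DEResult]:
    """Differential expression of stage b relative to stage a.

    Pools replicate counts into C_a, C_b with library sizes N_a, N_b;
    log2fc = log2((C_b+c0)/N_b) - log2((C_a+c0)/N_a) with pseudocount c0
    applied to the fold change only. The test statistic is the pooled
    two-proportion z (or an exact two-sided binomial when ``exact``);
    p-values are BH-adjusted across all transcripts of the comparison.
    """
    if counts.unit != "counts":
        raise ValueError("de_test requires raw counts")
    cols_a = counts.samples_of_stage(a)
    cols_b = counts.samples_of_stage(b)
    C_a = counts.values[cols_a].sum(axis=1).to_numpy()
    C_b = counts.values[cols_b].sum(axis=1).to_numpy()
    N_a, N_b = C_a.sum(), C_b.sum()
    if N_a == 0 or N_b == 0:
        raise ValueError("zero library size in one stage")

    log2fc = np.log2((C_b + pseudocount) / N_b) - np.log2((C_a + pseudocount) / N_a)

    if exact:
        # conditional on the pooled total, C_b ~ Binomial(C_a + C_b, N_b/(N_a+N_b)) under the null
        p = np.array([
            stats.binomtest(int(cb), int(ca + cb), N_b / (N_a + N_b)).pvalue if ca + cb > 0 else 1.0
            for ca, cb in zip(C_a, C_b)
        ])
        z = np.zeros_like(p)
    else:
        pooled = (C_a + C_b) / (N_a + N_b)
        denom = np.sqrt(pooled * (1.0 - pooled) * (1.0 / N_a + 1.0 / N_b))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (C_b / N_b - C_a / N_a) / denom
        z = np.nan_to_num(z)
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, 0.0, 1.0)

    p_adj = bh_adjust(p)
    lfc_cut = np.log2(fc_min)
    results = []
    for i, tid in enumerate(counts.values.index):
        sig = bool(abs(log2fc[i]) >= lfc_cut and p_adj[i] <= alpha)
        results.append(DEResult(
            transcript_id=tid,
            comparison=(a, b),
            log2fc=float(log2fc[i]),
            z=float(z[i]),
            p=float(p[i]),
            p_adj=float(p_adj[i]),
            direction="up" if log2fc[i] > 0 else "down",
            significant=sig,
        ))
    return results


def significant_ids(results: list[DEResult]) -> set[str]:
    return {r.transcript_id for r in results if r.significant}


def comparison_sets(results_by_comparison: dict[str, list[DEResult]]) -> dict:
    """Up/down tallies per comparison and intersection sizes over comparisons.

    Returns per-comparison counts (significant, up, down, percentages at one
    decimal) plus, for every subset of >= 2 comparisons, both the plain
    intersection cardinality and the exclusive (Venn-partition) cardinality.
    """
    if not results_by_comparison:
        raise ValueError("at least one comparison required")
    tallies = {}
    sig_sets = {}
    for name, results in results_by_comparison.items():
        sig = [r for r in results if r.significant]
        up = sum(1 for r in sig if r.direction == "up")
        down = len(sig) - up
        sig_sets[name] = {r.transcript_id for r in sig}
        tallies[name] = {
            "n_significant": len(sig),
            "n_up": up,
            "n_down": down,
            "up_pct": round(100.0 * up / len(sig), 1) if sig else 0.0,
            "down_pct": round(100.0 * down / len(sig), 1) if sig else 0.0,
        }
    names = sorted(sig_sets)
    intersections = {}
    exclusive = {}
    universe = set().union(*sig_sets.values()) if sig_sets else set()
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(sig_sets[c] for c in combo))
            intersections[combo] = len(inter)
            others = [sig_sets[c] for c in names if c not in combo]
            excl = inter - set().union(*others) if others else inter
            exclusive[combo] = len(excl)
    return {
        "tallies": tallies,
        "intersections": intersections,
        "exclusive": exclusive,
        "n_union": len(universe),
    }


@dataclass
class ClusterAssignment:
    transcript_id: str
    cluster: int
    profile: np.ndarray
    constant: bool = False


def kmeans_profiles(expr: ExpressionMatrix, dels: set[str], k: int = 6,
                    seed: int = 0) -> list[ClusterAssignment]:
    """K-means on standardized per-stage mean log2(FPKM+1) profiles.

    Profiles are z-scored across stages (constant profiles are centered
    only and flagged); Euclidean k-means++ with 50 restarts; cluster labels
    renumbered 1..k by descending cluster size for determinism.
    """
    if not dels:
        raise ValueError("empty transcript set")
    ids = sorted(dels)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of transcripts ({len(ids)})")
    sub = expr.subset(ids)
    means = np.log2(sub.stage_means().to_numpy() + 1.0)
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    profiles = means - mu
    nz = ~constant
    profiles[nz] = profiles[nz] / sd[nz]

    km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
    labels = km.fit_predict(profiles)
    # renumber by descending size; ties by smallest member id for determinism
    sizes = {lab: ((labels == lab).sum(), min(ids[i] for i in np.flatnonzero(labels == lab)))
             for lab in range(k)}
    order = sorted(sizes, key=lambda lab: (-sizes[lab][0], sizes[lab][1]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return [
        ClusterAssignment(tid, remap[lab], profiles[i], bool(constant[i]))
        for i, (tid, lab) in enumerate(zip(ids, labels))
    ]


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.transcript_id, f"S{r.comparison[0]}_vs_S{r.comparison[1]}", r.log2fc, r.z,
          r.p, r.p_adj, r.direction, r.significant) for r in results],
        columns=["transcript_id", "comparison", "log2fc", "z", "p", "p_adj",
                 "direction", "significant"],
    )
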