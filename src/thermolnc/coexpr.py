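"""Lightweight weighted co-expression network analysis.

Unsigned adjacency a_ij = |cor(x_i, x_j)|^beta over log-expression
profiles, topological overlap similarity, average-linkage hierarchical
module detection with a static cut, module eigengenes (first principal
component), module-trait correlation, and hub / trans-target extraction
via kME (member-eigengene correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import ExpressionMatrix, TraitVector

# canonical module color sequence, assigned by descending module size
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
)


@dataclass
class SoftThreshold:
    beta: int
    scale_free_r2: float
    mean_connectivity: float


@dataclass
class CoexprModule:
    module_id: str
    members: tuple[str, ...]
    eigengene: np.ndarray | None = None
    trait_cor: float = np.nan
    trait_p: float = np.nan
    hubs: list[tuple[str, float]] = field(default_factory=list)


def _log_profiles(expr: ExpressionMatrix) -> pd.DataFrame:
    vals = expr.values
    if expr.unit == "FPKM":
        return np.log2(vals + 1.0)
    return np.log2(vals + 1.0)


def correlation_matrix(expr: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Pairwise Pearson correlation of log2(x+1) profiles across samples.

    Zero-variance transcripts are excluded (their correlation is undefined).
    """
    prof = _log_profiles(expr)
    sd = prof.std(axis=1)
    keep = sd[sd > 0].index.tolist()
    mat = prof.loc[keep].to_numpy(float)
    cor = np.corrcoef(mat)
    return np.clip(cor, -1.0, 1.0), keep


def adjacency(cor: np.ndarray, beta: int, network_type: str = "signed") -> np.ndarray:
    """Soft-threshold adjacency with zero diagonal.

    signed (default): ((1 + cor)/2)^beta, which keeps anti-correlated
    transcripts apart; unsigned: |cor|^beta, which identifies a profile with
    its mirror image.
    """
    if network_type == "signed":
        a = ((1.0 + cor) / 2.0) ** beta
    elif network_type == "unsigned":
        a = np.abs(cor) ** beta
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) on log10 k over connectivity bins (scale-free fit)."""
    k = connectivity[connectivity > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    res = stats.linregress(xs, ys)
    return float(res.rvalue ** 2)


def pick_beta(expr: ExpressionMatrix, candidates=range(1, 21),
              r2_min: float = 0.8, network_type: str = "signed") -> SoftThreshold:
    """Smallest beta whose network fits scale-free topology at R^2 >= r2_min.

    When no candidate reaches the threshold (common on data without a
    scale-free backbone), falls back with a warning to the canonical default
    power for the network type (12 signed / 6 unsigned), reporting the R^2
    achieved there.
    """
    cor, keep = correlation_matrix(expr)
    if len(keep) < 3:
        raise ValueError("need at least 3 transcripts with non-constant profiles")
    if expr.values.shape[1] < 8:
        raise ValueError("need at least 8 samples")
    by_beta = {}
    for beta in candidates:
        a = adjacency(cor, beta, network_type)
        k = a.sum(axis=1)
        r2 = scale_free_r2(k)
        st = SoftThreshold(beta=int(beta), scale_free_r2=r2, mean_connectivity=float(k.mean()))
        if r2 >= r2_min:
            return st
        by_beta[int(beta)] = st
    fallback = 12 if network_type == "signed" else 6
    best_r2 = max(by_beta.values(), key=lambda s: s.scale_free_r2)
    st = by_beta.get(fallback, best_r2)
    warnings.warn(
        f"no soft threshold reached R^2 >= {r2_min} (best R^2 = "
        f"{best_r2.scale_free_r2:.3f} at beta={best_r2.beta}); "
        f"falling back to beta={st.beta}"
    )
    return st


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap: w_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    Requires a symmetric adjacency with zero diagonal and entries in [0,1];
    l_ij = sum_u a_iu a_uj. The diagonal of the result is defined as 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must be in [0, 1]")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    w = (l + a) / denom
    np.fill_diagonal(w, 1.0)
    return np.clip(w, 0.0, 1.0)


def detect_modules(tom: np.ndarray, ids: list[str], min_size: int = 10,
                   cut_height: float = 0.97) -> dict[str, str]:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than min_size fall into 'grey'; surviving modules are
    labelled by descending size with the canonical color sequence (ties
    broken by lexicographically smallest member id).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    n = len(ids)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match ids")
    # order-invariance: cluster in lexicographic id order
    order = np.argsort(np.asarray(ids, dtype=object))
    ids_sorted = [ids[i] for i in order]
    diss = 1.0 - tom[np.ix_(order, order)]
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for tid, lab in zip(ids_sorted, labels):
        clusters.setdefault(int(lab), []).append(tid)
    surviving = [mem for mem in clusters.values() if len(mem) >= min_size]
    surviving.sort(key=lambda mem: (-len(mem), min(mem)))
    assignment = {tid: "grey" for tid in ids}
    for rank, members in enumerate(surviving):
        color = (COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE)
                 else f"module{rank + 1}")
        for tid in members:
            assignment[tid] = color
    return assignment


def _standardized(expr: ExpressionMatrix, members) -> tuple[np.ndarray, list[str]]:
    prof = _log_profiles(expr).loc[list(members)]
    mat = prof.to_numpy(float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    mat = (mat[keep] - mu[keep]) / sd[keep]
    return mat, [m for m, k in zip(prof.index, keep) if k]


def eigengene(expr: ExpressionMatrix, members) -> np.ndarray:
    """First principal component of the module's standardized expression.

    Scaled to unit variance; sign chosen so the eigengene correlates
    positively with the module's mean standardized profile. A single-member
    module returns that member's standardized profile.
    """
    members = list(members)
    if not members:
        raise ValueError("empty module")
    mat, kept = _standardized(expr, members)
    if mat.shape[0] == 0:
        raise ValueError("all members have constant profiles")
    if mat.shape[0] == 1:
        return mat[0]
    # samples x members
    X = mat.T
    _u, _s, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    pc1 = (X - X.mean(axis=0)) @ vt[0]
    pc1 = pc1 / pc1.std(ddof=1)
    mean_profile = mat.mean(axis=0)
    if np.corrcoef(pc1, mean_profile)[0, 1] < 0:
        pc1 = -pc1
    return pc1


def module_trait(modules: list[CoexprModule], trait: TraitVector,
                 design: dict[str, tuple[int, int]], samples: list[str],
                 alpha: float = 0.05) -> list[CoexprModule]:
    """Pearson correlation of each eigengene with the per-sample trait.

    The stage-level trait is expanded to samples by repeating each stage's
    value across its replicates; two-sided p from the t-distribution with
    n - 2 df. Modules are flagged significant at p <= alpha via trait_p.
    """
    t = trait.per_sample(design, samples)
    if np.std(t) == 0:
        raise ValueError("constant trait")
    for mod in modules:
        if mod.eigengene is None:
            raise ValueError(f"module {mod.module_id}: eigengene not computed")
        res = stats.pearsonr(mod.eigengene, t)
        mod.trait_cor = float(res.statistic)
        mod.trait_p = float(res.pvalue)
    return modules


def hubs_and_trans_targets(expr: ExpressionMatrix, module: CoexprModule,
                           biotype: dict[str, str], kme_min: float = 0.9,
                           top_n: int = 10) -> tuple[list[tuple[str, float]],
                                                     list[tuple[str, str]]]:
    """kME-ranked hubs and lncRNA->mRNA trans pairs within one module.

    kME_i = cor(x_i, eigengene); hubs are members with kME >= kme_min capped
    at top_n; a trans pair is declared for every lncRNA l and mRNA m in the
    module with both kMEs >= kme_min.
    """
    mat, kept = _standardized(expr, module.members)
    kme = {}
    for row, tid in zip(mat, kept):
        kme[tid] = float(np.corrcoef(row, module.eigengene)[0, 1])
    ranked = sorted(kme.items(), key=lambda kv: (-kv[1], kv[0]))
    hubs = [(t, v) for t, v in ranked if v >= kme_min][:top_n]
    module.hubs = hubs
    lncs = sorted(t for t, v in kme.items() if v >= kme_min and biotype.get(t) == "lncRNA")
    mrnas = sorted(t for t, v in kme.items() if v >= kme_min and biotype.get(t) == "mRNA")
    trans_pairs = [(l, m) for l in lncs for m in mrnas]
    return hubs, trans_pairs


def run_wgcna(expr: ExpressionMatrix, trait: TraitVector | None = None,
              beta: int | None = None, r2_min: float = 0.8, min_size: int = 10,
              cut_height: float = 0.97, kme_min: float = 0.9,
              biotype: dict[str, str] | None = None,
              network_type: str = "signed") -> dict:
    """Full co-expression pass: beta -> adjacency -> TOM -> modules -> eigengenes.

    Returns modules (grey excluded), the grey member list, the chosen soft
    threshold, and lncRNA->mRNA trans-target pairs over all modules.
    """
    cor, ids = correlation_matrix(expr)
    if beta is None:
        st = pick_beta(expr, r2_min=r2_min, network_type=network_type)
    else:
        st = SoftThreshold(beta=int(beta), scale_free_r2=np.nan, mean_connectivity=np.nan)
    a = adjacency(cor, st.beta, network_type)
    tom = tom_similarity(a)
    assignment = detect_modules(tom, ids, min_size=min_size, cut_height=cut_height)
    colors = sorted({c for c in assignment.values() if c != "grey"},
                    key=lambda c: COLOR_SEQUENCE.index(c) if c in COLOR_SEQUENCE else 99)
    modules = []
    samples = list(expr.values.columns)
    for color in colors:
        members = tuple(sorted(t for t, c in assignment.items() if c == color))
        mod = CoexprModule(module_id=color, members=members)
        mod.eigengene = eigengene(expr, members)
        modules.append(mod)
    if trait is not None and modules:
        module_trait(modules, trait, expr.design, samples)
    trans_pairs = []
    if biotype:
        for mod in modules:
            _, pairs = hubs_and_trans_targets(expr, mod, biotype, kme_min=kme_min)
            trans_pairs.extend((mod.module_id, l, m) for l, m in pairs)
    return {
        "soft_threshold": st,
        "assignment": assignment,
        "modules": modules,
        "grey": sorted(t for t, c in assignment.items() if c == "grey"),
        "trans_pairs": trans_pairs,
    }
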