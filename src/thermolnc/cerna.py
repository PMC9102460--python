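"""lncRNA-miRNA-mRNA (ceRNA / endogenous-target-mimic) network inference.

For every lncRNA-mRNA pair sharing at least ``min_shared`` miRNAs, the
significance of the overlap is the hypergeometric upper tail
P(X >= k) with population N = all miRNAs in the table, K = miRNAs
targeting the lncRNA and n = miRNAs targeting the mRNA; p-values are
BH-corrected across all tested pairs and pairs at FDR <= fdr_max expand
into one eTM record per shared miRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .diffexpr import bh_adjust


@dataclass
class TargetTable:
    """miRNA-target interactions plus the transcript biotype map."""

    mirnas_of: dict[str, set[str]]  # transcript -> set of targeting miRNAs
    mirna_universe: set[str]
    transcript_type: dict[str, str]
    interactions: pd.DataFrame | None = None  # (mirna_id, transcript_id, score)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, transcript_type: dict[str, str]) -> "TargetTable":
        if df.duplicated(["mirna_id", "transcript_id"]).any():
            raise ValueError("duplicate (miRNA, transcript) interaction")
        mirnas_of: dict[str, set[str]] = {}
        universe = set()
        for mir, tid in zip(df["mirna_id"], df["transcript_id"]):
            mirnas_of.setdefault(str(tid), set()).add(str(mir))
            universe.add(str(mir))
        return cls(mirnas_of=mirnas_of, mirna_universe=universe,
                   transcript_type=dict(transcript_type),
                   interactions=df.reset_index(drop=True))

    def degree_summary(self) -> pd.DataFrame:
        """Per-miRNA target counts: total, lncRNA targets, mRNA targets."""
        rows: dict[str, list[int]] = {m: [0, 0, 0] for m in self.mirna_universe}
        for tid, mirs in self.mirnas_of.items():
            ttype = self.transcript_type.get(tid)
            for m in mirs:
                rows[m][0] += 1
                if ttype == "lncRNA":
                    rows[m][1] += 1
                elif ttype == "mRNA":
                    rows[m][2] += 1
        return pd.DataFrame(
            [(m, *rows[m]) for m in sorted(rows)],
            columns=["mirna_id", "n_targets", "n_lncrna_targets", "n_mrna_targets"],
        )


@dataclass
class CeRNAPair:
    lncrna_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    k_shared: int
    K_lnc: int
    n_mrna: int
    N: int
    p: float | None = None  # None while untested (k_shared below the gate)
    fdr: float | None = None
    significant: bool = False


@dataclass
class ETMRecord:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    pair_fdr: float


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable log-space summation."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    k_min = max(0, K + n - N)
    k_max = min(K, n)
    if k <= k_min:
        return 1.0
    if k > k_max:
        return 0.0
    # scalar lgamma keeps the summation in log space without array overhead
    log_denom = lgamma(N + 1) - lgamma(n + 1) - lgamma(N - n + 1)
    logs = [
        lgamma(K + 1) - lgamma(j + 1) - lgamma(K - j + 1)
        + lgamma(N - K + 1) - lgamma(n - j + 1) - lgamma(N - K - n + j + 1)
        - log_denom
        for j in range(k, k_max + 1)
    ]
    m = max(logs)
    return min(1.0, math.exp(m) * sum(math.exp(v - m) for v in logs))


def shared_mirna_test(table: TargetTable, lncrna: str, mrna: str,
                      min_shared: int = 3) -> CeRNAPair:
    """Hypergeometric shared-miRNA enrichment for one lncRNA-mRNA pair.

    Pairs sharing fewer than min_shared miRNAs are returned untested
    (p is None). Raises if either transcript has no interaction in the table.
    """
    for tid in (lncrna, mrna):
        if tid not in table.mirnas_of:
            raise ValueError(f"transcript {tid!r} absent from target table")
    set_l = table.mirnas_of[lncrna]
    set_m = table.mirnas_of[mrna]
    shared = frozenset(set_l & set_m)
    pair = CeRNAPair(
        lncrna_id=lncrna, mrna_id=mrna, shared_mirnas=shared, k_shared=len(shared),
        K_lnc=len(set_l), n_mrna=len(set_m), N=len(table.mirna_universe),
    )
    if pair.k_shared >= min_shared:
        pair.p = hypergeom_tail(pair.k_shared, pair.N, pair.K_lnc, pair.n_mrna)
    return pair


def build_network(table: TargetTable, lncrna_set=None, mrna_set=None,
                  min_shared: int = 3, fdr_max: float = 0.05
                  ) -> tuple[list[CeRNAPair], list[ETMRecord], pd.DataFrame]:
    """Test all lncRNA x mRNA pairs with >= min_shared shared miRNAs.

    BH FDR is applied jointly across all tested pairs; each significant pair
    expands into one ETMRecord per shared miRNA. Also returns the per-miRNA
    target-degree summary.
    """
    if not table.mirna_universe:
        raise ValueError("empty miRNA universe")
    if lncrna_set is None:
        lncrna_set = {t for t, b in table.transcript_type.items() if b == "lncRNA"}
    if mrna_set is None:
        mrna_set = {t for t, b in table.transcript_type.items() if b == "mRNA"}
    lncs = sorted(t for t in lncrna_set if t in table.mirnas_of)
    mrnas = sorted(t for t in mrna_set if t in table.mirnas_of)

    # invert index: only pairs co-targeted by some miRNA can share any
    by_mir: dict[str, tuple[list[str], list[str]]] = {}
    for tid in lncs:
        for m in table.mirnas_of[tid]:
            by_mir.setdefault(m, ([], []))[0].append(tid)
    for tid in mrnas:
        for m in table.mirnas_of[tid]:
            by_mir.setdefault(m, ([], []))[1].append(tid)
    shared_count: dict[tuple[str, str], int] = {}
    for m, (ls, ms) in by_mir.items():
        for l in ls:
            for r in ms:
                key = (l, r)
                shared_count[key] = shared_count.get(key, 0) + 1

    tested = []
    for (l, r), k in sorted(shared_count.items()):
        if k >= min_shared:
            tested.append(shared_mirna_test(table, l, r, min_shared=min_shared))
    if tested:
        fdrs = bh_adjust([p.p for p in tested])
        for pair, q in zip(tested, fdrs):
            pair.fdr = float(q)
            pair.significant = bool(q <= fdr_max)

    etms = []
    for pair in tested:
        if pair.significant:
            for mir in sorted(pair.shared_mirnas):
                etms.append(ETMRecord(pair.lncrna_id, mir, pair.mrna_id, pair.fdr))
    return tested, etms, table.degree_summary()


_RNA_TO_DNA = str.maketrans("ACGUTacgut", "ACGTTACGTT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize(seq: str, name: str) -> str:
    s = seq.translate(_RNA_TO_DNA)
    if not set(s) <= set("ACGT"):
        bad = sorted(set(s) - set("ACGT"))
        raise ValueError(f"{name}: invalid characters {bad}")
    return s


def seed_match_targets(mirnas: dict[str, str], transcripts: dict[str, str],
                       transcript_type: dict[str, str] | None = None,
                       seed_start: int = 2, seed_end: int = 8) -> TargetTable:
    """Seed-complementarity target scorer (stand-in for full duplex scoring).

    An interaction is recorded iff the reverse complement of the miRNA seed
    (positions seed_start..seed_end, 1-based from the 5' end) occurs in the
    transcript; the score is the number of distinct match sites. T/U are
    normalized; no G:U wobble pairing.
    """
    rows = []
    for mir_id in sorted(mirnas):
        mseq = _normalize(mirnas[mir_id], mir_id)
        if len(mseq) < seed_end:
            raise ValueError(f"{mir_id}: miRNA shorter than {seed_end} nt")
        seed = mseq[seed_start - 1:seed_end]
        site = seed.translate(_COMPLEMENT)[::-1]
        for tid in sorted(transcripts):
            tseq = _normalize(transcripts[tid], tid)
            count = start = 0
            while True:
                pos = tseq.find(site, start)
                if pos < 0:
                    break
                count += 1
                start = pos + 1
            if count > 0:
                rows.append((mir_id, tid, count))
    df = pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "score"])
    universe = set(mirnas)
    mirnas_of: dict[str, set[str]] = {}
    for mir, tid, _ in rows:
        mirnas_of.setdefault(tid, set()).add(mir)
    return TargetTable(mirnas_of=mirnas_of, mirna_universe=universe,
                       transcript_type=dict(transcript_type or {}),
                       interactions=df)


def pairs_to_frame(pairs: list[CeRNAPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.lncrna_id, p.mrna_id, ";".join(sorted(p.shared_mirnas)), p.k_shared,
          p.K_lnc, p.n_mrna, p.N, p.p, p.fdr, p.significant) for p in pairs],
        columns=["lncrna_id", "mrna_id", "shared_mirnas", "k_shared", "K_lnc",
                 "n_mrna", "N", "p", "fdr", "significant"],
    )
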