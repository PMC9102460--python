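"""Consensus lncRNA/mRNA classification and transcript characterization.

Four coding-potential evidence channels (CPC score, CNCI score,
txCdsPredict score, protein-domain hit) each cast a coding/noncoding vote;
a transcript is confirmed as lncRNA or mRNA only when at least
``votes_required`` channels agree, otherwise it stays ``uncertain``.
Stage-presence profiling classifies each transcript by which stages its
mean FPKM clears a floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, TranscriptRecord

EVIDENCE_COLUMNS = ["transcript_id", "cpc_score", "cnci_score", "txcds_score", "pfam_hit"]


@dataclass
class VoteThresholds:
    """Per-channel cutoffs; a score strictly below its cut votes noncoding."""

    cpc_cut: float = 0.0
    cnci_cut: float = 0.0
    txcds_cut: float = 500.0
    votes_required: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.votes_required <= 4:
            raise ValueError("votes_required must be in 1..4")


def vote_biotype(evidence: pd.Series | dict, thresholds: VoteThresholds | None = None) -> str:
    """Classify one transcript from its four-channel evidence row.

    Channel votes: cpc < cpc_cut, cnci < cnci_cut, txcds < txcds_cut and
    pfam_hit == False each vote noncoding (converse votes coding); scores
    exactly at a cut vote coding. >= votes_required noncoding -> 'lncRNA',
    >= votes_required coding -> 'mRNA', otherwise 'uncertain'.
    """
    thresholds = thresholds or VoteThresholds()
    for col in ("cpc_score", "cnci_score", "txcds_score", "pfam_hit"):
        v = evidence[col]
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            raise ValueError(f"missing or non-finite evidence channel {col!r}")
    noncoding = (
        int(evidence["cpc_score"] < thresholds.cpc_cut)
        + int(evidence["cnci_score"] < thresholds.cnci_cut)
        + int(evidence["txcds_score"] < thresholds.txcds_cut)
        + int(not bool(evidence["pfam_hit"]))
    )
    if noncoding >= thresholds.votes_required:
        return "lncRNA"
    if 4 - noncoding >= thresholds.votes_required:
        return "mRNA"
    return "uncertain"


def classify_all(evidence: pd.DataFrame, thresholds: VoteThresholds | None = None) -> pd.Series:
    """Vectorized consensus vote over an evidence table; index = transcript id."""
    thresholds = thresholds or VoteThresholds()
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table missing columns {missing}")
    scores = evidence[["cpc_score", "cnci_score", "txcds_score"]].to_numpy(float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite score in evidence table")
    if evidence["pfam_hit"].isna().any():
        raise ValueError("missing pfam_hit in evidence table")
    noncoding = (
        (evidence["cpc_score"] < thresholds.cpc_cut).astype(int)
        + (evidence["cnci_score"] < thresholds.cnci_cut).astype(int)
        + (evidence["txcds_score"] < thresholds.txcds_cut).astype(int)
        + (~evidence["pfam_hit"].astype(bool)).astype(int)
    )
    out = pd.Series("uncertain", index=evidence["transcript_id"], name="biotype")
    out[(noncoding >= thresholds.votes_required).to_numpy()] = "lncRNA"
    out[((4 - noncoding) >= thresholds.votes_required).to_numpy()] = "mRNA"
    return out


def length_filter(records: list[TranscriptRecord], min_len: int = 200) -> list[TranscriptRecord]:
    """Keep only transcripts strictly longer than min_len nt (lncRNA gate)."""
    return [r for r in records if r.length > min_len]


@dataclass
class StagePresence:
    transcript_id: str
    present: tuple[bool, ...]
    category: str  # 'all-stages' | 'stage-specific(k)' | 'partial' | 'absent'


def _categorize(present: tuple[bool, ...]) -> str:
    n_true = sum(present)
    if n_true == len(present):
        return "all-stages"
    if n_true == 1:
        k = present.index(True) + 1
        return f"stage-specific({k})"
    if n_true == 0:
        return "absent"
    return "partial"


def stage_presence(expr: ExpressionMatrix, floor: float = 0.5) -> list[StagePresence]:
    """Presence of each transcript per stage: mean FPKM over replicates >= floor."""
    if expr.unit != "FPKM":
        raise ValueError("stage presence is defined on FPKM (got counts)")
    means = expr.stage_means()
    out = []
    for tid in expr.values.index:
        present = tuple(bool(means.loc[tid, s] >= floor) for s in means.columns)
        out.append(StagePresence(tid, present, _categorize(present)))
    return out


def presence_summary(presences: list[StagePresence]) -> dict:
    """Counts per category plus the all-stages / non-all-stages percentages.

    Percentages are over transcripts present in at least one stage and are
    rounded to 2 decimals.
    """
    counts: dict[str, int] = {}
    for p in presences:
        counts[p.category] = counts.get(p.category, 0) + 1
    expressed = sum(n for cat, n in counts.items() if cat != "absent")
    all_stages = counts.get("all-stages", 0)
    summary = {
        "counts": counts,
        "n_expressed": expressed,
        "n_all_stages": all_stages,
    }
    if expressed:
        summary["all_stages_pct"] = round(100.0 * all_stages / expressed, 2)
        summary["non_all_stages_pct"] = round(100.0 * (expressed - all_stages) / expressed, 2)
    return summary


def characterize(records: list[TranscriptRecord],
                 expr: ExpressionMatrix | None = None) -> dict[str, pd.DataFrame]:
    """Per-biotype summaries: length bins, exon counts, isoforms per gene, expression.

    Length bins follow the short/long contrast between candidate classes:
    <=200, 201-500, >500 nt (bin edges recorded in the table itself).
    """
    rows = []
    for r in records:
        rows.append((r.transcript_id, r.gene_id, r.biotype, r.length, r.n_exons))
    df = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype", "length", "n_exons"])

    bins = [0, 200, 500, np.inf]
    labels = ["<=200", "201-500", ">500"]
    df["length_bin"] = pd.cut(df["length"], bins=bins, labels=labels)
    length_hist = (
        df.groupby(["biotype", "length_bin"], observed=False).size().unstack(fill_value=0)
    )
    exon_dist = df.groupby(["biotype", "n_exons"]).size().unstack(fill_value=0)
    per_gene = (
        df.groupby(["biotype", "gene_id"]).size().rename("n_transcripts").reset_index()
        .groupby(["biotype", "n_transcripts"]).size().unstack(fill_value=0)
    )
    out = {"length_hist": length_hist, "exon_dist": exon_dist, "transcripts_per_gene": per_gene}

    if expr is not None:
        med = expr.values.mean(axis=1)
        df2 = df.set_index("transcript_id")
        df2 = df2[df2.index.isin(med.index)]
        expr_summary = (
            pd.DataFrame({"biotype": df2["biotype"], "mean_expr": med[df2.index]})
            .groupby("biotype")["mean_expr"].describe()
        )
        out["expression"] = expr_summary
        out["median_length"] = df.groupby("biotype")["length"].median().to_frame("median_length")
    return out
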