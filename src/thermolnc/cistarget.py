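"""Cis target assignment: genomic window search plus a dual correlation gate.

A protein-coding gene's cis window spans from ``up_bp`` before its
strand-aware start to ``down_bp`` after its strand-aware end; any lncRNA
whose span intersects the window on the same chromosome is a candidate.
Candidates are kept when both Spearman and Pearson correlations of the
lncRNA with the gene's expression clear one-sided positive thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import ExpressionMatrix, TranscriptRecord

log = logging.getLogger(__name__)


@dataclass
class GeneSpan:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: tuple[str, ...]


@dataclass
class CisPair:
    lncrna_id: str
    gene_id: str
    signed_distance: int  # 0 if overlapping; negative = lncRNA upstream of the gene
    relation: str  # 'upstream' | 'downstream' | 'overlapping'
    same_strand: bool
    spearman: float = np.nan
    pearson: float = np.nan


def gene_spans(records: list[TranscriptRecord], biotype: str = "mRNA") -> list[GeneSpan]:
    """Collapse transcripts of the given biotype to gene-level hull spans."""
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for r in records:
        if r.biotype == biotype:
            by_gene.setdefault(r.gene_id, []).append(r)
    spans = []
    for gid in sorted(by_gene):
        recs = by_gene[gid]
        chroms = {r.chrom for r in recs}
        strands = {r.strand for r in recs}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gid}: transcripts on multiple chromosomes/strands")
        spans.append(GeneSpan(
            gene_id=gid,
            chrom=recs[0].chrom,
            start=min(r.start for r in recs),
            end=max(r.end for r in recs),
            strand=recs[0].strand,
            transcripts=tuple(sorted(r.transcript_id for r in recs)),
        ))
    return spans


def _window(gene: GeneSpan, up_bp: int, down_bp: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.start - up_bp, gene.end + down_bp
    return gene.start - down_bp, gene.end + up_bp


def _classify_pair(lnc: TranscriptRecord, gene: GeneSpan) -> tuple[int, str]:
    """Signed gap distance (closest edges) and strand-aware relation."""
    if lnc.end > gene.start and lnc.start < gene.end:
        return 0, "overlapping"
    if lnc.end <= gene.start:  # lncRNA on the genomic left
        gap = gene.start - lnc.end
        upstream = gene.strand == "+"
    else:  # genomic right
        gap = lnc.start - gene.end
        upstream = gene.strand == "-"
    return (-gap, "upstream") if upstream else (gap, "downstream")


def window_candidates(lncrnas: list[TranscriptRecord], genes: list[GeneSpan],
                      up_bp: int = 10_000, down_bp: int = 20_000) -> list[CisPair]:
    """All (lncRNA, gene) pairs whose spans intersect the gene's cis window.

    Interval-tree search per chromosome, O((n+m) log n); equivalent to the
    all-pairs intersection test. lncRNA strand is not restricted; only the
    gene's strand orients the window.
    """
    if up_bp < 0 or down_bp < 0:
        raise ValueError("window parameters must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for i, lnc in enumerate(lncrnas):
        trees.setdefault(lnc.chrom, IntervalTree()).addi(lnc.start, lnc.end, i)
    pairs = []
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        lo, hi = _window(gene, up_bp, down_bp)
        hits = sorted(iv.data for iv in tree.overlap(lo, hi))
        for i in hits:
            lnc = lncrnas[i]
            dist, relation = _classify_pair(lnc, gene)
            pairs.append(CisPair(
                lncrna_id=lnc.transcript_id,
                gene_id=gene.gene_id,
                signed_distance=dist,
                relation=relation,
                same_strand=lnc.strand == gene.strand,
            ))
    pairs.sort(key=lambda p: (p.lncrna_id, p.gene_id))
    return pairs


def window_candidates_bruteforce(lncrnas, genes, up_bp=10_000, down_bp=20_000) -> list[CisPair]:
    """O(n*m) all-pairs oracle for the window search (test reference)."""
    if up_bp < 0 or down_bp < 0:
        raise ValueError("window parameters must be non-negative")
    pairs = []
    for gene in genes:
        lo, hi = _window(gene, up_bp, down_bp)
        for lnc in lncrnas:
            if lnc.chrom != gene.chrom:
                continue
            if lnc.end > lo and lnc.start < hi:
                dist, relation = _classify_pair(lnc, gene)
                pairs.append(CisPair(lnc.transcript_id, gene.gene_id, dist, relation,
                                     lnc.strand == gene.strand))
    pairs.sort(key=lambda p: (p.lncrna_id, p.gene_id))
    return pairs


def gene_expression(expr: ExpressionMatrix, genes: list[GeneSpan]) -> pd.DataFrame:
    """Gene-level expression = sum of the gene's transcript rows (FPKM)."""
    rows = {}
    for gene in genes:
        present = [t for t in gene.transcripts if t in expr.values.index]
        if present:
            rows[gene.gene_id] = expr.values.loc[present].sum(axis=0)
    return pd.DataFrame(rows).T


def correlation_gate(candidates: list[CisPair], expr: ExpressionMatrix,
                     genes: list[GeneSpan], rho_min: float = 0.6,
                     r_min: float = 0.6) -> list[CisPair]:
    """Keep candidates with Spearman >= rho_min AND Pearson >= r_min.

    Spearman uses average ranks for ties; Pearson is computed on FPKM values
    across all samples. Pairs with a zero-variance vector are dropped with a
    logged reason (correlation undefined).
    """
    gx = gene_expression(expr, genes)
    kept = []
    for pair in candidates:
        if pair.lncrna_id not in expr.values.index or pair.gene_id not in gx.index:
            raise ValueError(f"pair ({pair.lncrna_id}, {pair.gene_id}) absent from expression")
        x = expr.values.loc[pair.lncrna_id].to_numpy(float)
        y = gx.loc[pair.gene_id].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            log.info("dropping pair (%s, %s): zero-variance expression",
                     pair.lncrna_id, pair.gene_id)
            continue
        rho = stats.spearmanr(x, y).statistic
        r = stats.pearsonr(x, y).statistic
        if rho >= rho_min and r >= r_min:
            pair.spearman = float(rho)
            pair.pearson = float(r)
            kept.append(pair)
    return kept


def multiplicity_stats(pairs: list[CisPair]) -> dict:
    """Degree summary of the bipartite lncRNA-gene pair set."""
    lnc_deg: dict[str, int] = {}
    gene_deg: dict[str, int] = {}
    for p in pairs:
        lnc_deg[p.lncrna_id] = lnc_deg.get(p.lncrna_id, 0) + 1
        gene_deg[p.gene_id] = gene_deg.get(p.gene_id, 0) + 1
    return {
        "n_pairs": len(pairs),
        "n_lncrnas": len(lnc_deg),
        "n_genes": len(gene_deg),
        "lncrnas_multi_target": sum(1 for d in lnc_deg.values() if d >= 2),
        "genes_multi_regulator": sum(1 for d in gene_deg.values() if d >= 2),
    }


def pairs_to_frame(pairs: list[CisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.signed_distance, p.relation, p.same_strand,
          p.spearman, p.pearson) for p in pairs],
        columns=["lncrna_id", "gene_id", "signed_distance", "relation",
                 "same_strand", "spearman", "pearson"],
    )
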