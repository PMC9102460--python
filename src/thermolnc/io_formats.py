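"""Readers and writers for every on-disk format the pipeline touches.

All readers validate strictly and raise rather than coerce; all writers
are deterministic given identical in-memory state. GTF is read and
written in the 2.2 dialect with ``gene_id``/``transcript_id`` attributes;
coordinates are converted between GTF's 1-based inclusive convention and
the package-internal 0-based half-open one at this boundary.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ExpressionMatrix, TranscriptRecord, TraitVector

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(field))
    if "transcript_id" not in attrs:
        raise ValueError(f"GTF line {lineno}: missing transcript_id attribute")
    if "gene_id" not in attrs:
        raise ValueError(f"GTF line {lineno}: missing gene_id attribute")
    return attrs


def read_gtf(path) -> list[TranscriptRecord]:
    """Parse a GTF 2.2 file into TranscriptRecords, preserving input order.

    Only ``transcript`` and ``exon`` features are interpreted; exon
    coordinates are converted 1-based inclusive -> 0-based half-open.
    A transcript line is optional: a transcript's span defaults to the
    hull of its exons.
    """
    spans: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_field = fields
            if feature not in ("transcript", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"GTF line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start1 < 1 or end1 < start1:
                raise ValueError(f"GTF line {lineno}: invalid coordinate range {start1}-{end1}")
            if strand not in ("+", "-"):
                raise ValueError(f"GTF line {lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(attr_field, lineno)
            tid = attrs["transcript_id"]
            rec = spans.setdefault(
                tid,
                {"gene_id": attrs["gene_id"], "chrom": chrom, "strand": strand,
                 "span": None, "exons": []},
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ValueError(f"GTF line {lineno}: transcript {tid} spans multiple chromosomes/strands")
            iv = (start1 - 1, end1)  # to 0-based half-open
            if feature == "transcript":
                rec["span"] = iv
                order.append(tid)
            else:
                rec["exons"].append(iv)
                if tid not in order:
                    order.append(tid)

    records = []
    for tid in dict.fromkeys(order):
        rec = spans[tid]
        exons = sorted(rec["exons"])
        span = rec["span"]
        if span is None:
            if not exons:
                raise ValueError(f"transcript {tid}: no exons and no transcript feature")
            span = (exons[0][0], max(e for _, e in exons))
        for a, b in exons:
            if a < span[0] or b > span[1]:
                raise ValueError(f"transcript {tid}: exon [{a},{b}) outside transcript span {span}")
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                start=span[0],
                end=span[1],
                strand=rec["strand"],
                exons=exons or [span],
            )
        )
    return records


def write_gtf(records: list[TranscriptRecord], path) -> None:
    """Emit transcript + exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for rec in records:
            attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
            fh.write(
                f"{rec.chrom}\tthermolnc\ttranscript\t{rec.start + 1}\t{rec.end}\t.\t{rec.strand}\t.\t{attrs}\n"
            )
            for a, b in rec.exons:
                fh.write(
                    f"{rec.chrom}\tthermolnc\texon\t{a + 1}\t{b}\t.\t{rec.strand}\t.\t{attrs}\n"
                )


def read_expression(path, design: dict[str, tuple[int, int]], unit: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column transcript id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty data section")
    for col in df.columns:
        if col not in design:
            raise ValueError(f"{path}: sample {col!r} not in design")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated transcript id {dup!r}")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression value")
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float), unit=unit, design=design)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="transcript_id")


def read_trait(path, stages: int) -> TraitVector:
    """Read a two-column TSV (stage, value) into a TraitVector."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values(df.columns[0])
    return TraitVector(values=df.iloc[:, 1].to_numpy(float), stages=stages)


def write_trait(trait: TraitVector, path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\ttemperature\n")
        for i, v in enumerate(trait.values, start=1):
            fh.write(f"{i}\t{v:g}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        str(path),
        "fasta",
    )


def write_network(pairs, path) -> None:
    """Write a tripartite edge list for significant ceRNA pairs.

    One lncRNA-mRNA edge per significant pair plus lncRNA-miRNA and
    miRNA-mRNA edges for each shared miRNA; rows sorted by FDR then ids,
    so output is byte-identical across runs.
    """
    rows = []
    for pair in pairs:
        if not pair.significant:
            continue
        rows.append((pair.lncrna_id, pair.mrna_id, "lncRNA-mRNA", pair.p, pair.fdr))
        for mir in sorted(pair.shared_mirnas):
            rows.append((pair.lncrna_id, mir, "lncRNA-miRNA", pair.p, pair.fdr))
            rows.append((mir, pair.mrna_id, "miRNA-mRNA", pair.p, pair.fdr))
    rows.sort(key=lambda r: (r[4], r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("source\ttarget\tedge_type\tp\tfdr\n")
        for src, tgt, etype, p, fdr in rows:
            fh.write(f"{src}\t{tgt}\t{etype}\t{p:.6g}\t{fdr:.6g}\n")


def read_target_table(path) -> pd.DataFrame:
    """Read a miRNA-target interaction TSV (mirna_id, transcript_id, score)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (mirna_id, transcript_id, score)")
    df.columns = ["mirna_id", "transcript_id", "score"] + list(df.columns[3:])
    if df.duplicated(["mirna_id", "transcript_id"]).any():
        raise ValueError(f"{path}: duplicate (miRNA, transcript) interaction")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
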