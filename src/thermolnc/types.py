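"""Core in-memory containers shared by every pipeline stage.

Coordinates are 0-based half-open everywhere inside the package; GTF I/O
converts to and from the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Interval = tuple[int, int]

BIOTYPES = ("mRNA", "lncRNA", "uncertain", "unset")


@dataclass
class TranscriptRecord:
    """One annotated transcript: genomic span, exon structure, biotype call.

    ``exons`` is an ordered list of non-overlapping 0-based half-open
    intervals contained in ``[start, end)``; ``length`` is the mature
    (spliced) length, i.e. the sum of exon lengths.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[Interval] = field(default_factory=list)
    biotype: str = "unset"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.transcript_id}: start must be < end ({self.start} >= {self.end})")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a >= b:
                raise ValueError(f"{self.transcript_id}: empty exon [{a},{b})")
            if a < self.start or b > self.end:
                raise ValueError(
                    f"{self.transcript_id}: exon [{a},{b}) outside transcript span [{self.start},{self.end})"
                )
            if prev_end is not None and a < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons at [{a},{b})")
            prev_end = b

    @property
    def length(self) -> int:
        """Mature transcript length in nt (sum of exon lengths)."""
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def sample_name(stage: int, rep: int) -> str:
    return f"S{stage}R{rep}"


def make_design(stages: int, replicates: int) -> dict[str, tuple[int, int]]:
    """Map sample id -> (stage, replicate), stages and replicates 1-based."""
    return {
        sample_name(s, r): (s, r)
        for s in range(1, stages + 1)
        for r in range(1, replicates + 1)
    }


@dataclass
class ExpressionMatrix:
    """Transcripts x samples expression, either raw counts or FPKM.

    ``values`` is a pandas DataFrame indexed by transcript id with one
    column per sample; ``design`` maps each sample id to its
    (stage, replicate) pair, both 1-based.
    """

    values: pd.DataFrame
    unit: str
    design: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "FPKM"):
            raise ValueError(f"unit must be 'counts' or 'FPKM', got {self.unit!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate transcript id {dup!r}")
        for col in self.values.columns:
            if col not in self.design:
                raise ValueError(f"sample {col!r} not in design")
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        stages = {s for s, _ in self.design.values()}
        if len(stages) < 2:
            raise ValueError("design must cover at least 2 stages")

    @property
    def n_stages(self) -> int:
        return max(s for s, _ in self.design.values())

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    def samples_of_stage(self, stage: int) -> list[str]:
        cols = [c for c in self.values.columns if self.design[c][0] == stage]
        if not cols:
            raise ValueError(f"stage {stage} absent from design")
        return cols

    def stage_means(self) -> pd.DataFrame:
        """Per-stage mean across replicates; columns are stage indices."""
        out = {}
        for stage in sorted({s for s, _ in self.design.values()}):
            out[stage] = self.values[self.samples_of_stage(stage)].mean(axis=1)
        return pd.DataFrame(out)

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(transcript_ids)], self.unit, self.design)


@dataclass
class TraitVector:
    """One scalar per stage (e.g. a tissue temperature trend)."""

    values: np.ndarray
    stages: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.stages:
            raise ValueError(f"trait length {len(self.values)} != number of stages {self.stages}")

    def per_sample(self, design: dict[str, tuple[int, int]], samples) -> np.ndarray:
        """Expand stage values to samples (each stage value repeated per replicate)."""
        return np.array([self.values[design[s][0] - 1] for s in samples])
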