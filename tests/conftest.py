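"""Shared fixtures and matrix-construction helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from thermolnc.synth import SynthConfig, generate_annotation, generate_expression
from thermolnc.types import ExpressionMatrix, make_design, sample_name


def make_matrix(rows: dict[str, list[float]], unit: str = "FPKM",
                stages: int = 5, replicates: int = 3) -> ExpressionMatrix:
    """Build an ExpressionMatrix from transcript -> per-sample value lists."""
    design = make_design(stages, replicates)
    cols = [sample_name(s, r) for s in range(1, stages + 1)
            for r in range(1, replicates + 1)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols).astype(float)
    return ExpressionMatrix(values=df, unit=unit, design=design)


def stage_profile_matrix(profiles: dict[str, list[float]], unit: str = "FPKM",
                         replicates: int = 3, noise: float = 0.0,
                         seed: int = 0) -> ExpressionMatrix:
    """Expand per-stage profiles to replicate-level samples, optionally noisy."""
    rng = np.random.default_rng(seed)
    rows = {}
    for tid, prof in profiles.items():
        vals = []
        for v in prof:
            for _ in range(replicates):
                vals.append(max(0.0, v + (rng.normal(0.0, noise) if noise else 0.0)))
        rows[tid] = vals
    return make_matrix(rows, unit=unit, stages=len(next(iter(profiles.values()))),
                       replicates=replicates)


@pytest.fixture(scope="session")
def synth_default():
    """Default synthetic dataset (seed 11) shared across recovery tests."""
    cfg = SynthConfig(seed=11)
    records, truth = generate_annotation(cfg)
    counts, fpkm, trait = generate_expression(records, truth, cfg)
    return {"config": cfg, "records": records, "truth": truth,
            "counts": counts, "fpkm": fpkm, "trait": trait}
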