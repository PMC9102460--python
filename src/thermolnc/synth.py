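"""Synthetic input generator with planted ground truth.

Emulates a 5-stage x 3-replicate staged-tissue RNA-seq design over a small
artificial genome: coding genes and lncRNA candidates with realistic length
and exon-structure contrasts, negative-binomial counts with stage-dependent
means, a thermogenic temperature trait peaking mid-series, coding-potential
evidence from four noisy channels, and a miRNA-target interaction table
with planted endogenous-target-mimic (eTM) triples. Every planted signal is
recorded in a GroundTruth object so each downstream stage has a recovery
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, TraitVector, TranscriptRecord, make_design, sample_name

# substream ids so each generator is deterministic on its own
_STREAM_ANNOT, _STREAM_EXPR, _STREAM_EVIDENCE, _STREAM_TARGETS, _STREAM_SEQS = range(5)


@dataclass
class SynthConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_coding_genes: int = 500
    n_lncrna: int = 400
    n_mirna: int = 50
    stages: int = 5
    replicates: int = 3
    frac_stage_specific: float = 0.2
    n_planted_modules: int = 3
    planted_module_sizes: tuple[int, ...] = (40, 60, 80)
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    dispersion: float = 0.1
    library_size_mean: int = 1_000_000
    seed: int = 0
    # structure of the annotation
    n_chromosomes: int = 8
    lncrna_short_frac: float = 0.85  # fraction of lncRNAs drawn in 200-500 nt
    lncrna_single_exon_frac: float = 0.9
    frac_cis: float = 0.3  # fraction of lncRNAs planted inside a gene's cis window
    # expression model
    module_amplitude: float = 1.2  # log2 swing of planted module profiles
    cis_amplitude: float = 1.5  # log2 sd of the shared profile of planted cis pairs
    background_rel: float = 0.0  # off-stage relative abundance of stage-specific transcripts
    # coding-potential evidence
    channel_error: float = 0.05
    # miRNA targets
    n_etm: int = 5
    etm_shared: int = 4  # miRNAs shared by each planted eTM pair
    background_density: float = 0.005

    def __post_init__(self) -> None:
        for name in ("n_coding_genes", "n_lncrna", "n_mirna", "replicates",
                     "library_size_mean", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.stages < 2:
            raise ValueError("stages must be >= 2")
        for name in ("frac_stage_specific", "frac_cis", "lncrna_short_frac",
                     "lncrna_single_exon_frac", "channel_error", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.de_log2fc <= 0:
            raise ValueError("de_log2fc must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0 (0 = Poisson)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        self.planted_module_sizes = tuple(self.planted_module_sizes)[: self.n_planted_modules]
        if len(self.planted_module_sizes) != self.n_planted_modules:
            raise ValueError("planted_module_sizes must list one size per planted module")
        if any(s <= 0 for s in self.planted_module_sizes):
            raise ValueError("module sizes must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class GroundTruth:
    """Planted signals, keyed by transcript id, used as recovery oracles."""

    biotype_by_transcript: dict[str, str] = field(default_factory=dict)
    de_sets_by_comparison: dict[str, set[str]] = field(default_factory=dict)
    de_direction: dict[str, int] = field(default_factory=dict)
    de_target_stage: dict[str, int] = field(default_factory=dict)
    module_membership: dict[str, int] = field(default_factory=dict)
    module_trait_sign: dict[int, int] = field(default_factory=dict)
    etm_triples: list[tuple[str, str, str]] = field(default_factory=list)
    stage_specific_set: set[str] = field(default_factory=set)
    stage_of_specific: dict[str, int] = field(default_factory=dict)
    cis_pairs: list[tuple[str, str]] = field(default_factory=list)


def default_trait(stages: int) -> TraitVector:
    """Bell-shaped temperature trend peaking at the middle stage."""
    peak = (stages + 1) / 2.0
    s = np.arange(1, stages + 1, dtype=float)
    temps = 22.0 + 13.0 * np.exp(-0.5 * ((s - peak) / 1.2) ** 2)
    return TraitVector(values=temps, stages=stages)


def _split_exons(rng, total_len: int, n_exons: int, start: int) -> list[tuple[int, int]]:
    """Split a mature length into n exons separated by random introns."""
    if n_exons == 1:
        return [(start, start + total_len)]
    cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1, replace=False))
    lens = np.diff(np.concatenate(([0], cuts, [total_len])))
    lens = np.maximum(lens, 1)
    lens[-1] = total_len - lens[:-1].sum()
    if lens[-1] < 1:  # pathological split; fall back to even split
        lens = np.full(n_exons, total_len // n_exons)
        lens[-1] += total_len - lens.sum()
    exons = []
    pos = start
    for i, ln in enumerate(lens):
        exons.append((pos, pos + int(ln)))
        pos += int(ln)
        if i < n_exons - 1:
            pos += int(rng.integers(100, 2000))
    return exons


def generate_annotation(config: SynthConfig) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Build the transcript annotation and plant every downstream signal.

    lncRNAs are mostly 200-500 nt and single-exon; mRNAs mostly > 500 nt with
    multiple exons and sometimes several isoforms per gene. A frac_cis subset
    of lncRNAs is placed inside the 10 kb-upstream / 20 kb-downstream window
    of a coding gene; the remaining lncRNAs are kept far (> 20 kb) from every
    gene so planted cis pairs are the only window candidates.
    """
    rng = config.rng(_STREAM_ANNOT)
    truth = GroundTruth()
    records: list[TranscriptRecord] = []
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursor = {c: 15_000 for c in chroms}
    gene_hulls: dict[str, tuple[str, int, int, str]] = {}  # gene -> (chrom, start, end, strand)
    mrna_ids: list[str] = []

    # --- coding genes ---
    for g in range(config.n_coding_genes):
        gene_id = f"GCOD_{g + 1:05d}"
        chrom = chroms[g % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < 0.9:
            mature = int(rng.integers(600, 3001))
        else:
            mature = int(rng.integers(300, 601))
        n_exons = 1 + int(rng.poisson(3.0))
        n_exons = min(n_exons, max(1, mature // 60))
        start = cursor[chrom]
        exons = _split_exons(rng, mature, n_exons, start)
        end = exons[-1][1]
        n_iso = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
        for t in range(n_iso):
            tid = f"{gene_id}.t{t + 1}"
            t_exons = exons
            if t > 0 and len(exons) > 2:
                drop = int(rng.integers(1, len(exons) - 1))
                t_exons = exons[:drop] + exons[drop + 1:]
                # keep the hull identical across isoforms
            records.append(TranscriptRecord(tid, gene_id, chrom, start, end, strand, list(t_exons)))
            truth.biotype_by_transcript[tid] = "mRNA"
            mrna_ids.append(tid)
        gene_hulls[gene_id] = (chrom, start, end, strand)
        cursor[chrom] = end + 100_000

    gene_ids = sorted(gene_hulls)
    lnc_tail_cursor = {c: cursor[c] + 50_000 for c in chroms}

    # --- lncRNAs ---
    n_cis = int(round(config.frac_cis * config.n_lncrna))
    lnc_ids: list[str] = []
    for i in range(config.n_lncrna):
        lnc_id = f"LNC_{i + 1:05d}"
        lnc_ids.append(lnc_id)
        if rng.random() < config.lncrna_short_frac:
            mature = int(rng.integers(201, 501))
        else:
            mature = int(rng.integers(501, 2001))
        n_exons = 1 if rng.random() < config.lncrna_single_exon_frac else 2
        strand = "+" if rng.random() < 0.5 else "-"
        if i < n_cis:
            host = gene_ids[int(rng.integers(len(gene_ids)))]
            hc, hs, he, hstrand = gene_hulls[host]
            upstream = rng.random() < 0.5
            if upstream:
                d = int(rng.integers(200, 9500))
            else:
                d = int(rng.integers(200, 19500))
            # genomic side of the window depends on the host gene's strand
            left = (upstream and hstrand == "+") or (not upstream and hstrand == "-")
            span = mature + (n_exons - 1) * 500
            if left:
                start = hs - d - span
            else:
                start = he + d
            start = max(start, 0)
            chrom = hc
            truth.cis_pairs.append((lnc_id, host))
        else:
            chrom = chroms[i % len(chroms)]
            start = lnc_tail_cursor[chrom]
            lnc_tail_cursor[chrom] += 30_000
        exons = _split_exons(rng, mature, n_exons, start) if n_exons > 1 else [(start, start + mature)]
        end = exons[-1][1]
        records.append(TranscriptRecord(lnc_id, f"GLNC_{i + 1:05d}", chrom, start, end, strand, exons))
        truth.biotype_by_transcript[lnc_id] = "lncRNA"

    # --- role assignment (disjoint pools) ---
    cis_lnc = set(l for l, _ in truth.cis_pairs)
    cis_gene_transcripts = {
        r.transcript_id for r in records if r.gene_id in {g for _, g in truth.cis_pairs}
    }
    free_lnc = [t for t in lnc_ids if t not in cis_lnc]
    free_mrna = [t for t in mrna_ids if t not in cis_gene_transcripts]

    for m, size in enumerate(config.planted_module_sizes, start=1):
        n_lnc_members = max(1, int(round(0.3 * size)))
        n_lnc_members = min(n_lnc_members, len(free_lnc))
        n_mrna_members = min(size - n_lnc_members, len(free_mrna))
        members = [free_lnc.pop() for _ in range(n_lnc_members)]
        members += [free_mrna.pop() for _ in range(n_mrna_members)]
        for t in members:
            truth.module_membership[t] = m
        # module 1 tracks the trait, module 2 mirrors it, further modules
        # follow trait-orthogonal contrasts (no expected trait correlation)
        truth.module_trait_sign[m] = {1: 1, 2: -1}.get(m, 0)

    n_ss = int(round(config.frac_stage_specific * config.n_lncrna))
    n_ss = min(n_ss, len(free_lnc))
    for _ in range(n_ss):
        t = free_lnc.pop()
        stage = int(rng.integers(1, config.stages + 1))
        truth.stage_specific_set.add(t)
        truth.stage_of_specific[t] = stage

    n_de = int(round(config.de_fraction * config.n_lncrna))
    n_de = min(n_de, len(free_lnc))
    for _ in range(n_de):
        t = free_lnc.pop()
        target = int(rng.integers(2, config.stages + 1))
        direction = 1 if rng.random() < 0.5 else -1
        truth.de_direction[t] = direction
        truth.de_target_stage[t] = target
        truth.de_sets_by_comparison.setdefault(f"S1_vs_S{target}", set()).add(t)

    # --- planted eTM triples: lncRNA and mRNA sharing etm_shared miRNAs ---
    mir_ids = [f"mir_{j + 1:04d}" for j in range(config.n_mirna)]
    mir_pool = list(mir_ids)
    etm_lnc_pool = sorted(cis_lnc) or lnc_ids
    for e in range(config.n_etm):
        if len(mir_pool) < config.etm_shared or not free_mrna:
            break
        lnc = etm_lnc_pool[e % len(etm_lnc_pool)]
        mrna = free_mrna.pop()
        shared = [mir_pool.pop() for _ in range(config.etm_shared)]
        for mir in shared:
            truth.etm_triples.append((lnc, mir, mrna))

    return records, truth


def _module_profile_basis(z_trait: np.ndarray, n_modules: int) -> list[np.ndarray]:
    """Mutually distinguishable stage profiles for planted modules.

    Module 1 follows the (standardized) trait, module 2 its mirror image;
    later modules follow polynomial stage contrasts orthogonalized against
    the constant and the trait, all scaled to unit variance. Orthogonality
    is what makes the planted modules separable by correlation clustering.
    """
    S = len(z_trait)
    profiles = [z_trait, -z_trait]
    if n_modules > 2:
        x = np.arange(S, dtype=float)
        basis = np.vander(x, N=min(S, n_modules + 1), increasing=True)[:, 1:]
        anchors = [np.ones(S) / np.sqrt(S), z_trait / np.linalg.norm(z_trait)]
        for col in basis.T:
            v = col.copy()
            for q in anchors:
                v = v - (v @ q) * q
            norm = np.linalg.norm(v)
            if norm < 1e-8:
                continue
            v = v / norm
            anchors.append(v)
            profiles.append(v / v.std())
            if len(profiles) >= n_modules:
                break
    while len(profiles) < n_modules:  # more modules than contrasts: recycle
        profiles.append(profiles[len(profiles) % 2])
    return profiles


def _stage_profiles(records, truth: GroundTruth, config: SynthConfig,
                    rng: np.random.Generator, trait: TraitVector):
    """Relative abundance and multiplicative per-stage profile per transcript."""
    n = len(records)
    S = config.stages
    abundance = np.exp(rng.normal(0.0, 1.0, size=n))
    profile = np.ones((n, S))
    idx = {r.transcript_id: i for i, r in enumerate(records)}

    z_trait = (trait.values - trait.values.mean()) / trait.values.std()
    module_profiles = _module_profile_basis(z_trait, max(truth.module_trait_sign, default=0))

    for t, m in truth.module_membership.items():
        jitter = rng.normal(0.0, 0.25, size=S)
        profile[idx[t]] = 2.0 ** (config.module_amplitude * module_profiles[m - 1] + jitter)
        abundance[idx[t]] = rng.uniform(0.5, 4.0)

    cis_profiles: dict[str, np.ndarray] = {}
    gene_of = {r.transcript_id: r.gene_id for r in records}
    def _shared_profile() -> np.ndarray:
        # permuted, evenly spread stage levels with a fixed realized log2
        # swing, so planted pairs never degenerate to a near-flat profile
        from scipy.stats import norm
        g = norm.ppf((np.arange(S) + 0.5) / S)
        rng.shuffle(g)
        return config.cis_amplitude * (g - g.mean()) / g.std()

    for lnc, gene in truth.cis_pairs:
        g = cis_profiles.setdefault(gene, _shared_profile())
        profile[idx[lnc]] = 2.0 ** (g + rng.normal(0.0, 0.1, size=S))
        abundance[idx[lnc]] = rng.uniform(0.8, 4.0)
    for r in records:
        if r.gene_id in cis_profiles and r.transcript_id not in truth.stage_specific_set:
            g = cis_profiles[r.gene_id]
            profile[idx[r.transcript_id]] = 2.0 ** (g + rng.normal(0.0, 0.1, size=S))
            abundance[idx[r.transcript_id]] = rng.uniform(0.8, 4.0)

    for t, stage in truth.stage_of_specific.items():
        p = np.full(S, config.background_rel)
        p[stage - 1] = 1.0
        profile[idx[t]] = p
        abundance[idx[t]] = rng.uniform(1.5, 6.0)

    for t, direction in truth.de_direction.items():
        target = truth.de_target_stage[t]
        p = np.ones(S)
        p[target - 1] = 2.0 ** (direction * config.de_log2fc)
        profile[idx[t]] = p
        abundance[idx[t]] = rng.uniform(0.5, 4.0)

    return abundance, profile


def generate_expression(records, truth: GroundTruth, config: SynthConfig,
                        trait: TraitVector | None = None
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix, TraitVector]:
    """Negative-binomial counts with stage-dependent means, plus FPKM.

    Planted differential transcripts are shifted by ``de_log2fc`` in their
    target stage; planted module members track (or mirror) the trait;
    stage-specific transcripts sit at a negligible background level outside
    their single active stage. FPKM = 1e9 * count / (length * library size),
    library size being the sample's total counts.
    """
    if trait is None:
        trait = default_trait(config.stages)
    if len(trait.values) != config.stages:
        raise ValueError("trait length must equal the number of stages")
    rng = config.rng(_STREAM_EXPR)
    design = make_design(config.stages, config.replicates)
    samples = list(design)
    abundance, profile = _stage_profiles(records, truth, config, rng, trait)
    lengths = np.array([r.length for r in records], dtype=float)

    n, S = len(records), config.stages
    counts = np.zeros((n, len(samples)))
    for j, s in enumerate(samples):
        stage = design[s][0]
        rel = abundance * profile[:, stage - 1]
        scale = config.library_size_mean * np.exp(rng.normal(0.0, 0.1)) / rel.sum()
        mean = rel * scale
        if config.dispersion == 0:
            counts[:, j] = rng.poisson(mean)
        else:
            r_nb = 1.0 / config.dispersion
            p_nb = r_nb / (r_nb + mean)
            counts[:, j] = rng.negative_binomial(r_nb, p_nb)

    tids = [r.transcript_id for r in records]
    counts_df = pd.DataFrame(counts, index=tids, columns=samples)
    libsize = counts_df.sum(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        fpkm = 1e9 * counts / (lengths[:, None] * libsize[None, :])
    fpkm = np.nan_to_num(fpkm)
    fpkm_df = pd.DataFrame(fpkm, index=tids, columns=samples)
    return (
        ExpressionMatrix(counts_df, "counts", design),
        ExpressionMatrix(fpkm_df, "FPKM", design),
        trait,
    )


def generate_coding_evidence(records, truth: GroundTruth, config: SynthConfig,
                             channel_error=None) -> pd.DataFrame:
    """Four-channel coding-potential evidence with independent channel noise.

    For a true lncRNA each channel votes noncoding (CPC < 0, CNCI < 0,
    txCdsPredict < 500, no protein-domain hit); for a true mRNA the converse.
    Each channel independently flips with its error rate.
    """
    rng = config.rng(_STREAM_EVIDENCE)
    if channel_error is None:
        channel_error = config.channel_error
    err = np.broadcast_to(np.asarray(channel_error, dtype=float), (4,)).copy()
    if ((err < 0) | (err > 1)).any():
        raise ValueError("channel error rates must be in [0, 1]")

    rows = []
    for r in records:
        is_lnc = truth.biotype_by_transcript[r.transcript_id] == "lncRNA"
        votes_noncoding = np.full(4, is_lnc)
        flips = rng.random(4) < err
        votes_noncoding ^= flips
        cpc = rng.uniform(-3.0, -0.5) if votes_noncoding[0] else rng.uniform(0.5, 3.0)
        cnci = rng.uniform(-3.0, -0.5) if votes_noncoding[1] else rng.uniform(0.5, 3.0)
        txcds = rng.uniform(100.0, 450.0) if votes_noncoding[2] else rng.uniform(550.0, 1200.0)
        pfam = not votes_noncoding[3]
        rows.append((r.transcript_id, cpc, cnci, txcds, pfam))
    return pd.DataFrame(rows, columns=["transcript_id", "cpc_score", "cnci_score",
                                       "txcds_score", "pfam_hit"])


def generate_mirna_targets(records, truth: GroundTruth, config: SynthConfig) -> pd.DataFrame:
    """miRNA-target interaction table containing every planted eTM triple.

    Each planted (lncRNA, miRNA, mRNA) triple contributes two interactions;
    background interactions are sprinkled at ``background_density`` over the
    full miRNA x transcript grid.
    """
    rng = config.rng(_STREAM_TARGETS)
    mir_ids = [f"mir_{j + 1:04d}" for j in range(config.n_mirna)]
    tids = [r.transcript_id for r in records]
    interactions: dict[tuple[str, str], int] = {}
    for lnc, mir, mrna in truth.etm_triples:
        interactions[(mir, lnc)] = 1
        interactions[(mir, mrna)] = 1
    if config.background_density > 0:
        mask = rng.random((len(mir_ids), len(tids))) < config.background_density
        for i, j in zip(*np.nonzero(mask)):
            interactions.setdefault((mir_ids[i], tids[j]), 1)
    rows = sorted((m, t, s) for (m, t), s in interactions.items())
    return pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "score"])


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_fastas(records, truth: GroundTruth, config: SynthConfig
                    ) -> tuple[dict[str, str], dict[str, str]]:
    """Random transcript and miRNA sequences with planted seed-match sites.

    Each planted eTM triple's lncRNA and mRNA sequence receives one copy of
    the reverse complement of the miRNA's seed (positions 2-8), so the
    built-in seed matcher recovers the planted interactions.
    """
    rng = config.rng(_STREAM_SEQS)
    bases = np.array(list("ACGT"))
    transcripts = {
        r.transcript_id: "".join(rng.choice(bases, size=r.length))
        for r in records
    }
    mirnas = {
        f"mir_{j + 1:04d}": "".join(rng.choice(bases, size=21))
        for j in range(config.n_mirna)
    }
    for lnc, mir, mrna in truth.etm_triples:
        site = _revcomp(mirnas[mir][1:8])
        for tid in (lnc, mrna):
            seq = transcripts[tid]
            pos = int(rng.integers(0, max(1, len(seq) - 7)))
            transcripts[tid] = seq[:pos] + site + seq[pos + 7:]
    return transcripts, mirnas
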