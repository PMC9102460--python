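"""End-to-end orchestration: synth -> classify -> diffexpr -> cistarget ->
coexpr -> cerna, from one config, with a JSON manifest of every parameter,
seed and per-stage record count. Reruns with the same config are identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, cerna, cistarget, classify, coexpr, diffexpr, io_formats, synth
from .classify import VoteThresholds
from .synth import SynthConfig


@dataclass
class PipelineConfig:
    """All thresholds of the screen; defaults are the study values."""

    outdir: str = "thermolnc_out"
    seed: int = 0
    # classify
    min_len: int = 200
    votes: int = 3
    presence_floor: float = 0.5
    # diffexpr
    fc_min: float = 2.0
    alpha: float = 0.001
    k_clusters: int = 6
    # cistarget
    up_bp: int = 10_000
    down_bp: int = 20_000
    rho_min: float = 0.6
    r_min: float = 0.6
    # coexpr
    beta: int | None = None
    r2_min: float = 0.8
    min_module_size: int = 10
    cut_height: float = 0.97
    kme_min: float = 0.9
    # cerna
    min_shared: int = 3
    fdr_max: float = 0.05
    # synthetic input generation
    synth: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("synth")
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on freshly generated synthetic inputs.

    Writes all stage outputs plus a manifest under config.outdir and returns
    the manifest. Any stage failure removes partial outputs and re-raises
    with the failing stage named.
    """
    outdir = Path(config.outdir)
    if outdir.exists():
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "stages": {},
    }
    stage = "synth"
    try:
        scfg = SynthConfig(seed=config.seed, **config.synth)
        records, truth = synth.generate_annotation(scfg)
        counts, fpkm, trait = synth.generate_expression(records, truth, scfg)
        evidence = synth.generate_coding_evidence(records, truth, scfg)
        targets = synth.generate_mirna_targets(records, truth, scfg)
        io_formats.write_gtf(records, outdir / "annotation.gtf")
        io_formats.write_expression(counts, outdir / "counts.tsv")
        io_formats.write_expression(fpkm, outdir / "fpkm.tsv")
        io_formats.write_trait(trait, outdir / "trait.tsv")
        evidence.to_csv(outdir / "coding_evidence.tsv", sep="\t", index=False)
        targets.to_csv(outdir / "mirna_targets.tsv", sep="\t", index=False)
        manifest["stages"]["synth"] = {
            "n_transcripts": len(records),
            "n_interactions": len(targets),
        }

        stage = "classify"
        candidates = classify.length_filter(records, min_len=config.min_len)
        calls = classify.classify_all(
            evidence, VoteThresholds(votes_required=config.votes))
        candidate_ids = {r.transcript_id for r in candidates}
        for r in records:
            call = calls.get(r.transcript_id, "uncertain")
            r.biotype = call if (call != "lncRNA" or r.transcript_id in candidate_ids) \
                else "uncertain"
        lnc_ids = sorted(r.transcript_id for r in records if r.biotype == "lncRNA")
        mrna_ids = sorted(r.transcript_id for r in records if r.biotype == "mRNA")
        lnc_fpkm = fpkm.subset([t for t in lnc_ids if t in fpkm.values.index])
        presences = classify.stage_presence(lnc_fpkm, floor=config.presence_floor)
        psummary = classify.presence_summary(presences)
        tables = classify.characterize(records, fpkm)
        for name, tab in tables.items():
            tab.to_csv(outdir / f"characterize_{name}.tsv", sep="\t")
        calls.to_csv(outdir / "biotype_calls.tsv", sep="\t")
        manifest["stages"]["classify"] = {
            "n_lncrna": len(lnc_ids),
            "n_mrna": len(mrna_ids),
            "n_uncertain": int((calls == "uncertain").sum()),
            "presence_floor": config.presence_floor,
            "presence": {k: v for k, v in psummary.items() if k != "counts"},
        }

        stage = "diffexpr"
        results_by_cmp = {}
        for b in range(2, scfg.stages + 1):
            res = diffexpr.de_test(counts, 1, b, fc_min=config.fc_min, alpha=config.alpha)
            res = [r for r in res if r.transcript_id in set(lnc_ids)]
            name = f"S1_vs_S{b}"
            results_by_cmp[name] = res
            diffexpr.results_to_frame(res).to_csv(outdir / f"de_{name}.tsv",
                                                  sep="\t", index=False)
        sets = diffexpr.comparison_sets(results_by_cmp)
        dels = set().union(*(diffexpr.significant_ids(r) for r in results_by_cmp.values()))
        manifest["stages"]["diffexpr"] = {
            "adjustment": "benjamini-hochberg",
            "n_dels": len(dels),
            "tallies": sets["tallies"],
        }
        if len(dels) >= config.k_clusters:
            assignments = diffexpr.kmeans_profiles(fpkm, dels, k=config.k_clusters,
                                                   seed=config.seed)
            with open(outdir / "kmeans_clusters.tsv", "w") as fh:
                fh.write("transcript_id\tcluster\n")
                for a in assignments:
                    fh.write(f"{a.transcript_id}\t{a.cluster}\n")

        stage = "cistarget"
        genes = cistarget.gene_spans(records, biotype="mRNA")
        lnc_records = [r for r in records if r.biotype == "lncRNA"]
        cands = cistarget.window_candidates(lnc_records, genes,
                                            up_bp=config.up_bp, down_bp=config.down_bp)
        cis_pairs = cistarget.correlation_gate(cands, fpkm, genes,
                                               rho_min=config.rho_min, r_min=config.r_min)
        cistarget.pairs_to_frame(cis_pairs).to_csv(outdir / "cis_pairs.tsv",
                                                   sep="\t", index=False)
        manifest["stages"]["cistarget"] = {
            "n_candidates": len(cands),
            **cistarget.multiplicity_stats(cis_pairs),
        }

        stage = "coexpr"
        biotype_map = {r.transcript_id: r.biotype for r in records}
        wg = coexpr.run_wgcna(fpkm, trait=trait, beta=config.beta, r2_min=config.r2_min,
                              min_size=config.min_module_size, cut_height=config.cut_height,
                              kme_min=config.kme_min, biotype=biotype_map)
        with open(outdir / "modules.tsv", "w") as fh:
            fh.write("transcript_id\tmodule\n")
            for tid in sorted(wg["assignment"]):
                fh.write(f"{tid}\t{wg['assignment'][tid]}\n")
        with open(outdir / "module_trait.tsv", "w") as fh:
            fh.write("module\tn_members\ttrait_cor\ttrait_p\n")
            for mod in wg["modules"]:
                fh.write(f"{mod.module_id}\t{len(mod.members)}\t"
                         f"{mod.trait_cor:.4f}\t{mod.trait_p:.4g}\n")
        manifest["stages"]["coexpr"] = {
            "beta": wg["soft_threshold"].beta,
            "n_modules": len(wg["modules"]),
            "n_grey": len(wg["grey"]),
            "n_trans_pairs": len(wg["trans_pairs"]),
        }

        stage = "cerna"
        table = cerna.TargetTable.from_frame(targets, biotype_map)
        pairs, etms, degrees = cerna.build_network(table, min_shared=config.min_shared,
                                                   fdr_max=config.fdr_max)
        cerna.pairs_to_frame(pairs).to_csv(outdir / "cerna_pairs.tsv", sep="\t", index=False)
        degrees.to_csv(outdir / "mirna_degrees.tsv", sep="\t", index=False)
        io_formats.write_network(pairs, outdir / "cerna_network.tsv")
        manifest["stages"]["cerna"] = {
            "mirna_universe": len(table.mirna_universe),
            "n_tested_pairs": len(pairs),
            "n_significant_pairs": sum(1 for p in pairs if p.significant),
            "n_etm_records": len(etms),
        }

        manifest["input_checksums"] = {
            f.name: _sha256(f)
            for f in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.gtf"))
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest
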