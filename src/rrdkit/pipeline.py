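"""Umbrella pipeline: chain the stages over synthetic (or file) inputs and
emit a machine-readable JSON report with full parameter provenance."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .clonality import CLONAL_CCF_THRESHOLD, CCFInput, compute_ccf
from .hla import LOH_ALPHA, allelic_imbalance_test, call_loh
from .msi import mmrdness_score, write_loci_tsv
from .nanostring import load_tis_weights, normalize, qc_filter, tis_score
from .repertoire import downsample, summary_metrics
from .signatures import load_signature_matrix, refit
from .survival import km_estimate, logrank_test
from .synthetic import (
    SimulationConfig,
    simulate_clonotypes,
    simulate_hla_coverage,
    simulate_indel_catalog,
    simulate_ms_loci,
    simulate_panel_counts,
    simulate_survival,
    simulate_variant_callsets,
)
from .variants import compute_tmb, flag_immune_escape, merge_consensus
from .vcfio import write_consensus_vcf, write_vcf_minimal

logger = logging.getLogger("rrdkit")

ALL_STAGES = ("variants", "clonality", "msi", "panel", "signatures",
              "hla", "repertoire", "survival")


@dataclass
class PipelineConfig:
    """Stage toggles plus the per-stage parameters, defaulting to the
    study's stated values (2-of-4 consensus, 50 Mb, CCF 0.85, MS loci
    10-15 bp, QC floor 100, LOH alpha 0.01)."""

    seed: int = 0
    outdir: str = "rrdkit_out"
    stages: tuple[str, ...] = ALL_STAGES
    min_callers: int = 2
    callable_mb: float = 50.0
    ccf_threshold: float = CLONAL_CCF_THRESHOLD
    ms_min_len: int = 10
    ms_max_len: int = 15
    ms_min_coverage: int = 10
    qc_floor: float = 100.0
    loh_alpha: float = LOH_ALPHA
    tcr_target_reads: int = 1_000_000
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 1 <= self.min_callers <= 4:
            raise ValueError("min_callers must be in 1..4")
        if self.callable_mb <= 0:
            raise ValueError("callable_mb must be positive")
        if not 0 < self.ccf_threshold <= 1:
            raise ValueError("ccf_threshold must be in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: (tuple(v) if k == "stages" else v) for k, v in raw.items()})
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages on synthetic inputs derived from the config
    seed; write per-stage outputs plus a JSON report under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if sim.seed != config.seed:
        sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})
    report: dict = {
        "rrdkit_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("simulation", "outdir")  # outdir is environment
        },
        "stages": {},
    }

    if "variants" in config.stages or "clonality" in config.stages:
        callsets, truth = simulate_variant_callsets(sim)
        for caller, calls in callsets.items():
            write_vcf_minimal(calls, outdir / f"{caller}.vcf")
        truth.to_csv(outdir / "variant_truth.tsv", sep="\t", index=False)

    if "variants" in config.stages:
        logger.info("stage variants: consensus merge + TMB (min_callers=%d)",
                    config.min_callers)
        consensus = merge_consensus(callsets, min_callers=config.min_callers)
        write_consensus_vcf(consensus, outdir / "consensus.vcf")
        tmb = compute_tmb(consensus, callable_mb=config.callable_mb)
        escape = flag_immune_escape(consensus)
        report["stages"]["variants"] = {
            "n_input_variants": int(truth.shape[0]),
            "n_consensus": len(consensus),
            "n_snv": tmb.n_snv,
            "tmb_per_mb": tmb.tmb,
            "immune_escape_hits": int(escape["n_variants"].sum()),
        }

    if "clonality" in config.stages:
        n_clonal = 0
        for row in truth.itertuples(index=False):
            rec = compute_ccf(
                CCFInput(vaf=row.vaf_obs, p=row.purity, c=row.c, m=row.m),
                threshold=config.ccf_threshold,
            )
            n_clonal += rec.clonal
        report["stages"]["clonality"] = {
            "n_variants": int(truth.shape[0]),
            "n_clonal": int(n_clonal),
            "clonal_fraction": n_clonal / truth.shape[0],
            "threshold": config.ccf_threshold,
        }

    if "msi" in config.stages:
        loci = simulate_ms_loci(sim)
        write_loci_tsv(loci, outdir / "ms_loci.tsv")
        res = mmrdness_score(
            loci, min_len=config.ms_min_len, max_len=config.ms_max_len,
            min_coverage=config.ms_min_coverage,
        )
        report["stages"]["msi"] = {
            "n_loci_used": res.n_loci_used,
            "sum_proportions": res.sum_proportions,
            "mmrdness_score": res.score,
            "status": res.status,
        }

    if "panel" in config.stages:
        matrix, factors = simulate_panel_counts(sim)
        matrix.to_tsv(outdir / "panel_counts.tsv")
        qc = qc_filter(matrix, min_geomean=config.qc_floor)
        passing = matrix.counts[qc.passing]
        sub = type(matrix)(counts=passing, gene_class=matrix.gene_class)
        normalized, _ = normalize(sub)
        scores = tis_score(normalized, load_tis_weights())
        report["stages"]["panel"] = {
            "n_samples": matrix.counts.shape[1],
            "n_passing_qc": len(qc.passing),
            "excluded": qc.excluded,
            "tis_mean": float(scores.mean()),
        }

    if "signatures" in config.stages:
        signatures = load_signature_matrix()
        catalog, mix = simulate_indel_catalog(sim, signatures)
        catalog.rename_axis("channel").to_csv(outdir / "indel_catalog.tsv", sep="\t")
        res = refit(catalog, signatures)
        report["stages"]["signatures"] = {
            "truth_mix": mix,
            "relative": None if res.relative is None else dict(res.relative.round(6)),
            "residual_norm": res.residual_norm,
        }

    if "hla" in config.stages:
        calls = {}
        for k, (gene, imbalance) in enumerate(
            (("HLA-A", 1.0), ("HLA-B", 1.0), ("HLA-C", 0.3))
        ):
            cov = simulate_hla_coverage(
                gene=gene, imbalance=imbalance, seed=config.seed * 8 + k
            )
            test = allelic_imbalance_test(cov)
            loh = call_loh(test.p_value, gene=gene, alpha=config.loh_alpha)
            calls[gene] = {"p_value": test.p_value, "loh": loh.loh}
        report["stages"]["hla"] = calls

    if "repertoire" in config.stages:
        table = simulate_clonotypes(total_reads=2_000_000, seed=config.seed)
        ds = downsample(table, config.tcr_target_reads, seed=config.seed)
        metrics = summary_metrics(ds.table)
        ds.table.to_csv(outdir / "clonotypes.tsv", sep="\t", index=False)
        report["stages"]["repertoire"] = {
            "downsample_status": ds.status,
            "clone_count": metrics.clone_count,
            "clonotypes_per_1000_reads": metrics.clonotypes_per_1000_reads,
            "shannon_diversity": metrics.shannon_diversity,
        }

    if "survival" in config.stages:
        records = simulate_survival(sim)
        km = {}
        for group in sorted({r.group for r in records}):
            est = km_estimate([r for r in records if r.group == group])
            km[group] = {"median": est.median, "n": est.n, "n_events": est.n_events}
        lr = logrank_test(records)
        report["stages"]["survival"] = {
            "km": km,
            "logrank_statistic": lr.statistic,
            "logrank_p": lr.p_value,
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
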