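"""End-to-end pipeline orchestration.

Runs the full chain — summary-statistics QC and meta-analysis, signal
isolation, fine-mapping, gene-level association, polygenic priority
scoring, prioritization — on a simulated multi-ancestry scenario, with a
reproducible run manifest and per-locus text reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import finemapping, gene_assoc, io, pops_engine, prioritization, sumstats
from .ld import LDPanel, combine_panels
from .signal_isolation import (
    IndependentSignal,
    Region,
    clump,
    cojo_select,
    leave_one_out_condition,
)
from .synthetic_data import Ancestry, Scenario, SimConfig, simulate_scenario

logger = logging.getLogger(__name__)

STAGES = ["sumstats", "signal_isolation", "finemapping", "gene_assoc",
          "pops_engine", "prioritization"]


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    abs_diff: float = 0.1
    fold: float = 12.0
    p_thresh: float = 5e-8
    r2_thresh: float = 0.1
    window_bp: int = 3_000_000
    pad_clump_bp: int = 500_000
    pad_locus_bp: int = 300_000
    coverage: float = 0.95
    prior_sd: float = 0.2
    maf_min: float = 0.01
    min_variants: int = 3
    alpha: float = 0.05
    nonsyn_pip_thresh: float = 0.5
    collinearity_r2: float = 0.9
    meta_scheme: str = "stderr"        # or "samplesize"
    pops_meta_scheme: str = "mean"     # or "z"
    nonsyn_rule: str = "sum"           # or "max" (single-variant reading)
    ld_panel_ancestry: str | None = None  # None -> mixed-ancestry panel
    seed: int | None = None  # overrides sim.seed when set

    def __post_init__(self) -> None:
        if not (0 < self.p_thresh < 1 and 0 < self.coverage <= 1
                and 0 <= self.r2_thresh <= 1 and 0 < self.alpha < 1):
            raise ValueError("threshold out of range")
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["ancestries"] = [dataclasses.asdict(a) for a in self.sim.ancestries]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "ancestries" in sim:
            sim["ancestries"] = tuple(Ancestry(**a) for a in sim["ancestries"])
        return cls(sim=SimConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    """Everything one run produced, in memory."""

    config: RunConfig
    scenario: Scenario
    qc_stats: dict[str, pd.DataFrame]
    qc_reports: dict[str, dict]
    meta: pd.DataFrame
    mixed_panel: LDPanel
    regions: list[Region]
    signals: list[IndependentSignal]
    credible_sets: list[finemapping.CredibleSet]
    loci: list[finemapping.Locus]
    gene_scores: dict[str, pd.DataFrame]
    gene_meta_z: pd.Series
    pops_fits: dict[str, pops_engine.PoPSFit]
    pops_meta: pd.Series
    pops_pct: pd.Series
    calls: list[prioritization.LocusCall]
    evidence: pd.DataFrame
    manifest: dict

    def locus(self, locus_id: str) -> finemapping.Locus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(f"unknown locus id {locus_id!r}")


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute every stage on a freshly simulated scenario.

    Writes all stage outputs plus a run manifest under ``outdir`` when
    given. Deterministic: identical config (including seed) reproduces
    identical outputs.
    """
    scenario = simulate_scenario(config.sim)
    genes = scenario.genes
    counts: dict[str, dict] = {}

    # --- sumstats: harmonize, AF-QC, meta ---------------------------------
    qc_stats: dict[str, pd.DataFrame] = {}
    qc_reports: dict[str, dict] = {}
    for anc in config.sim.ancestries:
        panel = scenario.panels[anc.label]
        harm, rep_h = sumstats.harmonize(scenario.sumstats[anc.label], panel)
        freqs = pd.Series(panel.freqs(), index=panel.variants["SNP"])
        qcd, rep_q = sumstats.af_qc(harm, freqs, config.abs_diff, config.fold)
        qc_stats[anc.label] = qcd
        qc_reports[anc.label] = {
            "harmonize": rep_h.to_dict(),
            "af_qc": rep_q.to_dict(),
        }
    meta = sumstats.meta_fixed_effects(list(qc_stats.values()), config.meta_scheme)
    counts["sumstats"] = {"n_meta_variants": len(meta)}

    # --- signal isolation -------------------------------------------------
    if config.ld_panel_ancestry is not None:
        mixed = scenario.panels[config.ld_panel_ancestry]
    else:
        mixed = combine_panels(
            [scenario.panels[a.label] for a in config.sim.ancestries],
            [a.n_eff for a in config.sim.ancestries],
        )
    regions = clump(meta, mixed, config.p_thresh, config.r2_thresh,
                    config.window_bp, config.pad_clump_bp)
    signals: list[IndependentSignal] = []
    for region in regions:
        hits = cojo_select(region, meta, mixed, config.p_thresh,
                           config.collinearity_r2)
        if hits:
            signals.extend(leave_one_out_condition(region, hits, meta, mixed))
    counts["signal_isolation"] = {
        "n_regions": len(regions),
        "n_independent_signals": len(signals),
    }

    # --- fine-mapping -----------------------------------------------------
    credible_sets = [
        finemapping.credible_set(s, config.coverage, config.prior_sd)
        for s in signals
    ]
    loci = [
        finemapping.define_locus(cs, genes, config.pad_locus_bp,
                                 locus_id=f"locus_{i + 1:03d}")
        for i, cs in enumerate(credible_sets)
    ]
    counts["finemapping"] = {
        "n_credible_sets": len(credible_sets),
        "n_loci": len(loci),
    }

    # --- gene association -------------------------------------------------
    gene_scores: dict[str, pd.DataFrame] = {}
    for anc in config.sim.ancestries:
        gene_scores[anc.label] = gene_assoc.score_genes(
            qc_stats[anc.label], scenario.panels[anc.label], genes,
            config.maf_min, config.min_variants,
        )
    gene_meta_z = gene_assoc.meta_gene_z(
        [(gene_scores[a.label]["Z"], a.n_eff) for a in config.sim.ancestries]
    )
    counts["gene_assoc"] = {
        "n_genes_scored": int(gene_meta_z.notna().sum()),
    }

    # --- PoPS -------------------------------------------------------------
    chrom_map = genes.set_index("GENE")["CHR"]
    pops_fits: dict[str, pops_engine.PoPSFit] = {}
    for anc in config.sim.ancestries:
        z = gene_scores[anc.label]["Z"]
        sel = pops_engine.select_features(z, scenario.features, config.alpha)
        pops_fits[anc.label] = pops_engine.loco_ridge(
            z, scenario.features, sel, chrom_map
        )
    pops_meta = pops_engine.meta_pops(
        [(pops_fits[a.label].scores, a.n_eff) for a in config.sim.ancestries],
        config.pops_meta_scheme,
    )
    pops_pct = pops_engine.pops_percentile(pops_meta)
    counts["pops_engine"] = {
        "n_selected_features": {
            a.label: int(len(pops_fits[a.label].selected))
            for a in config.sim.ancestries
        },
    }

    # --- prioritization ---------------------------------------------------
    calls = [
        prioritization.call_locus(locus, cs, genes, pops_meta, pops_pct,
                                  scenario.nonsyn, config.nonsyn_pip_thresh,
                                  config.nonsyn_rule)
        for locus, cs in zip(loci, credible_sets)
    ]
    evidence = prioritization.build_evidence_table(
        calls, {l.locus_id: l for l in loci}, gene_meta_z, pops_pct
    )
    counts["prioritization"] = {
        "n_loci_called": len(calls),
        "n_prioritized_genes": int(sum(c.prioritized_gene is not None for c in calls)),
    }

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "seed": config.sim.seed,
        "stages_completed": STAGES,
        "stage_counts": counts,
    }
    result = PipelineResult(
        config=config, scenario=scenario, qc_stats=qc_stats,
        qc_reports=qc_reports, meta=meta, mixed_panel=mixed, regions=regions,
        signals=signals, credible_sets=credible_sets, loci=loci,
        gene_scores=gene_scores, gene_meta_z=gene_meta_z, pops_fits=pops_fits,
        pops_meta=pops_meta, pops_pct=pops_pct, calls=calls,
        evidence=evidence, manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir) -> None:
    """Serialize every stage product into a workspace directory."""
    outdir = Path(outdir)
    scenario = result.scenario
    io.write_tsv(scenario.genes, outdir / "genes.tsv")
    io.write_genes_bed(scenario.genes, outdir / "genes.bed")
    io.write_tsv(scenario.features.reset_index(), outdir / "features.tsv")
    io.write_tsv(scenario.nonsyn, outdir / "nonsyn.tsv")
    for label, panel in scenario.panels.items():
        io.save_panel(panel, outdir / f"panel_{label}")
        io.write_tsv(scenario.sumstats[label], outdir / f"sumstats_{label}.tsv")
        io.write_tsv(result.qc_stats[label], outdir / "qc" / f"sumstats_{label}.qc.tsv")
    io.save_json(result.qc_reports, outdir / "qc" / "reports.json")
    io.write_tsv(result.meta, outdir / "meta.tsv")
    io.save_regions(result.regions, outdir / "regions.json")
    io.save_signals(result.signals, outdir / "signals")
    if result.credible_sets:
        io.save_credible_sets(result.credible_sets, outdir / "credible_sets.tsv")
    io.save_loci(result.loci, outdir / "loci.json", outdir / "loci.bed")
    scores = pd.concat(
        {label: df for label, df in result.gene_scores.items()}, axis=1
    )
    scores.columns = ["_".join(c) for c in scores.columns]
    scores["META_Z"] = result.gene_meta_z
    io.write_tsv(scores.reset_index(), outdir / "gene_scores.tsv")
    pops = pd.DataFrame(
        {
            **{f"POPS_{l}": f.scores for l, f in result.pops_fits.items()},
            "POPS_META": result.pops_meta,
            "POPS_PERCENTILE": result.pops_pct,
        }
    )
    io.write_tsv(pops.reset_index(names="GENE"), outdir / "pops_scores.tsv")
    io.write_tsv(result.evidence, outdir / "prioritized.tsv")
    candidates = pd.concat(
        [c.candidates.assign(LOCUS=c.locus_id) for c in result.calls],
        ignore_index=True,
    ) if result.calls else pd.DataFrame()
    io.write_tsv(candidates, outdir / "candidates.tsv")
    io.save_json(result.manifest, outdir / "manifest.json")


def locus_report(
    result: PipelineResult, locus_id: str
) -> dict[str, pd.DataFrame]:
    """Per-locus text report: variant panel and gene panel.

    Variants: position, marginal meta p, r² with the lead variant, and
    credible-set membership. Genes: span, raw meta PoPS score, genome-wide
    percentile, and flags against the genome-wide top-10%/top-1% PoPS
    thresholds.
    """
    locus = result.locus(locus_id)
    cs = next(c for c in result.credible_sets if c.signal_id == locus.signal_id)
    sig = next(s for s in result.signals if s.signal_id == locus.signal_id)

    reg = result.meta[
        (result.meta["CHR"] == locus.chrom)
        & (result.meta["POS"] >= locus.start)
        & (result.meta["POS"] <= locus.end)
    ].copy()
    panel = result.mixed_panel
    lead_col = panel.index_of([sig.lead])[0]
    r = panel.r_with(lead_col, panel.index_of(reg["SNP"]))
    in_cs = set(cs.members["SNP"])
    variants = pd.DataFrame(
        {
            "SNP": reg["SNP"],
            "POS": reg["POS"],
            "P": reg["P"],
            "R2_LEAD": r ** 2,
            "IN_CS": reg["SNP"].isin(in_cs),
        }
    ).reset_index(drop=True)

    top10 = float(result.pops_meta.quantile(0.90))
    top1 = float(result.pops_meta.quantile(0.99))
    genes = result.scenario.genes
    gsub = genes[genes["GENE"].isin(locus.genes)]
    gene_panel = pd.DataFrame(
        {
            "GENE": gsub["GENE"].to_numpy(),
            "START": gsub["START"].to_numpy(),
            "END": gsub["END"].to_numpy(),
            "POPS_RAW": gsub["GENE"].map(result.pops_meta).to_numpy(),
            "POPS_PERCENTILE": gsub["GENE"].map(result.pops_pct).to_numpy(),
        }
    )
    gene_panel["ABOVE_TOP10"] = gene_panel["POPS_RAW"] > top10
    gene_panel["ABOVE_TOP1"] = gene_panel["POPS_RAW"] > top1
    gene_panel.attrs["top10_threshold"] = top10
    gene_panel.attrs["top1_threshold"] = top1
    return {"variants": variants, "genes": gene_panel}


def evaluate_against_truth(result: PipelineResult) -> dict:
    """Recovery metrics of a run against the scenario's planted truth."""
    truth = result.scenario.truth
    causal_genes = set(truth.causal_genes)
    causal_snps = {cv.snp for cv in truth.causal_variants}

    n_cs_with_causal = 0
    n_signals_at_causal = 0
    for sig, cs in zip(result.signals, result.credible_sets):
        region_snps = set(sig.conditional_stats["SNP"])
        present = causal_snps & region_snps
        if present:
            n_signals_at_causal += 1
            if present & set(cs.members["SNP"]):
                n_cs_with_causal += 1

    prioritized = [c.prioritized_gene for c in result.calls
                   if c.prioritized_gene is not None]
    n_correct = sum(g in causal_genes for g in prioritized)
    pct = result.pops_pct
    causal_pct = pct.reindex(sorted(causal_genes)).dropna()
    return {
        "n_causal_loci": len(causal_genes),
        "n_signals": len(result.signals),
        "n_signals_at_causal_variant": n_signals_at_causal,
        "cs_coverage_rate": (n_cs_with_causal / n_signals_at_causal
                             if n_signals_at_causal else float("nan")),
        "n_prioritized": len(prioritized),
        "n_prioritized_causal": n_correct,
        "prioritization_precision": (n_correct / len(prioritized)
                                     if prioritized else float("nan")),
        "causal_gene_recall": n_correct / len(causal_genes),
        "mean_causal_pops_percentile": float(causal_pct.mean()),
    }
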