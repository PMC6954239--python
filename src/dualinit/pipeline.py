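"""End-to-end promoterome pipeline with config, manifest and reports.

The pipeline reads per-stage CTSS tables, a genome and gene models, then:
normalizes (TPM or power-law), classifies initiators, applies the two-level
expression filter, clusters per class, assigns clusters to promoter windows,
calls dual-initiation status per gene and writes every intermediate as plain
TSV/BED/JSON plus a run manifest (config hash, input checksums, record
counts).  Optional stages add component dynamics (SOM, anticorrelation) and
a treated/control component response analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ctss as ctss_mod
from . import dynamics as dyn
from . import perturb as pert
from . import promoters as prom
from .io import read_fasta, read_gene_models_bed12, read_gene_models_tsv

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    ctss_paths: dict[str, str]            # stage label -> TSV path
    genome_path: str
    gene_models_path: str
    outdir: str
    snorna_path: str | None = None
    repeats_path: str | None = None
    control_paths: dict[str, str] = field(default_factory=dict)
    treated_paths: dict[str, str] = field(default_factory=dict)
    primary_tpm: float = 1.0
    rescue_tpm: float = 0.5
    min_tpm: float = 3.0
    min_stages: int = 2
    max_gap: int = 20
    norm: str = "tpm"                     # "tpm" or "powerlaw"
    upstream: int = 500
    downstream: int = 300
    som_grid: tuple[int, int] = (4, 4)
    som_epochs: int = 30
    seed: int = 0
    report_stage: str | None = None       # default: next-to-last stage

    def __post_init__(self):
        for name in ("primary_tpm", "rescue_tpm", "min_tpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_stages < 1 or self.max_gap < 0:
            raise ValueError("min_stages must be >= 1 and max_gap >= 0")
        if self.upstream <= 0 or self.downstream <= 0:
            raise ValueError("promoter window must be positive")
        if self.norm not in ("tpm", "powerlaw"):
            raise ValueError(f"unknown normalization {self.norm!r}")
        self.som_grid = tuple(self.som_grid)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["som_grid"] = list(self.som_grid)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(cfg: PipelineConfig, record_counts: dict) -> dict:
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    inputs = dict(cfg.ctss_paths)
    inputs["genome"] = cfg.genome_path
    inputs["gene_models"] = cfg.gene_models_path
    return {
        "tool_version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()
                            if v and Path(v).exists()},
        "record_counts": record_counts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


# ---------------------------------------------------------------------------
# stage functions
# ---------------------------------------------------------------------------

def load_inputs(cfg: PipelineConfig):
    for label, path in {**cfg.ctss_paths, "genome": cfg.genome_path,
                        "gene_models": cfg.gene_models_path}.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"missing input ({label}): {path}")
    genome = read_fasta(cfg.genome_path)
    if cfg.gene_models_path.endswith((".bed", ".bed12")):
        genes = read_gene_models_bed12(cfg.gene_models_path)
    else:
        genes = read_gene_models_tsv(cfg.gene_models_path)
    tables = {stage: ctss_mod.read_ctss_table(path, stage)
              for stage, path in cfg.ctss_paths.items()}
    return genome, genes, tables


def normalize_stages(wide: pd.DataFrame, stage_cols: list[str],
                     norm: str) -> pd.DataFrame:
    out = wide.copy()
    for s in stage_cols:
        counts = wide[s].to_numpy(dtype=float)
        if norm == "powerlaw":
            out[s] = ctss_mod.powerlaw_normalize(counts)
        else:
            out[s] = ctss_mod.normalize_tpm(counts)
    return out


def process_ctss(cfg: PipelineConfig, genome, genes, tables):
    """Merge, normalize, classify and filter CTSSs; returns analysis state."""
    stages = list(tables)
    wide = ctss_mod.merge_stages(tables)
    logger.info("merged %d CTSS positions over %d stages", len(wide),
                len(stages))
    tpm = normalize_stages(wide, stages, cfg.norm)
    classified = ctss_mod.classify_table(genome, tpm)
    rates = prom.mapping_rate(classified, stages, genes,
                              cfg.upstream, cfg.downstream)
    filtered = ctss_mod.filter_ctss(classified, stages,
                                    cfg.primary_tpm, cfg.rescue_tpm)
    return stages, classified, filtered, rates


def make_clusters(cfg: PipelineConfig, filtered: pd.DataFrame,
                  stages: list[str]):
    clusters = ctss_mod.cluster_ctss(filtered, stages, cfg.max_gap)
    logger.info("built %d tag clusters (max_gap=%d)", len(clusters),
                cfg.max_gap)
    return clusters


def make_calls(cfg: PipelineConfig, clusters, genes, stages):
    assignment = prom.assign_clusters(clusters, genes,
                                      cfg.upstream, cfg.downstream)
    calls = prom.build_promoter_calls(clusters, assignment, genes,
                                      cfg.min_tpm, cfg.min_stages)
    n_assigned = sum(a is not None for a in assignment)
    logger.info("assigned %d/%d clusters to %d genes", n_assigned,
                len(assignment), len(genes))
    return assignment, calls


def report_summary(calls, mapping_rates: dict, stages: list[str],
                   report_stage: str | None = None) -> dict:
    """Headline statistics; every fraction ships with its num/denominator."""
    n = len(calls)
    by_status = {s: sum(c.di_status == s for c in calls)
                 for s in prom.DI_STATUSES}

    def frac(num, den):
        return {"numerator": int(num), "denominator": int(den),
                "fraction": (num / den) if den else 0.0}

    if report_stage is None:
        report_stage = stages[-2] if len(stages) >= 2 else stages[-1]
    si = stages.index(report_stage)
    dual = [c for c in calls if c.di_status == "DUAL"]
    dominance = [c.dominance[si] for c in dual]
    n_dom = sum(d is not None for d in dominance)
    offsets = [c.yc_offset for c in dual if c.yc_offset is not None]
    hist = pd.Series(offsets).value_counts().sort_index() if offsets else \
        pd.Series(dtype=int)
    summary = {
        "n_genes": n,
        "status_counts": by_status,
        "di_fraction": frac(by_status["DUAL"], n),
        "yr_only_fraction": frac(by_status["YR_ONLY"], n),
        "yc_only_fraction": frac(by_status["YC_ONLY"], n),
        "yc_promoters": frac(by_status["DUAL"] + by_status["YC_ONLY"], n),
        "yr_promoters": frac(by_status["DUAL"] + by_status["YR_ONLY"], n),
        "yc_in_di_of_yc": frac(
            by_status["DUAL"], by_status["DUAL"] + by_status["YC_ONLY"]),
        "report_stage": report_stage,
        "yc_dominant": frac(sum(d == "YC_DOM" for d in dominance), n_dom),
        "offset_histogram": {int(k): int(v) for k, v in hist.items()},
        "offset_mode": int(hist.idxmax()) if len(hist) else None,
        "offset_minus1": frac(int(hist.get(-1, 0)), len(offsets)),
        "mapping_rate_yr": mapping_rates.get("YR"),
        "mapping_rate_yc": mapping_rates.get("YC"),
    }
    return summary


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, force: bool = False) -> dict:
    """Run every stage and write artifacts + manifest under ``cfg.outdir``.

    Returns the summary dict.  Refuses to overwrite an existing manifest
    unless ``force`` is set.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} exists; pass force=True (--force) to rerun")

    genome, genes, tables = load_inputs(cfg)
    stages, classified, filtered, rates = process_ctss(cfg, genome, genes,
                                                       tables)
    clusters = make_clusters(cfg, filtered, stages)
    assignment, calls = make_calls(cfg, clusters, genes, stages)

    cluster_frame = ctss_mod.clusters_to_frame(clusters)
    cluster_frame["gene_id"] = [a if a is not None else "."
                                for a in assignment]
    cluster_frame.to_csv(outdir / "clusters.bed", sep="\t", index=False,
                         header=False)
    prom.calls_to_frame(calls).to_csv(outdir / "promoter_calls.tsv",
                                      sep="\t", index=False)

    dom_rows = [
        {"chrom": genes[0].chrom if genes else ".", "start0": p - 1, "end": p,
         "name": f"{c.gene_id}_{comp}", "score": 0, "strand": c.strand}
        for c in calls
        for comp, p in (("YR", c.dominant_yr_pos), ("YC", c.dominant_yc_pos))
        if p is not None
    ]
    pd.DataFrame(dom_rows).to_csv(outdir / "dominant_sites.bed", sep="\t",
                                  index=False, header=False)

    # dynamics on DUAL genes
    pairs = dyn.build_profiles(calls, stages)
    if pairs:
        anti = dyn.anticorrelation_rank(pairs)
        anti.to_csv(outdir / "anticorrelation.tsv", sep="\t", index=False)
        n_nodes = cfg.som_grid[0] * cfg.som_grid[1]
        if len(pairs) >= n_nodes:
            som = dyn.som_cluster(pairs, cfg.som_grid, cfg.seed,
                                  cfg.som_epochs)
            pd.DataFrame(
                {"gene_id": som.gene_ids,
                 "node": [som.node_of_gene[g] for g in som.gene_ids]}
            ).to_csv(outdir / "som_assignments.tsv", sep="\t", index=False)
        else:
            logger.info("skipping SOM: %d profiles < %d nodes", len(pairs),
                        n_nodes)

    summary = report_summary(calls, rates, stages, cfg.report_stage)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    counts = {
        "ctss_positions": int(len(classified)),
        "ctss_retained": int(len(filtered)),
        "tag_clusters": int(len(clusters)),
        "clusters_assigned": int(sum(a is not None for a in assignment)),
        "genes": int(len(genes)),
        "dual_genes": int(summary["status_counts"]["DUAL"]),
    }
    with open(manifest_path, "w") as fh:
        json.dump(build_manifest(cfg, counts), fh, indent=1, sort_keys=True)
    cfg.to_yaml(outdir / "config.yaml")
    return summary


def component_counts_by_gene(cfg: PipelineConfig, genome, genes,
                             control_tables, treated_tables) -> pd.DataFrame:
    """Per-gene YC/YR component totals in control and treated libraries.

    Both libraries are TPM-normalized so the 2x2 tables compare composition
    rather than depth; genes need both components detected in both
    conditions to enter the tested universe.
    """
    def totals(tables):
        stages = list(tables)
        wide = ctss_mod.merge_stages(tables)
        tpm = normalize_stages(wide, stages, "tpm")
        classified = ctss_mod.classify_table(genome, tpm)
        clusters = ctss_mod.cluster_ctss(classified, stages, cfg.max_gap)
        assignment = prom.assign_clusters(clusters, genes, cfg.upstream,
                                          cfg.downstream)
        out: dict[tuple[str, str], float] = {}
        for cl, gid in zip(clusters, assignment):
            if gid is None:
                continue
            key = (gid, cl.iclass)
            out[key] = out.get(key, 0.0) + cl.pooled_tpm
        return out

    t_ctrl = totals(control_tables)
    t_treat = totals(treated_tables)
    rows = []
    for g in genes:
        vals = {
            "yc_ctrl": t_ctrl.get((g.gene_id, "YC"), 0.0),
            "yr_ctrl": t_ctrl.get((g.gene_id, "YR"), 0.0),
            "yc_treat": t_treat.get((g.gene_id, "YC"), 0.0),
            "yr_treat": t_treat.get((g.gene_id, "YR"), 0.0),
        }
        if all(v > 0 for v in vals.values()):
            rows.append({"gene_id": g.gene_id, **vals})
    return pd.DataFrame(rows)


def run_perturbation(cfg: PipelineConfig) -> pd.DataFrame:
    """Treated-vs-control component response (Fisher + BH + KS + quadrants)."""
    genome = read_fasta(cfg.genome_path)
    if cfg.gene_models_path.endswith((".bed", ".bed12")):
        genes = read_gene_models_bed12(cfg.gene_models_path)
    else:
        genes = read_gene_models_tsv(cfg.gene_models_path)
    ctrl = {s: ctss_mod.read_ctss_table(p, s)
            for s, p in cfg.control_paths.items()}
    treat = {s: ctss_mod.read_ctss_table(p, s)
             for s, p in cfg.treated_paths.items()}
    counts = component_counts_by_gene(cfg, genome, genes, ctrl, treat)
    responses = pert.perturb_responses(counts)
    frame = pert.responses_to_frame(responses)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "perturb_responses.tsv", sep="\t", index=False)
    if len(frame) >= 2:
        d, p = pert.ks_compare(frame["lfc_yc"], frame["lfc_yr"])
        summary = pert.direction_summary(responses)
        summary.update({
            "ks_D": d,
            "ks_p": p,
            "n_significant": int(sum(r.padj <= 0.05 for r in responses)),
        })
        with open(outdir / "perturb_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return frame
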