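"""End-to-end pipeline orchestration.

Runs the stages in analysis order — synthetic generation (when requested)
-> RNA QC / normalization -> methylome QC and feature aggregation ->
variable-site screen and class enrichment -> methylation-expression
integration -> allelic analysis — writing every result table under the
output directory together with a manifest (file, rows, sha256) and the
effective configuration.  A stage failure stops the run and preserves the
outputs already written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic as al
from . import integration as integ
from . import methylome as meth
from . import rrbs
from . import transcriptome as tx
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat run configuration; unknown keys are rejected at load time."""

    outdir: str = "scmt_out"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    # thresholds (defaults mirror the stage functions)
    min_mean_rpkm: float = 0.1
    min_aligned: float = 0.20
    min_qc_genes: int = 3000
    promoter_min_sites: int = 5
    genebody_min_span: int = 500
    feature_min_depth: int = 5
    variable_min_cells: int | None = None
    variable_fdr: float = 0.01
    feature_fdr: float = 0.05
    feature_min_range: float = 0.3
    corr_min_cells: int = 5
    allelic_min_depth: int = 5
    allelic_min_rpkm: float = 5.0
    write_dataset_files: bool = False

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self, n_cells: int) -> None:
        if self.variable_min_cells is not None and self.variable_min_cells > n_cells:
            raise ValueError(
                f"variable_min_cells={self.variable_min_cells} exceeds "
                f"n_cells={n_cells}")
        for name in ("min_mean_rpkm", "variable_fdr", "feature_fdr"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.entries: list[dict] = []

    def write_table(self, df: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=index)
        self.entries.append({
            "file": name, "rows": int(len(df)), "sha256": _sha256(path),
        })
        return path

    def save(self, config: PipelineConfig) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump({"config": asdict(config), "outputs": self.entries},
                      fh, indent=2, sort_keys=True)
        return path


def run_pipeline(config: PipelineConfig,
                 dataset: SyntheticDataset | None = None) -> dict:
    """Execute all stages and return the run report (summary + manifest).

    ``dataset`` may be supplied directly; otherwise the ``synthetic``
    block of the config is used to generate one.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(outdir)
    summary: dict = {}

    stage = "synthetic"
    try:
        if dataset is None:
            syn = dict(config.synthetic)
            syn.setdefault("seed", config.seed)
            dataset = generate_dataset(SyntheticConfig(**syn))
        config.validate(n_cells=len(dataset.cells))
        if config.write_dataset_files:
            write_dataset(dataset, outdir / "dataset")
        ann = dataset.reference.annotation

        stage = "rrbs"
        logger.info("stage rrbs: fragment/CGI coverage")
        cov = rrbs.feature_coverage(dataset.fragments, ann.cgi)
        summary["cgi_coverage"] = {
            "n_total": cov.n_features_total, "n_covered": cov.n_features_covered,
            "fraction": cov.fraction_covered,
        }

        stage = "rna"
        logger.info("stage rna: QC, filtering, normalization, percentile")
        expr = dataset.expression
        qc = tx.library_qc(expr.cell_meta["aligned_fraction"], expr.rpkm,
                           min_aligned=config.min_aligned,
                           min_genes=config.min_qc_genes)
        man.write_table(qc, "rna_qc.tsv")
        ercc_mask = expr.rpkm.index.str.startswith("ERCC-")
        if ercc_mask.sum() >= 3:
            _, min_r = tx.ercc_concordance(expr.rpkm[ercc_mask])
            summary["ercc_min_r"] = min_r
        rpkm_genes = expr.rpkm[~ercc_mask]
        norm = tx.filter_and_normalize(rpkm_genes, config.min_mean_rpkm)
        pct = tx.percentile_layer(norm)
        man.write_table(norm, "rpkm_normalized.tsv")
        man.write_table(pct, "expression_percentile.tsv")
        summary["n_genes_expressed"] = int(len(norm))

        stage = "methylome"
        logger.info("stage methylome: conversion QC + feature aggregation")
        summary["conversion_rate"] = meth.conversion_rate(dataset.lambda_calls)
        prom_m = meth.feature_methylation(
            dataset.calls_by_cell, ann, "promoter",
            min_sites=config.promoter_min_sites,
            min_depth=config.feature_min_depth)
        body_m = meth.feature_methylation(
            dataset.calls_by_cell, ann, "genebody",
            min_span_bp=config.genebody_min_span,
            min_depth=config.feature_min_depth)
        man.write_table(prom_m.values, "promoter_methylation.tsv")
        man.write_table(body_m.values, "genebody_methylation.tsv")

        stage = "variable_sites"
        logger.info("stage variable_sites: variance screen + enrichment")
        var = meth.variable_sites(dataset.calls_by_cell,
                                  min_cells=config.variable_min_cells,
                                  fdr=config.variable_fdr)
        man.write_table(var, "variable_sites.tsv")
        tested = var.reset_index().rename(columns={"level_0": "chrom",
                                                   "level_1": "pos"})
        classes = meth.annotate_sites(tested, ann)
        bg = classes.value_counts()
        obs = classes[tested["significant"].to_numpy()].value_counts()
        summary["n_variable_sites"] = int(var["significant"].sum())
        summary["n_tested_sites"] = int(len(var))
        if summary["n_variable_sites"] > 0:
            enr = meth.enrichment(obs, bg)
            man.write_table(enr, "enrichment.tsv")
            summary["enrichment"] = {
                cls: {"fold": float(enr.loc[cls, "fold"]),
                      "p": float(enr.loc[cls, "p"])}
                for cls in enr.index}

        stage = "integration"
        logger.info("stage integration: correlations + gene patterns")
        strata = ann.promoter_classes()
        per_cell_prom = integ.per_cell_correlation(prom_m, pct, strata)
        man.write_table(per_cell_prom, "per_cell_promoter_correlation.tsv",
                        index=False)
        gb_strata = strata.rename(lambda g: g)  # gene-body strata = promoter class
        per_cell_body = integ.per_cell_correlation(body_m, pct, gb_strata)
        man.write_table(per_cell_body, "per_cell_genebody_correlation.tsv",
                        index=False)
        for name, tab in (("promoter", per_cell_prom), ("genebody", per_cell_body)):
            summary[f"per_cell_r_{name}"] = {
                str(s): float(tab[tab["stratum"] == s]["r"].mean())
                for s in tab["stratum"].unique()}
        per_gene = integ.per_gene_correlation(prom_m, pct,
                                              min_cells=config.corr_min_cells)
        man.write_table(per_gene, "per_gene_promoter_correlation.tsv")
        try:
            vm_prom = integ.variably_methylated_features(
                prom_m, min_cells=config.corr_min_cells,
                fdr=config.feature_fdr, min_range=config.feature_min_range)
            man.write_table(vm_prom, "variably_methylated_promoters.tsv")
            summary["n_variable_promoters"] = int(vm_prom["flagged"].sum())
            vm_body = integ.variably_methylated_features(
                body_m, min_cells=config.corr_min_cells,
                fdr=config.feature_fdr, min_range=config.feature_min_range)
            man.write_table(vm_body, "variably_methylated_genebodies.tsv")
            summary["n_variable_genebodies"] = int(vm_body["flagged"].sum())
        except ValueError as exc:
            logger.warning("variably-methylated screen skipped: %s", exc)
        patterns = integ.classify_gene_patterns(
            prom_m, pct, min_cells=config.corr_min_cells)
        man.write_table(patterns, "gene_patterns.tsv")
        counts = patterns["promoter_state"].value_counts()
        summary["promoter_states"] = {k: int(v) for k, v in counts.items()}

        stage = "allelic"
        logger.info("stage allelic: digitization + mono/bi-allelic analysis")
        all_calls = pd.concat(dataset.calls_by_cell.values(), ignore_index=True)
        digit = al.digitization_histogram(all_calls)
        summary["digitization"] = {k: float(v) for k, v in digit.items()}
        snps = al.filter_snps(dataset.snps)
        valid_ids = set(snps.loc[snps["valid"], "snp_id"])
        ac = dataset.allelic_counts
        ac = ac[ac["snp_id"].isin(valid_ids)]
        frag_calls = al.classify_fragments(ac, dataset.snp_fragment,
                                           min_site_depth=config.allelic_min_depth)
        man.write_table(frag_calls, "fragment_allelicity.tsv", index=False)
        call_counts = frag_calls["call"].value_counts()
        summary["fragment_allelicity"] = {k: int(v) for k, v in call_counts.items()}
        for which in ("bi-allelic", "mono-allelic"):
            try:
                hist = al.biallelic_methylation_distribution(
                    dataset.calls_by_cell, frag_calls, dataset.site_fragment,
                    which=which)
                summary[f"digitization_{which}"] = {
                    k: float(v) for k, v in hist.items()}
            except ValueError as exc:
                logger.warning("%s distribution skipped: %s", which, exc)
        expr_allelic = al.allelic_expression_matrix(
            ac, dataset.snp_gene, dataset.expression.rpkm,
            min_rpkm=config.allelic_min_rpkm)
        man.write_table(expr_allelic, "allelic_expression.tsv")
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        man.save(config)
        raise

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest_path = man.save(config)
    logger.info("pipeline complete: %d tables, manifest %s",
                len(man.entries), manifest_path)
    return {"summary": summary, "manifest": man.entries,
            "outdir": str(outdir)}
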