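"""Configuration-driven orchestration of the full analysis.

Stages: (optional) simulate -> variant QC -> phenotype preparation ->
association scan -> known-SNP subset tests with Bonferroni thresholds ->
grouped-statistics report for top hits.  Every stage logs records in / out /
excluded, and the counts reconcile exactly.  Result files are byte-identical
across reruns of the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from domdev import grouped, io, meta, models, phenotypes, qc, synthetic

__all__ = [
    "load_config",
    "validate_config",
    "run_pipeline",
    "make_report",
    "trunc_dp",
]

logger = logging.getLogger("domdev.pipeline")

_TOP_KEYS = {
    "seed", "out_dir", "simulate", "vcf", "cohort", "known_snps",
    "qc", "scan", "report",
}
_BINARY_TRAITS = ("obese", "severely_obese", "t2d")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    """Schema-check a run configuration before any stage executes."""
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" not in config and ("vcf" not in config or "cohort" not in config):
        raise ValueError("config needs either a 'simulate' block or both 'vcf' and 'cohort' paths")
    if not isinstance(config.get("seed", 0), int):
        raise ValueError("seed must be an integer")
    for key in ("vcf", "cohort", "known_snps"):
        if key in config and not Path(config[key]).exists():
            raise ValueError(f"{key} path does not exist: {config[key]}")
    qc_block = config.get("qc", {})
    if not isinstance(qc_block, dict):
        raise ValueError("qc block must be a mapping")
    qc.QCThresholds(**qc_block)  # validates ranges
    scan_block = config.get("scan", {})
    traits = scan_block.get("traits", ["bmi"])
    bad = [t for t in traits if t not in ("bmi",) + _BINARY_TRAITS]
    if bad:
        raise ValueError(f"unknown scan traits: {bad}")
    if scan_block.get("mode", "dosage") not in ("dosage", "hardcall"):
        raise ValueError("scan mode must be 'dosage' or 'hardcall'")


def _sim_config(block: dict, seed: int) -> synthetic.SimConfig:
    effects = tuple(
        synthetic.PlantedEffect(**eff) for eff in block.get("effects", [])
    )
    kwargs = {k: v for k, v in block.items() if k != "effects"}
    for key in ("maf_range", "info_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return synthetic.SimConfig(seed=seed, effect_spec=effects, **kwargs)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute all stages; returns a summary dict of paths and key numbers."""
    validate_config(config)
    out = Path(out_dir or config.get("out_dir", "domdev_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0)

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("domdev")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"out_dir": str(out)}
    try:
        logger.info("config_hash=%s seed=%d", _config_hash(config), seed)

        # --- inputs ---------------------------------------------------
        if "simulate" in config:
            sim = _sim_config(config["simulate"], seed)
            variants = synthetic.simulate_genotypes(sim)
            cohort = synthetic.simulate_phenotypes(sim, variants)
            io.write_vcf(variants, out / "genotypes.vcf", list(cohort["sample_id"]))
            io.write_cohort(cohort, out / "cohort.tsv")
            logger.info("simulate: %d variants, %d samples", len(variants), len(cohort))
        else:
            variants = list(io.read_vcf(config["vcf"]))
            cohort = io.read_cohort(config["cohort"])
            logger.info("load: %d variants, %d samples", len(variants), len(cohort))

        # --- variant QC -----------------------------------------------
        thresholds = qc.QCThresholds(**config.get("qc", {}))
        passing, reasons = qc.apply_filters(variants, thresholds)
        reason_rows = pd.DataFrame(
            {
                "vid": [v.vid for v in variants],
                "pass": [not reasons[v.vid] for v in variants],
                "reasons": [";".join(sorted(reasons[v.vid])) for v in variants],
            }
        )
        io.write_results(reason_rows, out / "qc_reasons.tsv")
        n_failed = len(variants) - len(passing)
        logger.info(
            "qc: in=%d out=%d excluded=%d", len(variants), len(passing), n_failed
        )
        assert len(passing) + n_failed == len(variants)
        summary["n_variants_in"] = len(variants)
        summary["n_variants_pass"] = len(passing)
        if not passing:
            logger.warning("qc: no variants passed; scan output will be empty")

        # --- phenotype preparation ------------------------------------
        prepared = phenotypes.prepare_phenotypes(cohort)
        table = prepared.table
        io.write_results(table, out / "phenotypes_prepared.tsv")
        n_bmi = int(table["bmi_invnorm"].notna().sum())
        logger.info(
            "prep: in=%d bmi_available=%d bmi_excluded=%d",
            len(table), n_bmi, len(table) - n_bmi,
        )

        # --- association scan -----------------------------------------
        scan_block = config.get("scan", {})
        traits = scan_block.get("traits", ["bmi"])
        mode = scan_block.get("mode", "dosage")
        results: dict[str, pd.DataFrame] = {}
        for trait in traits:
            if trait == "bmi":
                y = table["bmi_invnorm"].to_numpy()
                covars = cohort[["chip"]]
                kind = "quantitative"
            else:
                labels = table[trait]
                y = np.where(
                    labels == phenotypes.CASE, 1.0,
                    np.where(labels == phenotypes.CONTROL, 0.0, np.nan),
                )
                covars = cohort[["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5", "chip"]]
                kind = "binary"
            res = models.scan_table(passing, y, covars, trait_kind=kind, mode=mode)
            io.write_results(res, out / f"assoc_{trait}.tsv")
            if len(res):
                io.write_results(
                    models.qq_table(res["p_domdev"]), out / f"qq_{trait}.tsv"
                )
                lam = models.genomic_inflation(res["p_domdev"])
                logger.info("scan[%s]: %d variants, lambda_gc=%.3f", trait, len(res), lam)
                summary[f"lambda_{trait}"] = lam
            else:
                io.write_results(res, out / f"qq_{trait}.tsv")
                logger.info("scan[%s]: empty", trait)
            results[trait] = res

        # --- known-SNP subsets ----------------------------------------
        known_tables = {}
        if "known_snps" in config:
            known = io.read_known_snps(config["known_snps"])
            for trait, res in results.items():
                subset_ids = known.loc[known["trait"] == trait, "vid"]
                sub = res[res["vid"].isin(set(subset_ids))].copy()
                if len(sub):
                    thr = meta.bonferroni_threshold(0.05, len(sub))
                    sub["domdev_threshold"] = thr
                    sub["domdev_significant"] = sub["p_domdev"] < thr
                io.write_results(sub, out / f"known_snps_{trait}.tsv")
                logger.info("known[%s]: %d SNPs", trait, len(sub))
                known_tables[trait] = sub

        # --- grouped stats for the top dominance-deviation hit --------
        top_summary = None
        bmi_res = results.get("bmi")
        if bmi_res is not None and len(bmi_res):
            top = bmi_res.loc[bmi_res["p_domdev"].idxmin()]
            summary["top_domdev_vid"] = top["vid"]
            summary["top_domdev_p"] = float(top["p_domdev"])
            top_variant = next(v for v in passing if v.vid == top["vid"])
            top_summary = models.genotype_class_summary(
                top_variant, cohort["bmi_standard"].to_numpy()
            )
            logger.info("top domdev hit: %s p=%.3g", top["vid"], top["p_domdev"])

        report_text = make_report(
            results,
            class_summaries={summary.get("top_domdev_vid", ""): top_summary}
            if top_summary is not None
            else {},
            thresholds={
                "genome_wide": meta.bonferroni_threshold(0.05, max(len(passing), 1)),
            },
            options=config.get("report", {}),
        )
        (out / "report.md").write_text(report_text)
        summary["report"] = str(out / "report.md")
    finally:
        root.removeHandler(handler)
        handler.close()
    return summary


def trunc_dp(x: float, dp: int = 2) -> float:
    """Truncate toward zero at ``dp`` decimals (reproduces printed CIs)."""
    scale = 10**dp
    return math.trunc(round(x * scale, 6)) / scale


def format_class_row(summary: grouped.GenotypeClassSummary, dp: int = 2) -> list[str]:
    """Render "mean (lo, hi)" per genotype class with truncated CI bounds."""
    lo, hi = summary.ci95()
    rows = []
    for k in range(3):
        if np.isnan(summary.mean[k]):
            rows.append("NA")
        else:
            rows.append(
                f"{summary.mean[k]:.{dp}f} "
                f"({trunc_dp(lo[k], dp):.{dp}f}, {trunc_dp(hi[k], dp):.{dp}f})"
            )
    return rows


def format_or(result: grouped.OddsRatioResult, dp: int = 2) -> str:
    return (
        f"{result.or_value:.{dp}f} "
        f"({result.ci_low:.{dp}f}, {result.ci_high:.{dp}f})"
    )


def make_report(
    results: dict[str, pd.DataFrame],
    class_summaries: dict[str, grouped.GenotypeClassSummary] | None = None,
    or_tables: dict[str, grouped.OddsRatioResult] | None = None,
    thresholds: dict[str, float] | None = None,
    options: dict | None = None,
) -> str:
    """Markdown report: genotype-class mean/CI tables, OR tables, QQ data
    pointers and significance thresholds."""
    options = options or {}
    dp = int(options.get("ci_decimals", 2))
    lines = ["# domdev report", ""]

    if thresholds:
        lines.append("## Significance thresholds")
        lines.append("")
        for name, value in thresholds.items():
            lines.append(f"- {name}: {meta.render_one_sigfig(value)}")
        lines.append("")

    for trait, res in (results or {}).items():
        lines.append(f"## Association scan: {trait}")
        lines.append("")
        lines.append(f"- variants tested: {len(res)}")
        if len(res):
            lam = models.genomic_inflation(res["p_domdev"])
            lines.append(f"- genomic inflation (domdev): {lam:.3f}")
            top = res.loc[res["p_domdev"].idxmin()]
            lines.append(
                f"- top dominance-deviation hit: {top['vid']} "
                f"(p = {top['p_domdev']:.3g})"
            )
        lines.append("")

    if class_summaries:
        lines.append("## Trait values by genotype class")
        lines.append("")
        lines.append("| variant | hom-ref | het | hom-alt |")
        lines.append("|---|---|---|---|")
        for vid, summ in class_summaries.items():
            cells = format_class_row(summ, dp)
            lines.append(f"| {vid} | {cells[0]} | {cells[1]} | {cells[2]} |")
        lines.append("")

    if or_tables:
        lines.append("## Odds ratios")
        lines.append("")
        lines.append("| contrast | OR (95% CI) |")
        lines.append("|---|---|")
        for name, orr in or_tables.items():
            lines.append(f"| {name} | {format_or(orr, dp)} |")
        lines.append("")

    return "\n".join(lines)
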