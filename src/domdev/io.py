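"""Standard-format interchange: VCF 4.2 genotypes and tab-separated tables.

Genotypes are written as plain-text VCF with GT, DS and GP FORMAT fields and
a per-variant ``INFO=<score>`` info key; positions are 1-based.  Reading uses
cyvcf2 (htslib) and accepts records carrying any subset of {GP, DS, GT}:
probabilities are taken from GP when present, otherwise reconstructed from DS
(preserving dosage = P(het) + 2 P(hom-alt)), otherwise from the GT hard call.
Cohort and results tables are TSV with "NA" for missing values.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from domdev.synthetic import COHORT_COLUMNS, VariantRecord, validate_cohort

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_cohort",
    "read_cohort",
    "write_results",
    "read_known_snps",
]

logger = logging.getLogger(__name__)

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Hard-call genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">
##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities (hom-ref, het, hom-alt)">
"""

_GT_STRINGS = ("0/0", "0/1", "1/1")


def write_vcf(variants: Iterable[VariantRecord], path: str | Path, sample_ids: list[str] | None = None) -> None:
    """Write variants as uncompressed VCF 4.2 (GT, DS and GP per sample)."""
    variants = list(variants)
    path = Path(path)
    if variants:
        n = variants[0].n_samples
    else:
        n = len(sample_ids or [])
    if sample_ids is None:
        sample_ids = [f"S{i:07d}" for i in range(n)]
    if any(v.n_samples != len(sample_ids) for v in variants):
        raise ValueError("all variants must cover the same sample set")

    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted({v.chrom for v in variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos)):
            calls = v.hard_calls()
            probs = v.genotype_probs
            dosage = v.dosage
            fields = []
            for i in range(len(sample_ids)):
                if calls[i] < 0:
                    fields.append("./.:.:.,.,.")
                else:
                    fields.append(
                        f"{_GT_STRINGS[calls[i]]}:{dosage[i]:.8f}:"
                        f"{probs[i, 0]:.8f},{probs[i, 1]:.8f},{probs[i, 2]:.8f}"
                    )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t"
                f"INFO={v.info:.4f}\tGT:DS:GP\t" + "\t".join(fields) + "\n"
            )


def _probs_from_ds(ds: np.ndarray) -> np.ndarray:
    """Minimal-entropy probabilities consistent with a dosage in [0, 2]."""
    probs = np.zeros((ds.size, 3))
    low = ds <= 1.0
    probs[low, 1] = ds[low]
    probs[low, 0] = 1.0 - ds[low]
    probs[~low, 1] = 2.0 - ds[~low]
    probs[~low, 2] = ds[~low] - 1.0
    return probs


def read_vcf(path: str | Path) -> Iterator[VariantRecord]:
    """Stream :class:`VariantRecord` objects from a VCF.

    Records without GP, DS or a called GT for a sample mark that sample
    missing; records missing all three FORMAT fields entirely are skipped
    with a logged reason.
    """
    vcf = VCF(str(path))
    n = len(vcf.samples)
    for rec in vcf:
        if not rec.ALT:
            logger.warning("skipping %s: no ALT allele", rec.ID)
            continue
        probs = None
        try:
            gp = rec.format("GP")
        except KeyError:
            gp = None
        if gp is not None:
            probs = np.asarray(gp, dtype=float)
            probs[probs < -1] = np.nan  # htslib missing-value sentinel
            bad = ~np.isfinite(probs).all(axis=1)
            probs[bad] = np.nan
            ok = ~bad
            # renormalise float32/text round-off so rows sum to 1 exactly
            probs[ok] /= probs[ok].sum(axis=1, keepdims=True)
        else:
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                ds = np.asarray(ds, dtype=float).reshape(-1)
                ds[(ds < -1) | (ds > 2.0 + 1e-6)] = np.nan
                probs = np.full((n, 3), np.nan)
                ok = np.isfinite(ds)
                probs[ok] = _probs_from_ds(np.clip(ds[ok], 0.0, 2.0))
            else:
                gt = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
                if gt is None:
                    logger.warning("skipping %s: no GP/DS/GT data", rec.ID)
                    continue
                probs = np.full((n, 3), np.nan)
                lut = {0: 0, 1: 1, 3: 2}
                for code, cls in lut.items():
                    probs[gt == code] = 0.0
                    probs[gt == code, cls] = 1.0
        info = rec.INFO.get("INFO")
        yield VariantRecord(
            chrom=str(rec.CHROM),
            pos=int(rec.POS),
            vid=str(rec.ID or f"{rec.CHROM}:{rec.POS}"),
            ref_allele=str(rec.REF),
            alt_allele=str(rec.ALT[0]),
            info=float(info) if info is not None else 1.0,
            genotype_probs=probs,
        )


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort table as TSV with header; missing values as NA."""
    validate_cohort(cohort)
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    validate_cohort(cohort)
    return cohort


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write an association results table (stable column order, NA missing)."""
    results.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_known_snps(path: str | Path) -> pd.DataFrame:
    """Known-SNP list: TSV with columns vid, locus, effect_allele, trait."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"vid", "locus", "effect_allele", "trait"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"known-SNP list missing columns: {sorted(missing)}")
    if df.groupby("trait")["vid"].apply(lambda s: s.duplicated().any()).any():
        raise ValueError("duplicate vid within a trait's known-SNP list")
    return df
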