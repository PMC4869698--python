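"""Variant-level quality control.

Implements the three exclusion filters (imputation info, Hardy-Weinberg
exact-test p value, minor allele frequency), pairwise linkage disequilibrium
(r^2 and composite D') and greedy independence pruning used to count
effectively independent tests.

Filter boundaries follow strict-inequality exclusion: a variant is removed
only if info < min_info, HWE p < hwe_alpha, or MAF < min_maf, so values
exactly at a threshold pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from domdev.synthetic import VariantRecord

__all__ = [
    "QCThresholds",
    "LDResult",
    "allele_frequency",
    "minor_allele_frequency",
    "hwe_exact_test",
    "apply_filters",
    "pairwise_r2",
    "count_independent",
]


@dataclass(frozen=True)
class QCThresholds:
    min_info: float = 0.9
    hwe_alpha: float = 1e-6
    min_maf: float = 0.005

    def __post_init__(self) -> None:
        for name in ("min_info", "hwe_alpha", "min_maf"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class LDResult:
    r2: float
    d_prime: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1.0 + 1e-9):
            raise ValueError("r2 out of [0, 1]")
        if not (-1e-9 <= self.d_prime <= 1.0 + 1e-9):
            raise ValueError("d_prime out of [0, 1]")


def allele_frequency(variant: VariantRecord) -> float:
    """Alt-allele frequency: mean dosage over non-missing samples, halved."""
    d = variant.dosage
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError(f"variant {variant.vid}: all samples missing")
    return float(d.mean() / 2.0)


def minor_allele_frequency(variant: VariantRecord) -> float:
    f = allele_frequency(variant)
    return min(f, 1.0 - f)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, the number of heterozygotes
    under HWE follows the distribution of Levene/Haldane; the returned p
    value is the sum of the probabilities of all heterozygote counts whose
    probability does not exceed that of the observed count (the
    Wigginton-Cutler-Abecasis formulation).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("total genotype count must be >= 1")

    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # heterozygote count shares the parity of the rare-allele count
    het_obs = n_het
    probs = np.zeros(n_rare + 1)

    # start from the mode-adjacent midpoint and fill by recurrence
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != n_rare % 2:
        mid += 1
    if mid > n_rare:
        mid -= 2
    probs[mid] = 1.0

    het = mid
    while het >= 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        # P(het-2) / P(het) = het (het-1) / (4 (hom_r+1)(hom_c+1))
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    het = mid
    while het <= n_rare - 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        # P(het+2) / P(het) = 4 hom_r hom_c / ((het+1)(het+2))
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 1) * (het + 2))
        het += 2

    total = probs.sum()
    p_obs = probs[het_obs]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum() / total
    return float(min(p, 1.0))


def _hard_call_counts(variant: VariantRecord) -> tuple[int, int, int]:
    calls = variant.hard_calls()
    calls = calls[calls >= 0]
    return (
        int((calls == 0).sum()),
        int((calls == 1).sum()),
        int((calls == 2).sum()),
    )


def apply_filters(
    variants: list[VariantRecord], thresholds: QCThresholds | None = None
) -> tuple[list[VariantRecord], dict[str, set[str]]]:
    """Apply info / HWE / MAF filters.

    Returns the passing variants (input order preserved) and a mapping from
    variant id to the set of failed criteria (``{"info", "hwe", "maf"}``);
    every failed criterion is recorded, not just the first.  Variants with
    an empty reason set pass.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    passing: list[VariantRecord] = []
    reasons: dict[str, set[str]] = {}
    for v in variants:
        failed: set[str] = set()
        if v.info < thresholds.min_info:
            failed.add("info")
        if hwe_exact_test(*_hard_call_counts(v)) < thresholds.hwe_alpha:
            failed.add("hwe")
        if minor_allele_frequency(v) < thresholds.min_maf:
            failed.add("maf")
        reasons[v.vid] = failed
        if not failed:
            passing.append(v)
    return passing, reasons


def pairwise_r2(a: VariantRecord, b: VariantRecord) -> LDResult:
    """Squared dosage correlation plus a composite (phase-free) D'.

    D' uses the Burrows composite disequilibrium Delta = cov(g_a, g_b)/2
    normalised by its allele-frequency bound; it is descriptive only and is
    never used for filtering.
    """
    da, db = a.dosage, b.dosage
    if da.shape != db.shape:
        raise ValueError("variants cover different sample sets")
    ok = ~(np.isnan(da) | np.isnan(db))
    da, db = da[ok], db[ok]
    if da.std() == 0 or db.std() == 0:
        raise ValueError("monomorphic variant in LD computation")
    r = np.corrcoef(da, db)[0, 1]
    r2 = float(min(r * r, 1.0))

    pa = da.mean() / 2.0
    pb = db.mean() / 2.0
    delta = float(np.cov(da, db, ddof=0)[0, 1] / 2.0)
    if delta >= 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = 1.0 if d_max == 0 else min(abs(delta) / d_max, 1.0)
    return LDResult(r2=r2, d_prime=float(d_prime))


def count_independent(
    variants: list[VariantRecord],
    r2_threshold: float = 0.9,
    window_variants: int = 1000,
    window_bp: int = 1_000_000,
) -> int:
    """Greedy pruning count of effectively independent variants.

    Variants are visited in (chrom, position) order; a variant is retained
    unless its r^2 with an already-retained variant within the sliding
    window (at most ``window_variants`` retained variants back and within
    ``window_bp`` base pairs on the same chromosome) exceeds the threshold.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos))
    retained: list[VariantRecord] = []
    for v in ordered:
        independent = True
        for kept in reversed(retained[-window_variants:]):
            if kept.chrom != v.chrom or v.pos - kept.pos > window_bp:
                break
            try:
                ld = pairwise_r2(v, kept)
            except ValueError:
                continue  # monomorphic: uninformative, treat as unlinked
            if ld.r2 > r2_threshold:
                independent = False
                break
        if independent:
            retained.append(v)
    return len(retained)
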