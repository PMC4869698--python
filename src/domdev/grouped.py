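"""Grouped-statistics engine.

Works entirely from printed summary statistics: genotype-class (n, mean, SD)
triplets, 2x2 case-control counts and published odds ratios.  Grouped fits
are exactly equivalent to individual-level OLS on any dataset with matching
class moments, which is what makes published tables re-analysable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenotypeClassSummary",
    "TwoByTwoTable",
    "OddsRatioResult",
    "GroupedFit",
    "fit_from_class_summaries",
    "variance_increment",
    "pooled_sd",
    "odds_ratio",
    "expected_hom_or_under_additive",
    "expected_het_or_under_additive",
    "bmi_diff_to_kg",
]

_Z95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass
class GenotypeClassSummary:
    """(n, mean, SD) for the hom-ref, het and hom-alt genotype classes.

    Arrays are length 3 in that order; empty classes carry NaN mean/SD.
    """

    n: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        for arr in (self.n, self.mean, self.sd):
            if arr.shape != (3,):
                raise ValueError("class summary arrays must have length 3")
        present = ~np.isnan(self.mean)
        if (self.n[present] <= 0).any():
            raise ValueError("class count must be positive where a mean is present")
        if (self.sd[present & ~np.isnan(self.sd)] < 0).any():
            raise ValueError("class SDs must be nonnegative")

    @property
    def total_n(self) -> float:
        return float(self.n.sum())

    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-class 95% CI: mean +/- 1.96 SD / sqrt(n)."""
        half = _Z95 * self.sd / np.sqrt(self.n)
        return self.mean - half, self.mean + half


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts: a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be nonnegative")


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    log_se: float
    zero_cell_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI must contain the point estimate")
        if min(self.or_value, self.ci_low, self.ci_high) <= 0:
            raise ValueError("odds ratios must be positive")


@dataclass(frozen=True)
class GroupedFit:
    """Weighted least-squares fit on genotype-class means.

    ``beta_domdev`` is None for the additive model.  Sums of squares are on
    the individual-level scale: ``ss_model`` is the explained between-class
    SS, ``ss_within`` the pooled within-class SS, ``ss_total`` their sum with
    the residual between-class SS.
    """

    beta0: float
    beta_add: float
    beta_domdev: float | None
    ss_model: float
    ss_between: float
    ss_within: float
    ss_total: float

    @property
    def r2(self) -> float:
        return self.ss_model / self.ss_total


def fit_from_class_summaries(
    summary: GenotypeClassSummary, model: str = "genotypic"
) -> GroupedFit:
    """Fit class means by weighted least squares (weights = class counts).

    The genotypic fit (intercept + additive 0/1/2 term + heterozygote 0/1/0
    term) is saturated on three classes, so it reproduces the class means
    exactly: beta0 = m0, beta_add = (m2 - m0)/2, beta_domdev =
    m1 - (m0 + m2)/2.  The additive fit is the weighted regression of class
    means on allele count.
    """
    if model not in ("additive", "genotypic"):
        raise ValueError(f"unknown model {model!r}")
    n, m, sd = summary.n, summary.mean, summary.sd
    if np.isnan(m).any() or (n <= 0).any():
        raise ValueError("all three genotype classes must be present")

    x = np.array([0.0, 1.0, 2.0])
    grand = float((n * m).sum() / n.sum())
    ss_between = float((n * (m - grand) ** 2).sum())
    ss_within = float(((n - 1.0) * sd**2).sum())
    ss_total = ss_between + ss_within

    if model == "genotypic":
        beta0 = float(m[0])
        beta_add = float((m[2] - m[0]) / 2.0)
        beta_domdev = float(m[1] - (m[0] + m[2]) / 2.0)
        ss_model = ss_between  # saturated: all between-class SS explained
        return GroupedFit(beta0, beta_add, beta_domdev, ss_model, ss_between, ss_within, ss_total)

    xbar = float((n * x).sum() / n.sum())
    sxx = float((n * (x - xbar) ** 2).sum())
    sxy = float((n * (x - xbar) * (m - grand)).sum())
    slope = sxy / sxx
    beta0 = grand - slope * xbar
    ss_model = slope * sxy  # = slope^2 * Sxx
    return GroupedFit(beta0, slope, None, ss_model, ss_between, ss_within, ss_total)


def variance_increment(summary: GenotypeClassSummary) -> float:
    """Additional percent of trait variance explained by the genotypic model
    over the additive one (both against the same total SS)."""
    gen = fit_from_class_summaries(summary, "genotypic")
    add = fit_from_class_summaries(summary, "additive")
    if gen.ss_total <= 0:
        raise ValueError("degenerate total sum of squares")
    return 100.0 * (gen.r2 - add.r2)


def pooled_sd(summary: GenotypeClassSummary) -> float:
    """Trait SD pooled across genotype classes (total SS / (N - 1))."""
    fit = fit_from_class_summaries(summary, "genotypic")
    return math.sqrt(fit.ss_total / (summary.total_n - 1.0))


def odds_ratio(table: TwoByTwoTable) -> OddsRatioResult:
    """Woolf odds ratio with 95% CI on the log scale.

    A zero cell triggers the Haldane-Anscombe 0.5 correction on every cell
    and flags the result.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_value = (a * d) / (b * c)
    log_se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = math.log(or_value)
    return OddsRatioResult(
        or_value=or_value,
        ci_low=math.exp(log_or - _Z95 * log_se),
        ci_high=math.exp(log_or + _Z95 * log_se),
        log_se=log_se,
        zero_cell_corrected=corrected,
    )


def expected_hom_or_under_additive(or_het: float) -> float:
    """Homozygote OR implied by a per-allele multiplicative model: or_het^2."""
    if or_het <= 0:
        raise ValueError("odds ratio must be positive")
    return or_het * or_het


def expected_het_or_under_additive(or_hom: float) -> float:
    """Heterozygote OR implied by a per-allele multiplicative model:
    sqrt(or_hom)."""
    if or_hom <= 0:
        raise ValueError("odds ratio must be positive")
    return math.sqrt(or_hom)


def bmi_diff_to_kg(delta_bmi: float, height: float) -> float:
    """Convert a BMI difference (kg/m^2) to kg at a given height (m)."""
    if height <= 0:
        raise ValueError("height must be positive")
    return delta_bmi * height * height
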