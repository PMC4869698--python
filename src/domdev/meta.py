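"""Fixed-effects meta-analysis, significance thresholds and power.

Standard errors can be recovered from a 95% CI or from a two-sided p value
when not given directly; precedence is explicit SE > CI-derived > p-derived.
Power for a 1-df test uses the non-central chi-square with non-centrality
n * (variance explained), the classic quantitative-trait formulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "MetaStudy",
    "MetaResult",
    "PowerSpec",
    "se_from_ci",
    "se_from_p",
    "recover_se",
    "fixed_effects_meta",
    "bonferroni_threshold",
    "render_one_sigfig",
    "power_1df",
    "recessive_variance_explained",
    "effective_n_case_control",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class MetaStudy:
    """One study's effect estimate for meta-analysis."""

    label: str
    beta: float
    n: int
    se: float | None = None
    ci: tuple[float, float] | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.se is None and self.ci is None and self.p is None:
            raise ValueError(f"study {self.label!r}: need at least one of se, ci, p")


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    n_total: int


@dataclass(frozen=True)
class PowerSpec:
    n: int
    r2: float
    alpha: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must lie in (0, 1)")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")


def se_from_ci(ci: tuple[float, float]) -> float:
    """SE implied by a 95% CI: width / (2 * 1.959964)."""
    lo, hi = ci
    if hi <= lo:
        raise ValueError("inverted confidence bounds")
    return (hi - lo) / (2.0 * _Z95)


def se_from_p(beta: float, p: float) -> float:
    """SE implied by a two-sided normal p value: |beta| / z(p/2)."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    z = stats.norm.isf(p / 2.0)
    if z <= 0:
        raise ValueError("p too large to recover an SE")
    return abs(beta) / z


def recover_se(study: MetaStudy) -> float:
    """SE with precedence: explicit > CI-derived > p-derived."""
    if study.se is not None:
        return study.se
    if study.ci is not None:
        return se_from_ci(study.ci)
    return se_from_p(study.beta, study.p)


def fixed_effects_meta(studies: list[MetaStudy]) -> MetaResult:
    """Inverse-variance weighted fixed-effects combination."""
    if len(studies) < 2:
        raise ValueError("meta-analysis needs at least two studies")
    weights = []
    for s in studies:
        se = recover_se(s)
        if se <= 0:
            raise ValueError(f"study {s.label!r}: nonpositive SE")
        weights.append(1.0 / (se * se))
    wsum = sum(weights)
    beta = sum(w * s.beta for w, s in zip(weights, studies)) / wsum
    se = 1.0 / math.sqrt(wsum)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MetaResult(beta=beta, se=se, z=z, p=float(p), n_total=sum(s.n for s in studies))


def bonferroni_threshold(alpha_total: float, n_tests: int) -> float:
    """Per-test threshold alpha / m."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha_total <= 1.0):
        raise ValueError("alpha_total must lie in (0, 1]")
    return alpha_total / n_tests


def render_one_sigfig(value: float) -> str:
    """One-significant-figure scientific rendering, half-away-from-zero.

    E.g. 3.33e-9 -> "3e-09", 6.94e-4 -> "7e-04", 7.58e-4 -> "8e-04".
    """
    if value <= 0:
        raise ValueError("value must be positive")
    exponent = math.floor(math.log10(value))
    mantissa = value / 10**exponent
    m = math.floor(mantissa + 0.5)  # half-away-from-zero for positives
    if m == 10:
        m, exponent = 1, exponent + 1
    return f"{m}e{exponent:+03d}"


def one_sigfig(value: float) -> float:
    """Numeric counterpart of :func:`render_one_sigfig`."""
    if value <= 0:
        raise ValueError("value must be positive")
    exponent = math.floor(math.log10(value))
    mantissa = value / 10**exponent
    m = math.floor(mantissa + 0.5)
    if m == 10:
        m, exponent = 1, exponent + 1
    return float(f"{m}e{exponent}")


def power_1df(spec: PowerSpec) -> float:
    """Power of a 1-df chi-square test.

    Non-centrality NCP = n * r2; power is the upper-tail probability of the
    non-central chi-square beyond the central 1-df quantile at 1 - alpha.
    """
    if spec.alpha >= 1.0:
        return 1.0
    ncp = spec.n * spec.r2
    crit = stats.chi2.isf(spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def recessive_variance_explained(effect: float, allele_freq: float, trait_sd: float) -> float:
    """Percent of trait variance from a purely recessive shift.

    The homozygote indicator has frequency q^2 under HWE, hence variance
    q^2 (1 - q^2); the explained fraction is effect^2 * q^2 (1 - q^2) /
    trait_sd^2, returned in percent.
    """
    if not (0.0 < allele_freq < 1.0):
        raise ValueError("allele_freq must lie in (0, 1)")
    if trait_sd <= 0:
        raise ValueError("trait_sd must be positive")
    q2 = allele_freq * allele_freq
    return 100.0 * effect * effect * q2 * (1.0 - q2) / (trait_sd * trait_sd)


def effective_n_case_control(n_cases: int, n_controls: int) -> float:
    """Quantitative-trait-equivalent sample size: 4 / (1/Ncase + 1/Nctrl)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)
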