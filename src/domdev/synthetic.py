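"""Synthetic cohort generation.

Generates genotype and phenotype data with the statistical structure the
downstream analysis assumes: Hardy-Weinberg genotype frequencies across a
minor-allele-frequency spectrum, imputation-style genotype probabilities with
a tunable info score, standard GWAS covariates, a right-skewed quantitative
trait (BMI-like) with planted additive and dominance-deviation effects, a
second impedance-style BMI measure with occasional gross discordance, and
questionnaire-style type 2 diabetes fields.

Everything is deterministic under ``SimConfig.seed``: the single integer seed
is expanded into independent per-stage substreams so each stage is
individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantedEffect",
    "SimConfig",
    "VariantRecord",
    "COHORT_COLUMNS",
    "simulate_genotypes",
    "simulate_phenotypes",
    "validate_cohort",
]

#: Column contract for the cohort table (one row per sample).
COHORT_COLUMNS = [
    "sample_id",
    "bmi_standard",
    "bmi_impedance",
    "age",
    "sex",
    "centre",
    "chip",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "pc5",
    "t2d_self_report",
    "age_at_diagnosis",
    "insulin_first_year",
    "years_since_diagnosis",
]

_TRAITS = ("bmi", "t2d_liability")


@dataclass(frozen=True)
class PlantedEffect:
    """A genetic effect planted at one simulated variant.

    ``beta_add`` is the per-allele additive effect and ``beta_domdev`` the
    heterozygote deviation (0/1/0 coding), both in trait-SD units for the
    quantitative trait and in liability (log-odds) units for the binary one.
    A pure recessive shift of ``delta`` corresponds to
    ``beta_add = delta / 2, beta_domdev = -delta / 2``.
    """

    variant_index: int
    beta_add: float
    beta_domdev: float
    trait: str = "bmi"

    def __post_init__(self) -> None:
        if self.trait not in _TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}; expected one of {_TRAITS}")


@dataclass(frozen=True)
class SimConfig:
    """Generative knobs for a synthetic cohort."""

    n_samples: int = 120286
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    info_range: tuple[float, float] = (0.9, 1.0)
    seed: int = 0
    effect_spec: tuple[PlantedEffect, ...] = ()
    bmi_base_mean: float = 27.4
    bmi_base_sd: float = 4.8
    skew: float = 0.0
    discordance_rate: float = 0.0
    impedance_missing_rate: float = 0.0
    impedance_noise_sd: float = 0.2
    # fractions of disease-positive samples whose questionnaire answers
    # violate each downstream exclusion rule
    frac_insulin_first_year: float = 0.0
    frac_young_diagnosis: float = 0.0
    frac_unknown_diagnosis_age: float = 0.0
    frac_recent_diagnosis: float = 0.0
    frac_type1_reports: float = 0.0
    t2d_base_log_odds: float = -3.3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (isinstance(self.n_samples, (int, np.integer)) and self.n_samples > 0):
            raise ValueError("n_samples must be a positive integer")
        if not (isinstance(self.n_variants, (int, np.integer)) and self.n_variants > 0):
            raise ValueError("n_variants must be a positive integer")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        ilo, ihi = self.info_range
        if not (0.0 < ilo <= ihi <= 1.0):
            raise ValueError("info_range must satisfy 0 < low <= high <= 1")
        for name in (
            "bmi_base_mean",
            "bmi_base_sd",
            "skew",
            "discordance_rate",
            "impedance_missing_rate",
            "impedance_noise_sd",
            "frac_insulin_first_year",
            "frac_young_diagnosis",
            "frac_unknown_diagnosis_age",
            "frac_recent_diagnosis",
            "frac_type1_reports",
            "t2d_base_log_odds",
        ):
            value = getattr(self, name)
            if not math.isfinite(float(value)):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.bmi_base_sd <= 0:
            raise ValueError("bmi_base_sd must be positive")
        if self.skew < 0:
            raise ValueError("skew must be nonnegative")
        for name in (
            "discordance_rate",
            "impedance_missing_rate",
            "frac_insulin_first_year",
            "frac_young_diagnosis",
            "frac_unknown_diagnosis_age",
            "frac_recent_diagnosis",
            "frac_type1_reports",
        ):
            value = float(getattr(self, name))
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for eff in self.effect_spec:
            if not (0 <= eff.variant_index < self.n_variants):
                raise ValueError(
                    f"planted effect variant_index {eff.variant_index} out of "
                    f"range for n_variants={self.n_variants}"
                )

    def substream(self, stage: str) -> np.random.Generator:
        """Independent generator for a named pipeline stage."""
        stages = ("genotypes", "covariates", "bmi", "t2d")
        if stage not in stages:
            raise ValueError(f"unknown stage {stage!r}")
        children = np.random.SeedSequence(self.seed).spawn(len(stages))
        return np.random.default_rng(children[stages.index(stage)])


@dataclass
class VariantRecord:
    """One variant's identity plus per-sample genotype probabilities.

    ``genotype_probs`` is an (n_samples, 3) array of
    (P(hom-ref), P(het), P(hom-alt)) rows summing to 1; missing samples are
    encoded as all-NaN rows.  Dosage is always derived from the probabilities
    so the invariant ``dosage = P(het) + 2 P(hom-alt)`` holds by construction.
    """

    chrom: str
    pos: int
    vid: str
    ref_allele: str
    alt_allele: str
    info: float
    genotype_probs: np.ndarray
    effect_allele: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.genotype_probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ValueError("genotype_probs must have shape (n_samples, 3)")
        self.genotype_probs = probs
        if not self.effect_allele:
            self.effect_allele = self.alt_allele
        present = ~np.isnan(probs).any(axis=1)
        if present.any():
            block = probs[present]
            if (block < -1e-12).any():
                raise ValueError("genotype probabilities must be nonnegative")
            if np.abs(block.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("genotype probabilities must sum to 1 within 1e-9")

    @property
    def n_samples(self) -> int:
        return self.genotype_probs.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.genotype_probs).any(axis=1)

    @property
    def dosage(self) -> np.ndarray:
        """Expected alt-allele count per sample in [0, 2]; NaN where missing."""
        p = self.genotype_probs
        return p[:, 1] + 2.0 * p[:, 2]

    def hard_calls(self) -> np.ndarray:
        """Maximum-probability genotype (0/1/2); ties break toward fewer alt
        alleles; -1 where missing."""
        calls = np.full(self.n_samples, -1, dtype=np.int8)
        ok = ~self.missing_mask
        # np.argmax returns the first maximum, i.e. the genotype with fewer
        # alt alleles on ties
        calls[ok] = np.argmax(self.genotype_probs[ok], axis=1)
        return calls


def _hwe_probs(q: float) -> np.ndarray:
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


def simulate_genotypes(config: SimConfig) -> list[VariantRecord]:
    """Draw variants with HWE hard calls and info-score-blurred probabilities.

    Per variant: an alt-allele frequency is drawn uniformly from
    ``maf_range`` and hard genotypes from the HWE proportions p^2, 2pq, q^2.
    An info target is drawn from ``info_range`` and each sample's one-hot
    genotype vector is mixed with the population HWE vector using weight
    ``w = 1 - sqrt(info)``; this leaves dosage means unbiased and makes the
    expected ratio of dosage variance to 2pq equal to the info target.
    """
    config.validate()
    rng = config.substream("genotypes")
    n = config.n_samples
    records: list[VariantRecord] = []
    for j in range(config.n_variants):
        q = rng.uniform(*config.maf_range)
        info = rng.uniform(*config.info_range)
        hwe = _hwe_probs(q)
        hard = rng.choice(3, size=n, p=hwe)
        onehot = np.zeros((n, 3))
        onehot[np.arange(n), hard] = 1.0
        w = 1.0 - math.sqrt(info)
        probs = (1.0 - w) * onehot + w * hwe
        records.append(
            VariantRecord(
                chrom="1",
                pos=10_000 + 2_000 * j,
                vid=f"sim{j:05d}",
                ref_allele="A",
                alt_allele="G",
                info=float(info),
                genotype_probs=probs,
            )
        )
    return records


def realised_info(variant: VariantRecord) -> float:
    """Observed dosage variance over the 2pq expected under HWE."""
    d = variant.dosage
    d = d[~np.isnan(d)]
    q = d.mean() / 2.0
    denom = 2.0 * q * (1.0 - q)
    if denom == 0:
        return float("nan")
    return float(d.var(ddof=0) / denom)


def _skewed_noise(rng: np.random.Generator, n: int, skew: float) -> np.ndarray:
    """Zero-mean unit-SD noise; right-skewed via an exponentiated normal.

    ``skew`` is the log-scale SD of the lognormal before standardisation;
    skew = 0 degenerates to a standard normal.
    """
    z = rng.standard_normal(n)
    if skew == 0.0:
        return z
    raw = np.exp(skew * z)
    mean = math.exp(skew * skew / 2.0)
    sd = math.sqrt((math.exp(skew * skew) - 1.0) * math.exp(skew * skew))
    return (raw - mean) / sd


def _planted_contributions(
    config: SimConfig, variants: list[VariantRecord], trait: str
) -> np.ndarray:
    """Sum of beta_add * g + beta_domdev * h over planted effects (hard calls)."""
    total = np.zeros(config.n_samples)
    for eff in config.effect_spec:
        if eff.trait != trait:
            continue
        if eff.variant_index >= len(variants):
            raise ValueError(
                f"planted effect refers to variant {eff.variant_index} but only "
                f"{len(variants)} variants supplied"
            )
        g = variants[eff.variant_index].hard_calls().astype(float)
        g[g < 0] = np.nan
        h = (g == 1).astype(float)
        total += np.nan_to_num(eff.beta_add * g + eff.beta_domdev * h)
    return total


def simulate_phenotypes(config: SimConfig, variants: list[VariantRecord]) -> pd.DataFrame:
    """Build the cohort table (phenotypes, covariates, questionnaire fields).

    BMI is ``base_mean + (planted effects) * base_sd + noise * base_sd`` with
    optionally right-skewed noise.  The impedance BMI equals the standard BMI
    plus small noise, except with probability ``discordance_rate`` a gross
    offset far beyond 5 SD of the ordinary differences is added.  Disease
    status is drawn from a logistic model on age, sex and planted liability
    effects, and the questionnaire fields are filled so that configurable
    fractions of positives violate each downstream exclusion rule.
    """
    config.validate()
    n = config.n_samples
    rng_cov = config.substream("covariates")
    rng_bmi = config.substream("bmi")
    rng_t2d = config.substream("t2d")

    age = rng_cov.uniform(40.0, 70.0, size=n)
    sex = rng_cov.integers(0, 2, size=n)
    centre = rng_cov.choice([f"centre{i}" for i in range(1, 6)], size=n)
    chip = rng_cov.choice(["chipA", "chipB"], size=n)
    pcs = rng_cov.standard_normal((n, 5))

    genetic_bmi = _planted_contributions(config, variants, "bmi")
    noise = _skewed_noise(rng_bmi, n, config.skew)
    bmi = config.bmi_base_mean + (genetic_bmi + noise) * config.bmi_base_sd

    impedance = bmi + rng_bmi.normal(0.0, config.impedance_noise_sd, size=n)
    gross = rng_bmi.random(n) < config.discordance_rate
    # offset of 10 kg/m^2: ~50 SD of the ordinary differences, and still far
    # beyond 5 SD of the mixture when the discordance rate is small
    impedance[gross] += np.where(rng_bmi.random(gross.sum()) < 0.5, -10.0, 10.0)
    impedance_missing = rng_bmi.random(n) < config.impedance_missing_rate
    impedance[impedance_missing] = np.nan

    liability = (
        config.t2d_base_log_odds
        + 0.04 * (age - 55.0)
        + 0.3 * sex
        + _planted_contributions(config, variants, "t2d_liability")
    )
    disease = rng_t2d.random(n) < 1.0 / (1.0 + np.exp(-liability))

    self_report = np.full(n, "none", dtype=object)
    age_at_diag = np.full(n, np.nan)
    insulin = np.full(n, "unknown", dtype=object)
    years_since = np.full(n, np.nan)

    idx = np.flatnonzero(disease)
    if idx.size:
        self_report[idx] = np.where(rng_t2d.random(idx.size) < 0.9, "type2", "generic")
        type1 = rng_t2d.random(idx.size) < config.frac_type1_reports
        self_report[idx[type1]] = "type1"
        # age at diagnosis between 35 and current age, >1 year ago by default
        hi = np.maximum(age[idx] - 1.5, 36.0)
        diag = rng_t2d.uniform(36.0, np.maximum(hi, 36.0 + 1e-6))
        young = rng_t2d.random(idx.size) < config.frac_young_diagnosis
        diag[young] = rng_t2d.uniform(20.0, 34.9, size=young.sum())
        recent = rng_t2d.random(idx.size) < config.frac_recent_diagnosis
        diag[recent] = age[idx][recent] - rng_t2d.uniform(0.05, 0.95, size=recent.sum())
        unknown_age = rng_t2d.random(idx.size) < config.frac_unknown_diagnosis_age
        diag[unknown_age] = np.nan
        age_at_diag[idx] = diag
        years_since[idx] = age[idx] - diag
        insulin[idx] = np.where(
            rng_t2d.random(idx.size) < config.frac_insulin_first_year, "yes", "no"
        )

    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i:07d}" for i in range(n)],
            "bmi_standard": bmi,
            "bmi_impedance": impedance,
            "age": age,
            "sex": sex.astype(int),
            "centre": centre,
            "chip": chip,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
            "pc4": pcs[:, 3],
            "pc5": pcs[:, 4],
            "t2d_self_report": self_report,
            "age_at_diagnosis": age_at_diag,
            "insulin_first_year": insulin,
            "years_since_diagnosis": years_since,
        }
    )
    validate_cohort(cohort)
    return cohort


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort-table column contract and basic invariants."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if cohort["sample_id"].duplicated().any():
        raise ValueError("duplicated sample_id in cohort table")
    ages = cohort["age"].dropna()
    if (ages <= 0).any():
        raise ValueError("ages must be positive")
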