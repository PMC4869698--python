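"""Phenotype preparation.

Resolves the two BMI measures into one analysis value (with the 4.56-SD
discordance exclusion), residualises on covariates, applies the rank-based
inverse-normal transform, and assigns obesity / severe-obesity / type 2
diabetes case-control labels.

Label semantics: every sample ends up in exactly one of {case, control,
excluded}; exclusion reasons are recorded per trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DISCORDANCE_SD_MULTIPLE",
    "PreparedPhenotypes",
    "resolve_bmi",
    "residualize",
    "inverse_normalize",
    "classify_obesity",
    "classify_t2d",
    "prepare_phenotypes",
]

#: Samples with |impedance - standard| beyond this many SDs of the
#: difference distribution are excluded.
DISCORDANCE_SD_MULTIPLE = 4.56

CASE = "case"
CONTROL = "control"
EXCLUDED = "excluded"


@dataclass
class PreparedPhenotypes:
    """Analysis-ready per-sample phenotype frame.

    ``table`` columns: sample_id, bmi_raw, bmi_invnorm, obese,
    severely_obese, t2d, exclusion_reason.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        defined = t["bmi_invnorm"].notna()
        if (defined & t["bmi_raw"].isna()).any():
            raise ValueError("bmi_invnorm defined where bmi_raw missing")
        if (t.loc[t["obese"] == CASE, "bmi_raw"] <= 30).any():
            raise ValueError("obese case with BMI <= 30")
        if (t.loc[t["severely_obese"] == CASE, "bmi_raw"] <= 40).any():
            raise ValueError("severely obese case with BMI <= 40")
        ctrl = (t["obese"] == CONTROL) | (t["severely_obese"] == CONTROL)
        if (t.loc[ctrl, "bmi_raw"] >= 25).any():
            raise ValueError("obesity control with BMI >= 25")


def resolve_bmi(cohort: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Resolve dual BMI measures into one value per sample.

    Where both measures are present the difference (impedance - standard) is
    computed; samples with an absolute difference greater than 4.56 times the
    SD of the differences (single pass, SD over all dual-measure samples
    before any exclusion) are excluded.  Where only one measure is present it
    is used.  Samples with neither measure are dropped with a reason code.

    Returns the resolved BMI (indexed like ``cohort``; NaN where excluded or
    unavailable) and a flags frame with boolean columns ``excluded_discordant``
    and ``missing_both`` plus the ``difference`` column.
    """
    std = pd.to_numeric(cohort["bmi_standard"], errors="coerce")
    imp = pd.to_numeric(cohort["bmi_impedance"], errors="coerce")
    both = std.notna() & imp.notna()
    diff = pd.Series(np.nan, index=cohort.index, name="difference")
    diff[both] = imp[both] - std[both]

    excluded = pd.Series(False, index=cohort.index, name="excluded_discordant")
    if both.sum() >= 2:
        sd = float(diff[both].std(ddof=1))
        if sd > 0:
            # NaN differences (a measure missing) compare False and stay kept
            excluded = (diff.abs() > DISCORDANCE_SD_MULTIPLE * sd).rename(
                "excluded_discordant"
            )

    resolved = std.copy()
    only_imp = std.isna() & imp.notna()
    resolved[only_imp] = imp[only_imp]
    missing_both = std.isna() & imp.isna()
    resolved[excluded | missing_both] = np.nan

    flags = pd.DataFrame(
        {
            "difference": diff,
            "excluded_discordant": excluded,
            "missing_both": pd.Series(missing_both, name="missing_both"),
        }
    )
    return resolved.rename("bmi_resolved"), flags


def residualize(values: np.ndarray | pd.Series, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus ``covariates``.

    Categorical (object/category dtype) covariates are expanded to indicator
    columns dropping the first level.  Raises on a rank-deficient design.
    Residuals are orthogonal to every design column.
    """
    y = np.asarray(values, dtype=float)
    X = _design_matrix(covariates, n=len(y))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient covariate design: rank {rank} < {X.shape[1]} columns"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _design_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    expanded = pd.get_dummies(covariates, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(n), expanded.to_numpy(dtype=float)])
    return X


def inverse_normalize(values: np.ndarray | pd.Series, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform.

    A value with rank r among n maps to the standard-normal quantile of
    (r - c) / (n - 2c + 1); the default offset c = 3/8 is Blom's.  Ties
    receive average ranks, so the transform is deterministic and invariant
    under strictly monotone transforms of the input.
    """
    y = np.asarray(values, dtype=float)
    if np.unique(y[~np.isnan(y)]).size < 2:
        raise ValueError("inverse_normalize requires >= 2 distinct values")
    out = np.full(y.shape, np.nan)
    ok = ~np.isnan(y)
    ranks = stats.rankdata(y[ok], method="average")
    n = ok.sum()
    out[ok] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def classify_obesity(bmi: pd.Series) -> pd.DataFrame:
    """Obesity (>30) and severe obesity (>40) labels; controls are BMI <25.

    BMI in the dead zone ([25, 30] for obesity, [25, 40] for severe obesity)
    is excluded -- neither case nor control.  Missing BMI is excluded.
    """
    obese = pd.Series(EXCLUDED, index=bmi.index, dtype=object)
    severe = pd.Series(EXCLUDED, index=bmi.index, dtype=object)
    obese[bmi > 30.0] = CASE
    severe[bmi > 40.0] = CASE
    obese[bmi < 25.0] = CONTROL
    severe[bmi < 25.0] = CONTROL
    return pd.DataFrame({"obese": obese, "severely_obese": severe})


def classify_t2d(cohort: pd.DataFrame, study_end_window_years: float = 1.0) -> pd.DataFrame:
    """Type 2 diabetes labels from questionnaire fields.

    Case: self-report in {type2, generic}, no insulin within the first year
    of diagnosis, a known age at diagnosis of at least 35 years, and a
    diagnosis more than ``study_end_window_years`` before data extraction.
    Reporting type 1 diabetes excludes the sample; reporters failing any case
    rule are excluded with a reason; everyone who reports nothing is a
    control.
    """
    report = cohort["t2d_self_report"].astype(str)
    age_dx = pd.to_numeric(cohort["age_at_diagnosis"], errors="coerce")
    insulin = cohort["insulin_first_year"].astype(str)
    years = pd.to_numeric(cohort["years_since_diagnosis"], errors="coerce")

    label = pd.Series(CONTROL, index=cohort.index, dtype=object)
    reason = pd.Series("", index=cohort.index, dtype=object)

    reports = report.isin(["type2", "generic"])
    label[reports] = CASE

    def _exclude(mask: pd.Series, code: str) -> None:
        mask = mask & reports
        label[mask] = EXCLUDED
        reason[mask] = np.where(
            reason[mask] == "", code, reason[mask] + ";" + code
        )

    _exclude(insulin == "yes", "insulin_first_year")
    _exclude(age_dx.isna(), "unknown_diagnosis_age")
    _exclude(age_dx < 35.0, "diagnosis_under_35")
    _exclude(years.notna() & (years <= study_end_window_years), "recent_diagnosis")

    type1 = report == "type1"
    label[type1] = EXCLUDED
    reason[type1] = "type1_report"

    return pd.DataFrame({"t2d": label, "t2d_exclusion_reason": reason})


def prepare_phenotypes(
    cohort: pd.DataFrame,
    covariate_names: tuple[str, ...] = ("age", "sex", "centre", "pc1", "pc2", "pc3", "pc4", "pc5"),
    study_end_window_years: float = 1.0,
) -> PreparedPhenotypes:
    """Full phenotype pipeline: resolve BMI, residualise, inverse-normalise,
    and label obesity and diabetes case-control status."""
    resolved, flags = resolve_bmi(cohort)
    invnorm = pd.Series(np.nan, index=cohort.index)
    ok = resolved.notna()
    if ok.sum() >= 2:
        resid = residualize(resolved[ok], cohort.loc[ok, list(covariate_names)])
        invnorm[ok] = inverse_normalize(resid)

    obesity = classify_obesity(resolved)
    t2d = classify_t2d(cohort, study_end_window_years=study_end_window_years)

    reason = pd.Series("", index=cohort.index, dtype=object)
    reason[flags["excluded_discordant"]] = "bmi_discordant"
    reason[flags["missing_both"]] = "bmi_missing"

    table = pd.DataFrame(
        {
            "sample_id": cohort["sample_id"],
            "bmi_raw": resolved,
            "bmi_invnorm": invnorm,
            "obese": obesity["obese"],
            "severely_obese": obesity["severely_obese"],
            "t2d": t2d["t2d"],
            "exclusion_reason": np.where(
                reason != "",
                reason,
                t2d["t2d_exclusion_reason"],
            ),
        }
    )
    return PreparedPhenotypes(table=table)
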