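"""Per-variant genetic model fitting.

Genotype coding: the additive term g counts effect alleles (0/1/2 on hard
calls, expected count on dosages); the heterozygote term h is the 0/1/0
indicator (or its expectation P(het) under genotype uncertainty).  The
"genotypic" model fits g and h jointly; the h coefficient is the dominance
deviation -- the departure of the heterozygote mean from the additive
midpoint.  Derived codings: recessive = P(hom-alt) = (g - h)/2 and
dominant = P(carrier) = h + (g - h)/2.

Quantitative traits are fitted by OLS with Wald t-based p values; binary
traits by logistic maximum likelihood via iteratively reweighted least
squares with Wald SEs from the observed information.  Complete separation is
detected by coefficient divergence and reported as a flagged result rather
than an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from domdev.grouped import GenotypeClassSummary
from domdev.synthetic import VariantRecord

__all__ = [
    "ModelSpec",
    "GenotypeCoding",
    "AssocResult",
    "encode_genotype",
    "fit_linear",
    "fit_logistic",
    "likelihood_ratio_pvalue",
    "scan",
    "scan_table",
    "qq_table",
    "genomic_inflation",
    "genotype_class_summary",
]

_CODINGS = ("additive", "domdev", "recessive", "dominant", "genotypic")

#: |beta| beyond which a logistic fit is flagged as separated.
SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class ModelSpec:
    coding: str = "genotypic"
    trait_kind: str = "quantitative"
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.coding not in _CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.trait_kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")

    @property
    def genetic_terms(self) -> tuple[str, ...]:
        # "domdev" is an alias for the joint (genotypic) fit: the deviation
        # term is only interpretable alongside the additive term
        if self.coding in ("genotypic", "domdev"):
            return ("add", "domdev")
        if self.coding == "additive":
            return ("add",)
        if self.coding == "recessive":
            return ("rec",)
        return ("dom",)


@dataclass
class GenotypeCoding:
    """Per-sample additive code g and heterozygote code h."""

    g: np.ndarray
    h: np.ndarray
    mode: str
    class_counts: tuple[int, int, int]
    mask: np.ndarray  # True where genotype data present

    @property
    def recessive(self) -> np.ndarray:
        return (self.g - self.h) / 2.0

    @property
    def dominant(self) -> np.ndarray:
        return self.h + (self.g - self.h) / 2.0


@dataclass
class AssocResult:
    vid: str
    effect_allele: str
    n_used: int
    class_counts: tuple[int, int, int]
    beta_add: float | None = None
    se_add: float | None = None
    p_add: float | None = None
    beta_domdev: float | None = None
    se_domdev: float | None = None
    p_domdev: float | None = None
    beta_recessive: float | None = None
    se_recessive: float | None = None
    p_recessive: float | None = None
    beta_dominant: float | None = None
    se_dominant: float | None = None
    p_dominant: float | None = None
    converged: bool = True
    separation_flag: bool = False

    def odds_ratios(self) -> dict[str, float]:
        """exp(beta) for each fitted term (meaningful for logistic fits)."""
        out = {}
        for term in ("add", "domdev", "recessive", "dominant"):
            beta = getattr(self, f"beta_{term}" if term != "add" else "beta_add")
            if beta is not None:
                out[term] = math.exp(beta)
        return out


def encode_genotype(variant: VariantRecord, mode: str = "dosage") -> GenotypeCoding:
    """Code a variant for regression.

    ``hardcall`` takes the maximum-probability genotype (ties toward fewer
    alt alleles); ``dosage`` uses g = expected alt count and h = P(het).
    Samples with missing genotype data are masked.
    """
    if mode not in ("hardcall", "dosage"):
        raise ValueError(f"unknown genotype mode {mode!r}")
    calls = variant.hard_calls()
    present = calls >= 0
    counts = (
        int((calls == 0).sum()),
        int((calls == 1).sum()),
        int((calls == 2).sum()),
    )
    if mode == "hardcall":
        g = calls.astype(float)
        g[~present] = np.nan
        h = (calls == 1).astype(float)
        h[~present] = np.nan
    else:
        g = variant.dosage
        h = variant.genotype_probs[:, 1].astype(float)
    return GenotypeCoding(g=g, h=h, mode=mode, class_counts=counts, mask=present)


def _genetic_columns(coding: GenotypeCoding, spec: ModelSpec) -> dict[str, np.ndarray]:
    cols = {}
    for term in spec.genetic_terms:
        if term == "add":
            cols["add"] = coding.g
        elif term == "domdev":
            cols["domdev"] = coding.h
        elif term == "rec":
            cols["rec"] = coding.recessive
        else:
            cols["dom"] = coding.dominant
    return cols


def _build_design(
    y: np.ndarray,
    coding: GenotypeCoding,
    covariates: pd.DataFrame | None,
    spec: ModelSpec,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    y = np.asarray(y, dtype=float)
    genetic = _genetic_columns(coding, spec)
    mask = np.isfinite(y) & coding.mask
    for col in genetic.values():
        mask &= np.isfinite(col)
    blocks = [np.ones(y.shape[0])] + list(genetic.values())
    names = ["intercept"] + list(genetic.keys())
    if covariates is not None and covariates.shape[1] > 0:
        expanded = pd.get_dummies(covariates, drop_first=True, dtype=float)
        arr = expanded.to_numpy(dtype=float)
        mask &= np.isfinite(arr).all(axis=1)
        blocks.append(arr.T)
        names += list(expanded.columns.astype(str))
    X = np.column_stack([b if b.ndim == 1 else b.T for b in blocks])
    return X[mask], y[mask], names, mask


def _fill_result(
    result: AssocResult, names: list[str], beta: np.ndarray, se: np.ndarray, p: np.ndarray
) -> AssocResult:
    mapping = {"add": "add", "domdev": "domdev", "rec": "recessive", "dom": "dominant"}
    for i, name in enumerate(names):
        if name in mapping:
            suffix = mapping[name]
            setattr(result, f"beta_{suffix}", float(beta[i]))
            setattr(result, f"se_{suffix}", float(se[i]))
            setattr(result, f"p_{suffix}", float(p[i]))
    return result


def fit_linear(
    y: np.ndarray | pd.Series,
    coding: GenotypeCoding,
    covariates: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    vid: str = "",
    effect_allele: str = "",
) -> AssocResult:
    """Ordinary least squares fit of a quantitative trait on genetic terms.

    Wald two-sided p values from t statistics on n - p degrees of freedom.
    A zero-residual fit (e.g. constant y) reports zero SEs and p = 1 for the
    genetic terms.
    """
    spec = spec or ModelSpec(coding="genotypic", trait_kind="quantitative")
    X, yv, names, mask = _build_design(y, coding, covariates, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n_used={n} too small for {p} parameters")
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("rank-deficient design matrix")
    beta = np.linalg.solve(xtx, X.T @ yv)
    resid = yv - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    if sigma2 < 1e-20:  # exact fit, e.g. constant y: zero SEs, p = 1
        sigma2 = 0.0
        beta = np.where(np.abs(beta) < 1e-10, 0.0, beta)
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = np.where(se > 0, 2.0 * stats.t.sf(np.abs(tstat), dof), 1.0)
    result = AssocResult(
        vid=vid,
        effect_allele=effect_allele,
        n_used=n,
        class_counts=coding.class_counts,
    )
    return _fill_result(result, names, beta, se, pvals)


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), stable for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    status: np.ndarray | pd.Series,
    coding: GenotypeCoding,
    covariates: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    vid: str = "",
    effect_allele: str = "",
    max_iter: int = 50,
    tol: float = 1e-10,
) -> AssocResult:
    """Logistic regression by IRLS with Wald SEs from observed information.

    Convergence: relative log-likelihood change < ``tol`` or ``max_iter``
    iterations.  Complete separation (any coefficient diverging beyond
    |beta| > 15) yields a result flagged via ``separation_flag`` rather than
    an exception.
    """
    spec = spec or ModelSpec(coding="genotypic", trait_kind="binary")
    X, yv, names, mask = _build_design(status, coding, covariates, spec)
    classes = np.unique(yv)
    if not np.isin(yv, (0.0, 1.0)).all():
        raise ValueError("binary outcome must be coded 0/1")
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n_used={n} too small for {p} parameters")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")

    beta = np.zeros(p)
    ll_old = _log_likelihood(yv, X @ beta)
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xtwx = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(xtwx, X.T @ (yv - mu))
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.abs(beta).max() > SEPARATION_BETA:
            separated = True
            break
        ll = _log_likelihood(yv, X @ beta)
        if abs(ll - ll_old) < tol * (abs(ll_old) + tol):
            converged = True
            break
        ll_old = ll

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    result = AssocResult(
        vid=vid,
        effect_allele=effect_allele,
        n_used=n,
        class_counts=coding.class_counts,
        converged=converged and not separated,
        separation_flag=separated,
    )
    return _fill_result(result, names, beta, se, pvals)


def likelihood_ratio_pvalue(
    status: np.ndarray,
    coding: GenotypeCoding,
    covariates: pd.DataFrame | None,
    full: ModelSpec,
    reduced: ModelSpec,
) -> float:
    """LRT cross-check between nested logistic specs (df = term difference)."""

    def _maximised_ll(spec: ModelSpec) -> tuple[float, int]:
        X, yv, _, _ = _build_design(status, coding, covariates, spec)
        beta = np.zeros(X.shape[1])
        for _ in range(100):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            beta = beta + np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (yv - mu))
        return _log_likelihood(yv, X @ beta), X.shape[1]

    ll_full, p_full = _maximised_ll(full)
    ll_red, p_red = _maximised_ll(reduced)
    df = p_full - p_red
    if df <= 0:
        raise ValueError("full model must have more terms than reduced")
    return float(stats.chi2.sf(2.0 * (ll_full - ll_red), df))


def scan(
    variants: list[VariantRecord],
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    trait_kind: str = "quantitative",
    mode: str = "dosage",
):
    """Yield one :class:`AssocResult` per variant.

    Each result carries the additive effect from the additive-only fit, the
    dominance deviation from the joint (genotypic) fit and the recessive
    effect from the recessive-only fit, mirroring standard summary-statistic
    output.
    """
    fitter = fit_linear if trait_kind == "quantitative" else fit_logistic
    for v in variants:
        coding = encode_genotype(v, mode=mode)
        joint = fitter(
            phenotype, coding, covariates,
            ModelSpec(coding="genotypic", trait_kind=trait_kind),
            vid=v.vid, effect_allele=v.effect_allele,
        )
        add_only = fitter(
            phenotype, coding, covariates,
            ModelSpec(coding="additive", trait_kind=trait_kind),
            vid=v.vid, effect_allele=v.effect_allele,
        )
        rec_only = fitter(
            phenotype, coding, covariates,
            ModelSpec(coding="recessive", trait_kind=trait_kind),
            vid=v.vid, effect_allele=v.effect_allele,
        )
        joint.beta_add = add_only.beta_add
        joint.se_add = add_only.se_add
        joint.p_add = add_only.p_add
        joint.beta_recessive = rec_only.beta_recessive
        joint.se_recessive = rec_only.se_recessive
        joint.p_recessive = rec_only.p_recessive
        joint.separation_flag = (
            joint.separation_flag or add_only.separation_flag or rec_only.separation_flag
        )
        yield joint


RESULT_COLUMNS = [
    "vid", "effect_allele", "n_used",
    "beta_add", "se_add", "p_add",
    "beta_domdev", "se_domdev", "p_domdev",
    "beta_recessive", "se_recessive", "p_recessive",
    "n_hom_ref", "n_het", "n_hom_alt",
    "converged", "separation_flag",
]


def scan_table(
    variants: list[VariantRecord],
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    trait_kind: str = "quantitative",
    mode: str = "dosage",
) -> pd.DataFrame:
    """Materialise :func:`scan` as a results table (header-only if empty)."""
    rows = []
    for r in scan(variants, phenotype, covariates, trait_kind, mode):
        rows.append(
            {
                "vid": r.vid,
                "effect_allele": r.effect_allele,
                "n_used": r.n_used,
                "beta_add": r.beta_add, "se_add": r.se_add, "p_add": r.p_add,
                "beta_domdev": r.beta_domdev, "se_domdev": r.se_domdev,
                "p_domdev": r.p_domdev,
                "beta_recessive": r.beta_recessive, "se_recessive": r.se_recessive,
                "p_recessive": r.p_recessive,
                "n_hom_ref": r.class_counts[0], "n_het": r.class_counts[1],
                "n_hom_alt": r.class_counts[2],
                "converged": r.converged, "separation_flag": r.separation_flag,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def qq_table(pvalues: np.ndarray | pd.Series) -> pd.DataFrame:
    """Sorted observed vs expected -log10 p for a QQ plot."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[np.isfinite(p)]
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, 1e-300, None))
    return pd.DataFrame({"expected_neglog10p": expected, "observed_neglog10p": observed})


def genomic_inflation(pvalues: np.ndarray | pd.Series) -> float:
    """Lambda GC: median association chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p values")
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def genotype_class_summary(
    variant: VariantRecord, y: np.ndarray | pd.Series
) -> GenotypeClassSummary:
    """Per-genotype-class (n, mean, SD) with 95% CI = mean +/- 1.96 SD/sqrt(n).

    Uses hard calls; classes with no samples get NaN summaries.
    """
    yv = np.asarray(y, dtype=float)
    calls = variant.hard_calls()
    n = np.zeros(3, dtype=int)
    mean = np.full(3, np.nan)
    sd = np.full(3, np.nan)
    for k in range(3):
        vals = yv[(calls == k) & np.isfinite(yv)]
        n[k] = vals.size
        if vals.size:
            mean[k] = vals.mean()
            sd[k] = vals.std(ddof=1) if vals.size > 1 else 0.0
    return GenotypeClassSummary(n=n, mean=mean, sd=sd)
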