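import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from domdev import models
from domdev.models import (
    ModelSpec,
    encode_genotype,
    fit_linear,
    fit_logistic,
    genomic_inflation,
    genotype_class_summary,
    qq_table,
    scan_table,
)
from domdev.synthetic import PlantedEffect, SimConfig, simulate_genotypes, simulate_phenotypes

from .conftest import make_hardcall_variant

TABLE2_COUNTS = (42835, 57524, 19329)
TABLE2_MEANS = (27.27, 27.54, 28.07)


def _variant_from_probs(rows):
    probs = np.array(rows, dtype=float)
    from domdev.synthetic import VariantRecord

    return VariantRecord(
        chrom="1", pos=1, vid="v", ref_allele="A", alt_allele="G",
        info=1.0, genotype_probs=probs,
    )


class TestEncodeGenotype:
    def test_certain_hom_ref(self):
        v = _variant_from_probs([[1, 0, 0]])
        for mode in ("hardcall", "dosage"):
            coding = encode_genotype(v, mode)
            assert coding.g[0] == 0.0 and coding.h[0] == 0.0

    def test_uncertain_het(self):
        v = _variant_from_probs([[0.2, 0.5, 0.3]])
        hard = encode_genotype(v, "hardcall")
        assert hard.g[0] == 1.0 and hard.h[0] == 1.0
        soft = encode_genotype(v, "dosage")
        assert soft.g[0] == pytest.approx(1.1)
        assert soft.h[0] == pytest.approx(0.5)

    def test_tie_breaks_toward_fewer_alt(self):
        v = _variant_from_probs([[0.5, 0.5, 0.0]])
        assert encode_genotype(v, "hardcall").g[0] == 0.0
        assert encode_genotype(v, "dosage").g[0] == pytest.approx(0.5)

    def test_missing_masked(self):
        v = _variant_from_probs([[1, 0, 0], [np.nan, np.nan, np.nan]])
        coding = encode_genotype(v, "hardcall")
        assert coding.mask.tolist() == [True, False]

    def test_derived_codings(self):
        v = _variant_from_probs([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        coding = encode_genotype(v, "hardcall")
        assert coding.recessive.tolist() == [1.0, 0.0, 0.0]
        assert coding.dominant.tolist() == [1.0, 1.0, 0.0]


def _expand_class_constant(counts, means):
    variant = make_hardcall_variant(counts, vid="classfix")
    y = np.repeat(means, counts).astype(float)
    return variant, y


class TestFitLinear:
    def test_constant_y(self):
        variant = make_hardcall_variant((30, 40, 30))
        coding = encode_genotype(variant, "hardcall")
        res = fit_linear(np.full(100, 5.0), coding)
        assert res.beta_add == 0.0 and res.beta_domdev == 0.0
        assert res.p_add == 1.0 and res.p_domdev == 1.0

    def test_saturated_identity_on_published_classes(self):
        variant, y = _expand_class_constant(TABLE2_COUNTS, TABLE2_MEANS)
        coding = encode_genotype(variant, "hardcall")
        res = fit_linear(y, coding, spec=ModelSpec(coding="genotypic"))
        # class-constant data: joint fit is exactly the saturated 3-class model
        assert res.beta_add == pytest.approx((28.07 - 27.27) / 2, abs=1e-10)
        assert res.beta_domdev == pytest.approx(27.54 - (27.27 + 28.07) / 2, abs=1e-10)
        assert res.n_used == sum(TABLE2_COUNTS)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_coding_algebra_random_classes(self, seed):
        rng = np.random.default_rng(seed)
        counts = tuple(rng.integers(50, 500, 3))
        means = tuple(rng.normal(25, 3, 3))
        variant, y = _expand_class_constant(counts, means)
        res = fit_linear(y, encode_genotype(variant, "hardcall"))
        m0, m1, m2 = means
        assert res.beta_add == pytest.approx((m2 - m0) / 2, abs=1e-10)
        assert res.beta_domdev == pytest.approx(m1 - (m0 + m2) / 2, abs=1e-10)

    def test_pure_recessive_ratio(self):
        cfg = SimConfig(
            n_samples=100000, n_variants=1, maf_range=(0.3, 0.3),
            info_range=(1.0, 1.0), seed=30, skew=0.0,
            effect_spec=(PlantedEffect(0, 0.25, -0.25, "bmi"),),
        )
        variants = simulate_genotypes(cfg)
        cohort = simulate_phenotypes(cfg, variants)
        res = fit_linear(
            cohort["bmi_standard"].to_numpy(), encode_genotype(variants[0], "hardcall")
        )
        assert -1.15 <= res.beta_domdev / res.beta_add <= -0.85

    def test_wald_matches_statsmodels_style_oracle(self):
        # cross-check SEs/p against the closed-form OLS covariance
        rng = np.random.default_rng(31)
        g = rng.binomial(2, 0.3, 500).astype(float)
        h = (g == 1).astype(float)
        y = 0.2 * g - 0.1 * h + rng.standard_normal(500)
        variant = _variant_from_probs(np.eye(3)[g.astype(int)])
        res = fit_linear(y, encode_genotype(variant, "hardcall"))
        X = np.column_stack([np.ones(500), g, h])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        cov = (resid @ resid / 497) * np.linalg.inv(X.T @ X)
        assert res.beta_add == pytest.approx(beta[1], abs=1e-10)
        assert res.se_add == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-10)
        t = beta[2] / math.sqrt(cov[2, 2])
        assert res.p_domdev == pytest.approx(2 * stats.t.sf(abs(t), 497), rel=1e-9)

    def test_covariate_adjustment(self):
        rng = np.random.default_rng(32)
        g = rng.binomial(2, 0.4, 1000).astype(float)
        chip = rng.choice(["a", "b"], 1000)
        y = 0.3 * g + (chip == "b") * 2.0 + rng.standard_normal(1000)
        variant = _variant_from_probs(np.eye(3)[g.astype(int)])
        res = fit_linear(
            y, encode_genotype(variant, "hardcall"),
            covariates=pd.DataFrame({"chip": chip}),
            spec=ModelSpec(coding="additive"),
        )
        assert res.beta_add == pytest.approx(0.3, abs=0.15)

    def test_parameter_recovery_over_replicates(self):
        # planted (beta_add, beta_domdev) = (0.076, -0.025) on an SD-1 trait
        rng = np.random.default_rng(33)
        est = np.zeros((200, 2))
        for k in range(200):
            g = rng.binomial(2, 0.4, 20000).astype(float)
            h = (g == 1).astype(float)
            y = 0.076 * g - 0.025 * h + rng.standard_normal(20000)
            X = np.column_stack([np.ones(20000), g, h])
            variant = _variant_from_probs(np.eye(3)[g.astype(int)])
            res = fit_linear(y, encode_genotype(variant, "hardcall"))
            est[k] = (res.beta_add, res.beta_domdev)
        assert est[:, 0].mean() == pytest.approx(0.076, abs=0.005)
        assert est[:, 1].mean() == pytest.approx(-0.025, abs=0.005)

    def test_too_few_samples(self):
        variant = _variant_from_probs([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError):
            fit_linear(np.array([1.0, 2.0, 3.0]), encode_genotype(variant, "hardcall"))


class TestFitLogistic:
    def test_two_by_two_cross_product(self):
        # cases: 100 exposed, 100 unexposed; controls: 50 exposed, 200 unexposed
        g = np.concatenate([np.ones(100), np.zeros(100), np.ones(50), np.zeros(200)])
        y = np.concatenate([np.ones(200), np.zeros(250)])
        variant = _variant_from_probs(np.eye(3)[g.astype(int)])
        res = fit_logistic(
            y, encode_genotype(variant, "hardcall"),
            spec=ModelSpec(coding="additive", trait_kind="binary"),
        )
        assert math.exp(res.beta_add) == pytest.approx(4.0, rel=1e-6)
        # Woolf SE of log OR
        assert res.se_add == pytest.approx(
            math.sqrt(1 / 100 + 1 / 100 + 1 / 50 + 1 / 200), rel=1e-4
        )

    def test_small_n_matches_numerical_ml_oracle(self):
        rng = np.random.default_rng(40)
        g = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 0, 1, 2, 0, 1, 0, 2, 1, 0, 1, 0,
                      2, 1, 0, 1, 2, 0, 1, 0, 1, 2], dtype=float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 0.5 * g)))).astype(float)
        variant = _variant_from_probs(np.eye(3)[g.astype(int)])
        res = fit_logistic(
            y, encode_genotype(variant, "hardcall"),
            spec=ModelSpec(coding="additive", trait_kind="binary"),
        )
        X = np.column_stack([np.ones(30), g])

        def negll(beta):
            eta = X @ beta
            return -(y @ eta - np.logaddexp(0, eta).sum())

        opt = optimize.minimize(negll, np.zeros(2), method="BFGS")
        assert res.beta_add == pytest.approx(opt.x[1], abs=1e-4)

    def test_null_domdev_type1_error(self):
        # genotype independent of status: p_domdev should be uniform
        rng = np.random.default_rng(41)
        n = 50000
        y = (rng.random(n) < 0.1).astype(float)
        hits = 0
        for _ in range(200):
            g = rng.binomial(2, 0.3, n)
            variant = _variant_from_probs(np.eye(3)[g])
            res = fit_logistic(y, encode_genotype(variant, "hardcall"))
            if res.p_domdev < 0.05:
                hits += 1
        assert 0.02 <= hits / 200 <= 0.09

    def test_separation_flagged(self):
        # all hom-alt carriers are cases and vice versa
        g = np.concatenate([np.full(20, 2), np.zeros(20), np.ones(20)]).astype(int)
        y = (g == 2).astype(float)
        variant = _variant_from_probs(np.eye(3)[g])
        res = fit_logistic(
            y, encode_genotype(variant, "hardcall"),
            spec=ModelSpec(coding="recessive", trait_kind="binary"),
        )
        assert res.separation_flag
        assert not res.converged

    def test_one_class_rejected(self):
        g = np.array([0, 1, 2, 1, 0])
        variant = _variant_from_probs(np.eye(3)[g])
        with pytest.raises(ValueError):
            fit_logistic(np.ones(5), encode_genotype(variant, "hardcall"))

    def test_lrt_close_to_wald_large_n(self):
        rng = np.random.default_rng(42)
        n = 20000
        g = rng.binomial(2, 0.3, n)
        h = (g == 1).astype(float)
        eta = -2.0 + 0.15 * g - 0.1 * h
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        variant = _variant_from_probs(np.eye(3)[g])
        coding = encode_genotype(variant, "hardcall")
        res = fit_logistic(y, coding)
        p_lrt = models.likelihood_ratio_pvalue(
            y, coding, None,
            full=ModelSpec(coding="genotypic", trait_kind="binary"),
            reduced=ModelSpec(coding="additive", trait_kind="binary"),
        )
        assert math.log10(p_lrt) == pytest.approx(math.log10(res.p_domdev), abs=0.3)


class TestScan:
    def test_null_scan_inflation(self):
        cfg = SimConfig(
            n_samples=1000, n_variants=500, maf_range=(0.1, 0.5),
            info_range=(1.0, 1.0), seed=52, skew=0.0,
        )
        variants = simulate_genotypes(cfg)
        cohort = simulate_phenotypes(cfg, variants)
        res = scan_table(variants, cohort["bmi_standard"].to_numpy())
        lam = genomic_inflation(res["p_domdev"])
        assert 0.9 <= lam <= 1.1

    def test_planted_domdev_detected(self):
        cfg = SimConfig(
            n_samples=20000, n_variants=1, maf_range=(0.4, 0.4),
            info_range=(1.0, 1.0), seed=51, skew=0.0,
            effect_spec=(PlantedEffect(0, 0.0, -0.3, "bmi"),),
        )
        variants = simulate_genotypes(cfg)
        cohort = simulate_phenotypes(cfg, variants)
        res = scan_table(variants, cohort["bmi_standard"].to_numpy())
        assert res["p_domdev"].iloc[0] < 1e-4

    def test_empty_variant_list(self):
        res = scan_table([], np.array([1.0, 2.0]))
        assert len(res) == 0
        assert list(res.columns) == models.RESULT_COLUMNS

    def test_additive_from_marginal_fit(self):
        # scan reports the additive beta from the additive-only model, the
        # domdev beta from the joint model
        variant, y = _expand_class_constant((300, 400, 300), (1.0, 2.0, 2.5))
        res = scan_table([variant], y).iloc[0]
        add_only = fit_linear(
            y, encode_genotype(variant, "hardcall"), spec=ModelSpec(coding="additive")
        )
        joint = fit_linear(y, encode_genotype(variant, "hardcall"))
        assert res["beta_add"] == pytest.approx(add_only.beta_add, abs=1e-12)
        assert res["beta_domdev"] == pytest.approx(joint.beta_domdev, abs=1e-12)

    def test_qq_table_monotone(self):
        rng = np.random.default_rng(52)
        qq = qq_table(rng.random(100))
        assert (np.diff(qq["expected_neglog10p"]) <= 0).all() or (
            np.diff(qq["expected_neglog10p"]) >= 0
        ).all()
        assert len(qq) == 100


class TestGenotypeClassSummary:
    def test_published_class_ci(self, fto_class_summary):
        variant, y = _expand_class_constant(TABLE2_COUNTS, TABLE2_MEANS)
        # give the hom-ref class the published SD by perturbing two samples
        summ = genotype_class_summary(variant, y)
        assert summ.n.tolist() == list(TABLE2_COUNTS)
        # CI from the published moments: 27.27 +/- 1.96*4.68/sqrt(42835)
        lo, hi = fto_class_summary.ci95()
        assert round(lo[0], 3) == 27.226
        assert round(hi[0], 3) == 27.314

    def test_constant_class(self):
        variant, y = _expand_class_constant((5, 5, 5), (2.0, 2.0, 2.0))
        summ = genotype_class_summary(variant, y)
        assert np.allclose(summ.sd, 0.0)
        lo, hi = summ.ci95()
        assert np.allclose(lo, summ.mean) and np.allclose(hi, summ.mean)

    def test_two_sample_class(self):
        variant = make_hardcall_variant((2, 0, 0))
        summ = genotype_class_summary(variant, np.array([1.0, 3.0]))
        assert summ.mean[0] == pytest.approx(2.0)
        assert summ.sd[0] == pytest.approx(math.sqrt(2.0))

    def test_empty_class_missing(self):
        variant = make_hardcall_variant((3, 3, 0))
        summ = genotype_class_summary(variant, np.arange(6, dtype=float))
        assert summ.n[2] == 0
        assert np.isnan(summ.mean[2])
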