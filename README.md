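# domdev

Dominance-deviation association analysis for quantitative and binary traits.

The package implements a complete, reproducible pipeline for testing whether
the trait value of heterozygotes departs from the midpoint of the two
homozygote groups (the "dominance deviation" test), together with everything
needed to run it end to end without external data:

- **`domdev.synthetic`** — synthetic cohort generator: Hardy-Weinberg
  genotypes across a MAF spectrum, imputation-style genotype probabilities
  with a tunable info score, standard GWAS covariates, a right-skewed
  BMI-like trait with planted additive/dominance effects, a second
  impedance-style BMI measure with occasional gross discordance, and
  questionnaire-style diabetes fields. Fully deterministic under one seed.
- **`domdev.qc`** — variant QC: allele frequency, exact Hardy-Weinberg test
  (Wigginton-style conditional enumeration), info/HWE/MAF filters with full
  reason codes, pairwise LD (r², composite D′) and greedy independence
  pruning.
- **`domdev.phenotypes`** — dual-measure BMI resolution with the 4.56-SD
  discordance exclusion, OLS residualisation on covariates, rank-based
  inverse-normal transform (Blom offset), obesity / severe-obesity /
  type 2 diabetes case-control labelling with exclusion accounting.
- **`domdev.models`** — per-variant additive, dominance-deviation (joint),
  recessive and dominant fits; OLS with Wald t p values for quantitative
  traits, logistic IRLS with Wald SEs and separation flagging for binary
  traits; genome-wide scan with QQ table and genomic-inflation statistic.
- **`domdev.grouped`** — analysis of printed summary tables alone:
  exact saturated and weighted-additive fits from genotype-class
  (n, mean, SD) triplets, variance-explained increments, Woolf odds ratios
  from 2×2 counts, additive-model OR expectations, BMI-to-kg conversion.
- **`domdev.meta`** — inverse-variance fixed-effects meta-analysis with SE
  recovery from CIs or p values, Bonferroni thresholds with
  one-significant-figure rendering, non-central chi-square power, recessive
  variance-explained and case-control effective sample size.
- **`domdev.pipeline` / `domdev.io` / `domdev.cli`** — YAML-driven
  orchestration, plain-text VCF 4.2 (GT/DS/GP) and TSV interchange,
  markdown reporting.

## Test

```sh
python -m pytest -q tests/
```

The suite contains unit tests per module, property-based tests (hypothesis)
for the transform/OR invariants, and `tests/test_acceptance.py` with one
test per acceptance criterion (printed-value reproductions, type-I error,
recessive-effect recovery, exact-vs-chi-square agreement, filter
enumeration, end-to-end planted-effect detection).

## Command line

```sh
# end-to-end run from a YAML config (simulate -> QC -> prep -> scan -> report)
domdev run --config cfg.yaml

# individual stages, composable via files
domdev simulate --config cfg.yaml --out-prefix sim
domdev qc --vcf sim.vcf --out qc.tsv
domdev prep --cohort sim.cohort.tsv --out prepared.tsv
domdev assoc --vcf sim.vcf --cohort sim.cohort.tsv --phenotypes prepared.tsv \
    --trait bmi --out assoc.tsv

# summary-statistics utilities
domdev grouped --class-summary classes.tsv
domdev meta --studies studies.tsv
domdev power --n 119688 --r2 0.0004 --alpha 3e-9
```

Example config:

```yaml
seed: 9
simulate:
  n_samples: 5000
  n_variants: 200
  maf_range: [0.2, 0.5]
  info_range: [0.95, 1.0]
  skew: 0.2
  discordance_rate: 0.01
  effects:
    - {variant_index: 17, beta_add: 0.3, beta_domdev: -0.3, trait: bmi}
scan:
  traits: [bmi]
```

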