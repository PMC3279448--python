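# repmeth

Analysis pipeline linking placental repetitive-element DNA methylation
(LINE-1 and AluYb8, measured by bisulfite pyrosequencing) to infant growth
and to genomewide CpG methylation measured on a 27K-style beta-value array.
It is written for epigenetic epidemiologists who want the full chain —
cohort statistics, model-based locus clustering, familywise permutation
testing and TFBS enrichment — as tested, reusable code. Because the
original study cohort was never deposited, the package ships a calibrated
synthetic-cohort generator that reproduces the printed descriptive
statistics, and every downstream method is validated against that ground
truth.

## What it computes

- **Beta-values and repeat summaries.** β = max(M,0)/[max(M,0)+max(U,0)+100]
  from methylated/unmethylated intensities; LINE-1 and AluYb8 methylation
  as the mean of 4 and 5 pyrosequencing positions (percent scale).
  Sample QC by Mahalanobis screening of per-subject β summaries; loci on
  X/Y excluded.
- **Growth associations.** SGA/AGA/LGA categories (strict 10th/90th
  percentile boundaries), greedy case–control matching, Kruskal–Wallis /
  chi-square univariate tests, Pearson correlation with Fisher-z CI, and
  adjusted OLS of birth weight percentile on each marker per 10% methylation
  (covariates: infant sex, maternal age, BMI, ethnicity, tobacco, alcohol,
  prenatal vitamins).
- **Recursively partitioned beta-mixture clustering.** Loci are split
  recursively into 2-component mixtures with an independent Beta(a_j, b_j)
  density per subject column; a split is kept iff it improves BIC, recursion
  is pruned after four splits (≤ 16 classes), and classes are numbered by
  increasing mean methylation.
- **Omnibus max-|t| permutation test.** Each class's aggregate methylation
  (mean β over member loci, per subject) is regressed on a marker; the test
  statistic is max over classes of |t|, with the null built by jointly
  permuting the marker across subjects (10,000 permutations by default).
  The 0.95 null quantile doubles as a multiplicity-adjusted per-class limit.
- **TFBS gene-set enrichment.** Loci ranked by the t of β-on-marker
  regressions; each transcription factor's ≤1 kb proximity set scored by
  the weighted Kolmogorov–Smirnov running sum (weight exponent 1), with
  phenotype-permutation NES, p and FDR q.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
bundle. With the default seed:

```
$ python analysis/01_simulate_cohort.py --seed 0
cohort: 380 subjects (SGA 31, AGA 323, LGA 26)
beta matrix: 2000 loci x 184 subjects, mean beta 0.239

$ python analysis/02_growth_associations.py
LINE-1 vs AluYb8: r = 0.330 (95% CI 0.238, 0.417), n = 380
line1 per-10%: 13.3 (95% CI 7.6, 19.0), p = 5.5e-06
aluyb8 per-10%: 11.6 (95% CI 3.8, 19.4), p = 0.0038

$ python analysis/03_cluster_loci.py
2000 autosomal loci, 184 subjects; 0 Mahalanobis outlier(s) at alpha=0.001
16 terminal classes (class 1 mean 0.005 ... class 16 mean 0.761)
majority-mapping agreement with latent classes: 1.000

$ python analysis/05_omnibus_tests.py
line1   vs rpmm         : max|t| =  1.49, p = 0.9046, null limit = 3.01
aluyb8  vs rpmm         : max|t| =  2.48, p = 0.1975, null limit = 2.97
...
```

Reading the output: a single simulated cohort of n = 380 gives a marker
correlation of 0.33 (the configured population value is 0.29; the Fisher
interval covers it) and adjusted per-10% coefficients of 13.3 and 11.6
percentile points (population values 9.7 and 14.5 — single-cohort estimates
scatter with SE ≈ 3–4, which is why the calibration checks below average
over 50 cohorts). The depth-4 clustering recovers all 16 latent methylation
classes exactly. Because this generator encodes no true marker→class-
methylation link, the omnibus p-values are null, and the per-class |t|
values stay inside the dashed familywise limits (figures under
`results/omnibus/`). `04_class_methylation.py` and `06_tfbs_enrichment.py`
produce the attribute-class census (38 nonempty classes at the default
annotation frequencies) and the ranked TFBS enrichment tables.

The same stages are available as a CLI (`repmeth simulate|preprocess|
associations|cluster|classes|omnibus|gsea|report|all`) and as one call,
`repmeth.pipeline.run_pipeline`, which writes a markdown report.

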