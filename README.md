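# snvnet

Candidate-gene SNV association pipeline for smoking-cessation case–control
cohorts: univariate behavioral statistics, an SNV filtering cascade,
elastic-net penalized logistic regression with leave-one-out cross-validated
AUC model selection, and post-selection (selective) inference yielding
per-allele adjusted odds ratios.

## The problem

Cohorts of persons with HIV who smoke are compared against biochemically
verified long-term ex-smokers: which behavioral covariates (hazardous
alcohol use, marijuana and cocaine use, anxiety) and which of several
hundred single-nucleotide variants in a 12-gene candidate panel (*IREB2*,
*SLC25A21*, *SEMA6D*, *CHRNA3/4/5*, *CHRNB4*, *PSMA4*, *DNMT3B*, *CADM2*,
*CYP2A6*, *HTR2B*) distinguish the successful quitters? The setting is
p ≈ n with heavy autocollinearity, so the multivariable model is a penalized
logistic regression

    min_β (1/n) Σᵢ [log(1 + e^{ηᵢ}) − yᵢ ηᵢ] + λ Σⱼ (α|βⱼ| + (1−α)βⱼ²/2),

with genotypes coded additively (0/1/2 alt-allele copies), (α, λ) chosen by
leave-one-out cross-validated AUC over α ∈ {0, 0.5, 1} × 100 λ values, and
p-values for the lasso-selected coefficients computed by the polyhedral
(truncated-Gaussian) post-selection framework, so that the selection step
itself is accounted for and false discoveries stay controlled at the nominal
level. See `docs/methods.md` for the full model account.

Because individual-level genotype data of this kind are not publicly
deposited, the package ships a synthetic-cohort generator with the same
statistical structure (Hardy–Weinberg genotypes, LD blocks, co-used
substance covariates, planted per-allele effects) and a deterministic
"mirror" fixture whose filtering and univariate accounting equal the
published counts exactly.

## Worked example

Run the full pipeline on the built-in mirror cohort (194 participants,
142 smokers / 52 ex-smokers, 759 SNVs):

```bash
$ snvnet analyze --study-mirror --seed 1 --out out/
best alpha=0.5 log(lambda)=-3.030 LOO AUC=0.776; 41 predictors selected; reports in out/
```

`out/filter_report.json` shows the cascade accounting — 759 input SNVs, 124
removed for < 2% variation, 458 for ≥ 5% missingness, 21 as duplicate
profiles, 156 retained; 157 of 194 participants are complete cases.
`out/table1.tsv` holds the univariate report; e.g. the marijuana row

```
variable       or      ci_low  ci_high  p           test        n_smokers  n_exsmokers
marijuana_30d  3.73647 1.69119 8.25526  0.000691131 chi_square  139        52
```

reads: 43.9% of smokers vs 17.3% of ex-smokers used marijuana in the past 30
days, OR 3.74 [1.69–8.26] — current use strongly opposes successful
quitting. `out/table2.tsv` is the multivariable report: per selected
predictor the adjusted odds ratio (per allele for SNVs, ex-smoker oriented)
and its selective p-value, e.g.

```
name           or_adj    p
marijuana_30d  0.287681  0.0177791
gad7           0.803618  0.168177
```

so after adjustment, current marijuana use multiplies the odds of being a
long-term quitter by 0.29 (p = 0.018 after accounting for selection). Since
the CV optimum here is α = 0.5, the inference stage falls back to the best
pure-lasso grid point (a warning says so); the SNV rows on this fixture are
noise by construction. The same pipeline runs on your own data:

```bash
snvnet analyze --genotypes geno.tsv --phenotypes pheno.csv --out out/
```

with genotypes as a dosage TSV (+ `*.meta.tsv` sidecar: id, chrom, pos, ref,
alt, gene) or a biallelic GT-only VCF (`--format vcf`), and phenotypes as a
CSV (see `snvnet.io.PHENO_COLUMNS`). `snvnet simulate` writes synthetic
cohorts, `snvnet table1` just the univariate report, and `snvnet check`
runs a quick numerical self-test.

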