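# imputebench

A simulation benchmark of nine missing-data approaches on nonnormal count
data, built for longitudinal eHealth-style cohorts where attrition is the
rule rather than the exception.

## The problem

Follow-up measurements in online intervention studies go missing for
reasons correlated with the participants themselves — heavier drinkers are
likelier to skip a follow-up diary than light drinkers.  Missingness of
this kind is *missing at random* (MAR): the probability that a value is
missing depends on observed data (here, baseline consumption), not on the
missing value itself once the observed data are taken into account.  How a
study handles those holes determines whether its estimates are biased,
overconfident, or both.

`imputebench` evaluates the common choices on data shaped like a real
two-wave cohort of problem drinkers: n = 124 participants, seven daily
drink counts (standard 10 g ethanol units) at baseline and at a 3-month
follow-up, with one designated follow-up day calibrated to mean 2.62 and
SD 5.22 drinks/day — nonnegative integers, a visible mass at zero
(post-intervention abstainers), and a heavy right tail.  Missingness is
induced in that one variable for 50% of cases, with deletion probability a
logistic function of the same weekday's baseline count.

## The approaches

| label | description |
|---|---|
| `complete_cases` | drop every row with a missing cell |
| `mean_imputation` | fill with the column's observed mean |
| `locf` | carry the baseline day forward (`locb` carries backward) |
| `regression_imputation` | OLS prediction from the baseline week + normal noise |
| `em_imputation` | conditional means under an EM-fitted multivariate normal |
| `mi_norm` | MI by normal-model data augmentation (I-step/P-step) |
| `mi_chained` | MI by chained equations with predictive mean matching |
| `mi_norm_minimal` | the same sampler under a deliberately minimal model (target + its baseline only, short burn-in) |
| `mi_bootstrap_em` | MI by bootstrap-EM: EM on row resamples, then conditional draws |

Multiple-imputation results (m = 5 by default) are combined with Rubin's
rules: pooled estimate Q̄ = mean(Qⱼ); within-variance W̄ = mean(Uⱼ);
between-variance B = var(Qⱼ); total T = W̄ + (1 + 1/m)B; degrees of
freedom ν = (m − 1)(1 + W̄/((1 + 1/m)B))².

Each approach is scored three ways against the pre-deletion reference:

* **validity** — pooled-variance t test and Cohen's d of the completed
  target variable against the reference variable (df = n₁ + n₂ − 2);
* **reliability** — the variance of the completed-data means across 75
  bootstrap resamples of the masked cohort;
* **coverage** — the proportion of those 75 means inside the reference
  mean's 95% t interval (70 of 75 inside = 93%).

## Worked example

```python
from imputebench import (CohortConfig, generate_cohort, induce_mar, MISettings,
                         mi_bootstrap_em, mean_impute, locf,
                         pool_mean_analysis, summarize_variable)
from imputebench.missingness import default_spec

cohort = generate_cohort(CohortConfig(seed=3))
ref = summarize_variable(cohort, "f1")
print(f"reference f1: mean={ref.mean:.2f} sd={ref.sd:.2f} n={ref.n}")

masked = induce_mar(cohort, default_spec(cohort, fraction=0.5, seed=4))
print(f"missing cells in f1: {masked.n_missing}")

print(f"mean imputation completed mean: {mean_impute(masked).first['f1'].mean():.2f}")
print(f"LOCF completed mean:            {locf(masked).first['f1'].mean():.2f}")

pe = pool_mean_analysis(mi_bootstrap_em(masked, MISettings(m=5, seed=9)), "f1")
lo, hi = pe.confidence_interval()
print(f"bootstrap-EM MI pooled mean:    {pe.estimate:.2f}  "
      f"(se {pe.se:.2f}, df {pe.df:.1f}, 95% CI [{lo:.2f}, {hi:.2f}])")
```

prints

```
reference f1: mean=2.56 sd=4.13 n=124
missing cells in f1: 59
mean imputation completed mean: 2.17
LOCF completed mean:            5.00
bootstrap-EM MI pooled mean:    2.91  (se 0.68, df 13.8, 95% CI [1.44, 4.38])
```

Mean imputation undershoots the reference (it fills holes with the mean of
a selectively *low* observed subsample), LOCF overshoots badly (it carries
the higher pre-intervention baseline forward), and proper MI lands near the
reference with an honest interval.

The same pipeline is scriptable from the shell:

```bash
imputebench simulate --seed 3 --out cohort.csv
imputebench mask cohort.csv --target f1 --fraction 0.5 --seed 4 --out masked.csv
imputebench impute masked.csv --method mi_bootstrap_em --m 5 --seed 9 --out-dir imputed/
imputebench pool imputed/mi_bootstrap_em_*.csv --variable f1
imputebench study --seed 1 --out-dir study/     # full nine-approach benchmark
```

`study` writes the validity table, coverage table, strip-chart data and
bootstrap-mean data as CSVs plus a `report.json` with full provenance.

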