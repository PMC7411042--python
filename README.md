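# lifedemog

Cohort life-table demography for interval-censused life-history
experiments, with the statistical machinery that typically surrounds
them: Euler–Lotka estimation of the intrinsic rate of population
increase with bootstrap confidence intervals, survival and fecundity
comparisons across treatments, and the sequence-side filters needed when
the same organisms are also profiled by RNA-seq from mixed
(animal + food-algae) cultures.

It is written for experimental ecologists and biostatisticians running
zooplankton-style life-table assays: single females followed from birth
at a fixed census interval (12 h by default) until death, recording
survival and offspring at every census, across species × temperature
treatments.

## The model

From a cohort of `n₀` females the package builds the classical schedule

- `x` — age at the start of each census interval (days),
- `l(x)` — survivorship: proportion of the cohort alive at the start of `x`,
- `m(x)` — fecundity: offspring per female alive during the interval at `x`,

and solves the Euler–Lotka renewal equation for the intrinsic rate of
increase `r` (per day):

```
Σₓ e^(−r·x) · l(x) · m(x) = 1
```

The left side is strictly decreasing in `r` whenever reproduction occurs
at a positive age, so the root is unique; it is found by bracketed
root-finding to a residual below 1e-10. The net reproductive rate is
`R₀ = Σ l(x)·m(x)`, and `sign(r) = sign(R₀ − 1)`. Sampling uncertainty
comes from a percentile bootstrap: individuals are resampled with
replacement 199 times, the life table rebuilt and `r` re-solved per
replicate; the 95% interval is the 5th and 195th order statistics of the
replicate distribution.

Treatment comparisons use Kaplan–Meier curves with pairwise log-rank
tests, Kruskal–Wallis and pairwise Wilcoxon rank-sum tests with
Bonferroni correction, and gaussian/poisson GLMs over the
species × temperature design selected by AIC — all implemented from
their defining formulas and cross-checked in the test suite against
lifelines, scipy and statsmodels.

For transcriptome work on the same cultures, contigs are assigned
competitively from blastn hit tables: a contig is of target (animal)
origin only when its top hit is the target genome **and** the bit-score
gain over the best hit in any competitor (algae) database exceeds 100;
rRNA-matching contigs are removed first, and genes with total count
below 10 or expressed in fewer than 2 replicates are dropped before
differential-expression modelling.

## Worked example

```python
from lifedemog import CohortDemography, CohortParams, simulate_cohort

params = CohortParams(
    species="tolerant", temperature=20.0, n_individuals=24,
    q=(0.05,),                                  # death prob per 12-h interval
    fecundity=(0, 0, 0, 0, 0, 0, 1.0, 1.0, 1.0, 1.0),  # maturation at day 3
    max_intervals=400,
)
records = simulate_cohort(params, seed=42)
results = CohortDemography(records).fit(n_boot=199, seed=42)
print(results.summary())
```

prints

```
Cohort demography
==============================================
individuals                                 24
mean lifespan (days)                    7.9792
net reproductive rate R0               10.9583
intrinsic rate r (per day)            0.411318
Lotka residual |f(r)|                 0.00e+00
95% CI low                            0.321209
95% CI high                           0.489571
bootstrap replicates                       199
failed replicates                            0
```

The 24 simulated females lived 7.98 days on average and left 10.96
offspring each (`R₀`), giving an intrinsic growth rate of 0.41 per day —
the population would multiply by `e^0.41 ≈ 1.5` daily — with a 95%
bootstrap interval of (0.32, 0.49). The generating schedule's analytic
rate (`solve_lotka(analytic_schedule(params))`) is 0.399 per day, inside
the interval.

The same pipeline runs from the shell:

```
lifedemog simulate --seed 1 --out records.csv
lifedemog demography --records records.csv --n-boot 199 --seed 1 --out r.tsv
lifedemog survtest --records records.csv --response fecundity --out stats.tsv
lifedemog contamfilter --hits hits.tsv --labels labels.tsv --gain 100 --out-dir out/
lifedemog countfilter --counts counts.tsv --min-count 10 --min-replicates 2 --out kept.tsv
lifedemog run --config config.yaml --out-dir results/   # end-to-end + manifest
```

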