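# Methods

## The demographic model

The experimental unit is a single female observed from birth at a fixed
census interval Δ (default 0.5 d = 12 h) until death; at each census the
observer records survival and the neonates produced since the last
census. Data are therefore interval-censored at Δ: a death scored at
census `j` occurred somewhere in `((j−1)Δ, jΔ]`. The package stores no
continuous death times; an individual dying in interval `j` is assigned
lifespan `jΔ` (end of its death interval). This end-of-interval
convention is stated rather than hidden because it shifts mean lifespan
by at most Δ/2 relative to a midpoint convention; it is the conservative
reading of interval-censored observation.

From `n₀` records the life table is

- `lx[j] = (alive at start of interval j+1) / n₀`, so `lx[0] = 1` and
  `lx` is non-increasing;
- `mx[j] = (offspring counted at census j+1) / (alive at start of
  interval j+1)`.

The `mx` denominator is the risk set at the interval start: a female
dying within an interval still contributes the neonates found at its
closing census. This makes the identity `Σ lx·mx = total offspring / n₀`
exact on integer data, which the tests check. Age `x` is the interval
start in days; a whole-day aggregation (`aggregate_daily`) is provided
that takes `lx` at day starts and pools the day's reproduction so that
`Σ lx·mx` is conserved, for users who prefer daily resolution.

## Euler–Lotka solution

`r` solves `f(r) = Σ e^(−r·x)·lx·mx − 1 = 0`. With any reproduction at
`x > 0` the sum is strictly decreasing in `r`, so the root is unique.
The solver expands an initial bracket `[−10, 10]` per day geometrically
until the residual changes sign, then applies Brent's method
(`scipy.optimize.brentq`, xtol 1e-14); the result is accepted only if
`|f(r)| < 1e-10`. Degenerate inputs fail loudly: `R₀ = 0` (no
reproduction) and reproduction confined to `x = 0` (residual constant in
`r`) raise typed errors. Exponents in the residual are clipped to
[−745, 500] so bracket scans at extreme `r` stay finite without
affecting any root: at the clip boundary the residual is already far
from zero on any schedule whose `r` is remotely biological
(|r| < 20 d⁻¹).

## Bootstrap confidence intervals

Uncertainty in `r` is sampling variation across females, so the
resampling unit is the individual: each of 199 replicates draws `n₀`
records with replacement, rebuilds the life table and re-solves. The CI
is the percentile interval; with `B` replicates and tail probability `q`
the bounds are the `⌈(B+1)q⌉`-th and `⌊(B+1)(1−q)⌋`-th order statistics
— for B = 199 at 95%, the 5th and 195th. 199 replicates is the default
because it makes these order statistics exact. BCa was considered and
rejected as the default: with 24 individuals and a non-smooth
resample-to-r map, the acceleration estimate is noisier than the
interval it corrects; the percentile method is the minimal-assumption
choice. A resampled cohort can be unsolvable (e.g. every drawn female
sterile); such replicates are excluded and counted (`n_failed`), and
more than 50% failures aborts with an error rather than returning an
interval built on a minority of replicates. Note the percentile CI of
resampled cohorts is not forced to contain the point estimate in
pathological small-n cases; only `ci_low ≤ ci_high` is guaranteed.

## Statistical battery

All tests are two-sided; p-values are floored at the smallest positive
double rather than printed as 0.

- **Kaplan–Meier**: product-limit estimator; with no censoring it equals
  the empirical survivor function.
- **Log-rank** (two groups): at each distinct death time the observed
  deaths in group A are compared with the hypergeometric mean given the
  pooled risk set; `(ΣO−E)²/ΣV` on 1 df with the pooled-tie variance
  `V = d·(n₁/n)·(n₂/n)·(n−d)/(n−1)`. Ties are certain at a 12-h census,
  hence the tie-pooled form.
- **Kruskal–Wallis**: average-rank H with the standard tie correction,
  chi-square on k−1 df.
- **Wilcoxon rank-sum**: exact null distribution (dynamic-programming
  enumeration of rank-sum counts) when both groups have n ≤ 8 and the
  pooled sample is tie-free — the regime where enumeration is cheap and
  the normal approximation worst — otherwise normal approximation with
  tie-corrected variance and 0.5 continuity correction.
- **Bonferroni** for all pairwise families: `p_adj = min(1, m·p)`.
- **GLM**: IRLS, gaussian/identity (equals OLS closed form) and
  poisson/log, converged when the deviance changes by < 1e-8
  relatively within 100 iterations. AIC = 2k − 2ℓ with k counting the
  gaussian dispersion (R's convention). Candidate models for a
  species × temperature design form the nested lattice {temperature},
  {species}, {temperature+species}, {+interaction}; temperature enters
  as a numeric covariate (three to four levels spanning a monotone
  thermal gradient), species as treatment-coded dummies. Selection is
  minimum AIC with exact ties resolved toward fewer parameters.

Families are configurable; the defaults — gaussian for lifespan
(continuous, bounded noise) and poisson for total fecundity (counts) —
match the response types.

## Sequence filters

Contig decontamination is competitive: per contig, `B_t` is the best
bit-score against the target genome and `B_c` the best against any
competitor database (0 when absent). Classes: *target* iff `B_t > B_c`
and `B_t − B_c > 100` (strictly greater; a gain of exactly 100 is
*ambiguous*); *contaminant* iff `B_c ≥ B_t` — a tie fails the "top hit
is the target" requirement; *ambiguous* otherwise; *unassigned* for
hitless contigs, which are written to their own partition rather than
silently dropped. Contigs hitting the 18S/28S rRNA database at e-value
≤ 1e-10 are flagged and removed before assignment. Raising the gain
threshold can only shrink the target class (tested property).

The count pre-filter keeps a gene iff its **total** count across samples
is ≥ 10 and it is non-zero in ≥ 2 samples. "Low count (< 10)" could also
be read per sample; the total reading is the common pre-filtering
convention and a `per_sample` flag provides the alternative. "Present in
at least 2 replicates" is read as non-zero in ≥ 2 samples overall, not
per condition, since no condition is named; `min_replicates` is
configurable. The filter is a pure row subset and idempotent.

## Synthetic data generator

The generator emulates the life-table assay: ≥ 24 females per
species × temperature, censused every 12 h until all die. Death is drawn
per interval from piecewise-constant probabilities `q_j` or from a
Gompertz hazard `h(t) = a·e^{bt}` converted through the cumulative
hazard (`q_j = 1 − exp(−(H(t_{j+1}) − H(t_j)))`, verified against
quadrature); offspring are Poisson(`f_j`) per interval survived,
independent across intervals — the simplest count model consistent with
neonates being removed at every census. Offspring observed at the census
closing the death interval are counted (the "interval of hatching"
convention). `analytic_schedule` returns the exact large-n limit
(`lx = Π(1−q_j)`, `mx = f_j`), which is what parameter-recovery tests
compare against. Per-treatment sub-seeds are SHA-256 hashes of
(global seed, species, temperature), so a design simulates identically
regardless of treatment order.

Two species presets encode a thermal-tolerance contrast (a tolerant
species whose hazard rises slowly with temperature and a sensitive one
with a lower optimum); the parameter-recovery schedule used in the
verification runs is a constant hazard of 0.05 per 12 h with maturation
after 3 days and about one neonate per half-day thereafter — a
realistic rotifer-like schedule at a benign temperature, giving
r* ≈ 0.40 d⁻¹. Its interval cap is 400 (200 days) so that an individual
outliving the cap (probability ≈ 1e-9) is effectively impossible;
individuals that do hit a cap are flagged censored, never silently
killed.

What the generator does **not** emulate: sexual (mictic) phases,
maternal age effects, acclimation, food dynamics, or overdispersed
clutch sizes. Passing tests therefore demonstrate correctness of the
estimators under interval-censored Bernoulli–Poisson life histories,
not robustness to those biological complications.

Hit-table fixtures place the constructed bit-score margins strictly
above (target) or inside (ambiguous) the gain window, so a correct
classifier must recover 100% of labels; count-matrix fixtures plant
genes violating each retention criterion separately.

## Verification problem sizes

The standing verification runs use: 1,000 random schedules against a
1e-12 bisection oracle (agreement < 1e-8); 200 cohorts of 24 females
with 199 bootstrap replicates each (mean r̂ within 2 SE of r*, CI
coverage required in [90%, 99%]); 500 random datasets against
lifelines/scipy (statistics to 1e-8, p to 1e-6); 2,000 null simulations
per test (type-I error required in [3%, 7%] at α = 0.05); 400 contigs
and 600 genes for the filters; and a full double pipeline run compared
checksum-by-checksum.

## Known limitations

- No left truncation or staggered entry; all individuals enter at age 0.
- The log-rank test is the unweighted (1-df) form only; no trend or
  stratified variants.
- The exact Wilcoxon path does not handle ties (falls back to the
  corrected normal approximation, standard practice).
- Poisson GLMs do not model overdispersion; for strongly overdispersed
  fecundities the gaussian family on transformed counts, or an external
  negative-binomial fit, is more appropriate.
- `r` inherits the life table's discrete age grid; with very coarse
  censusing the discretisation bias of `r` grows with `r·Δ`.
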