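# Methods note

This package benchmarks inpatient antibiotic use across hospitals at three
levels of risk adjustment and quantifies how much the adjustment changes
facility rankings. This note records the statistical models, the estimation
choices, and the known limits of the synthetic-data generator.

## Outcomes and metrics

For each inpatient stay we track two use metrics over a denominator of
*days present* (`dp`, the number of calendar days the patient occupied a
bed):

- **DOT** (days of therapy): one count per antibiotic agent per calendar
  day of administration. Two agents on the same day count twice.
- **DASC** (spectrum-weighted days): DOT with each agent-day weighted by
  the agent's spectrum score, so broad-spectrum use counts for more.
  The bundled score table (`toy_spectrum_table`) is synthetic — roughly
  twenty agents with scores between 1 and 16 — and is **not** a published
  scoring system; users benchmarking real data should supply their own
  score table.

Crude facility rates are `1000 * metric / dp` aggregated over stays.

## Method 1: aggregate negative binomial (O:E ratios)

Stays are aggregated to unit-month records (sums of the outcome and `dp`,
plus average length of stay). The outcome count follows NB2:

```
y_um ~ NB(mu_um, theta),   log mu_um = x_um' beta + log dp_um
```

with variance `mu + mu^2/theta`. Covariates are unit type flags (ICU,
surgical), average-LOS quintile, and facility attributes (complexity
level, ICU/surgical complexity, resident-trainee quintile) entered as
categorical blocks. Model terms are chosen by backward elimination on
AIC, removing the single term whose removal lowers AIC most, with
categorical variables entering and leaving as whole blocks.

Scoring a later evaluation period freezes the coefficients *and* the
average-LOS quintile cutpoints at their baseline values. The facility
O:E ratio is `sum(observed) / sum(expected)` over the facility's
evaluation unit-months, with an exact-Poisson interval on the observed
total (chi-square quantiles) conditional on the expected total.

## Method 2: patient-level zero-inflated NB with hospital random intercepts

Each stay's outcome is a two-part mixture:

- with probability `pi_i` the stay is a structural zero
  (`logit pi_i = z_i' gamma + b_zero[h(i)]`, where `z` includes patient
  covariates and `log dp` as a regular term);
- otherwise `y_i ~ NB2(mu_i, theta)` with
  `log mu_i = x_i' beta + log dp_i + b_count[h(i)]` (`dp` as offset).

`b_count ~ N(0, sigma2_count)` and `b_zero ~ N(0, sigma2_zero)` are
hospital random intercepts, modelled as independent in the likelihood;
their empirical correlation is examined after fitting (Spearman, robust
to shrinkage nonlinearity). The marginal likelihood integrates the
intercept pair out per hospital with a bivariate **Laplace
approximation** at the posterior mode; an adaptive Gauss–Hermite tensor
grid is available as an accuracy cross-check. Inner posterior modes are
found by a vectorised damped Newton iteration with analytic per-stay
gradients and Hessians; the outer optimisation over
`(beta, gamma, log theta, log sigma2_count, log sigma2_zero)` uses
L-BFGS-B with finite-difference gradients. Wald standard errors come
from a numerical Hessian of the marginal likelihood.

Facility **P:E ratios** for an evaluation period freeze the fixed
effects, dispersion and variance components, re-estimate only the
intercept pairs from evaluation stays (posterior modes = BLUPs), and
compare mixture-mean predictions with and without the intercepts:

```
P:E = sum_i (1 - pi_i(b)) mu_i(b)  /  sum_i (1 - pi_i(0)) mu_i(0)
```

Because posterior modes shrink toward zero when a hospital contributes
little information, P:E flags small hospitals as outliers less often
than O:E does — the intended specificity property.

**Numerical choices.** DASC is non-integer after spectrum weighting; the
NB2 pmf is evaluated at the rounded outcome (`round_outcome=True`).
Variance estimates are floored at 1e-8 on the natural scale; a variance
at the floor is reported as (numerically) zero and variance-reduction
summaries against it are undefined rather than infinite. Newton steps in
the inner solver are capped in length and fall back to prior-
preconditioned steepest ascent when the local Hessian is not negative
definite.

## Variable selection for method 2

1. **Prescreen** — a comorbidity/procedure flag is a candidate only if
   its prevalence is at least 0.5% and its univariate Spearman
   correlation with the stay-level outcome rate is significant at
   alpha = 0.05, for either outcome (union over DOT and DASC).
2. **Consensus LASSO** — stays are partitioned into K = 10 disjoint
   random subsets stratified by hospital. Within each subset an
   L1-penalised ZINB is fitted by an EM alternation: posterior
   structural-zero weights, then a posterior-weighted NB LASSO for the
   count part and a fractional-response logistic LASSO for the zero
   part, with the penalty chosen by BIC along a warm-started descending
   path. Base demographic terms and the intercept are never penalised.
   Only flags selected in *all* K subsets survive.
3. **Backward AIC for facility/unit terms** — facility attributes are
   then offered and eliminated on AIC with the consensus patient terms
   held fixed. The AIC here is evaluated on a patient-level NB GLM for
   the count mean (a tractability approximation; refitting the full
   mixed model per candidate subset would be orders of magnitude
   slower).

## Ranking agreement

Hospitals are ranked (average ranks for ties) under up to six columns:
crude DOT/DASC, O:E DOT/DASC, P:E DOT/DASC. Agreement between any two
columns is Kendall tau-b, computed on the ratio values (equivalent to
ranks under monotonicity), with tie corrections in both margins.
Classification: strong >= 0.7, moderate [0.5, 0.7), weak < 0.5.
Incomplete hospitals are dropped listwise with a logged count.
Benchmark summaries use median-unbiased quantiles.

## Synthetic cohort generator

The generator draws hospitals (with complexity attributes), units
(ICU/surgical flags), and stays with patient covariates: age, sex, ICU
stay, surgical specialty, and configurable comorbidity/procedure flags.
Outcomes are drawn from exactly the method-2 ZINB data-generating
process, with a bivariate normal intercept pair per hospital
(configurable `rho`). Options plant a hospital with a known
count-intercept (its intercept pair is *set* to `(log RR, 0)`),
impose hospital-level case-mix shifts on flag prevalences
(`casemix_sd`), order facility complexity by case-mix severity
(`complexity_tracks_casemix` — a marginal association fully mediated by
patient flags; `complexity_casemix_noise_sd` adds noise to that ordering
so complexity proxies case mix only partially), and couple the DOT/DASC
outcomes to an explicit agent-day table (`coupled_agents`).

**Realism limits.** Stays carry a single month tag (no stays spanning
months); `dp` is drawn independently of the covariates apart from its
role in the zero component; DASC in the uncoupled mode is DOT times a
noisy spectrum multiplier rather than an agent-level aggregate; flag
correlations within patients are not modelled; and seasonal or secular
trends are absent. None of these affect the estimators' correctness on
their own terms, but absolute rate levels and tau values from the
generator should not be read as empirical estimates for any real
system.

## Limitations

- The Laplace approximation can bias variance components when hospitals
  contribute few stays; the quadrature cross-check bounds this in tests
  at desk scale only.
- The intercept pair is fitted as independent even when the generator
  couples it; the post-hoc correlation of BLUPs under-estimates the
  generating correlation because of shrinkage.
- Wald intervals from the numerical Hessian of the Laplace marginal
  likelihood are mildly anti-conservative at moderate scale: the
  parameter-recovery test (40 hospitals x ~400 stays, 10 replicates)
  measures ~90% coverage at nominal 95%, with no material bias in the
  point estimates.
- Exact-Poisson O:E intervals ignore uncertainty in the expected total.
- Backward AIC explores single-term removals only (no re-entry), and
  the facility-term offer uses the count-component GLM approximation
  noted above.
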