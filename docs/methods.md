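# Methods

## Estimand and model

The unit of analysis is the site-month. For site $s$ and calendar month
$m$, $n_{sm}$ is the number of adolescent (ages 11–17) hospitalizations
admitted that month and $k_{sm}$ the number carrying at least one
mental-health diagnosis code. The outcome series is the monthly
percentage $p_{sm} = 100\,k_{sm}/n_{sm}$.

Months are split into a prepandemic period (February 2019 – March 2020,
14 months) and a pandemic period (April 2020 – April 2021, 13 months);
period boundaries are inclusive and assignment uses the admission date
only, so a hospitalization spanning months or periods is counted once, in
its admission month. Within each period an unweighted OLS line is fitted
to $p_{sm}$ on a 0-based month index. The estimand is the slope
difference Δ = pandemic slope − prepandemic slope, in percentage points
per month.

Modelling choices worth making explicit:

- **Unweighted OLS, not a binomial GLM and not $n$-weighted.** The trend
  model treats the monthly percentages as the data; the binomial
  uncertainty enters through the bootstrap, not the fit. This keeps the
  point estimate a transparent function of the plotted series.
- **No seasonality or autocorrelation adjustment.** With a single
  prepandemic year there is no basis for estimating a seasonal component;
  the inference is conditional on the linear-trend assumption.
- **Level shifts are not part of the estimand.** Δ is a pure
  slope contrast; adding a constant to every month's proportion leaves it
  unchanged (this invariance is tested).

## Bootstrap inference

Each bootstrap iteration redraws every usable month independently,
$k^\*_m \sim \mathrm{Binomial}(n_m, k_m/n_m)$, refits both period lines
and records the resampled slopes and their difference. Defaults:
B = 10,000 iterations, α = 0.05. The CI is the empirical 2.5th/97.5th
percentile of Δ*; the two-sided p-value is a z statistic,
mean(Δ*)/sd(Δ*), referred to the standard normal (a symmetric percentile
p-value is available via `p_method="percentile"`). The z construction was
chosen as the natural reading of a "z test on the bootstrapped
distribution"; for these near-normal linear statistics the two variants
agree closely. Both periods are resampled jointly in each iteration so
each Δ* is one coherent draw.

Numerical details: a month with $n_m = 0$ is excluded from the fit (a
0/0 proportion is undefined) with a logged warning; fits require at least
3 usable months per period; a degenerate bootstrap distribution
(sd = 0, e.g. all-zero numerators) reports an NA p-value with a warning.
Draws come from one `numpy` Generator seeded per run, filled
iteration-major, so results are bit-reproducible given (seed, B). In the
full battery (`run_all_its`) per-task seeds are spawned deterministically
from the run seed, so adding or removing an outcome does not perturb the
other results.

## Meta-analysis

Per-site Δ estimates are pooled with DerSimonian–Laird: fixed-effect
weights $w_i = 1/\hat{se}_i^2$ give Cochran's Q; the moment estimator
$\hat\tau^2 = \max(0, (Q-(k-1))/c)$ with $c = \sum w_i - \sum w_i^2/\sum
w_i$; random-effects weights $1/(\hat{se}_i^2 + \hat\tau^2)$ give the
pooled estimate, its SE and a Wald 95% CI, plus
$I^2 = \max(0, 100(Q-(k-1))/Q)$. The site SE is the bootstrap SD of Δ —
the only per-site uncertainty the pipeline computes. Pools are produced
per country and overall; the country level is a stratification, not a
nested random effect (a full site-within-country likelihood model is out
of scope). With $k=1$ the single estimate and its own Wald CI are
returned and τ² is reported as 0 with a flag. A Knapp–Hartung
small-sample adjustment (t reference, rescaled SE) is available but off
by default. When $\hat\tau^2 = 0$ the pool reduces exactly to the
inverse-variance fixed-effect mean.

## Condition code map

The packaged default maps normalized ICD code prefixes (uppercase, dots
removed, `startswith` matching) to 16 condition groups following the
CAMHD-CS group structure: F40/F41/F93 anxiety; F32–F34 depressive;
X60–X84, T14.91, R45.851 and Z91.5 suicidality or self-injury; F50
eating; F10–F19 substance; F20–F29 psychotic; F42 OCD; F30–F31 bipolar;
F43/F94 trauma/stressor; F51/G47 sleep-wake; F60/F61/F68/F69 personality;
F44 dissociative; F45 somatic; F63/F91 disruptive/impulse/conduct;
R45.0–R45.7 and R46 symptom codes; residual F-codes miscellaneous. US and
French pattern sets are merged into one map; the French self-harm
additions are an approximation (the exact institutional list is not
published) represented here by Z91.5, and any exact list can be supplied
as a `group,pattern` CSV. Codes may match several groups — condition
outcomes are multi-label by design. R45 symptom subcodes are enumerated
so that R45.851 (suicidal ideation) maps only to the suicidality group.

## Characteristics table

The period comparison counts unique patients per period (a patient
hospitalized in both periods contributes to both); sex and age come from
the patient's first mental-health hospitalization in the period, and a
condition flag means any qualifying diagnosis in the period. Because
"patients with condition X" and "hospitalizations with condition X" are
both defensible tallies, both are computed; unique patients is the
default and `per_patient=False` switches to hospitalization counts.
Categorical contrasts use Pearson's χ² (no continuity correction), age
uses Welch's t test, and the median length of stay uses a median
(quantile) regression on a period indicator whose p-value comes from a
case-resampling bootstrap z test (the inference procedure for the median
contrast is not standardized; the bootstrap makes the assumption explicit).

## Synthetic data generator

Each site scenario specifies: a Poisson mean for total monthly admissions
(floored at 1, so no denominator is empty by construction — the analysis
layer still guards against zero months in supplied data); a piecewise-
linear true proportion (baseline, prepandemic slope, and a level shift
plus slope shift switching on at April 2020), clamped to [0.01, 0.99];
per-period female probabilities; a multi-label condition mix (independent
Bernoulli per group given the mental-health flag, with a guaranteed
minimum of one group); and a lognormal length of stay (rounded, +1 day).
Each sampled group contributes one representative ICD code; non-flagged
records get non-mental-health filler codes.

Defaults are chosen to emulate the multi-site study setting: seven sites
(five US, two FR analysed as single sites), monthly volumes of 260–550
admissions per site, baseline proportions near 0.33, flat prepandemic
trends, heterogeneous slope shifts of 0.05–0.9 percentage points/month
averaging ≈0.6, a 1-point level shift at onset, female probabilities
0.615 (pre) and 0.685 (pandemic), a condition mix following the
prevalence ranking of adolescent inpatient cohorts, and a median stay of
7 days (log-SD 0.75, giving an IQR of roughly 4–12 days).

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: ICD code co-occurrence structure beyond
independent group draws, readmission dynamics (every hospitalization gets
a fresh patient ID, so per-patient and per-hospitalization tallies
coincide in synthetic data), seasonality, within-month admission
clustering, reporting lags, and site capacity effects. The tests
establish that the estimators recover the parameters of their assumed
data-generating process, not that the process matches any hospital.

## Validation studies

`propits.validation` runs four simulation studies on the counts-only fast
path (problem sizes chosen to give tight Monte-Carlo error at interactive
runtimes):

- **Recovery**: 200 replicate 7-site datasets, true shift 0.6 pp/month,
  monthly volume 2000, B = 500; the mean of the 1400 site estimates is
  compared with the truth (observed bias ≲ 0.01 pp).
- **Coverage**: 500 single-site replicates at monthly volume 400,
  B = 1000; the 95% CI covers the truth in 92–98% of replicates.
- **Type-I error**: 500 replicate 7-site null datasets (slope and level
  shifts zero); 3–7% of the 3500 CIs exclude zero.
- **Meta recovery**: 20 replicates of 7 sites whose true shifts are
  Normal(0.6, 0.1) pp/month at monthly volume 4000, so the between-site
  SD exceeds the per-site SE (~0.07 pp); the pooled estimate recovers the
  mean and τ² > 0 is detected in most replicates.

`scripts/acceptance.py` re-runs these four studies plus the published
worked-example proportions and writes the results as JSON.

## Known limitations

- The estimand is a slope contrast; it cannot distinguish a gradual
  acceleration from a delayed step change, and the onset date is fixed by
  design, not estimated.
- Bootstrap draws are independent across months; any real
  month-to-month correlation (outbreak waves, admission policies) would
  make the intervals anticonservative.
- The DL pool treats site SEs as known; with few sites the Wald CI can
  undercover (the Knapp–Hartung switch mitigates this at the cost of
  wider intervals).
- The default code map is a faithful structural stand-in, not any
  institution's exact list; real analyses should supply their own.
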