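# Methods

## The pipeline

The unit of observation is a tweet record: timestamp, language tag, topic
flags (COVID, vaccine), and per-record attributes — user type, gender, age
band, occupation class, continent/country, account age, follower count,
sentiment polarity in [−1, 1], and a six-class emotion label. Attribute
inference (demographic classifiers, sentiment and emotion scorers) is out
of scope: those values are input fields, produced upstream by whatever
models the user trusts. A tiny keyword matcher is included only so that the
topic-filtering cascade can run on raw text when flags are absent.

The analysis proceeds in stages:

1. **Filtering cascade.** Keep English records, then COVID-topic records,
   then vaccine-topic records, reporting the count at every stage. The
   stage counts are monotone non-increasing by construction.
2. **Attentiveness.** Per UTC calendar day and population group,
   `100 · n_vaccine / n_covid`. Days with no COVID tweets are missing —
   a 0/0 day carries no information and must not be imputed as zero.
3. **Lag scan.** For each epidemic statistic, Pearson correlation between
   `Y(t)` and `X(t − l)` for delays l = 0..30; the selected delay maximizes
   |r|, ties broken toward the smaller delay. By default every delay is
   evaluated on a common response window (days where even the most-shifted
   predictor exists): with per-lag ("pairwise") windows the evaluation
   window drifts with the lag and, for slowly-varying predictors whose
   correlation profile is nearly flat, the drifting variance normalization
   rather than genuine alignment can decide the argmax. The pairwise option
   remains available. P-values are per-lag with no multiplicity
   correction; the selected lag's p-value is therefore optimistic.
4. **Lag-shifted OLS.** `Y(t) = β₀ + Σ βᵢ Xᵢ(t − Lᵢ) + ε`. Lag `l` always
   means the predictor's value `l` days *before* the response day; rows
   where any shifted predictor is unavailable (the first max(L) days) are
   dropped listwise. The design matrix is column-scaled to unit norm before
   the least-squares solve — the raw series span nine orders of magnitude
   and an unscaled solve loses several digits — and coefficients are mapped
   back to raw scales. Adjusted R² uses p = 8 regressors:
   `1 − (1 − R²)(n − 1)/(n − p − 1)`. A condition number above 1e8 attaches
   a collinearity warning (the fit is still returned); a rank-deficient
   design is an error.
5. **Event detection.** Residuals `e(t) = y(t) − ŷ(t)`; the threshold σ is
   their sample standard deviation over the whole aligned window, computed
   once — event days are *not* excluded (an iterative re-estimate excluding
   detected runs exists behind `reestimate_sigma`, off by default).
   Maximal runs with `e(t) > σ` (strict: a day exactly at σ closes the run)
   of length ≥ `min_run` (default 6, i.e. "more than 5 days") are events.
   Runs separated by sub-threshold days are not merged unless
   `gap_tolerance` is raised from 0.
6. **Cross-sections.** In a window of `window_days` (default 7) from an
   event date, per-group vaccine-tweet counts are referenced against a
   benchmark corpus: OR = (a/b)/(c/d) with Wald 95% CI
   `exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`. If any cell is zero, 0.5
   is added to all four cells (Haldane–Anscombe) and the result flagged.
7. **Quadrants.** Attentiveness level is high iff OR > 1 (strict; the
   reference group, OR ≡ 1, is low by convention). Sentiment level is high
   iff the group's mean polarity strictly exceeds the median over all
   classified groups. Categories: 1 = (low, low), 2 = (high, low),
   3 = (high, high), 4 = (low, high).

Deterministic conventions: sentiment classes are negative ≤ −0.05 <
neutral < 0.05 ≤ positive (the standard VADER trichotomy; the published
range endpoints overlap at ±0.05, so the boundary is assigned to the outer
classes); account age uses 365.25-day years with half-open bands [0,5),
[5,10), [10,∞); follower bands are [0,500), [500,5000), [5000,∞);
occupation collapses C2→OC1, {C1,C3}→OC2, C4..C9→OC3; table percentages
round half-up to two decimals; chi-square composition tests use the k×2
count matrix with df = k−1 and no continuity correction.

Demographic denominators follow attribute availability: gender/age exclude
organization accounts, location uses located records only, sentiment and
emotion use scored records. The published aggregate tables bundled in
`vaxlens.datasets` are consistent with this rule (most shares are over the
1,079,105 individual-classified scored tweets; location over 684,275
located tweets; user type over the full 1,197,763).

## The synthetic world

`SimulationConfig` defines a ground-truth world spanning 418 days from
June 2020 (the defaults); all randomness flows from one integer seed
through independent substreams.

**Epidemic panel.** Daily new cases are Gaussian epidemic waves over an
endemic floor (the global count never approached zero in that period),
modulated by a within-week reporting cycle and lognormal reporting jitter,
with Poisson sampling. New deaths follow the case waves at a 14-day delay
with a declining case-fatality ratio, plus deaths waves of regions whose
epidemics are offset from the global case curve, and a much lower fatality
on the endemic floor. Vaccinations ramp up logistically from day ~190;
people-vaccinated integrates the first-dose share, which decays as
campaigns mature and pulses as new country cohorts come online. Totals are
running sums; the reproduction rate is two slow oscillations plus AR(1)
and white estimation jitter around 1.

Two structural choices serve identifiability and deserve explanation:

* *Orthogonal weekly harmonics.* The three daily-reported series carry
  mutually orthogonal within-week patterns (first, second, third harmonic
  of the week). Each series therefore has a day-scale signature that only
  its own lagged copy can explain, which is what lets a marginal lag scan
  pin the delay of a daily series exactly.
* *Shape-diverse cumulative series.* Level correlations between smooth
  monotone cumulative series are inherently near 1 at every shift, so their
  delays are only weakly identified and their regression coefficients are
  the hardest to estimate. The defaults push their shapes apart (deaths
  front-loaded with offset regional waves, cases steady over a floor,
  people-vaccinated saturating in pulses while total doses accelerate) so
  that each carries usable independent variation. One deliberate
  consequence: the true coefficient on people-vaccinated is 0 — given
  total vaccinations, it carries no additional effect in the generating
  model — because no realistic geometry makes both nearly-identical dose
  series separately influential *and* separately estimable.

**Attentiveness.** `Y(t) = β₀ + Σ βᵢ Zᵢ(t − Lᵢ) + ε`, with `Zᵢ` the
z-scored panel variables (keeping the coefficients O(1); raw-scale
equivalents come from `raw_scale_coefficients`), true lags
(5, 3, 4, 0, 0, 0, 0, 10), Gaussian noise (default sd 0.5 percentage
points), and rectangular event bumps. Default bumps mirror the five
pronounced surges of the study period in timing and duration
(14, 12, 6, 21, 46 days); their heights (3–8 points) are many times the
daily noise, as the real surges are. `Y` is clipped to [0, 100]; under the
defaults the deterministic part stays inside, so clipping only trims rare
noise excursions. A raw-scale option applies β directly to unscaled
predictors for pedagogical and testing use.

**Tweet stream.** Each available day emits `tweets_per_day` COVID records.
Group labels are drawn independently per characteristic from a composition
resembling a large real vaccine corpus (≈90% individuals, male-skewed,
oldest age band largest, fear the dominant emotion); gender and age are
absent for organizations. A record's vaccine flag is Bernoulli with
log-odds = per-day base + the sum of its groups' log odds ratios; the base
is solved by bisection so the expected population share equals `y(t)`
(infeasible shares of exactly 0 or 100 raise an error naming the day).
Sentiment is Gaussian around a group- and time-dependent mean with a
slight downward drift over the period, truncated to [−1, 1]. With a single
non-unit characteristic, the vaccine/non-vaccine 2×2 within the stream
identifies the generating odds ratio exactly; a general-content benchmark
with the same group mix identifies a risk ratio instead, which approximates
the OR only at low attentiveness — recovery tests therefore use the
case-control form. When several characteristics carry non-unit ORs
simultaneously, marginal (collapsed) ORs deviate from the conditional ones
(non-collapsibility), as they would in real data.

**What the generator does not emulate.** Characteristics are independent
within a record (no gender×age structure); text is absent (topic flags are
carried directly); tweet volume is constant per day; there are no bots,
duplicates or deletions; sentiment has no event coupling. Passing recovery
tests therefore demonstrates the statistical machinery, not robustness to
the messiness of real streams.

## Validation design and problem sizes

The recovery suite runs at n_days = 400, noise sd 0.5, 100 seeds for lag
and coefficient recovery (coefficients compared in the z-scored
parameterization, error `|β̂−β|/max(|β|,1)` per non-zero coefficient,
medians over seeds below 0.15); 50 seeds for event recovery, using two
injected 6-point bumps — about 3.9 residual standard deviations, detected
against the noise-free baseline with start and duration errors ≤ 1 day;
and 100 streams of 10⁵ records for odds-ratio recovery (true OR 2.0 on the
user-type characteristic alone, estimated within [1.8, 2.2], Wald CI
covering truth in ≥ 90/100). The OR streams use a flat attentiveness
series: a cross-section is a short window at roughly constant rate, and
aggregating a 2×2 over days with strongly varying rates attenuates the
marginal OR (time-strata non-collapsibility). Under the full default world
(five events of heights 3–8), the residual-sd threshold is inflated by the
events themselves, so only the pronounced bumps are detected — consistent
with tabulating only major events — and the iterative σ re-estimate exists
for users who want higher sensitivity.

## Known limitations

* The marginal lag scan identifies the delay of slowly-varying cumulative
  statistics only weakly; the reported per-lag correlations for those
  variables are nearly flat and the selected lag should be read
  accordingly.
* OLS inference here is descriptive: daily series are autocorrelated and
  no HAC correction is applied, matching the plain-OLS design of the
  analysis this package implements.
* Wald CIs on ORs are first-order; for very sparse cells the
  Haldane–Anscombe correction is a blunt instrument and exact methods
  would be preferable.
* The quadrant thresholds (OR > 1; sentiment above the cross-group median)
  are conventions, configurable but inevitably somewhat arbitrary near the
  boundaries.
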