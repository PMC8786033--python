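# vaxlens

Group-stratified analysis of vaccine attitudes in COVID-19 tweet streams:
how much of the online COVID conversation is about vaccines, what drives
that attention, and how it differs across population groups.

The package is aimed at infodemiology and digital-epidemiology researchers
who work with large topic-filtered tweet corpora next to official epidemic
surveillance data. Raw tweet corpora of this kind cannot be redistributed,
so the package ships a synthetic tweet-stream generator with known ground
truth; every stage of the pipeline is validated by recovering that truth.

## What it computes

**Attentiveness.** For a population group on day *t*, attentiveness is the
percentage of vaccine-topic tweets among the group's COVID-topic tweets,
*Y(t)* for the whole population. Days without COVID tweets are missing, not
zero.

**Lag-shifted regression.** Epidemic statistics need not act on attention
instantaneously, so each of the eight daily statistics *X₁..X₈* (new/total
cases, deaths, vaccinations, people vaccinated, reproduction rate) is first
scanned over delays 0–30 days for the delay *Lᵢ* maximizing |Pearson *r*|
with *Y*, then ordinary least squares fits

&nbsp;&nbsp;&nbsp;&nbsp;*Y(t) = β₀ + Σᵢ βᵢ · Xᵢ(t − Lᵢ) + ε(t)*

reporting β, the adjusted R², and *r(Y, Ŷ)* with its Evans verbal band
(very weak < 0.20 ≤ weak < 0.40 ≤ moderate < 0.60 ≤ strong < 0.80 ≤ very
strong, on |r|).

**Event periods.** Runs of more than 5 consecutive days on which *Y*
exceeds the fitted curve by more than one residual standard deviation are
reported as vaccine-related event periods (start, duration, peak).

**Cross-sections.** At event dates, each group's attentiveness odds ratio
against a reference group is computed from a 2×2 table whose benchmark side
is a general-content tweet sample, OR = (a/b)/(c/d), with Wald 95% CIs and
Haldane–Anscombe correction for zero cells. Crossing the OR dimension
(above/below 1) with group mean sentiment (above/below the cross-group
median) assigns each group one of four attitude quadrants.

**Per-record machinery.** JSONL/CSV tweet-record I/O with line-level
diagnostics, the English → COVID → vaccine keyword filtering cascade, UK
SOC 9-class → 3-class occupation collapse, VADER-style sentiment
trichotomization (negative ≤ −0.05, positive ≥ 0.05), account-age and
follower-count banding, demographic tables with chi-square composition
tests.

## Worked example

```python
import vaxlens as vl

counts = vl.cascade_from_counts(524_293_459, 512_781_119, 10_314_577)
print(f"vaccine-related tweets retained: {counts['vaccine']:,}")

cfg = vl.SimulationConfig(seed=1)          # a year-long synthetic world
panel = vl.simulate_covid_stats(cfg)       # daily epidemic statistics
y_true = vl.simulate_attentiveness(panel, cfg)
tweets = vl.simulate_tweets(y_true, cfg)   # ~830k tweet records
y = vl.daily_attentiveness(tweets)         # empirical attentiveness

est = vl.LagShiftedRegression().fit(panel, y)
fit = est.fit_
print("selected lags:", dict(zip(vl.STAT_VARIABLES, map(int, est.lags_))))
print(f"adjusted R^2 = {fit.adj_r2:.4f}")
print(f"r(Y, Yhat) = {fit.fit_corr.r:.4f} ({fit.fit_corr.strength})")
for ev in vl.detect_events(y, fit.fitted):
    print(f"event {ev.start.date()} .. {ev.end.date()} "
          f"({ev.duration_days} days, peak {ev.peak_attentiveness_pct:.2f}%)")
```

prints

```
vaccine-related tweets retained: 1,197,763
selected lags: {'new_cases': 5, 'new_deaths': 3, 'new_vaccinations': 4,
 'total_cases': 0, 'total_deaths': 0, 'total_vaccinations': 0,
 'people_vaccinated': 0, 'reproduction_rate': 10}
adjusted R^2 = 0.8156
r(Y, Yhat) = 0.9051 (very strong)
event 2020-12-15 .. 2021-01-04 (21 days, peak 22.55%)
event 2021-04-21 .. 2021-05-08 (18 days, peak 25.00%)
```

The cascade arithmetic reproduces the published corpus size. The lag scan
applied to the *empirical* attentiveness of the simulated stream recovers
every generating delay exactly; the two most pronounced injected event
bumps are detected, the first at exactly its injected start and 21-day
duration (the smaller early bumps sit below the residual-sd threshold,
which the large events inflate — see `docs/methods.md`).

A `vaxlens` command-line tool wraps the stages: `vaxlens simulate`,
`lagscan`, `regress`, `events`, `crosssec`, and `vaxlens run` for the whole
pipeline from a YAML config, writing a JSON results bundle, stage CSVs and
plots.

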