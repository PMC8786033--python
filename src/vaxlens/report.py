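"""End-to-end pipeline: records -> attentiveness -> regression -> events ->
cross-sections -> quadrants, from a single config, with a machine-readable
results bundle.

On synthetic input the bundle additionally carries a recovery report
comparing estimated lags, coefficients, event periods and odds ratios with
the generator's ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attentiveness import AttentivenessSeries, daily_attentiveness, series_similarity
from .crosssec import attentiveness_or, classify_quadrants, event_window_counts, or_table
from .events import detect_events, event_table
from .lagreg import (
    STAT_VARIABLES,
    CovidStatsPanel,
    LagShiftedRegression,
    fit_quality_exceeds_marginals,
)
from .records import read_records, records_to_frame, _characteristic_values
from .synthetic import (
    SimulationConfig,
    raw_scale_coefficients,
    simulate_attentiveness,
    simulate_covid_stats,
    simulate_tweets,
    simulation_truth,
)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_REFERENCES"]

DEFAULT_REFERENCES = {
    "user_type": "individual",
    "gender": "male",
    "age_band": "<=18",
    "occupation_cat": "OC1",
    "account_age_band": "<5",
    "follower_band": "<500",
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``synthetic`` is set (the generator provides tweets, statistics
    and ground truth) or ``tweets_path`` and ``stats_path`` point at a
    JSONL/CSV tweet table and a daily statistics CSV.
    """

    out_dir: str
    synthetic: SimulationConfig | None = None
    tweets_path: str | None = None
    stats_path: str | None = None
    max_lag: int = 30
    min_run: int = 6
    window_days: int = 7
    characteristics: tuple[str, ...] = tuple(DEFAULT_REFERENCES)
    references: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    make_plots: bool = True

    def validate(self) -> None:
        if self.synthetic is None:
            if not self.tweets_path or not self.stats_path:
                raise ValueError("either synthetic config or input paths are required")
            for path in (self.tweets_path, self.stats_path):
                if not Path(path).exists():
                    raise FileNotFoundError(path)
        for char in self.characteristics:
            if char not in self.references:
                raise ValueError(f"no reference group configured for {char!r}")


def _stage(log: list, name: str, **info) -> None:
    log.append({"stage": name, **info})


def _group_series(frame: pd.DataFrame, characteristic: str, whole: AttentivenessSeries):
    values = _characteristic_values(frame, characteristic)
    out = {}
    for group in values.dropna().unique():
        mask = (values == group).to_numpy()
        try:
            series = daily_attentiveness(
                frame[mask],
                date_range=(whole.dates[0], whole.dates[-1]),
                group_label=f"{characteristic}={group}",
            )
            sim = series_similarity(series, whole)
            out[str(group)] = {
                "series": series,
                "similarity_r": sim.r,
                "similarity_strength": sim.strength,
            }
        except ValueError:
            continue
    return out


def _match_events(detected, truth_events) -> list[dict]:
    rows = []
    for truth in truth_events:
        t_start = pd.Timestamp(truth["start"])
        t_end = pd.Timestamp(truth["end"])
        best, overlap = None, 0
        for ev in detected:
            lo = max(t_start, ev.start)
            hi = min(t_end, ev.end)
            days = (hi - lo).days + 1
            if days > overlap:
                best, overlap = ev, days
        row = {"true_start": truth["start"], "true_duration": truth["duration_days"]}
        if best is None:
            row.update({"detected": False})
        else:
            row.update(
                {
                    "detected": True,
                    "est_start": best.start.date().isoformat(),
                    "est_duration": best.duration_days,
                    "start_error_days": int((best.start - t_start).days),
                    "duration_error_days": int(best.duration_days - truth["duration_days"]),
                }
            )
        rows.append(row)
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the results bundle to ``config.out_dir``.

    Returns the bundle dict; on disk it is ``bundle.json`` plus per-stage
    CSVs (attentiveness, scan table, events, odds ratios) and, when enabled,
    PNG plots.  Deterministic given the config and seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    truth = None

    if config.synthetic is not None:
        sim = config.synthetic
        panel = simulate_covid_stats(sim)
        y_true = simulate_attentiveness(panel, sim)
        tweets = simulate_tweets(y_true, sim)
        truth = simulation_truth(sim, panel)
        _stage(log, "simulate", n_days=sim.n_days, n_tweets=int(len(tweets)))
    else:
        if str(config.tweets_path).endswith(".csv"):
            recs, issues = read_records(config.tweets_path, format="csv")
        else:
            recs, issues = read_records(config.tweets_path, format="jsonl")
        tweets = records_to_frame(recs)
        panel = CovidStatsPanel.from_csv(config.stats_path)
        _stage(log, "read", n_records=int(len(tweets)), n_rejected=len(issues))

    whole = daily_attentiveness(tweets)
    whole.to_csv(out / "attentiveness.csv")
    _stage(log, "attentiveness", n_days=int(whole.value.notna().sum()))

    groups: dict[str, dict] = {}
    for char in config.characteristics:
        groups[char] = _group_series(tweets, char, whole)
    _stage(log, "group_series", n_groups=sum(len(g) for g in groups.values()))

    est = LagShiftedRegression(lags=None, max_lag=config.max_lag)
    est.fit(panel, whole)
    fit = est.fit_
    scans = est.scan_results_
    scan_frame = pd.DataFrame(
        [
            {"variable": s.variable, "lag": s.lag, "r": round(s.r, 4), "p": s.p}
            for s in scans
        ]
    )
    scan_frame.to_csv(out / "lag_scan.csv", index=False)
    _stage(log, "regression", n_used=fit.n_used, adj_r2=round(fit.adj_r2, 4))

    events = detect_events(whole, fit.fitted, min_run=config.min_run)
    event_table(events).to_csv(out / "events.csv", index=False)
    _stage(log, "events", n_events=len(events))

    # cross sections at the detected event starts (truth events when synthetic)
    if truth is not None:
        section_dates = [ev["start"] for ev in truth["events"]]
    else:
        section_dates = [ev.start.date().isoformat() for ev in events]
    sections = []
    for date in section_dates:
        section = {"event_date": date, "window_days": config.window_days, "odds_ratios": []}
        for char in config.characteristics:
            try:
                vac = event_window_counts(
                    tweets, date, config.window_days, char, vaccine_only=True
                )
                frame = records_to_frame(tweets)
                # benchmark: the non-vaccine COVID records of the same window
                start = pd.Timestamp(date)
                end = start + pd.Timedelta(days=config.window_days - 1)
                days = pd.to_datetime(frame["created_at"], utc=True).dt.tz_localize(None).dt.normalize()
                in_window = (days >= start) & (days <= end)
                bench_frame = frame[in_window & ~frame["is_vaccine"].fillna(False).astype(bool)]
                values = _characteristic_values(bench_frame, char).dropna()
                bench = {str(g): int(n) for g, n in values.value_counts().items()}
                common = set(vac) & set(bench)
                ref = config.references[char]
                if ref not in common:
                    continue
                ors = attentiveness_or(
                    {g: vac[g] for g in common},
                    {g: bench[g] for g in common},
                    reference=ref,
                    characteristic=char,
                )
                section["odds_ratios"].extend(ors)
            except ValueError:
                continue
        sections.append(section)
    if sections:
        pd.concat(
            [
                or_table(sec["odds_ratios"]).assign(event_date=sec["event_date"])
                for sec in sections
            ],
            ignore_index=True,
        ).to_csv(out / "odds_ratios.csv", index=False)
    _stage(log, "cross_sections", n_sections=len(sections))

    quadrants = []
    if sections and sections[-1]["odds_ratios"]:
        last = sections[-1]
        start = pd.Timestamp(last["event_date"])
        end = start + pd.Timedelta(days=config.window_days - 1)
        frame = records_to_frame(tweets)
        days = pd.to_datetime(frame["created_at"], utc=True).dt.tz_localize(None).dt.normalize()
        window = frame[(days >= start) & (days <= end)]
        sentiments: dict[str, float] = {}
        for char in config.characteristics:
            values = _characteristic_values(window, char)
            for group in values.dropna().unique():
                pol = window.loc[values == group, "sentiment_polarity"].dropna()
                if len(pol):
                    sentiments[str(group)] = float(pol.mean())
        quadrants = classify_quadrants(last["odds_ratios"], sentiments)
    _stage(log, "quadrants", n_groups=len(quadrants))

    bundle = {
        "version": __version__,
        "config": {
            "max_lag": config.max_lag,
            "min_run": config.min_run,
            "window_days": config.window_days,
            "references": config.references,
            "synthetic": config.synthetic.to_dict() if config.synthetic else None,
            "tweets_path": config.tweets_path,
            "stats_path": config.stats_path,
        },
        "attentiveness": {
            "n_days": int(whole.value.notna().sum()),
            "mean_pct": float(whole.dropna().mean()),
        },
        "lag_scan": scan_frame.to_dict("records"),
        "regression": fit.to_dict(),
        "fit_exceeds_marginals": bool(fit_quality_exceeds_marginals(fit, scans)),
        "events": event_table(events).to_dict("records"),
        "group_similarity": {
            char: {
                g: {
                    "r": round(info["similarity_r"], 4),
                    "strength": info["similarity_strength"],
                }
                for g, info in by_group.items()
            }
            for char, by_group in groups.items()
        },
        "cross_sections": [
            {
                "event_date": sec["event_date"],
                "window_days": sec["window_days"],
                "odds_ratios": or_table(sec["odds_ratios"]).to_dict("records"),
            }
            for sec in sections
        ],
        "quadrants": [
            {
                "group": q.group,
                "attentiveness_level": q.attentiveness_level,
                "sentiment_level": q.sentiment_level,
                "category": q.category,
            }
            for q in quadrants
        ],
        "stages": log,
    }

    if truth is not None:
        est_lags = {v: int(l) for v, l in zip(STAT_VARIABLES, fit.lags)}
        beta_true = np.array(truth["beta_raw"])
        beta_est = fit.beta
        rel_err = np.abs(beta_est - beta_true) / np.maximum(np.abs(beta_true), 1.0)
        bundle["recovery"] = {
            "truth": truth,
            "lag_errors": {
                v: est_lags[v] - truth["lags"][v] for v in STAT_VARIABLES
            },
            "beta_relative_error": [float(e) for e in rel_err],
            "events": _match_events(events, truth["events"]),
        }

    with open(out / "bundle.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=str)

    if config.make_plots:
        _plots(out, whole, fit, events, sections)
    return bundle


def _plots(out: Path, whole, fit, events, sections) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(whole.value.index, whole.value.values, lw=0.8, label="observed Y(t)")
    ax.plot(fit.fitted.index, fit.fitted.values, lw=1.2, label="fitted $\\hat Y(t)$")
    for ev in events:
        ax.axvspan(ev.start, ev.end, color="orange", alpha=0.25)
    ax.set_ylabel("attentiveness (%)")
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(out / "attentiveness_fit.png", dpi=120)
    plt.close(fig)

    if sections and sections[-1]["odds_ratios"]:
        ors = sections[-1]["odds_ratios"]
        fig, ax = plt.subplots(figsize=(6, 0.4 * len(ors) + 1))
        ys = np.arange(len(ors))
        ax.errorbar(
            [o.or_value for o in ors],
            ys,
            xerr=[
                [o.or_value - o.ci_low for o in ors],
                [o.ci_high - o.or_value for o in ors],
            ],
            fmt="o",
            capsize=3,
        )
        ax.axvline(1.0, color="grey", lw=0.8)
        ax.set_yticks(ys)
        ax.set_yticklabels([f"{o.characteristic}: {o.group}" for o in ors])
        ax.set_xscale("log")
        ax.set_xlabel("attentiveness odds ratio (95% CI)")
        fig.tight_layout()
        fig.savefig(out / "odds_ratios.png", dpi=120)
        plt.close(fig)
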