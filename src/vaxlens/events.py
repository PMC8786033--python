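"""Residual-threshold detection of vaccine-related event periods.

An event period is a run of consecutive days on which observed attentiveness
exceeds the regression fit by more than one residual standard deviation,
lasting at least ``min_run`` days (default 6, i.e. "more than 5 days").  The
threshold sigma is the standard deviation of the daily gaps e(t) = y(t) -
yhat(t) over the whole aligned window, computed once — event days are not
excluded unless the iterative re-estimation flag is set.

Shaped as a small detector object (:class:`ResidualEventDetector`) with the
usual get_params/set_params surface plus a `detect_events` wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .attentiveness import AttentivenessSeries

__all__ = ["EventPeriod", "ResidualEventDetector", "detect_events", "event_table"]


@dataclass(frozen=True)
class EventPeriod:
    """One detected period of significantly elevated attentiveness."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration_days: int
    peak_attentiveness_pct: float
    peak_date: pd.Timestamp

    def __post_init__(self) -> None:
        expected = (self.end - self.start).days + 1
        if self.duration_days != expected:
            raise ValueError(
                f"duration {self.duration_days} inconsistent with span {expected}"
            )


def _runs_above(mask: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal [i, j] index runs of True, merging gaps of <= gap_tolerance False days."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    if gap_tolerance > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe - 1 <= gap_tolerance:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    return runs


class ResidualEventDetector(BaseEstimator):
    """Detect attentiveness surges above the fitted curve.

    Parameters
    ----------
    min_run : int
        Minimal run length in days for a run to count as an event (6 keeps
        exactly the runs lasting more than 5 days).
    gap_tolerance : int
        Merge neighbouring runs separated by at most this many sub-threshold
        days (0: never merge).
    reestimate_sigma : bool
        If set, re-estimate the threshold excluding detected runs and detect
        again, iterating to a fixed point (off by default: the plain
        single-pass threshold over all aligned days).

    Attributes
    ----------
    threshold_ : float
        The residual standard deviation used as the exceedance threshold.
    residuals_ : pd.Series
        Aligned daily gaps y - fitted.
    events_ : list of EventPeriod
    """

    def __init__(self, min_run: int = 6, gap_tolerance: int = 0, reestimate_sigma: bool = False):
        self.min_run = min_run
        self.gap_tolerance = gap_tolerance
        self.reestimate_sigma = reestimate_sigma

    def fit(self, y: AttentivenessSeries | pd.Series, fitted: pd.Series):
        ys = y.value if isinstance(y, AttentivenessSeries) else y
        aligned = pd.concat({"y": ys, "fit": fitted}, axis=1, join="inner").dropna()
        if len(aligned) < 2:
            raise ValueError(f"only {len(aligned)} aligned days; need at least 2")
        residuals = aligned["y"] - aligned["fit"]

        sigma = float(residuals.std(ddof=1))
        events = self._detect(aligned, residuals, sigma)
        if self.reestimate_sigma:
            for _ in range(20):
                inside = pd.Series(False, index=residuals.index)
                for ev in events:
                    inside.loc[ev.start : ev.end] = True
                new_sigma = float(residuals[~inside].std(ddof=1))
                if not np.isfinite(new_sigma) or np.isclose(new_sigma, sigma):
                    break
                sigma = new_sigma
                events = self._detect(aligned, residuals, sigma)

        self.threshold_ = sigma
        self.residuals_ = residuals
        self.events_ = events
        return self

    def _detect(self, aligned: pd.DataFrame, residuals: pd.Series, sigma: float) -> list[EventPeriod]:
        # strict inequality: a day exactly at sigma ends a run
        mask = (residuals > sigma).to_numpy()
        events = []
        dates = residuals.index
        for s, e in _runs_above(mask, self.gap_tolerance):
            # runs are in day-index units only if days are consecutive; guard
            span_days = (dates[e] - dates[s]).days + 1
            if span_days != e - s + 1:
                raise ValueError("aligned days are not consecutive inside a run")
            if span_days < self.min_run:
                continue
            window = aligned["y"].iloc[s : e + 1]
            peak_date = window.idxmax()
            events.append(
                EventPeriod(
                    start=dates[s],
                    end=dates[e],
                    duration_days=span_days,
                    peak_attentiveness_pct=float(window.max()),
                    peak_date=peak_date,
                )
            )
        return events


def detect_events(
    y: AttentivenessSeries | pd.Series,
    fitted: pd.Series,
    min_run: int = 6,
    gap_tolerance: int = 0,
    reestimate_sigma: bool = False,
) -> list[EventPeriod]:
    """Runs of > 1 residual-sd exceedance lasting at least ``min_run`` days."""
    det = ResidualEventDetector(
        min_run=min_run, gap_tolerance=gap_tolerance, reestimate_sigma=reestimate_sigma
    )
    det.fit(y, fitted)
    return det.events_


def event_table(events: list[EventPeriod], y: AttentivenessSeries | None = None) -> pd.DataFrame:
    """One row per detected event: start, end, peak and duration."""
    rows = [
        {
            "start": ev.start.date().isoformat(),
            "end": ev.end.date().isoformat(),
            "peak_date": ev.peak_date.date().isoformat(),
            "peak_attentiveness_pct": round(ev.peak_attentiveness_pct, 2),
            "duration_days": ev.duration_days,
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=["start", "end", "peak_date", "peak_attentiveness_pct", "duration_days"],
    )
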