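"""Daily attentiveness series and group-vs-whole similarity.

Attentiveness of a population group on a day is the percentage of
vaccine-topic tweets among that group's COVID-topic tweets — a volume-robust
measure of how much of the COVID conversation is about vaccines, denoted
Y(t) for the whole population.  Days are UTC calendar days of the tweet
timestamps.  Days with no COVID tweets are missing, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import TweetRecord, records_to_frame

__all__ = [
    "AttentivenessSeries",
    "CorrelationResult",
    "daily_attentiveness",
    "series_similarity",
    "evans_strength",
]

#: Evans' verbal bands for |r|: upper edges of very weak .. strong
_EVANS_EDGES = (0.20, 0.40, 0.60, 0.80)
_EVANS_LABELS = ("very weak", "weak", "moderate", "strong", "very strong")


def evans_strength(r: float) -> str:
    """Verbal strength label for a Pearson correlation, by absolute value.

    Bands: very weak [0, .20), weak [.20, .40), moderate [.40, .60),
    strong [.60, .80), very strong [.80, 1].
    """
    a = abs(r)
    if not 0.0 <= a <= 1.0 + 1e-12:
        raise ValueError(f"|r| = {a} outside [0, 1]")
    for edge, label in zip(_EVANS_EDGES, _EVANS_LABELS):
        if a < edge:
            return label
    return _EVANS_LABELS[-1]


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its Evans strength band."""

    r: float
    p: float
    n: int
    strength: str
    sign: str

    @classmethod
    def from_r(cls, r: float, p: float, n: int) -> "CorrelationResult":
        return cls(
            r=float(r),
            p=float(p),
            n=int(n),
            strength=evans_strength(r),
            sign="negative" if r < 0 else "positive",
        )


@dataclass
class AttentivenessSeries:
    """Daily vaccine-share-of-COVID-tweets series for one population group.

    ``value`` holds the daily percentage 100 * n_vaccine / n_covid (NaN on
    days with no COVID tweets); the count columns are optional for
    model-generated (truth) series.
    """

    value: pd.Series  # indexed by normalized UTC dates, float percent
    n_covid: pd.Series | None = None
    n_vaccine: pd.Series | None = None
    group_label: str = "whole population"

    def __post_init__(self) -> None:
        idx = self.value.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("dates must be strictly increasing without duplicates")
        finite = self.value.dropna()
        if ((finite < 0) | (finite > 100)).any():
            raise ValueError("attentiveness values must lie in [0, 100]")
        if self.n_covid is not None and self.n_vaccine is not None:
            if (self.n_vaccine > self.n_covid).any():
                raise ValueError("n_vaccine exceeds n_covid on some day")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.value.index

    def dropna(self) -> pd.Series:
        return self.value.dropna()

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"date": self.value.index, "attentiveness_pct": self.value.values})
        frame.insert(1, "n_covid", self.n_covid.values if self.n_covid is not None else np.nan)
        frame.insert(
            2, "n_vaccine", self.n_vaccine.values if self.n_vaccine is not None else np.nan
        )
        frame["group"] = self.group_label
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AttentivenessSeries":
        frame = pd.read_csv(path, parse_dates=["date"])
        value = pd.Series(frame["attentiveness_pct"].values, index=pd.DatetimeIndex(frame["date"]))
        n_covid = (
            pd.Series(frame["n_covid"].values, index=value.index)
            if frame["n_covid"].notna().any()
            else None
        )
        n_vaccine = (
            pd.Series(frame["n_vaccine"].values, index=value.index)
            if frame["n_vaccine"].notna().any()
            else None
        )
        group = str(frame["group"].iloc[0]) if len(frame) else "whole population"
        return cls(value=value, n_covid=n_covid, n_vaccine=n_vaccine, group_label=group)


GroupFilter = Callable[[pd.DataFrame], pd.Series] | tuple[str, str] | None


def _apply_filter(frame: pd.DataFrame, group_filter: GroupFilter) -> pd.DataFrame:
    if group_filter is None:
        return frame
    if callable(group_filter):
        mask = group_filter(frame)
    else:
        column, value = group_filter
        mask = frame[column] == value
    return frame[np.asarray(mask, dtype=bool)]


def daily_attentiveness(
    records: Sequence[TweetRecord] | pd.DataFrame,
    group_filter: GroupFilter = None,
    date_range: tuple | None = None,
    group_label: str | None = None,
) -> AttentivenessSeries:
    """Daily attentiveness of the records passing ``group_filter``.

    Parameters
    ----------
    records
        COVID-topic tweet records (``is_covid`` true), as objects or a frame.
    group_filter
        ``None`` for the whole population, a ``(column, value)`` pair, or a
        callable mapping the record frame to a boolean mask.
    date_range
        Optional (start, end) pair of dates bounding the series (inclusive);
        defaults to the observed span.
    """
    frame = records_to_frame(records)
    frame = _apply_filter(frame, group_filter)
    if "is_covid" in frame:
        frame = frame[frame["is_covid"].fillna(False).astype(bool)]
    if frame.empty:
        raise ValueError("no COVID records after filtering; series would be all-missing")

    days = pd.to_datetime(frame["created_at"], utc=True).dt.tz_localize(None).dt.normalize()
    vaccine = frame["is_vaccine"].fillna(False).astype(bool).values

    if date_range is not None:
        start, end = (pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1]))
    else:
        start, end = days.min(), days.max()
    index = pd.date_range(start, end, freq="D")
    if len(index) == 0:
        raise ValueError("empty date range")

    n_covid = days.value_counts().reindex(index, fill_value=0).astype(int)
    n_vaccine = (
        days[vaccine].value_counts().reindex(index, fill_value=0).astype(int)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        value = 100.0 * n_vaccine / n_covid.replace(0, np.nan)
    if value.isna().all():
        raise ValueError("all days missing (no COVID tweets on any day)")

    if group_label is None:
        if group_filter is None:
            group_label = "whole population"
        elif isinstance(group_filter, tuple):
            group_label = f"{group_filter[0]}={group_filter[1]}"
        else:
            group_label = getattr(group_filter, "__name__", "custom group")
    return AttentivenessSeries(
        value=value, n_covid=n_covid, n_vaccine=n_vaccine, group_label=group_label
    )


def series_similarity(
    group: AttentivenessSeries | pd.Series, whole: AttentivenessSeries | pd.Series
) -> CorrelationResult:
    """Pearson similarity between a group series and the whole-population series.

    Computed over the day-aligned intersection of non-missing days; missing
    days are dropped pairwise, never imputed.  Raises on constant input, for
    which the correlation is undefined.
    """
    g = group.value if isinstance(group, AttentivenessSeries) else group
    w = whole.value if isinstance(whole, AttentivenessSeries) else whole
    aligned = pd.concat({"g": g, "w": w}, axis=1, join="inner").dropna()
    if len(aligned) < 3:
        raise ValueError(f"only {len(aligned)} overlapping days; need at least 3")
    if aligned["g"].nunique() == 1 or aligned["w"].nunique() == 1:
        raise ValueError("correlation undefined: a series is constant on the overlap")
    r, p = stats.pearsonr(aligned["g"], aligned["w"])
    return CorrelationResult.from_r(r, p, len(aligned))
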