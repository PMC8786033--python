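"""Cross-sectional attentiveness odds ratios and attitude quadrants.

The attentiveness odds ratio of a population group contrasts its share of
the vaccine-tweet corpus against its share of a benchmark corpus of general
content tweets, relative to a reference group:

    OR = (a / b) / (c / d)

with a, b the vaccine-tweet counts of group and reference and c, d the
benchmark counts.  95% CIs are Wald intervals on the log scale,
exp(ln OR +- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)); when any cell is zero the
Haldane-Anscombe +0.5 correction is applied to all four cells and flagged.

Crossing the attentiveness dimension (OR above/below 1) with the sentiment
dimension (group mean polarity above/below the cross-group median) assigns
each group one of four attitude categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import TweetRecord, records_to_frame, _characteristic_values

__all__ = [
    "GroupOddsRatio",
    "AttitudeQuadrant",
    "attentiveness_or",
    "event_window_counts",
    "classify_quadrants",
    "or_table",
]


@dataclass(frozen=True)
class GroupOddsRatio:
    """A 2x2-derived attentiveness OR of one group against its reference."""

    characteristic: str
    group: str
    reference: str
    a: float  # vaccine-tweet count, group
    b: float  # vaccine-tweet count, reference
    c: float  # benchmark count, group
    d: float  # benchmark count, reference
    or_value: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    haldane_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI does not bracket the OR")


def _wald_or(a: float, b: float, c: float, d: float, alpha: float) -> tuple[float, float, float, bool]:
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_value = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = np.log(or_value)
    return (
        float(or_value),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
        corrected,
    )


def attentiveness_or(
    vaccine_counts: Mapping[str, int],
    benchmark_counts: Mapping[str, int],
    reference: str,
    characteristic: str = "",
    alpha: float = 0.05,
) -> list[GroupOddsRatio]:
    """Attentiveness OR with Wald CI for every non-reference group.

    Both count mappings must cover the same groups and include the
    reference.  Only count ratios matter: rescaling the benchmark leaves the
    ORs unchanged.
    """
    if reference not in vaccine_counts or reference not in benchmark_counts:
        raise ValueError(f"reference group {reference!r} missing from the counts")
    missing = set(vaccine_counts) ^ set(benchmark_counts)
    if missing:
        raise ValueError(f"groups missing from one of the tables: {sorted(missing)}")

    b = float(vaccine_counts[reference])
    d = float(benchmark_counts[reference])
    out = []
    for group in vaccine_counts:
        if group == reference:
            continue
        a = float(vaccine_counts[group])
        c = float(benchmark_counts[group])
        or_value, lo, hi, corrected = _wald_or(a, b, c, d, alpha)
        out.append(
            GroupOddsRatio(
                characteristic=characteristic,
                group=group,
                reference=reference,
                a=a,
                b=b,
                c=c,
                d=d,
                or_value=or_value,
                ci_low=lo,
                ci_high=hi,
                alpha=alpha,
                haldane_corrected=corrected,
            )
        )
    return out


def event_window_counts(
    records: Sequence[TweetRecord] | pd.DataFrame,
    event_date,
    window_days: int,
    characteristic: str,
    vaccine_only: bool = True,
) -> dict[str, int]:
    """Per-group tweet counts inside [event_date, event_date + window_days - 1].

    By default only vaccine-flagged records are counted (the numerator side
    of a cross-sectional OR); with ``vaccine_only=False`` all records in the
    window are counted, as for a benchmark corpus.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    frame = records_to_frame(records)
    start = pd.Timestamp(event_date)
    end = start + pd.Timedelta(days=window_days - 1)
    days = pd.to_datetime(frame["created_at"], utc=True).dt.tz_localize(None).dt.normalize()
    mask = (days >= start) & (days <= end)
    if vaccine_only:
        mask &= frame["is_vaccine"].fillna(False).astype(bool)
    window = frame[np.asarray(mask, dtype=bool)]
    if window.empty:
        raise ValueError(f"no records in window {start.date()}..{end.date()}")
    values = _characteristic_values(window, characteristic).dropna()
    return {str(g): int(n) for g, n in values.value_counts().items()}


@dataclass(frozen=True)
class AttitudeQuadrant:
    """A group's cell in the 2x2 attentiveness x sentiment grid.

    Categories: 1 = (low attentiveness, low sentiment), 2 = (high, low),
    3 = (high, high), 4 = (low, high).
    """

    group: str
    attentiveness_level: str
    sentiment_level: str
    category: int


_CATEGORY = {
    ("low", "low"): 1,
    ("high", "low"): 2,
    ("high", "high"): 3,
    ("low", "high"): 4,
}


def classify_quadrants(
    ors: Sequence[GroupOddsRatio],
    sentiments: Mapping[str, float],
) -> list[AttitudeQuadrant]:
    """Cross the attentiveness-ratio and sentiment dimensions of attitude.

    Attentiveness is high iff the group's OR exceeds 1 (strict); the
    reference group, whose OR is 1 by construction, is low by convention.
    Sentiment is high iff the group's mean polarity strictly exceeds the
    median of all classified groups' means.  Groups without a sentiment
    value are skipped.
    """
    levels: dict[str, str] = {}
    for orr in ors:
        levels[orr.group] = "high" if orr.or_value > 1.0 else "low"
        levels.setdefault(orr.reference, "low")

    groups = [g for g in levels if g in sentiments]
    if not groups:
        raise ValueError("no group has both an OR level and a sentiment value")
    median = float(np.median([sentiments[g] for g in groups]))
    out = []
    for g in groups:
        sent_level = "high" if sentiments[g] > median else "low"
        out.append(
            AttitudeQuadrant(
                group=g,
                attentiveness_level=levels[g],
                sentiment_level=sent_level,
                category=_CATEGORY[(levels[g], sent_level)],
            )
        )
    return out


def or_table(ors: Sequence[GroupOddsRatio]) -> pd.DataFrame:
    """Tabular view of a list of group odds ratios."""
    return pd.DataFrame(
        [
            {
                "characteristic": o.characteristic,
                "group": o.group,
                "reference": o.reference,
                "or": round(o.or_value, 4),
                "ci_low": round(o.ci_low, 4),
                "ci_high": round(o.ci_high, 4),
                "haldane_corrected": o.haldane_corrected,
            }
            for o in ors
        ],
        columns=[
            "characteristic",
            "group",
            "reference",
            "or",
            "ci_low",
            "ci_high",
            "haldane_corrected",
        ],
    )
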