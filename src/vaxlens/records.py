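"""Tweet-record data model, I/O, topic-filtering cascade, and per-record binning.

A :class:`TweetRecord` is one observed tweet together with its user metadata
and inferred attributes (user type, gender, age band, occupation, location,
sentiment polarity, emotion).  Everything downstream — daily attentiveness
series, demographic tables, odds ratios — is counting over these records.

The module also carries the deterministic mappings applied per record:

* the keyword filtering cascade (English -> COVID topic -> vaccine topic),
* the 9-class UK SOC occupation collapse into three categories OC1-OC3,
* trichotomization of VADER-style compound sentiment scores,
* account-age and follower-count banding,
* demographic summary tables with chi-square comparison between two corpora.
"""

from __future__ import annotations

import csv
import json

import yaml
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TweetRecord",
    "KeywordPattern",
    "DemographicTable",
    "CascadeResult",
    "ParseIssue",
    "read_records",
    "write_jsonl",
    "write_csv",
    "records_to_frame",
    "frame_to_records",
    "filter_cascade",
    "cascade_from_counts",
    "map_occupation",
    "bin_sentiment",
    "bin_account_age",
    "bin_followers",
    "summarize_demographics",
    "chi_square_compare",
    "round_percent",
]

USER_TYPES = ("individual", "organization")
GENDERS = ("male", "female")
AGE_BANDS = ("<=18", "19-29", "30-39", ">=40")
OCCUPATION_SOC = tuple(f"C{i}" for i in range(1, 10))
OCCUPATION_CATS = ("OC1", "OC2", "OC3")
CONTINENTS = (
    "North America",
    "Europe",
    "Asia",
    "Africa",
    "Oceania",
    "South America",
    "Antarctica",
)
ACCOUNT_AGE_BANDS = ("<5", "5-10", ">=10")
FOLLOWER_BANDS = ("<500", "500-5000", ">=5000")
SENTIMENT_CLASSES = ("negative", "neutral", "positive")
EMOTIONS = ("anger", "disgust", "fear", "joy", "sadness", "surprise")

# UK SOC major group -> 3-class occupation category.
# C2 (professional) stands alone; C1 (managers/directors/senior officials) and
# C3 (associate professional & technical) form the second class; C4-C9 the third.
_SOC_TO_CAT = {
    "C1": "OC2",
    "C2": "OC1",
    "C3": "OC2",
    "C4": "OC3",
    "C5": "OC3",
    "C6": "OC3",
    "C7": "OC3",
    "C8": "OC3",
    "C9": "OC3",
}

# minimal topic keyword lists for tests and demos; real analyses supply
# their own much larger curated lists via YAML
DEFAULT_COVID_TERMS = frozenset(
    ["covid", "covid19", "covid-19", "coronavirus", "sars-cov-2", "pandemic",
     "#covid19", "#coronavirus", "lockdown", "quarantine"]
)
DEFAULT_VACCINE_TERMS = frozenset(
    ["vaccine", "vaccines", "vaccination", "vaccinated", "vax", "jab",
     "pfizer", "moderna", "astrazeneca", "#covidvaccine", "booster"]
)

#: the characteristics a DemographicTable can summarize
CHARACTERISTICS = (
    "user_type",
    "gender",
    "age_band",
    "occupation_cat",
    "continent",
    "country",
    "account_age_band",
    "follower_band",
    "sentiment",
    "emotion",
)


@dataclass
class TweetRecord:
    """One tweet with user metadata and inferred attributes.

    Optional attributes are ``None`` when not available (e.g. gender and age
    band are absent for organization accounts).
    """

    tweet_id: str
    created_at: datetime
    lang: str = "en"
    text: str | None = None
    user_type: str | None = None
    gender: str | None = None
    age_band: str | None = None
    occupation_soc: str | None = None
    occupation_cat: str | None = None
    continent: str | None = None
    country: str | None = None
    user_created_at: datetime | None = None
    follower_count: int | None = None
    sentiment_polarity: float | None = None
    emotion: str | None = None
    is_covid: bool | None = None
    is_vaccine: bool | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if not self.tweet_id:
            problems.append("missing mandatory field tweet_id")
        if self.created_at is None:
            problems.append("missing mandatory field created_at")
        if self.sentiment_polarity is not None and not (
            -1.0 <= self.sentiment_polarity <= 1.0
        ):
            problems.append(
                f"sentiment_polarity {self.sentiment_polarity} outside [-1, 1]"
            )
        if (
            self.user_created_at is not None
            and self.created_at is not None
            and self.user_created_at > self.created_at
        ):
            problems.append("user_created_at later than created_at")
        if self.follower_count is not None and self.follower_count < 0:
            problems.append(f"follower_count {self.follower_count} negative")
        if self.is_vaccine and not self.is_covid:
            problems.append("is_vaccine set without is_covid")
        for attr, allowed in (
            ("user_type", USER_TYPES),
            ("gender", GENDERS),
            ("age_band", AGE_BANDS),
            ("occupation_soc", OCCUPATION_SOC),
            ("occupation_cat", OCCUPATION_CATS),
            ("continent", CONTINENTS),
            ("emotion", EMOTIONS),
        ):
            value = getattr(self, attr)
            if value is not None and value not in allowed:
                problems.append(f"{attr} {value!r} not one of {allowed}")
        return problems


@dataclass(frozen=True)
class KeywordPattern:
    """A case-insensitive keyword/hashtag pattern for topic filtering.

    ``match_mode='token'`` matches whole word tokens and hashtags;
    ``'substring'`` matches anywhere in the lowercased text.
    """

    terms: frozenset[str]
    match_mode: str = "token"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("KeywordPattern needs at least one term")
        if self.match_mode not in ("token", "substring"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if any(t != t.lower() for t in self.terms):
            raise ValueError("pattern terms must be lowercase")

    @classmethod
    def from_terms(cls, terms: Iterable[str], match_mode: str = "token") -> "KeywordPattern":
        return cls(frozenset(t.lower() for t in terms), match_mode)

    @classmethod
    def from_yaml(cls, path, key: str) -> "KeywordPattern":
        """Load a named keyword list from a YAML file.

        The file maps pattern names to either a list of terms or a mapping
        with ``terms`` and optional ``match_mode``.
        """
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if key not in payload:
            raise KeyError(f"no keyword list named {key!r} in {path}")
        entry = payload[key]
        if isinstance(entry, dict):
            return cls.from_terms(entry["terms"], entry.get("match_mode", "token"))
        return cls.from_terms(entry)

    def matches(self, text: str) -> bool:
        low = text.lower()
        if self.match_mode == "substring":
            return any(t in low for t in self.terms)
        tokens = set(_tokenize(low))
        return any(t in tokens for t in self.terms)


def _tokenize(low_text: str) -> Iterable[str]:
    # word tokens; a hashtag token is kept both with and without '#'
    token = []
    for ch in low_text + " ":
        if ch.isalnum() or ch in "#_'-":
            token.append(ch)
        else:
            if token:
                word = "".join(token)
                yield word
                if word.startswith("#"):
                    yield word[1:]
                token = []


@dataclass(frozen=True)
class ParseIssue:
    """Line-level diagnostic emitted by :func:`read_records`."""

    line: int
    message: str


_TIMESTAMP_FIELDS = ("created_at", "user_created_at")
_BOOL_FIELDS = ("is_covid", "is_vaccine")


def _parse_timestamp(value) -> datetime:
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert("UTC").to_pydatetime()


def _coerce_row(row: Mapping) -> TweetRecord:
    kwargs: dict = {}
    for f in TweetRecord.__dataclass_fields__:
        value = row.get(f)
        if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
            continue
        if f in _TIMESTAMP_FIELDS:
            value = _parse_timestamp(value)
        elif f in _BOOL_FIELDS:
            if isinstance(value, str):
                value = value.strip().lower() in ("true", "1", "yes")
            else:
                value = bool(value)
        elif f == "follower_count":
            value = int(value)
        elif f == "sentiment_polarity":
            value = float(value)
        kwargs[f] = value
    if "tweet_id" in kwargs:
        kwargs["tweet_id"] = str(kwargs["tweet_id"])
    return TweetRecord(**kwargs)


def read_records(
    path, format: str | None = None
) -> tuple[list[TweetRecord], list[ParseIssue]]:
    """Read tweet records from JSONL or CSV.

    Malformed rows are rejected with a line-numbered :class:`ParseIssue`
    instead of aborting the whole read; timestamps are normalized to UTC.

    Returns
    -------
    (records, issues)
        Parsed records and the diagnostics for rejected rows.
    """
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")

    rows: list[tuple[int, Mapping]] = []
    issues: list[ParseIssue] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append((lineno, json.loads(line)))
                except json.JSONDecodeError as exc:
                    issues.append(ParseIssue(lineno, f"invalid JSON: {exc}"))
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            # +1 for the header line
            for lineno, row in enumerate(reader, start=2):
                rows.append((lineno, row))

    records: list[TweetRecord] = []
    for lineno, row in rows:
        try:
            rec = _coerce_row(row)
        except (ValueError, TypeError, OverflowError) as exc:
            issues.append(ParseIssue(lineno, f"unparseable record: {exc}"))
            continue
        problems = rec.validate()
        if problems:
            issues.append(ParseIssue(lineno, "; ".join(problems)))
            continue
        records.append(rec)
    return records, issues


def _record_to_jsonable(rec: TweetRecord) -> dict:
    out = {}
    for key, value in asdict(rec).items():
        if value is None:
            continue
        if isinstance(value, datetime):
            value = value.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
        out[key] = value
    return out


def write_jsonl(records: Iterable[TweetRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_jsonable(rec), sort_keys=True))
            fh.write("\n")


def write_csv(records: Iterable[TweetRecord], path) -> None:
    fields = list(TweetRecord.__dataclass_fields__)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in records:
            row = _record_to_jsonable(rec)
            writer.writerow({f: row.get(f, "") for f in fields})


def records_to_frame(records: Sequence[TweetRecord] | pd.DataFrame) -> pd.DataFrame:
    """Tabular view of a record sequence (no-op if already a DataFrame)."""
    if isinstance(records, pd.DataFrame):
        return records
    frame = pd.DataFrame([asdict(r) for r in records])
    for col in _TIMESTAMP_FIELDS:
        if col in frame:
            frame[col] = pd.to_datetime(frame[col], utc=True)
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[TweetRecord]:
    return [_coerce_row(row) for row in frame.to_dict("records")]


# ---------------------------------------------------------------------------
# filtering cascade
# ---------------------------------------------------------------------------


@dataclass
class CascadeResult:
    """Stage counts and retained records of the topic filtering cascade."""

    n_input: int
    n_english: int
    n_covid: int
    n_vaccine: int
    retained: list[TweetRecord]
    issues: list[ParseIssue] = field(default_factory=list)

    @property
    def stage_counts(self) -> tuple[int, int, int, int]:
        return (self.n_input, self.n_english, self.n_covid, self.n_vaccine)


def filter_cascade(
    records: Sequence[TweetRecord],
    covid_pattern: KeywordPattern,
    vaccine_pattern: KeywordPattern,
) -> CascadeResult:
    """Apply the English -> COVID -> vaccine topic cascade.

    A record's precomputed ``is_covid``/``is_vaccine`` flags take precedence;
    otherwise its ``text`` is matched against the keyword patterns.  Records
    carrying neither flags nor text are rejected with a diagnostic and do not
    advance past the English stage.
    """
    n_english = 0
    n_covid = 0
    retained: list[TweetRecord] = []
    issues: list[ParseIssue] = []
    for idx, rec in enumerate(records):
        if rec.lang != "en":
            continue
        n_english += 1
        if rec.is_covid is None and rec.text is None:
            issues.append(
                ParseIssue(idx, f"record {rec.tweet_id}: no text and no topic flags")
            )
            continue
        covid = rec.is_covid if rec.is_covid is not None else covid_pattern.matches(rec.text)
        if not covid:
            continue
        n_covid += 1
        vaccine = (
            rec.is_vaccine
            if rec.is_vaccine is not None
            else vaccine_pattern.matches(rec.text)
        )
        if vaccine:
            retained.append(rec)
    result = CascadeResult(
        n_input=len(records),
        n_english=n_english,
        n_covid=n_covid,
        n_vaccine=len(retained),
        retained=retained,
        issues=issues,
    )
    return result


def cascade_from_counts(
    n_english: int, n_non_covid_excluded: int, n_non_vaccine_excluded: int
) -> dict[str, int]:
    """Cascade arithmetic from aggregate stage counts.

    Given the English-tweet count and the counts excluded at the COVID and
    vaccine stages, return every stage total.  Stage counts must be monotone
    non-increasing.
    """
    n_covid = n_english - n_non_covid_excluded
    n_vaccine = n_covid - n_non_vaccine_excluded
    if not (n_english >= n_covid >= n_vaccine >= 0):
        raise ValueError(
            f"inconsistent cascade counts: english={n_english}, "
            f"covid={n_covid}, vaccine={n_vaccine}"
        )
    return {"english": n_english, "covid": n_covid, "vaccine": n_vaccine}


# ---------------------------------------------------------------------------
# per-record mappings and binnings
# ---------------------------------------------------------------------------


def map_occupation(soc: str) -> str:
    """Collapse a UK SOC major group C1..C9 into OC1/OC2/OC3."""
    try:
        return _SOC_TO_CAT[soc]
    except KeyError:
        raise ValueError(f"unknown SOC code {soc!r}; expected C1..C9") from None


def bin_sentiment(polarity: float) -> str:
    """Trichotomize a compound sentiment score in [-1, 1].

    Negative for scores <= -0.05, positive for scores >= 0.05, neutral for
    the open interval in between (the standard VADER convention).
    """
    if not -1.0 <= polarity <= 1.0:
        raise ValueError(f"sentiment polarity {polarity} outside [-1, 1]")
    if polarity <= -0.05:
        return "negative"
    if polarity >= 0.05:
        return "positive"
    return "neutral"


def account_age_years(user_created_at: datetime, created_at: datetime) -> float:
    """Account age in 365.25-day years at posting time."""
    delta_days = (created_at - user_created_at).total_seconds() / 86400.0
    if delta_days < 0:
        raise ValueError("user_created_at is later than created_at")
    return delta_days / 365.25


def bin_account_age(user_created_at: datetime, created_at: datetime) -> str:
    """Band the account age into <5, 5-10, >=10 years (half-open intervals)."""
    years = account_age_years(user_created_at, created_at)
    if years < 5:
        return "<5"
    if years < 10:
        return "5-10"
    return ">=10"


def bin_followers(n: int) -> str:
    """Band a follower count into <500, 500-5000, >=5000 (half-open)."""
    if n < 0:
        raise ValueError(f"follower count {n} negative")
    if n < 500:
        return "<500"
    if n < 5000:
        return "500-5000"
    return ">=5000"


def _characteristic_values(frame: pd.DataFrame, characteristic: str) -> pd.Series:
    """Per-record group label for a characteristic; NaN when not applicable."""
    if characteristic in ("user_type", "gender", "age_band", "continent", "country", "emotion"):
        return frame[characteristic]
    if characteristic == "occupation_cat":
        if "occupation_cat" in frame and frame["occupation_cat"].notna().any():
            return frame["occupation_cat"]
        return frame["occupation_soc"].map(lambda s: map_occupation(s) if pd.notna(s) else None)
    if characteristic == "account_age_band":
        mask = frame["user_created_at"].notna() & frame["created_at"].notna()
        out = pd.Series(index=frame.index, dtype=object)
        out[mask] = [
            bin_account_age(u, c)
            for u, c in zip(frame.loc[mask, "user_created_at"], frame.loc[mask, "created_at"])
        ]
        return out
    if characteristic == "follower_band":
        return frame["follower_count"].map(
            lambda n: bin_followers(int(n)) if pd.notna(n) else None
        )
    if characteristic == "sentiment":
        return frame["sentiment_polarity"].map(
            lambda p: bin_sentiment(float(p)) if pd.notna(p) else None
        )
    raise ValueError(
        f"unknown characteristic {characteristic!r}; expected one of {CHARACTERISTICS}"
    )


_GROUP_ORDER = {
    "user_type": list(USER_TYPES),
    "gender": list(GENDERS),
    "age_band": list(AGE_BANDS),
    "occupation_cat": list(OCCUPATION_CATS),
    "continent": list(CONTINENTS),
    "account_age_band": list(ACCOUNT_AGE_BANDS),
    "follower_band": list(FOLLOWER_BANDS),
    "sentiment": list(SENTIMENT_CLASSES),
    "emotion": list(EMOTIONS),
}


def round_percent(count: int, denominator: int) -> float:
    """Percentage rounded half-up to two decimals."""
    if denominator <= 0:
        raise ValueError("empty denominator")
    pct = Decimal(count) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class DemographicTable:
    """Counts and percentages of one characteristic over a record corpus."""

    characteristic: str
    rows: list[tuple[str, int, float]]
    column_total: int
    denominator_note: str = ""

    @classmethod
    def from_counts(
        cls,
        characteristic: str,
        counts: Mapping[str, int],
        denominator_note: str = "records with this attribute present",
    ) -> "DemographicTable":
        total = int(sum(counts.values()))
        rows = [(g, int(n), round_percent(int(n), total)) for g, n in counts.items()]
        return cls(characteristic, rows, total, denominator_note)

    @property
    def counts(self) -> dict[str, int]:
        return {g: n for g, n, _ in self.rows}

    @property
    def percents(self) -> dict[str, float]:
        return {g: p for g, _, p in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["group", "count", "percent"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def summarize_demographics(
    records: Sequence[TweetRecord] | pd.DataFrame, characteristic: str
) -> DemographicTable:
    """Tabulate one characteristic over a corpus.

    The denominator is the number of records for which the characteristic is
    defined (e.g. gender and age exclude organizations; location counts only
    located records), so percentages are comparable across corpora with
    different coverage.
    """
    frame = records_to_frame(records)
    values = _characteristic_values(frame, characteristic).dropna()
    if values.empty:
        raise ValueError(f"no records carry characteristic {characteristic!r}")
    counts = values.value_counts()
    order = _GROUP_ORDER.get(characteristic)
    if order is not None:
        labels = [g for g in order if g in counts.index]
        labels += [g for g in counts.index if g not in labels]
    else:  # open-ended label sets (country): sort by frequency
        labels = list(counts.index)
    return DemographicTable.from_counts(
        characteristic,
        {g: int(counts[g]) for g in labels},
        denominator_note=f"records with non-missing {characteristic}",
    )


def chi_square_compare(
    table_a: DemographicTable, table_b: DemographicTable
) -> tuple[float, int, float]:
    """Pearson chi-square comparing group composition of two corpora.

    The k groups of the two tables form a k x 2 count matrix; returns
    (statistic, df, p) with df = k - 1 and no continuity correction.
    """
    if set(table_a.counts) != set(table_b.counts):
        raise ValueError(
            f"group labels differ: {sorted(table_a.counts)} vs {sorted(table_b.counts)}"
        )
    labels = [g for g, _, _ in table_a.rows]
    matrix = np.array(
        [[table_a.counts[g], table_b.counts[g]] for g in labels], dtype=float
    )
    if (matrix.sum(axis=1) == 0).any():
        raise ValueError("a group has zero count in both tables")
    statistic, p, df, expected = stats.chi2_contingency(matrix, correction=False)
    if (expected <= 0).any():
        raise ValueError("zero expected count in chi-square table")
    return float(statistic), int(df), float(p)
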