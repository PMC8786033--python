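"""Synthetic tweet-stream and epidemic-statistics generator with known truth.

Real vaccine-attitude tweet corpora cannot be redistributed, so every
downstream stage is exercised against a generator whose ground truth is
known exactly:

* an epidemic-statistics panel shaped like the daily global surveillance
  export (wave-structured cases with weekend reporting dips, lagged deaths
  with a declining case-fatality ratio, a late vaccination ramp, cumulative
  totals, a reproduction-rate series wandering around 1);
* an attentiveness series Y(t) generated by the lag-shifted linear model
  Y(t) = b0 + sum_i b_i Z_i(t - L_i) + eps with rectangular multi-day event
  bumps injected on top;
* a stream of COVID tweet records whose per-record vaccine propensity is
  calibrated day by day (logit offsets per group, base logit solved by
  bisection) so that the population share matches Y(t) and the
  group-vs-reference odds ratios match configured values, with
  group-composition and sentiment structure resembling a large vaccine-tweet
  corpus.

One integer seed drives everything through independent substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attentiveness import AttentivenessSeries
from .lagreg import STAT_VARIABLES, CovidStatsPanel

__all__ = [
    "SimulationConfig",
    "simulate_covid_stats",
    "simulate_attentiveness",
    "simulate_tweets",
    "simulate_benchmark",
    "raw_scale_coefficients",
    "simulation_truth",
    "write_tweets_jsonl",
]

# Default group composition, loosely following the published year-long
# vaccine-tweet corpus: ~90% individuals, male-skewed, oldest age band
# largest, fear the dominant emotion.
_DEFAULT_MIX: dict[str, dict[str, float]] = {
    "user_type": {"individual": 0.9009, "organization": 0.0991},
    "gender": {"male": 0.6130, "female": 0.3870},
    "age_band": {"<=18": 0.1459, "19-29": 0.2362, "30-39": 0.1876, ">=40": 0.4303},
    "occupation_cat": {"OC1": 0.3570, "OC2": 0.3218, "OC3": 0.3212},
    "continent": {
        "North America": 0.4012,
        "Europe": 0.2626,
        "Asia": 0.1560,
        "Africa": 0.0991,
        "Oceania": 0.0576,
        "South America": 0.0231,
        "Antarctica": 0.0004,
    },
    "account_age_band": {"<5": 0.4438, "5-10": 0.3240, ">=10": 0.2322},
    "follower_band": {"<500": 0.5744, "500-5000": 0.3417, ">=5000": 0.0839},
    "emotion": {
        "fear": 0.4899,
        "joy": 0.2904,
        "surprise": 0.1425,
        "sadness": 0.0390,
        "anger": 0.0221,
        "disgust": 0.0161,
    },
}

# Group log-odds multipliers on per-record vaccine propensity.  Groups not
# listed are the per-characteristic reference (OR 1).  Magnitudes follow the
# qualitative ordering reported for vaccine attentiveness: organizations,
# older users, long-lived and high-follower accounts more attentive;
# lower occupation classes and female users less.
_DEFAULT_OR: dict[str, dict[str, float]] = {
    "user_type": {"organization": 1.7},
    "gender": {"female": 0.7},
    "age_band": {"19-29": 2.0, "30-39": 4.3, ">=40": 7.0},
    "occupation_cat": {"OC2": 0.58, "OC3": 0.42},
    "account_age_band": {"5-10": 1.8, ">=10": 2.7},
    "follower_band": {"500-5000": 1.05, ">=5000": 1.45},
}

_DEFAULT_SENTIMENT_OFFSETS: dict[str, dict[str, float]] = {
    "user_type": {"organization": 0.05},
    "occupation_cat": {"OC1": 0.03, "OC3": -0.03},
    "age_band": {"<=18": -0.02, ">=40": -0.02},
    "account_age_band": {"<5": -0.02},
    "follower_band": {"<500": -0.02, ">=5000": 0.04},
}

# (start day, duration days, bump height in attentiveness %).  Timing and
# durations mirror the five pronounced surges of the study period; heights
# are several-fold the daily noise scale, as the real surges are.
_DEFAULT_EVENTS: tuple[tuple[int, int, float], ...] = (
    (35, 14, 3.0),
    (64, 12, 3.5),
    (153, 6, 5.0),
    (189, 21, 8.0),
    (290, 46, 6.0),
)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic world.

    The linear-model coefficients ``true_beta`` (intercept first) act on
    z-scored predictors so they stay O(1) against raw series spanning many
    orders of magnitude; :func:`raw_scale_coefficients` converts them to the
    raw predictor scales for comparison with a fitted model.
    """

    n_days: int = 418
    start: str = "2020-06-09"
    seed: int = 0
    true_lags: tuple[int, ...] = (5, 3, 4, 0, 0, 0, 0, 10)
    true_beta: tuple[float, ...] = (12.5, 1.8, 1.2, 1.2, 1.15, 1.15, 0.6, 0.0, -1.7)
    noise_sd: float = 0.5
    events: tuple[tuple[int, int, float], ...] = _DEFAULT_EVENTS
    tweets_per_day: int = 2000
    group_mix: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MIX.items()})
    group_vaccine_or: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_OR.items()}
    )
    sentiment_base_mean: float = 0.02
    sentiment_drift_total: float = -0.06
    sentiment_sd: float = 0.3
    sentiment_offsets: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SENTIMENT_OFFSETS.items()}
    )
    # epidemic-wave shape: (center as fraction of n_days, width days, peak daily cases)
    case_waves: tuple[tuple[float, float, float], ...] = (
        (0.10, 20.0, 55_000.0),
        (0.38, 22.0, 75_000.0),
        (0.77, 26.0, 65_000.0),
    )
    # endemic floor as a fraction of the mean wave height; the global daily
    # count never approached zero during the study period
    case_floor_frac: float = 0.5
    case_fatality: tuple[float, ...] = (0.035, 0.010, 0.004)
    # deaths waves of regions whose epidemics are offset from the global
    # case curve: (center frac, width days, peak daily deaths)
    regional_death_waves: tuple[tuple[float, float, float], ...] = (
        (0.60, 30.0, 700.0),
        (0.92, 35.0, 1400.0),
    )
    death_delay_days: int = 14
    reporting_jitter_sd: float = 0.15
    vaccination_start_frac: float = 0.45
    vaccination_peak: float = 2.5e7
    # first-dose share profile: decays from 1 toward the floor; tau_frac 0
    # selects a linear decline over the remaining days
    first_dose_floor: float = 0.08
    first_dose_tau_frac: float = 0.07
    # amplitude and period (as a fraction of n_days) of campaign pulsing:
    # new country cohorts starting first-dose campaigns in waves
    first_dose_pulse: float = 0.6
    first_dose_pulse_period_frac: float = 0.12
    # within-week reporting amplitudes for cases, deaths, vaccinations
    weekly_amplitudes: tuple[float, float, float] = (0.45, 0.40, 0.30)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be positive")
        if len(self.true_lags) != len(STAT_VARIABLES):
            raise ValueError(f"true_lags must have length {len(STAT_VARIABLES)}")
        if any(not 0 <= l <= 30 for l in self.true_lags):
            raise ValueError("lags must lie in [0, 30]")
        if len(self.true_beta) != len(STAT_VARIABLES) + 1:
            raise ValueError(f"true_beta must have length {len(STAT_VARIABLES) + 1}")
        if any(d < 1 for _, d, _ in self.events):
            raise ValueError("event durations must be >= 1 day")
        if any(s < 0 or s >= self.n_days for s, _, _ in self.events):
            raise ValueError("event start days must lie within [0, n_days)")
        if self.tweets_per_day <= 0:
            raise ValueError("tweets_per_day must be positive")
        for char, mix in self.group_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"group_mix[{char!r}] sums to {total}, not 1")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_days, freq="D")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream of the single config seed."""
        return np.random.default_rng([self.seed, stream])

    def to_dict(self) -> dict:
        return asdict(self)


# Within-week reporting cycles, one distinct harmonic per reporting system
# (weekend dip, twice-weekly batching, thrice-weekly delivery rhythm).  The
# three centered patterns are mutually orthogonal under every cyclic shift,
# so each statistic carries its own weekly signature and the lag scan cannot
# confuse one variable's delay with another's.
_WEEK_PHASE = (0.5, 1.1, 2.0)


def _weekly(harmonic: int, amplitude: float, t: np.ndarray) -> np.ndarray:
    pattern = 1.0 + amplitude * np.cos(
        2 * np.pi * harmonic * np.arange(7) / 7 - _WEEK_PHASE[harmonic - 1]
    )
    pattern = pattern / pattern.mean()
    return pattern[t % 7]


def simulate_covid_stats(config: SimulationConfig) -> CovidStatsPanel:
    """Generate the daily 8-variable epidemic-statistics panel.

    New cases are a sum of Gaussian epidemic waves with weekly reporting
    structure and Poisson noise; new deaths are a delayed copy with a
    per-wave declining case-fatality ratio; vaccinations ramp up late in the
    period; totals are running sums; the reproduction rate wanders smoothly
    around 1.
    """
    n = config.n_days
    t = np.arange(n)
    rng = config.rng(0)

    base_cases = np.zeros(n)
    base_deaths = np.zeros(n)
    cfrs = list(config.case_fatality) + [0.01] * len(config.case_waves)
    for (center_frac, width, height), cfr in zip(config.case_waves, cfrs):
        center = center_frac * n
        wave = height * np.exp(-0.5 * ((t - center) / width) ** 2)
        base_cases += wave
        delayed = height * cfr * np.exp(
            -0.5 * ((t - center - config.death_delay_days) / width) ** 2
        )
        base_deaths += delayed
    if config.case_waves:
        heights = [h for _, _, h in config.case_waves]
        floor = config.case_floor_frac * float(np.mean(heights))
        base_cases += floor
        # inter-wave endemic cases skew young and mild: far lower fatality
        base_deaths += 0.15 * floor * float(np.mean(cfrs[: len(config.case_waves)]))
        for center_frac, width, height in config.regional_death_waves:
            base_deaths += height * np.exp(-0.5 * ((t - center_frac * n) / width) ** 2)

    sd = config.reporting_jitter_sd
    amp_c, amp_d, amp_v = config.weekly_amplitudes
    jitter_c = rng.lognormal(0.0, sd, size=n)
    jitter_d = rng.lognormal(0.0, sd, size=n)
    new_cases = rng.poisson(base_cases * _weekly(1, amp_c, t) * jitter_c).astype(float)
    new_deaths = rng.poisson(base_deaths * _weekly(2, amp_d, t) * jitter_d).astype(float)

    start_day = config.vaccination_start_frac * n
    ramp = config.vaccination_peak / (1.0 + np.exp(-(t - 0.72 * n) / (0.08 * n)))
    ramp[t < start_day] = 0.0
    jitter_v = rng.lognormal(0.0, sd, size=n)
    new_vaccinations = np.round(ramp * _weekly(3, amp_v, t) * jitter_v)

    # share of doses that are first doses decays quickly as campaigns mature,
    # so people-vaccinated saturates while total doses keep accelerating
    # share of doses that are first doses decays as campaigns mature
    floor = config.first_dose_floor
    delta = np.maximum(t - start_day, 0.0)
    if config.first_dose_tau_frac > 0:
        frac_first = floor + (1.0 - floor) * np.exp(-delta / (config.first_dose_tau_frac * n))
    else:
        frac_first = np.clip(1.0 - (1.0 - floor) * delta / max(n - start_day, 1), floor, 1.0)
    if config.first_dose_pulse > 0:
        pulse = 1.0 + config.first_dose_pulse * np.sin(
            2 * np.pi * delta / (config.first_dose_pulse_period_frac * n)
        )
        frac_first = np.clip(frac_first * pulse, 0.0, 1.0)
    people_vaccinated = np.cumsum(new_vaccinations * frac_first)

    ar = np.zeros(n)
    eps = rng.normal(0.0, 0.01, size=n)
    for i in range(1, n):
        ar[i] = 0.7 * ar[i - 1] + eps[i]
    reproduction_rate = (
        1.0
        + 0.08 * np.sin(2 * np.pi * t / (0.42 * n) + 0.7)
        + 0.18 * np.sin(2 * np.pi * t / (0.13 * n) + 2.1)
        + ar
        + rng.normal(0.0, 0.05, size=n)  # day-to-day estimation jitter
    )
    reproduction_rate = np.clip(reproduction_rate, 0.0, None)

    frame = pd.DataFrame(
        {
            "new_cases": new_cases,
            "new_deaths": new_deaths,
            "new_vaccinations": new_vaccinations,
            "total_cases": np.cumsum(new_cases),
            "total_deaths": np.cumsum(new_deaths),
            "total_vaccinations": np.cumsum(new_vaccinations),
            "people_vaccinated": people_vaccinated,
            "reproduction_rate": reproduction_rate,
        },
        index=config.dates,
    )
    return CovidStatsPanel(frame)


def _zscore_stats(panel: CovidStatsPanel) -> tuple[np.ndarray, np.ndarray]:
    data = panel.data[list(STAT_VARIABLES)].to_numpy(dtype=float)
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("a panel variable is constant; cannot z-score")
    return mu, sd


def simulate_attentiveness(
    panel: CovidStatsPanel,
    config: SimulationConfig,
    include_noise: bool = True,
    include_events: bool = True,
    scale: str = "zscore",
) -> AttentivenessSeries:
    """Generate Y(t) from the lag-shifted linear model plus event bumps.

    ``scale='zscore'`` (default) applies the coefficients to z-scored
    predictors; ``'raw'`` applies them to the raw series directly.  Days on
    which any lagged predictor reaches before the panel start are left
    missing.  The series is clipped to [0, 100]; under the default
    parameters the deterministic part stays comfortably inside, so clipping
    only trims rare noise excursions.
    """
    if scale not in ("zscore", "raw"):
        raise ValueError(f"unknown scale {scale!r}")
    n = config.n_days
    data = panel.data[list(STAT_VARIABLES)].to_numpy(dtype=float)
    if scale == "zscore":
        mu, sd = _zscore_stats(panel)
        design = (data - mu) / sd
    else:
        design = data

    beta = np.asarray(config.true_beta, dtype=float)
    lags = np.asarray(config.true_lags, dtype=int)
    y = np.full(n, beta[0])
    for i, lag in enumerate(lags):
        shifted = np.full(n, np.nan)
        if lag == 0:
            shifted[:] = design[:, i]
        else:
            shifted[lag:] = design[:-lag, i]
        y = y + beta[i + 1] * shifted

    if include_noise and config.noise_sd > 0:
        y = y + config.rng(1).normal(0.0, config.noise_sd, size=n)
    if include_events:
        for start, duration, height in config.events:
            y[start : start + duration] += height
    y = np.clip(y, 0.0, 100.0)
    return AttentivenessSeries(
        value=pd.Series(y, index=config.dates),
        group_label="whole population (simulated)",
    )


def raw_scale_coefficients(panel: CovidStatsPanel, config: SimulationConfig) -> np.ndarray:
    """True coefficients on the raw predictor scales (intercept first)."""
    beta = np.asarray(config.true_beta, dtype=float)
    mu, sd = _zscore_stats(panel)
    raw = np.empty_like(beta)
    raw[1:] = beta[1:] / sd
    raw[0] = beta[0] - float(np.sum(beta[1:] * mu / sd))
    return raw


def simulation_truth(config: SimulationConfig, panel: CovidStatsPanel | None = None) -> dict:
    """Machine-readable ground truth for recovery reports."""
    dates = config.dates
    truth = {
        "lags": {v: int(l) for v, l in zip(STAT_VARIABLES, config.true_lags)},
        "beta_zscore": list(config.true_beta),
        "noise_sd": config.noise_sd,
        "events": [
            {
                "start": dates[s].date().isoformat(),
                "end": dates[min(s + d - 1, config.n_days - 1)].date().isoformat(),
                "duration_days": int(d),
                "height_pct": float(h),
            }
            for s, d, h in config.events
        ],
        "group_vaccine_or": {k: dict(v) for k, v in config.group_vaccine_or.items()},
        "seed": config.seed,
    }
    if panel is not None:
        truth["beta_raw"] = [float(b) for b in raw_scale_coefficients(panel, config)]
    return truth


# ---------------------------------------------------------------------------
# tweet stream
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _calibrate_base_logit(offsets_2d: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-day base logit b solving mean(sigmoid(b + offsets)) = target."""
    lo = np.full(len(targets), -35.0)
    hi = np.full(len(targets), 35.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        mean_p = _sigmoid(mid[:, None] + offsets_2d).mean(axis=1)
        too_high = mean_p > targets
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    return 0.5 * (lo + hi)


def _sample_groups(
    rng: np.random.Generator, config: SimulationConfig, n: int
) -> dict[str, np.ndarray]:
    """Sample group labels per record; gender/age only for individuals."""
    labels: dict[str, np.ndarray] = {}
    for char, mix in config.group_mix.items():
        groups = np.array(list(mix), dtype=object)
        probs = np.array(list(mix.values()), dtype=float)
        probs = probs / probs.sum()
        labels[char] = rng.choice(groups, size=n, p=probs)
    if "user_type" in labels:
        org = labels["user_type"] == "organization"
        for char in ("gender", "age_band"):
            if char in labels:
                labels[char] = labels[char].astype(object)
                labels[char][org] = None
    return labels


def _group_offsets(
    labels: Mapping[str, np.ndarray], table: Mapping[str, Mapping[str, float]], n: int
) -> np.ndarray:
    offsets = np.zeros(n)
    for char, mapping in table.items():
        if char not in labels:
            continue
        for group, value in mapping.items():
            offsets[labels[char] == group] += value
    return offsets


def _assemble_frame(
    rng: np.random.Generator,
    config: SimulationConfig,
    day_index: pd.DatetimeIndex,
    labels: dict[str, np.ndarray],
    is_vaccine: np.ndarray,
    is_covid: bool,
    id_prefix: str,
) -> pd.DataFrame:
    n = len(day_index)
    seconds = rng.integers(0, 86400, size=n)
    created_at = pd.DatetimeIndex(day_index) + pd.to_timedelta(seconds, unit="s")
    created_at = created_at.tz_localize("UTC")

    # account age uniform inside its band: [0,5), [5,10), [10,15) years
    band = labels["account_age_band"]
    age_years = np.empty(n)
    for b, (lo, hi) in {"<5": (0.0, 5.0), "5-10": (5.0, 10.0), ">=10": (10.0, 15.0)}.items():
        mask = band == b
        age_years[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
    user_created_at = created_at - pd.to_timedelta(np.round(age_years * 365.25 * 86400), unit="s")

    fband = labels["follower_band"]
    followers = np.empty(n, dtype=int)
    for b, (lo, hi) in {"<500": (0, 500), "500-5000": (500, 5000), ">=5000": (5000, 100000)}.items():
        mask = fband == b
        followers[mask] = rng.integers(lo, hi, size=int(mask.sum()))

    day_frac = (day_index - pd.Timestamp(config.start)).days / max(config.n_days - 1, 1)
    sent_mean = (
        config.sentiment_base_mean
        + config.sentiment_drift_total * day_frac
        + _group_offsets(labels, config.sentiment_offsets, n)
    )
    polarity = np.clip(rng.normal(sent_mean, config.sentiment_sd), -1.0, 1.0)

    frame = pd.DataFrame(
        {
            "tweet_id": [f"{id_prefix}{i:07d}" for i in range(n)],
            "created_at": created_at,
            "lang": "en",
            "text": None,
            "user_type": labels["user_type"],
            "gender": labels.get("gender"),
            "age_band": labels.get("age_band"),
            "occupation_soc": None,
            "occupation_cat": labels.get("occupation_cat"),
            "continent": labels.get("continent"),
            "country": None,
            "user_created_at": user_created_at,
            "follower_count": followers,
            "sentiment_polarity": polarity,
            "emotion": labels.get("emotion"),
            "is_covid": is_covid,
            "is_vaccine": is_vaccine,
        }
    )
    return frame


def simulate_tweets(y: AttentivenessSeries, config: SimulationConfig) -> pd.DataFrame:
    """Emit ``tweets_per_day`` COVID records per available day of Y(t).

    Each record's vaccine flag is Bernoulli with probability
    sigmoid(b(t) + sum of its groups' log-OR offsets); the base logit b(t)
    is solved by bisection so the expected population share equals y(t).
    Returns a DataFrame with one row per record (convert with
    ``records.frame_to_records`` when objects are needed).
    """
    values = y.dropna()
    if values.empty:
        raise ValueError("attentiveness series has no available days")
    bad = values[(values <= 0) | (values >= 100)]
    if not bad.empty:
        day = bad.index[0].date()
        raise ValueError(
            f"infeasible attentiveness {bad.iloc[0]:.4g}% on {day}: "
            "per-record probability must lie strictly inside (0, 1)"
        )
    rng = config.rng(2)
    m = len(values)
    tpd = config.tweets_per_day
    n = m * tpd

    labels = _sample_groups(rng, config, n)
    log_or = {
        char: {g: math.log(v) for g, v in mapping.items()}
        for char, mapping in config.group_vaccine_or.items()
    }
    offsets = _group_offsets(labels, log_or, n)
    base = _calibrate_base_logit(offsets.reshape(m, tpd), values.to_numpy() / 100.0)
    p = _sigmoid(np.repeat(base, tpd) + offsets)
    is_vaccine = rng.random(n) < p

    day_index = pd.DatetimeIndex(np.repeat(values.index.to_numpy(), tpd))
    return _assemble_frame(rng, config, day_index, labels, is_vaccine, True, "sim")


def simulate_benchmark(
    config: SimulationConfig, n_records: int, seed_stream: int = 3
) -> pd.DataFrame:
    """A general-content benchmark stream: group mix only, no vaccine topic."""
    rng = config.rng(seed_stream)
    labels = _sample_groups(rng, config, n_records)
    days = config.dates[rng.integers(0, config.n_days, size=n_records)]
    return _assemble_frame(
        rng,
        config,
        pd.DatetimeIndex(days),
        labels,
        np.zeros(n_records, dtype=bool),
        False,
        "bench",
    )


def write_tweets_jsonl(frame: pd.DataFrame, path) -> None:
    """Deterministic JSONL export of a simulated tweet frame."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for row in frame.to_dict("records"):
            out = {}
            for key, value in row.items():
                if value is None or (isinstance(value, float) and np.isnan(value)):
                    continue
                if isinstance(value, pd.Timestamp):
                    value = value.strftime("%Y-%m-%dT%H:%M:%SZ")
                elif isinstance(value, (np.bool_,)):
                    value = bool(value)
                elif isinstance(value, np.integer):
                    value = int(value)
                elif isinstance(value, np.floating):
                    value = float(value)
                out[key] = value
            fh.write(json.dumps(out, sort_keys=True))
            fh.write("\n")
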