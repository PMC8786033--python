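"""Lag-optimized correlation and lag-shifted multiple linear regression.

The attentiveness series Y(t) is modelled on the eight daily epidemic
statistics X_1..X_8 (new/total cases, deaths and vaccinations, people
vaccinated, reproduction rate).  Because an epidemic statistic need not act
on attentiveness instantaneously, each predictor is first scanned over
delays 0..max_lag for the delay maximizing |Pearson r|, then the regression

    Y(t) = beta_0 + sum_i beta_i * X_i(t - L_i) + eps(t)

is fit by ordinary least squares with each predictor shifted by its own lag
L_i.  The shift convention: lag ``l`` means the predictor's value ``l`` days
BEFORE the response day explains today's attentiveness, i.e. the predictor
column is shifted forward in time.  Days on which any shifted predictor is
unavailable (the first max(L) days) are dropped listwise.

The regression is exposed sklearn-style as :class:`LagShiftedRegression`
(fit/predict, ``get_params``/``set_params``, trailing-underscore fitted
attributes) so it composes with sklearn model selection; the module-level
functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .attentiveness import AttentivenessSeries, CorrelationResult

__all__ = [
    "STAT_VARIABLES",
    "CovidStatsPanel",
    "LagScanResult",
    "RegressionFit",
    "lag_scan",
    "lag_scan_panel",
    "LagShiftedRegression",
    "shifted_regression",
    "fit_quality_exceeds_marginals",
]

#: canonical order of the eight epidemic statistics
STAT_VARIABLES = (
    "new_cases",
    "new_deaths",
    "new_vaccinations",
    "total_cases",
    "total_deaths",
    "total_vaccinations",
    "people_vaccinated",
    "reproduction_rate",
)

_CUMULATIVE = ("total_cases", "total_deaths", "total_vaccinations", "people_vaccinated")


@dataclass
class CovidStatsPanel:
    """Daily panel of the eight epidemic statistics, date-indexed."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [v for v in STAT_VARIABLES if v not in self.data.columns]
        if missing:
            raise ValueError(f"panel lacks variables: {missing}")
        idx = self.data.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("panel dates must be strictly increasing")
        for v in _CUMULATIVE:
            series = self.data[v].dropna()
            if (series.diff().dropna() < -1e-9).any():
                raise ValueError(f"cumulative series {v} is not monotone non-decreasing")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    def __getitem__(self, variable: str) -> pd.Series:
        return self.data[variable]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="date")

    @classmethod
    def from_csv(cls, path) -> "CovidStatsPanel":
        frame = pd.read_csv(path, index_col="date", parse_dates=["date"])
        return cls(frame)


@dataclass(frozen=True)
class LagScanResult:
    """The |r|-maximizing delay of one predictor against attentiveness."""

    variable: str
    lag: int
    r: float
    p: float
    scan_table: pd.DataFrame = field(repr=False, compare=False, default=None)


def _series_of(y) -> pd.Series:
    return y.value if isinstance(y, AttentivenessSeries) else y


def lag_scan(
    y: AttentivenessSeries | pd.Series,
    x: pd.Series,
    max_lag: int = 30,
    variable: str = "",
    window: str = "common",
) -> LagScanResult:
    """Scan delays 0..max_lag of a predictor for maximal |Pearson r|.

    For each lag ``l`` the correlation pairs Y(t) with X(t-l); ties in |r|
    break toward the smallest lag.  With ``window='common'`` (default) every
    lag is evaluated on the same response days (those where all scanned
    shifts exist), so r values are comparable across lags; ``'pairwise'``
    uses all overlapping days per lag, which maximizes data but lets the
    evaluation window — and hence the variance normalization — drift with
    the lag.  P-values are per-lag and carry no multiplicity correction
    (the selected lag's p-value is therefore optimistic).
    """
    ys = _series_of(y)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if window not in ("common", "pairwise"):
        raise ValueError(f"unknown window {window!r}")
    common_start = None
    if window == "common":
        # response days where even the most-shifted predictor exists
        first_x = x.dropna().index.min()
        common_start = first_x + pd.Timedelta(days=max_lag)
    rows = []
    for lag in range(max_lag + 1):
        shifted = x.copy()
        shifted.index = shifted.index + pd.Timedelta(days=lag)
        aligned = pd.concat({"y": ys, "x": shifted}, axis=1, join="inner").dropna()
        if common_start is not None:
            aligned = aligned[aligned.index >= common_start]
        if len(aligned) < 3:
            raise ValueError(f"fewer than 3 overlapping days at lag {lag}")
        if aligned["x"].nunique() == 1:
            raise ValueError(f"predictor {variable or 'x'} constant on overlap at lag {lag}")
        r, p = stats.pearsonr(aligned["y"], aligned["x"])
        rows.append((lag, float(r), float(p), len(aligned)))
    table = pd.DataFrame(rows, columns=["lag", "r", "p", "n"])
    best = int(table["r"].abs().idxmax())  # idxmax returns the first maximum: smallest lag
    return LagScanResult(
        variable=variable or (x.name or "x"),
        lag=int(table.loc[best, "lag"]),
        r=float(table.loc[best, "r"]),
        p=float(table.loc[best, "p"]),
        scan_table=table,
    )


def lag_scan_panel(
    y: AttentivenessSeries | pd.Series,
    panel: CovidStatsPanel,
    max_lag: int = 30,
    window: str = "common",
) -> list[LagScanResult]:
    """Lag scan of every panel variable, in canonical order."""
    return [
        lag_scan(y, panel[v], max_lag=max_lag, variable=v, window=window)
        for v in STAT_VARIABLES
    ]


@dataclass
class RegressionFit:
    """Result of the lag-shifted OLS fit of attentiveness on the panel."""

    beta: np.ndarray  # intercept first, then the 8 slopes
    lags: np.ndarray
    fitted: pd.Series
    adj_r2: float
    fit_corr: CorrelationResult
    n_used: int
    condition_number: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.beta[0]),
            "coef": {v: float(b) for v, b in zip(STAT_VARIABLES, self.beta[1:])},
            "lags": {v: int(l) for v, l in zip(STAT_VARIABLES, self.lags)},
            "adj_r2": self.adj_r2,
            "fit_corr_r": self.fit_corr.r,
            "fit_corr_p": self.fit_corr.p,
            "fit_corr_strength": self.fit_corr.strength,
            "n_used": self.n_used,
            "condition_number": self.condition_number,
            "warnings": list(self.warnings),
        }


class LagShiftedRegression(RegressorMixin, BaseEstimator):
    """OLS of a daily response on per-predictor lag-shifted covariates.

    Parameters
    ----------
    lags : sequence of int or None
        Per-predictor delays in days.  ``None`` selects each delay by a
        marginal |r|-maximizing lag scan during :meth:`fit`.
    max_lag : int
        Scan bound when ``lags`` is None, and validation bound otherwise.
    cond_threshold : float
        Condition number of the (column-scaled) design above which a
        collinearity warning is attached; the fit is still returned.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (8,)
        Slopes on the raw predictor scales, canonical variable order.
    lags_ : ndarray of shape (8,)
    fit_ : RegressionFit
        Full fit bundle (fitted series, adjusted R^2, r(Y, Yhat), ...).
    scan_results_ : list of LagScanResult, present when lags was None.
    """

    def __init__(self, lags=None, max_lag: int = 30, cond_threshold: float = 1e8):
        self.lags = lags
        self.max_lag = max_lag
        self.cond_threshold = cond_threshold

    # -- internals ----------------------------------------------------

    @staticmethod
    def _design(y: pd.Series, panel: CovidStatsPanel, lags: np.ndarray) -> pd.DataFrame:
        cols = {"y": y}
        for v, lag in zip(STAT_VARIABLES, lags):
            shifted = panel[v].copy()
            shifted.index = shifted.index + pd.Timedelta(days=int(lag))
            cols[v] = shifted
        return pd.concat(cols, axis=1, join="inner").dropna()

    def fit(self, X: CovidStatsPanel | pd.DataFrame, y: AttentivenessSeries | pd.Series):
        panel = X if isinstance(X, CovidStatsPanel) else CovidStatsPanel(X)
        ys = _series_of(y).dropna()

        if self.lags is None:
            self.scan_results_ = lag_scan_panel(ys, panel, max_lag=self.max_lag)
            lags = np.array([s.lag for s in self.scan_results_], dtype=int)
        else:
            lags = np.asarray(self.lags, dtype=int)
            if lags.shape != (len(STAT_VARIABLES),):
                raise ValueError(f"lags must have length {len(STAT_VARIABLES)}")
            if (lags < 0).any() or (lags > self.max_lag).any():
                raise ValueError(f"lags must lie in [0, {self.max_lag}]")

        design = self._design(ys, panel, lags)
        n, p = len(design), len(STAT_VARIABLES)
        if n <= p + 1:
            raise ValueError(f"post-shift sample size {n} too small for {p} predictors")

        raw = design[list(STAT_VARIABLES)].to_numpy(dtype=float)
        yv = design["y"].to_numpy(dtype=float)
        # scale columns to unit norm for numerical stability; raw series span
        # many orders of magnitude and an unscaled solve loses precision
        exog = np.column_stack([np.ones(n), raw])
        scales = np.linalg.norm(exog, axis=0)
        if (scales == 0).any():
            raise ValueError("a predictor column is identically zero")
        exog_scaled = exog / scales
        rank = np.linalg.matrix_rank(exog_scaled)
        if rank < p + 1:
            raise ValueError(f"rank-deficient design (rank {rank} < {p + 1})")
        cond = float(np.linalg.cond(exog_scaled))

        notes: list[str] = []
        if cond > self.cond_threshold:
            msg = f"ill-conditioned design (condition number {cond:.3g})"
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)

        ols = sm.OLS(yv, exog_scaled).fit()
        beta = ols.params / scales
        fitted_values = exog @ beta
        fitted = pd.Series(fitted_values, index=design.index)

        r2 = float(ols.rsquared)
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        r, pval = stats.pearsonr(yv, fitted_values)
        fit_corr = CorrelationResult.from_r(r, pval, n)

        self.lags_ = lags
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.n_features_in_ = p
        self.fit_ = RegressionFit(
            beta=beta,
            lags=lags,
            fitted=fitted,
            adj_r2=float(adj_r2),
            fit_corr=fit_corr,
            n_used=n,
            condition_number=cond,
            warnings=notes,
        )
        return self

    def predict(self, X: CovidStatsPanel | pd.DataFrame) -> pd.Series:
        """Fitted attentiveness on the days where every shifted predictor exists."""
        if not hasattr(self, "fit_"):
            raise RuntimeError("estimator is not fitted")
        panel = X if isinstance(X, CovidStatsPanel) else CovidStatsPanel(X)
        cols = {}
        for v, lag in zip(STAT_VARIABLES, self.lags_):
            shifted = panel[v].copy()
            shifted.index = shifted.index + pd.Timedelta(days=int(lag))
            cols[v] = shifted
        design = pd.concat(cols, axis=1, join="inner").dropna()
        values = self.intercept_ + design[list(STAT_VARIABLES)].to_numpy() @ self.coef_
        return pd.Series(values, index=design.index)


def shifted_regression(
    y: AttentivenessSeries | pd.Series,
    panel: CovidStatsPanel,
    lags: Sequence[int],
    max_lag: int = 30,
) -> RegressionFit:
    """OLS of Y(t) on the panel with each predictor shifted by its own lag."""
    est = LagShiftedRegression(lags=list(lags), max_lag=max_lag)
    est.fit(panel, y)
    return est.fit_


def fit_quality_exceeds_marginals(
    fit: RegressionFit, scans: Sequence[LagScanResult]
) -> bool:
    """Whether |r(Y, Yhat)| reaches every single-predictor |r| from the scan."""
    return abs(fit.fit_corr.r) >= max(abs(s.r) for s in scans)
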