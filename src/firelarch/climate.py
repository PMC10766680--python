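"""Monthly climate forcing: reading, localization, and synthetic generation.

The simulator is driven by monthly mean temperature (``t_mon``, degC) and
monthly precipitation sums (``p_mon``, mm).  A climate series is represented
as a :class:`pandas.DataFrame` with columns ``year, month, t_mon, p_mon``,
sorted by (year, month), with exactly 12 contiguous months per year.  The
on-disk CSV format uses the headers ``year,month,t_mon_degC,p_mon_mm``.

Coarse climate-model output is localized to a site by matching the monthly
climatology of a reference product over a fitting window: additively for
temperature, multiplicatively for precipitation.

The synthetic generator emulates an eastern Siberian continental climate —
a sinusoidal seasonal temperature cycle with AR(1) interannual noise and an
optional linear trend, and gamma-distributed monthly precipitation with a
summer-weighted seasonal mean cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimateLocalization",
    "SyntheticClimateParams",
    "read_climate_csv",
    "write_climate_csv",
    "validate_climate",
    "localize_climate",
    "generate_synthetic_climate",
    "growing_season_mean",
    "thaw_index",
]

_CSV_COLUMNS = {"year": "year", "month": "month",
                "t_mon_degC": "t_mon", "p_mon_mm": "p_mon"}


def _seasonal_temperature(months: np.ndarray, mean: float, amplitude: float) -> np.ndarray:
    # coldest in January (month 1), warmest in July (month 7)
    return mean - amplitude * np.cos(2.0 * np.pi * (months - 1) / 12.0)


def _seasonal_precip_means(annual_total: float, summer_weight: float) -> np.ndarray:
    months = np.arange(1, 13)
    seasonal = 0.5 * (1.0 - np.cos(2.0 * np.pi * (months - 1) / 12.0))  # 0 in Jan, 1 in Jul
    weights = 1.0 + summer_weight * seasonal
    return annual_total * weights / weights.sum()


@dataclass(frozen=True)
class ClimateLocalization:
    """Monthly reference climatology used to localize coarse climate input.

    Temperature is adjusted additively, precipitation multiplicatively, so
    that the mean of each calendar month over the fitting window equals the
    reference mean.
    """

    reference_t_means: np.ndarray  # 12 values, degC
    reference_p_means: np.ndarray  # 12 values, mm

    def __post_init__(self) -> None:
        t = np.asarray(self.reference_t_means, dtype=float)
        p = np.asarray(self.reference_p_means, dtype=float)
        if t.shape != (12,) or p.shape != (12,):
            raise ValueError("reference climatologies must have 12 monthly values")
        if np.any(p < 0):
            raise ValueError("reference precipitation means must be >= 0")
        object.__setattr__(self, "reference_t_means", t)
        object.__setattr__(self, "reference_p_means", p)


@dataclass(frozen=True)
class SyntheticClimateParams:
    """Parameters of the synthetic monthly climate generator.

    Defaults emulate the climate of western Central Yakutia: January /
    July mean temperatures of -32.3 / 17.8 degC (annual mean c. -7 degC)
    and a 303 mm mean annual precipitation sum concentrated in summer.
    """

    t_mean: float = -7.25          # degC, annual mean of the seasonal cycle
    t_amplitude: float = 25.05     # degC, half-range of the seasonal cycle
    t_noise_sd: float = 2.0        # degC, innovation sd of the AR(1) anomaly
    t_noise_ar1: float = 0.3       # lag-1 autocorrelation of monthly anomalies
    t_trend_per_year: float = 0.0  # degC / yr linear trend
    p_annual_mean: float = 303.0   # mm / yr
    p_summer_weight: float = 2.0   # seasonal concentration of precipitation
    p_shape: float = 2.0           # gamma shape of monthly precipitation

    def monthly_t_means(self) -> np.ndarray:
        return _seasonal_temperature(np.arange(1, 13), self.t_mean, self.t_amplitude)

    def monthly_p_means(self) -> np.ndarray:
        return _seasonal_precip_means(self.p_annual_mean, self.p_summer_weight)


def validate_climate(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a climate frame: 12 contiguous months per year, p_mon >= 0.

    Returns the frame sorted by (year, month).  Raises ``ValueError`` on
    incomplete years, gaps between years, or negative precipitation.
    """
    required = {"year", "month", "t_mon", "p_mon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate frame missing columns: {sorted(missing)}")
    df = df.sort_values(["year", "month"]).reset_index(drop=True)
    for year, grp in df.groupby("year"):
        if list(grp["month"]) != list(range(1, 13)):
            raise ValueError(f"incomplete year {year}: expected months 1..12")
    years = df["year"].unique()
    if len(years) > 1 and np.any(np.diff(years) != 1):
        raise ValueError("years are not contiguous")
    if (df["p_mon"] < 0).any():
        raise ValueError("negative precipitation in climate series")
    return df


def read_climate_csv(path) -> pd.DataFrame:
    """Read a monthly climate CSV (``year,month,t_mon_degC,p_mon_mm``)."""
    raw = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = raw.rename(columns=_CSV_COLUMNS)[["year", "month", "t_mon", "p_mon"]]
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric value in column '{col}' at line {row}")
        df[col] = vals
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    return validate_climate(df)


def write_climate_csv(df: pd.DataFrame, path) -> None:
    """Write a climate frame with the canonical CSV header."""
    out = df[["year", "month", "t_mon", "p_mon"]].rename(
        columns={v: k for k, v in _CSV_COLUMNS.items()})
    out.to_csv(path, index=False)


def localize_climate(series: pd.DataFrame, loc: ClimateLocalization,
                     fit_window: tuple[int, int]) -> pd.DataFrame:
    """Localize a climate series to a reference monthly climatology.

    For each calendar month the temperature is shifted so that its mean over
    ``fit_window`` (inclusive year range) equals the reference mean, and the
    precipitation is scaled so that its window mean equals the reference
    mean.  Precipitation is clipped at zero (a no-op unless the source had
    negative values).
    """
    series = validate_climate(series)
    y0, y1 = fit_window
    window = series[(series["year"] >= y0) & (series["year"] <= y1)]
    if window.empty:
        raise ValueError("fit window does not overlap the climate series")
    if window["year"].nunique() != y1 - y0 + 1:
        raise ValueError("fit window extends outside the climate series")

    out = series.copy()
    for m in range(1, 13):
        sel = window["month"] == m
        t_src = window.loc[sel, "t_mon"].mean()
        p_src = window.loc[sel, "p_mon"].mean()
        t_ref = loc.reference_t_means[m - 1]
        p_ref = loc.reference_p_means[m - 1]
        month_mask = out["month"] == m
        out.loc[month_mask, "t_mon"] += t_ref - t_src
        if p_ref == 0.0:
            out.loc[month_mask, "p_mon"] = 0.0
        else:
            if p_src == 0.0:
                raise ValueError(
                    f"month {m}: zero precipitation mean in source over the fit "
                    "window with nonzero reference (multiplicative factor undefined)")
            out.loc[month_mask, "p_mon"] *= p_ref / p_src
    out["p_mon"] = out["p_mon"].clip(lower=0.0)
    return out


def generate_synthetic_climate(n_years: int,
                               params: SyntheticClimateParams | None = None,
                               seed: int = 0,
                               start_year: int = 0) -> pd.DataFrame:
    """Generate a reproducible synthetic monthly climate series.

    Temperature: sinusoidal seasonal cycle plus an AR(1) monthly anomaly and
    an optional linear trend.  Precipitation: independent gamma draws with
    seasonal monthly means.  With zero noise the series is exactly periodic
    with period 12 (plus any trend).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    params = params or SyntheticClimateParams()
    rng = np.random.default_rng(seed)

    n = 12 * n_years
    years = np.repeat(np.arange(start_year, start_year + n_years), 12)
    months = np.tile(np.arange(1, 13), n_years)

    t = _seasonal_temperature(months.astype(float), params.t_mean, params.t_amplitude)
    t = t + params.t_trend_per_year * (years - start_year)
    if params.t_noise_sd > 0:
        anom = np.empty(n)
        innov = rng.normal(0.0, params.t_noise_sd, size=n)
        anom[0] = innov[0]
        rho = params.t_noise_ar1
        for i in range(1, n):
            anom[i] = rho * anom[i - 1] + innov[i]
        t = t + anom

    p_means = params.monthly_p_means()[months - 1]
    # gamma with fixed shape k and seasonal mean => scale = mean / k
    p = rng.gamma(params.p_shape, p_means / params.p_shape)

    return pd.DataFrame({"year": years, "month": months, "t_mon": t, "p_mon": p})


def growing_season_mean(t_mon: np.ndarray) -> float:
    """Mean temperature over months above 0 degC (0.0 if no month thaws)."""
    t = np.asarray(t_mon, dtype=float)
    warm = t[t > 0.0]
    return float(warm.mean()) if warm.size else 0.0


def thaw_index(t_mon: np.ndarray, days_per_month: float = 30.4) -> float:
    """Degree-day thaw index: sum of positive monthly means x days per month."""
    t = np.asarray(t_mon, dtype=float)
    return float(np.sum(np.clip(t, 0.0, None)) * days_per_month)
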