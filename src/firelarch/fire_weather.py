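"""Fire-weather rating: monthly fire probability, categories, annual ignition
probability, calibration, and refitting against observed fire counts.

The monthly fire probability rating (FPR_mon) is a linear model of monthly
mean temperature and precipitation, evaluated only for months above 0 degC.
Ratings are categorized as mild / severe / extreme by fixed thresholds
(6.6 / 7.0 / 7.46; boundaries belong to the higher class), the category
counts of a year are combined into an annual fire probability rating
(FPR_ann) in [0, 1] — a clamped weighted count with weights (1, 2, 4) —
and a single scale factor is calibrated so the mean FPR_ann over a climate
series equals a target (default 0.03, i.e. about one fire per 33 years).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .climate import validate_climate

__all__ = [
    "NO_RATING",
    "FprModel",
    "FprCalibration",
    "AnnualFireRating",
    "fpr_mon",
    "categorize",
    "annual_rating",
    "annual_ratings",
    "calibrate",
    "refit_fpr_model",
]

#: Sentinel returned for months at or below 0 degC ("no rating").
NO_RATING = -np.inf

CATEGORY_NONE = "none"
CATEGORY_MILD = "mild"
CATEGORY_SEVERE = "severe"
CATEGORY_EXTREME = "extreme"


@dataclass(frozen=True)
class FprModel:
    """Linear monthly fire-probability-rating model with category thresholds.

    ``rating = intercept + coef_t * t + coef_p * p`` for months with
    t > 0 degC.  Default coefficients are chosen so a warm dry month
    (20 degC, 20 mm) rates near the extreme threshold; warmer is riskier
    (coef_t > 0), wetter is safer (coef_p < 0).  The thresholds themselves
    (6.6 minimum, 7.0 severe, 7.46 extreme) are the quantile-based values
    used with the observational fit at the reference site.
    """

    intercept: float = 6.46
    coef_t: float = 0.06
    coef_p: float = -0.01
    threshold_min: float = 6.6
    threshold_severe: float = 7.0
    threshold_extreme: float = 7.46

    def __post_init__(self) -> None:
        if not (self.threshold_min < self.threshold_severe < self.threshold_extreme):
            raise ValueError("thresholds must satisfy min < severe < extreme")


@dataclass(frozen=True)
class FprCalibration:
    """Weights and scale mapping category counts to FPR_ann.

    fpr_ann = clamp(scale * (w_mild*n_mild + w_severe*n_severe
                             + w_extreme*n_extreme), 0, 1)
    """

    weight_mild: float = 1.0
    weight_severe: float = 2.0
    weight_extreme: float = 4.0
    scale: float = 0.01
    target_mean: float = 0.03

    def weighted_count(self, n_mild: int, n_severe: int, n_extreme: int) -> float:
        return (self.weight_mild * n_mild + self.weight_severe * n_severe
                + self.weight_extreme * n_extreme)


@dataclass(frozen=True)
class AnnualFireRating:
    year: int
    n_mild: int
    n_severe: int
    n_extreme: int
    fpr_ann: float


def fpr_mon(t: float, p: float, model: FprModel | None = None) -> float:
    """Monthly fire probability rating; ``NO_RATING`` for t <= 0 degC."""
    model = model or FprModel()
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    rating = model.intercept + model.coef_t * t + model.coef_p * p
    out = np.where(t > 0.0, rating, NO_RATING)
    return float(out) if out.ndim == 0 else out


def categorize(rating: float, model: FprModel | None = None) -> str:
    """Fire-weather category of a monthly rating.

    Thresholds partition the real line; a boundary value belongs to the
    higher class (7.0 -> severe, 7.46 -> extreme).
    """
    model = model or FprModel()
    if rating >= model.threshold_extreme:
        return CATEGORY_EXTREME
    if rating >= model.threshold_severe:
        return CATEGORY_SEVERE
    if rating >= model.threshold_min:
        return CATEGORY_MILD
    return CATEGORY_NONE


def _count_categories(months: pd.DataFrame, model: FprModel) -> tuple[int, int, int]:
    ratings = fpr_mon(months["t_mon"].to_numpy(), months["p_mon"].to_numpy(), model)
    n_extreme = int(np.sum(ratings >= model.threshold_extreme))
    n_severe = int(np.sum((ratings >= model.threshold_severe)
                          & (ratings < model.threshold_extreme)))
    n_mild = int(np.sum((ratings >= model.threshold_min)
                        & (ratings < model.threshold_severe)))
    return n_mild, n_severe, n_extreme


def fpr_ann_from_counts(n_mild: int, n_severe: int, n_extreme: int,
                        cal: FprCalibration) -> float:
    return float(np.clip(cal.scale * cal.weighted_count(n_mild, n_severe, n_extreme),
                         0.0, 1.0))


def annual_rating(months: pd.DataFrame, model: FprModel | None = None,
                  cal: FprCalibration | None = None) -> AnnualFireRating:
    """Annual fire rating from the 12 months of one year."""
    model = model or FprModel()
    cal = cal or FprCalibration()
    if len(months) != 12:
        raise ValueError(f"annual_rating needs exactly 12 months, got {len(months)}")
    years = months["year"].unique()
    if len(years) != 1:
        raise ValueError("annual_rating needs months of a single year")
    n_mild, n_severe, n_extreme = _count_categories(months, model)
    return AnnualFireRating(
        year=int(years[0]), n_mild=n_mild, n_severe=n_severe, n_extreme=n_extreme,
        fpr_ann=fpr_ann_from_counts(n_mild, n_severe, n_extreme, cal))


def annual_ratings(series: pd.DataFrame, model: FprModel | None = None,
                   cal: FprCalibration | None = None) -> list[AnnualFireRating]:
    """Annual ratings for every year of a validated climate series."""
    series = validate_climate(series)
    return [annual_rating(grp, model, cal) for _, grp in series.groupby("year")]


def calibrate(series: pd.DataFrame, model: FprModel | None = None,
              target_mean: float = 0.03,
              cal: FprCalibration | None = None,
              tol: float = 1e-9) -> FprCalibration:
    """Solve for the FPR_ann scale so the series mean equals ``target_mean``.

    Weights stay at their defaults; the scale is found by monotone bisection
    on mean(clamp(scale * weighted_count)).  Errors if the series has no
    fire weather at all, or if clamping makes the target unattainable (the
    achievable maximum is reported in the message).
    """
    model = model or FprModel()
    cal = cal or FprCalibration()
    series = validate_climate(series)
    counts = np.array([_count_categories(grp, model)
                       for _, grp in series.groupby("year")])
    weighted = (cal.weight_mild * counts[:, 0] + cal.weight_severe * counts[:, 1]
                + cal.weight_extreme * counts[:, 2]).astype(float)
    if np.all(weighted == 0.0):
        raise ValueError("no fire weather in series: all category counts are zero")

    def mean_fpr(scale: float) -> float:
        return float(np.mean(np.clip(scale * weighted, 0.0, 1.0)))

    achievable_max = float(np.mean(weighted > 0))  # limit scale -> inf
    if target_mean > achievable_max + tol:
        raise ValueError(
            f"target mean {target_mean} unattainable under clamping; "
            f"achievable maximum is {achievable_max:.6f}")

    # closed form ignoring the clamp, then verify / bisect
    scale = target_mean / float(np.mean(weighted))
    if abs(mean_fpr(scale) - target_mean) > tol:
        lo, hi = 0.0, scale
        while mean_fpr(hi) < target_mean:
            hi *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mean_fpr(mid) < target_mean:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol * max(1.0, hi):
                break
        scale = 0.5 * (lo + hi)
    return replace(cal, scale=scale, target_mean=target_mean)


def refit_fpr_model(monthly_fire_counts: np.ndarray, climate: pd.DataFrame,
                    model: FprModel | None = None) -> tuple[FprModel, dict]:
    """Refit the monthly rating model against observed monthly fire counts.

    Ordinary least squares of log1p(fire count) on (t, p) over months above
    0 degC (counts are zero-inflated; any monotone transform works since
    only the rating's quantiles matter downstream).  Category thresholds
    are then recomputed from the fitted rating distribution: severe = Q3
    (75th percentile), extreme = Q4 (the distribution maximum), and the
    minimum threshold = the highest fitted rating among months with zero
    observed fires (falling back to Q1 if every month saw fire).

    Returns the refitted model and a dict with ``params``, ``bse``, ``r2``,
    and ``n_obs``.
    """
    import statsmodels.api as sm

    climate = validate_climate(climate)
    counts = np.asarray(monthly_fire_counts, dtype=float)
    if counts.shape[0] != len(climate):
        raise ValueError("fire count series must align with the climate series")
    if np.any(counts < 0):
        raise ValueError("fire counts must be >= 0")

    t = climate["t_mon"].to_numpy()
    p = climate["p_mon"].to_numpy()
    usable = t > 0.0
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable months (above 0 degC)")

    y = np.log1p(counts[usable])
    X = sm.add_constant(np.column_stack([t[usable], p[usable]]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: climate has zero variance")
    fit = sm.OLS(y, X).fit()
    intercept, coef_t, coef_p = fit.params

    ratings = intercept + coef_t * t[usable] + coef_p * p[usable]
    zero_fire = counts[usable] == 0
    if zero_fire.any():
        threshold_min = float(ratings[zero_fire].max())
    else:
        threshold_min = float(np.quantile(ratings, 0.25))
    threshold_severe = float(np.quantile(ratings, 0.75))
    threshold_extreme = float(np.quantile(ratings, 1.0))
    # keep the strict ordering required by the model even on odd samples
    eps = 1e-9 + 1e-6 * max(1.0, abs(threshold_extreme))
    threshold_min = min(threshold_min, threshold_severe - eps)
    threshold_extreme = max(threshold_extreme, threshold_severe + eps)

    refitted = FprModel(intercept=float(intercept), coef_t=float(coef_t),
                        coef_p=float(coef_p), threshold_min=threshold_min,
                        threshold_severe=threshold_severe,
                        threshold_extreme=threshold_extreme)
    stats = {"params": np.asarray(fit.params), "bse": np.asarray(fit.bse),
             "r2": float(fit.rsquared), "n_obs": int(usable.sum())}
    return refitted, stats
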