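"""Post-processing of simulation output: recovery statistics and
forest-structure metrics.

The central tool is a superposed epoch analysis (SEA): around every fire
year, a fixed window of the stem-count timeseries (10 years before to 30
years after) is cut out; the windows are superimposed and summarized by
their median and quantile band per relative year, extracting the common
post-fire response.  Recovery time is the first post-fire year at which
the SEA median regains the pre-fire baseline (the mean of the median over
relative years -10..-1); if the median never recovers within the window
the value is missing.

Structure metrics use the fixed height classes of the simulation output:
stems are trees >= 130 cm, seedlings are 0-40 cm, mature mean height is
taken over trees > 200 cm, and the composition index is the ratio of
evergreen to deciduous individuals (missing when there are no deciduous
trees).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SEAResult", "superposed_epoch", "recovery_time",
           "structure_metrics", "natural_sort_key", "natural_sorted"]


@dataclass
class SEAResult:
    """Superposed epoch analysis of a timeseries around repeated events."""

    rel_years: np.ndarray      # -pre .. +post
    median: np.ndarray
    q_lo: np.ndarray
    q_hi: np.ndarray
    n_events: int
    n_dropped: int             # windows truncated by the series edges
    quantiles: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rel_year": self.rel_years, "median": self.median,
            "q_lo": self.q_lo, "q_hi": self.q_hi,
            "n_events": self.n_events,
        })

    def baseline(self) -> float:
        """Pre-fire baseline: mean of the median over relative years -pre..-1."""
        pre = self.rel_years < 0
        return float(self.median[pre].mean())


def superposed_epoch(series: pd.Series | np.ndarray,
                     fire_years: np.ndarray,
                     years: np.ndarray | None = None,
                     pre: int = 10, post: int = 30,
                     quantiles: tuple[float, float] = (0.25, 0.75)) -> SEAResult:
    """Superimpose fixed windows of ``series`` around each fire year.

    ``series`` is an annual timeseries; ``years`` gives its year axis
    (defaults to the index of a Series, else 0..n-1).  Windows extending
    beyond the series are dropped (and counted).  Overlapping windows from
    fires closer than ``pre + post`` years are all kept; superposition
    tolerates overlap.

    Raises ``ValueError`` when no window fits inside the series.
    """
    if isinstance(series, pd.Series):
        values = series.to_numpy(dtype=float)
        if years is None:
            years = series.index.to_numpy()
    else:
        values = np.asarray(series, dtype=float)
    if years is None:
        years = np.arange(len(values))
    years = np.asarray(years)
    if len(years) != len(values):
        raise ValueError("series and year axis length mismatch")

    year_pos = {int(y): i for i, y in enumerate(years)}
    windows, dropped = [], 0
    for fy in np.asarray(fire_years, dtype=int):
        if fy not in year_pos:
            dropped += 1
            continue
        i = year_pos[fy]
        if i - pre < 0 or i + post >= len(values):
            dropped += 1
            continue
        windows.append(values[i - pre: i + post + 1])
    if not windows:
        raise ValueError("no usable event windows inside the series")

    stack = np.vstack(windows)
    q_lo, q_hi = quantiles
    return SEAResult(
        rel_years=np.arange(-pre, post + 1),
        median=np.median(stack, axis=0),
        q_lo=np.quantile(stack, q_lo, axis=0),
        q_hi=np.quantile(stack, q_hi, axis=0),
        n_events=len(windows), n_dropped=dropped,
        quantiles=(q_lo, q_hi),
    )


def recovery_time(sea: SEAResult) -> float:
    """Years to recovery: first post-fire relative year with median >= the
    pre-fire baseline; NaN if the median never recovers within the window.

    A response with no drop recovers at year +1 by construction.
    """
    baseline = sea.baseline()
    post = sea.rel_years >= 1
    rel = sea.rel_years[post]
    med = sea.median[post]
    hit = np.flatnonzero(med >= baseline)
    if hit.size == 0:
        return float("nan")
    return float(rel[hit[0]])


def structure_metrics(heights: np.ndarray, deciduous: np.ndarray | None = None
                      ) -> dict[str, float]:
    """Stand-structure metrics from live-tree heights (cm).

    Returns stem_count (height >= 130), seedling_count (0 <= height <= 40),
    mean_height_mature (mean over trees > 200 cm; NaN if none), and, when
    ``deciduous`` flags are given, evergreen_deciduous_ratio (NaN when the
    stand holds no deciduous trees).
    """
    h = np.asarray(heights, dtype=float)
    out: dict[str, float] = {
        "stem_count": float(np.count_nonzero(h >= 130.0)),
        "seedling_count": float(np.count_nonzero((h >= 0.0) & (h <= 40.0))),
    }
    mature = h > 200.0
    out["mean_height_mature"] = float(h[mature].mean()) if mature.any() else float("nan")
    if deciduous is not None:
        dec = np.asarray(deciduous, dtype=bool)
        n_dec = int(dec.sum())
        n_ever = int((~dec).sum())
        out["evergreen_deciduous_ratio"] = (
            n_ever / n_dec if n_dec > 0 else float("nan"))
    return out


_NUM_RE = re.compile(r"(\d+)")


def natural_sort_key(text: str) -> tuple:
    """Mixed numeric-aware sort key: run_2 sorts before run_10."""
    parts = _NUM_RE.split(str(text))
    return tuple(int(p) if p.isdigit() else p for p in parts)


def natural_sorted(items) -> list:
    return sorted(items, key=natural_sort_key)
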