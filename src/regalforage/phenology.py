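"""Phenological overlap: weekly sex ratios, overlap windows, median dates.

In a protandrous butterfly the male flight curve leads the female curve by
roughly two weeks, so part of any sex difference in flower visitation can be
a pure phenology artifact.  The overlap analysis restricts each year to the
weeks in which both sexes are substantially active -- the span from the
first week in which females reach at least 25% of observations through the
last week in which they are at most 75% -- and re-runs the comparisons on
that restricted dataset.  Years whose window collapses to fewer than
``min_days`` distinct survey days are excluded outright.

Weeks are fixed 7-day bins anchored at ordinal day 1 (days 1-7 = week 1),
which is deterministic across locales and years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import VisitationDataset

DEFAULT_LOWER = 0.25
DEFAULT_UPPER = 0.75
DEFAULT_MIN_DAYS = 4


def week_of_day(day) -> np.ndarray:
    """Fixed 7-day bin index: days 1-7 -> week 1, days 8-14 -> week 2, ..."""
    return (np.asarray(day, dtype=np.int64) - 1) // 7 + 1


def weekly_female_proportion(ds: VisitationDataset, year: int) -> pd.DataFrame:
    """Per-week female/male tallies and female share for one year.

    Returns one row per week with >=1 observation, columns ``year``, ``week``,
    ``n_female``, ``n_male``, ``p_female``.  Tallies are weighted by the
    record ``count`` field.
    """
    df = ds.year_records(year)
    if df.empty:
        raise ValueError(f"year {year} not present in dataset")
    work = df.assign(week=week_of_day(df["ordinal_day"]))
    tally = (
        work.pivot_table(index="week", columns="sex", values="count",
                         aggfunc="sum", fill_value=0)
        .reindex(columns=["F", "M"], fill_value=0)
        .reset_index()
    )
    tally.columns.name = None
    tally = tally.rename(columns={"F": "n_female", "M": "n_male"})
    denom = tally["n_female"] + tally["n_male"]
    tally["p_female"] = tally["n_female"] / denom
    tally.insert(0, "year", year)
    return tally.sort_values("week").reset_index(drop=True)


@dataclass(frozen=True)
class OverlapWindow:
    """Per-year overlap period at week resolution, with exclusion status."""

    year: int
    start_week: int | None
    end_week: int | None
    start_day: int | None
    end_day: int | None
    n_observation_days: int | None
    excluded: bool
    reason: str | None = None


def detect_overlap_window(
    series: pd.DataFrame,
    *,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
    min_days: int = DEFAULT_MIN_DAYS,
    observed_days: Iterable[int] | None = None,
    rule: str = "caption",
) -> OverlapWindow:
    """Locate the male-female overlap window in a weekly sex-ratio series.

    ``rule='caption'`` (default): window runs from the first week with
    ``p_female >= lower`` through the last week (at or after the start) with
    ``p_female <= upper``.  ``rule='methods'``: the end point is instead the
    first week at/after the start in which females *exceed* ``upper`` (the
    week males drop below the lower share); if none exists the window runs to
    the last observed week.  The two conventions coincide whenever the female
    share rises monotonically.

    ``observed_days`` (distinct survey ordinal days for the year) enables the
    minimum-days exclusion: windows spanning fewer than ``min_days`` distinct
    observation days are excluded.  Exclusion is a value, not an error.
    """
    if series.empty:
        raise ValueError("empty weekly series")
    if rule not in ("caption", "methods"):
        raise ValueError(f"unknown rule {rule!r}")
    s = series.sort_values("week")
    year = int(s["year"].iloc[0]) if "year" in s.columns else -1
    weeks = s["week"].to_numpy()
    p = s["p_female"].to_numpy(dtype=float)

    start_idx = np.flatnonzero(p >= lower)
    if len(start_idx) == 0:
        return OverlapWindow(year, None, None, None, None, None, True,
                             f"no week reaches p_female >= {lower}")
    i0 = start_idx[0]
    if rule == "caption":
        end_idx = np.flatnonzero((np.arange(len(p)) >= i0) & (p <= upper))
        if len(end_idx) == 0:
            return OverlapWindow(year, None, None, None, None, None, True,
                                 f"no week at/after start has p_female <= {upper}")
        i1 = end_idx[-1]
    else:  # methods-text variant
        exceed = np.flatnonzero((np.arange(len(p)) >= i0) & (p > upper))
        i1 = exceed[0] if len(exceed) else len(p) - 1

    start_week, end_week = int(weeks[i0]), int(weeks[i1])
    start_day = (start_week - 1) * 7 + 1
    end_day = end_week * 7
    n_days = None
    if observed_days is not None:
        days = np.unique(np.asarray(list(observed_days), dtype=np.int64))
        n_days = int(np.sum((days >= start_day) & (days <= end_day)))
        if n_days < min_days:
            return OverlapWindow(
                year, start_week, end_week, start_day, end_day, n_days, True,
                f"insufficient observation days ({n_days} < {min_days})",
            )
    return OverlapWindow(year, start_week, end_week, start_day, end_day,
                         n_days, False, None)


def overlap_windows(
    ds: VisitationDataset,
    *,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
    min_days: int = DEFAULT_MIN_DAYS,
    rule: str = "caption",
) -> dict[int, OverlapWindow]:
    """Detect the overlap window of every year in the dataset."""
    out: dict[int, OverlapWindow] = {}
    for year in ds.years:
        series = weekly_female_proportion(ds, year)
        days = ds.year_records(year)["ordinal_day"].unique()
        out[year] = detect_overlap_window(
            series, lower=lower, upper=upper, min_days=min_days,
            observed_days=days, rule=rule,
        )
    return out


def restrict_to_overlap(
    ds: VisitationDataset, windows: Mapping[int, OverlapWindow]
) -> VisitationDataset:
    """Keep exactly the records inside their year's window; drop excluded years.

    Window bounds are inclusive on both ends at day resolution.
    """
    df = ds.records
    mask = pd.Series(False, index=df.index)
    for year, win in windows.items():
        if win.excluded:
            continue
        mask |= (
            (df["year"] == year)
            & (df["ordinal_day"] >= win.start_day)
            & (df["ordinal_day"] <= win.end_day)
        )
    return ds.replace_records(df[mask])


def median_day(ds: VisitationDataset, year: int, sex: str) -> int:
    """Weighted median ordinal day of one sex-year (lower-median convention)."""
    df = ds.year_records(year)
    df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError(f"no {sex} records in year {year}")
    agg = df.groupby("ordinal_day")["count"].sum().sort_index()
    total = int(agg.sum())
    k = (total + 1) // 2  # lower median of the expanded multiset
    cum = agg.cumsum()
    return int(agg.index[np.searchsorted(cum.to_numpy(), k)])


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int


def median_gap_regression(
    per_year_dmh: Mapping[int, float], ds: VisitationDataset
) -> RegressionResult:
    """OLS of yearly dissimilarity on the absolute male-female median-date gap.

    Quantifies how much of the year-to-year variation in foraging
    dissimilarity the timing offset between the sexes explains.
    """
    rows = []
    for year, d in sorted(per_year_dmh.items()):
        ydf = ds.year_records(year)
        if d is None or not {"F", "M"} <= set(ydf["sex"].unique()):
            continue
        gap = abs(median_day(ds, year, "F") - median_day(ds, year, "M"))
        rows.append((year, gap, float(d)))
    if len(rows) < 3:
        raise ValueError(f"need >=3 usable years, got {len(rows)}")
    frame = pd.DataFrame(rows, columns=["year", "gap", "dmh"])
    gaps = frame["gap"].to_numpy(dtype=float)
    y = frame["dmh"].to_numpy(dtype=float)
    if np.var(gaps) == 0:  # no timing variation: nothing to regress on
        return RegressionResult(slope=0.0, intercept=float(y.mean()),
                                r_squared=0.0, adj_r_squared=0.0,
                                p_value=1.0, n=len(frame))
    X = sm.add_constant(gaps)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    # Guard against a constant response: R^2 and p are 0/1 by convention.
    if np.var(frame["dmh"].to_numpy()) == 0 or not np.isfinite(fit.f_pvalue):
        p_value, r2, adj = 1.0, 0.0, 0.0
    else:
        p_value, r2 = float(fit.f_pvalue), float(fit.rsquared)
        adj = float(fit.rsquared_adj)
    return RegressionResult(
        slope=slope, intercept=float(fit.params[0]),
        r_squared=r2, adj_r_squared=adj, p_value=p_value, n=len(frame),
    )
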