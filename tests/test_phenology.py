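"""Weekly sex ratios, overlap windows, median dates, gap regression."""

import numpy as np
import pandas as pd
import pytest

from regalforage import (SeasonConfig, detect_overlap_window, median_day,
                         median_gap_regression, overlap_windows,
                         restrict_to_overlap, simulate_season,
                         weekly_female_proportion, week_of_day)

from conftest import make_dataset


def series_from_props(props, n_per_week=20):
    """Weekly series with the requested female shares (week k = index+1)."""
    rows = []
    for i, p in enumerate(props):
        nf = round(p * n_per_week)
        rows.append({"year": 2001, "week": i + 1, "n_female": nf,
                     "n_male": n_per_week - nf, "p_female": p})
    return pd.DataFrame(rows)


def test_week_binning_is_anchored_at_day_one():
    assert list(week_of_day([1, 7, 8, 14, 15])) == [1, 1, 2, 2, 3]


def test_weekly_proportion_arithmetic():
    ds = make_dataset([
        (2001, 1, "F", "A"), (2001, 2, "M", "A"),
        (2001, 3, "M", "A"), (2001, 4, "M", "A"),
        (2001, 10, "M", "A"),
    ])
    s = weekly_female_proportion(ds, 2001)
    assert s.loc[s.week == 1, "p_female"].item() == pytest.approx(0.25)
    assert s.loc[s.week == 2, "p_female"].item() == 0.0
    assert set(s["week"]) == {1, 2}  # empty weeks omitted


def test_weekly_proportion_all_male():
    ds = make_dataset([(2001, d, "M", "A") for d in (5, 12, 19)])
    s = weekly_female_proportion(ds, 2001)
    assert (s["p_female"] == 0).all()


def test_weekly_tallies_match_generator_truth(default_season):
    ds, truth = default_season
    year = ds.years[0]
    s = weekly_female_proportion(ds, year)
    t = truth.counts[truth.counts.year == year].groupby("sex")["count"].sum()
    assert s["n_female"].sum() == t.get("F", 0)
    assert s["n_male"].sum() == t.get("M", 0)


def test_caption_rule_worked_example():
    """Shares (0, 0.10, 0.40, 0.60, 0.90) -> window = weeks 3-4."""
    win = detect_overlap_window(series_from_props([0.0, 0.10, 0.40, 0.60, 0.90]))
    assert not win.excluded
    assert (win.start_week, win.end_week) == (3, 4)
    assert (win.start_day, win.end_day) == (15, 28)


def test_all_weeks_qualify_when_share_constant():
    win = detect_overlap_window(series_from_props([0.5] * 6))
    assert (win.start_week, win.end_week) == (1, 6)


def test_methods_rule_ends_at_first_week_exceeding_upper():
    props = [0.0, 0.10, 0.40, 0.60, 0.90, 0.40]
    cap = detect_overlap_window(series_from_props(props), rule="caption")
    met = detect_overlap_window(series_from_props(props), rule="methods")
    assert (cap.start_week, cap.end_week) == (3, 6)
    assert (met.start_week, met.end_week) == (3, 5)


def test_window_excluded_when_too_few_observation_days():
    win = detect_overlap_window(
        series_from_props([0.0, 0.40, 0.60, 0.90]),
        min_days=4, observed_days=[9, 16],  # 2 distinct days in weeks 2-3
    )
    assert win.excluded and "insufficient" in win.reason
    assert win.n_observation_days == 2


def test_no_qualifying_weeks_is_exclusion_not_error():
    win = detect_overlap_window(series_from_props([0.0, 0.05, 0.10]))
    assert win.excluded and "no week" in win.reason


def test_restrict_boundary_days_inclusive():
    ds = make_dataset([
        (2001, d, s, "A")
        for d, s in [(15, "F"), (15, "M"), (22, "F"), (22, "M"), (29, "F")]
    ])
    wins = overlap_windows(ds, min_days=1)
    win = wins[2001]
    out = restrict_to_overlap(ds, wins)
    days = out.records["ordinal_day"]
    assert win.start_day in days.values  # inclusive lower bound
    assert (days >= win.start_day).all() and (days <= win.end_day).all()


def test_restrict_matches_bruteforce_filter(default_season):
    """Window restriction equals an independent day-by-day filter, and never
    increases any per-year per-sex count."""
    ds, _ = default_season
    wins = overlap_windows(ds)
    out = restrict_to_overlap(ds, wins)
    keep = []
    for _, row in ds.records.iterrows():
        w = wins[row["year"]]
        keep.append((not w.excluded) and w.start_day <= row["ordinal_day"] <= w.end_day)
    assert len(out) == int(np.sum(keep))
    full_counts = ds.records.groupby(["year", "sex"])["count"].sum()
    over_counts = out.records.groupby(["year", "sex"])["count"].sum()
    joined = pd.concat([full_counts, over_counts], axis=1).fillna(0)
    assert (joined.iloc[:, 1] <= joined.iloc[:, 0]).all()


def test_all_years_excluded_gives_empty_dataset():
    ds = make_dataset([(2001, 15, "F", "A"), (2001, 15, "M", "A")])
    wins = overlap_windows(ds, min_days=4)  # single observation day
    assert wins[2001].excluded
    assert len(restrict_to_overlap(ds, wins)) == 0


def test_median_day_lower_median_convention():
    ds = make_dataset([
        (2001, 10, "F", "A"), (2001, 20, "F", "A"),
        (2001, 30, "F", "A"), (2001, 40, "F", "A"),
    ])
    assert median_day(ds, 2001, "F") == 20  # lower middle of an even multiset


def test_gap_regression_perfect_fit_and_constant_response():
    rows = []
    for year, gap_half, d in [(2001, 0, 0.1), (2002, 5, 0.3), (2003, 10, 0.5)]:
        rows += [(year, 100 - gap_half, "M", "A"), (year, 100 + gap_half, "F", "A")]
    ds = make_dataset(rows)
    res = median_gap_regression({2001: 0.1, 2002: 0.3, 2003: 0.5}, ds)
    assert res.r_squared == pytest.approx(1.0)
    assert res.slope == pytest.approx(0.02)
    const = median_gap_regression({2001: 0.3, 2002: 0.3, 2003: 0.3}, ds)
    assert const.slope == pytest.approx(0.0, abs=1e-12)
    assert const.r_squared == pytest.approx(0.0, abs=1e-12)


def test_gap_regression_recovers_slope(rng):
    """24 years with d = 0.02 * gap + N(0, 0.05): OLS slope lands within
    3 standard errors of the truth."""
    rows, dmh = [], {}
    gaps = rng.integers(0, 25, size=24)
    for i, gap in enumerate(gaps):
        year = 1998 + i
        rows += [(year, 150, "M", "A"), (year, 150 + int(gap), "F", "A")]
        dmh[year] = float(np.clip(0.02 * gap + rng.normal(0, 0.05), 0, 1))
    res = median_gap_regression(dmh, make_dataset(rows))
    se = 0.05 / np.sqrt(np.sum((gaps - gaps.mean()) ** 2))
    assert abs(res.slope - 0.02) < 3 * se
    assert res.n == 24
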