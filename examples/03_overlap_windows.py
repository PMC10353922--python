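"""Detect per-year male-female overlap windows and restrict the dataset.

The overlap window runs from the first week in which females reach 25% of
observations through the last week in which they stay at or below 75%;
windows with fewer than four distinct survey days are excluded.  Analyses
repeated on the restricted dataset show how much of the sex difference is
pure phenology.
"""

from regalforage import (SeasonConfig, overlap_windows, restrict_to_overlap,
                         simulate_season, weekly_female_proportion)

dataset, _ = simulate_season(SeasonConfig(), seed=1)
windows = overlap_windows(dataset)

year = dataset.years[0]
print(f"Weekly female share, year {year}:")
print(weekly_female_proportion(dataset, year).to_string(index=False))
print()
for y, win in list(windows.items())[:5]:
    if win.excluded:
        print(f"{y}: EXCLUDED ({win.reason})")
    else:
        print(f"{y}: weeks {win.start_week}-{win.end_week} "
              f"(days {win.start_day}-{win.end_day}, "
              f"{win.n_observation_days} survey days)")

overlap = restrict_to_overlap(dataset, windows)
print(f"\nFull dataset: {len(dataset)} records; "
      f"overlap dataset: {len(overlap)} records "
      f"({len(overlap) / len(dataset):.0%} retained).")
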