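"""Synthetic visitation seasons and nectar panels with known truth.

The visitation generator emulates a Pollard-walk survey of a protandrous
butterfly: weekly survey days across a June-October season (ordinal days
153-281), Gaussian flight curves per sex (the male peak leading the female
peak by two weeks by default), a trapezoidal bloom curve per plant species
creating seasonal flowering turnover, and per-sex multinomial plant choice
proportional to availability x preference.  A configurable fraction of the
two congeneric thistle species' records is masked to the ambiguous
``"Cirsium spp."`` label so the assignment stage has a test surface.  Every
realized count is recorded as truth, so each pipeline stage can be verified
without any external download.

The nectar generator draws log-normal concentrations per species x compound
with species-specific variances, 13 biological replicates per species by
default (8 for *Cirsium discolor*, mirroring the field design), and an
optional additive shift on female-associated species for recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AMBIGUOUS_CIRSIUM, VisitationDataset

SEASON = (153, 281)


@dataclass(frozen=True)
class PlantSpec:
    """One nectar plant: bloom window plus per-sex preference weights.

    Availability follows a trapezoid: linear ramp over ``ramp_days`` from
    ``bloom_start``, a plateau, and a symmetric ramp down ending at
    ``bloom_end``.  Preference weights must be positive (use a tiny weight
    to emulate a near-forbidden link).
    """

    name: str
    bloom_start: int
    bloom_end: int
    ramp_days: int = 10
    weight_female: float = 1.0
    weight_male: float = 1.0

    def __post_init__(self):
        if self.bloom_end < self.bloom_start:
            raise ValueError(f"{self.name}: bloom_end < bloom_start")
        if self.weight_female <= 0 or self.weight_male <= 0:
            raise ValueError(f"{self.name}: preference weights must be > 0")

    def availability(self, day) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        inside = (day >= self.bloom_start) & (day <= self.bloom_end)
        up = (day - self.bloom_start + 1) / self.ramp_days
        down = (self.bloom_end - day + 1) / self.ramp_days
        return np.where(inside, np.minimum(1.0, np.minimum(up, down)), 0.0)


#: Default community: the six focal species of the study system, with bloom
#: timing qualitatively matching the field site (early milkweeds preferred
#: by males, mid/late thistles-knapweed-beebalm preferred by females) plus
#: two minor generalist species.
DEFAULT_PLANTS: tuple[PlantSpec, ...] = (
    PlantSpec("Asclepias tuberosa", 155, 215, 12, weight_female=0.8, weight_male=2.0),
    PlantSpec("Asclepias syriaca", 155, 200, 12, weight_female=0.3, weight_male=1.2),
    PlantSpec("Monarda fistulosa", 175, 240, 12, weight_female=1.4, weight_male=0.7),
    PlantSpec("Centaurea stoebe", 170, 270, 15, weight_female=1.0, weight_male=0.5),
    PlantSpec("Cirsium pumilum", 160, 215, 10, weight_female=1.2, weight_male=0.6),
    PlantSpec("Cirsium discolor", 215, 275, 10, weight_female=1.5, weight_male=0.4),
    PlantSpec("Eryngium yuccifolium", 190, 250, 10, weight_female=0.2, weight_male=0.2),
    PlantSpec("Liatris spicata", 200, 255, 10, weight_female=0.15, weight_male=0.15),
)

CONGENERIC_PAIR = ("Cirsium pumilum", "Cirsium discolor")


@dataclass(frozen=True)
class SeasonConfig:
    """Study conditions for the visitation generator.

    Defaults emulate the observed survey: 21 years, weekly surveys over
    ordinal days 153-281, male flight peak two weeks ahead of the female
    peak, roughly 155 feeding observations per sex-year (the long-term
    average), and a modest fraction of thistle records masked to the
    ambiguous congeneric label.
    """

    n_years: int = 21
    first_year: int = 1998
    season_days: tuple[int, int] = SEASON
    survey_interval_days: int = 7
    male_peak_day: float = 180.0
    female_peak_day: float = 194.0
    male_spread: float = 14.0
    female_spread: float = 18.0
    visits_per_sex: float = 155.0
    #: SD (days) of a per-year timing shift shared by both sexes (seasons
    #: run early or late as a whole) and of independent per-sex shifts
    #: (emergence timing drifts between sexes), which drive interannual
    #: variation in the male-female median-date gap and hence in
    #: dissimilarity.
    year_peak_jitter_sd: float = 5.0
    sex_peak_jitter_sd: float = 3.0
    plants: tuple[PlantSpec, ...] = DEFAULT_PLANTS
    ambiguous_label_rate: float = 0.15
    congeneric_pair: tuple[str, str] | None = CONGENERIC_PAIR
    seed: int = 0

    def __post_init__(self):
        if self.male_spread <= 0 or self.female_spread <= 0:
            raise ValueError("flight-curve spreads must be > 0")
        if not 0 <= self.ambiguous_label_rate <= 1:
            raise ValueError("ambiguous_label_rate must be in [0, 1]")
        if not self.plants:
            raise ValueError("need at least one plant")

    def symmetric(self) -> "SeasonConfig":
        """A no-preference, no-phenology-difference variant (null model).

        Both sexes share the male flight curve and every plant's female
        weight, so any detected sex difference is a false positive.
        """
        plants = tuple(
            replace(p, weight_male=p.weight_female) for p in self.plants
        )
        return replace(
            self,
            female_peak_day=self.male_peak_day,
            female_spread=self.male_spread,
            sex_peak_jitter_sd=0.0,  # sexes must share one flight curve
            plants=plants,
            ambiguous_label_rate=0.0,
        )


@dataclass(frozen=True)
class TruthRecord:
    """Generator ground truth accompanying a simulated dataset."""

    counts: pd.DataFrame  # year, sex, plant_species, count (true labels)
    masked: pd.DataFrame  # record row index -> true species of masked records
    preference_divergent: bool  # any plant with unequal sex weights


def _survey_days(cfg: SeasonConfig) -> np.ndarray:
    lo, hi = cfg.season_days
    return np.arange(lo, hi + 1, cfg.survey_interval_days, dtype=np.int64)


def _sex_params(cfg: SeasonConfig, sex: str) -> tuple[float, float]:
    if sex == "F":
        return cfg.female_peak_day, cfg.female_spread
    return cfg.male_peak_day, cfg.male_spread


def _daily_counts(cfg: SeasonConfig, sex: str, days: np.ndarray, rng,
                  peak_shift: float = 0.0) -> np.ndarray:
    """Poisson visit counts per survey day under the truncated flight curve."""
    peak, spread = _sex_params(cfg, sex)
    peak = peak + peak_shift
    w = np.exp(-0.5 * ((days - peak) / spread) ** 2)
    total_w = w.sum()
    if total_w <= 0 or cfg.visits_per_sex <= 0:
        return np.zeros(len(days), dtype=np.int64)
    lam = cfg.visits_per_sex * w / total_w
    return rng.poisson(lam)


def _plant_probs(cfg: SeasonConfig, sex: str, day: int) -> np.ndarray:
    avail = np.array([p.availability(day) for p in cfg.plants], dtype=float)
    pref = np.array(
        [p.weight_female if sex == "F" else p.weight_male for p in cfg.plants]
    )
    w = avail * pref
    total = w.sum()
    return w / total if total > 0 else w


def simulate_year_counts(
    cfg: SeasonConfig, year: int, rng=None
) -> pd.DataFrame:
    """Aggregated draw for one year: rows (day, sex, plant, count).

    This is the sampling core of :func:`simulate_season`; calibration
    studies that only need sex x plant tables use it directly to avoid
    expanding every visit into a record row.
    """
    rng = np.random.default_rng(rng)
    days = _survey_days(cfg)
    names = [p.name for p in cfg.plants]
    shared_shift = rng.normal(0.0, cfg.year_peak_jitter_sd) \
        if cfg.year_peak_jitter_sd > 0 else 0.0
    rows = []
    for sex in ("M", "F"):  # male curve leads; order fixed for determinism
        sex_shift = rng.normal(0.0, cfg.sex_peak_jitter_sd) \
            if cfg.sex_peak_jitter_sd > 0 else 0.0
        counts = _daily_counts(cfg, sex, days, rng,
                               peak_shift=shared_shift + sex_shift)
        for day, n in zip(days, counts):
            if n == 0:
                continue
            probs = _plant_probs(cfg, sex, int(day))
            if probs.sum() <= 0:
                continue  # nothing blooming: no nectaring observed
            picks = rng.multinomial(int(n), probs)
            for j in np.flatnonzero(picks):
                rows.append((year, int(day), sex, names[j], int(picks[j])))
    return pd.DataFrame(
        rows, columns=["year", "ordinal_day", "sex", "plant_species", "count"]
    )


def simulate_season(
    cfg: SeasonConfig, seed: int | None = None
) -> tuple[VisitationDataset, TruthRecord]:
    """Simulate ``cfg.n_years`` seasons of individual feeding observations.

    Each visit becomes one record row with ``count=1`` (the survey records
    individual nectaring events).  Identical seeds give byte-identical
    output; each year consumes its own seeded stream so results are
    independent of year ordering.
    """
    master = cfg.seed if seed is None else seed
    year_frames = []
    for k in range(cfg.n_years):
        year = cfg.first_year + k
        rng = np.random.default_rng([int(master), 11, year])
        year_frames.append(simulate_year_counts(cfg, year, rng))
    agg = (
        pd.concat(year_frames, ignore_index=True)
        if year_frames
        else pd.DataFrame(columns=["year", "ordinal_day", "sex",
                                   "plant_species", "count"])
    )
    truth_counts = (
        agg.groupby(["year", "sex", "plant_species"], as_index=False)["count"]
        .sum()
        .sort_values(["year", "sex", "plant_species"], ignore_index=True)
    )

    # Expand to one row per visit.
    if len(agg):
        expanded = agg.loc[agg.index.repeat(agg["count"])].copy()
        expanded["count"] = 1
        expanded = expanded.reset_index(drop=True)
    else:
        expanded = agg.copy()

    # Mask a fraction of the congeneric pair's records to the ambiguous label.
    masked_rows = []
    if cfg.congeneric_pair is not None and cfg.ambiguous_label_rate > 0 and len(expanded):
        rng = np.random.default_rng([int(master), 13])
        in_pair = expanded["plant_species"].isin(cfg.congeneric_pair).to_numpy()
        mask = in_pair & (rng.random(len(expanded)) < cfg.ambiguous_label_rate)
        for idx in np.flatnonzero(mask):
            masked_rows.append(
                (int(idx), int(expanded.at[idx, "year"]),
                 int(expanded.at[idx, "ordinal_day"]),
                 expanded.at[idx, "sex"], expanded.at[idx, "plant_species"])
            )
        expanded.loc[mask, "plant_species"] = AMBIGUOUS_CIRSIUM
    masked = pd.DataFrame(
        masked_rows,
        columns=["row", "year", "ordinal_day", "sex", "true_species"],
    )

    divergent = any(p.weight_female != p.weight_male for p in cfg.plants)
    ds = VisitationDataset.from_frame(expanded)
    return ds, TruthRecord(counts=truth_counts, masked=masked,
                           preference_divergent=divergent)


# -- nectar panel ----------------------------------------------------------

FOCAL_COMPOUNDS = ("glucose", "fructose", "sucrose", "maltose",
                   "proline", "glycine", "leucine")

#: Synthetic per-species concentration profiles (normalized units): means
#: and SDs chosen so female-associated species are sugar- and amino-acid-
#: richer and variances differ strongly across species (heteroscedastic,
#: as in real nectar panels).
DEFAULT_NECTAR_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "Asclepias syriaca":   {"glucose": (4.0, 1.0), "fructose": (4.5, 1.2),
                            "sucrose": (6.0, 2.0), "maltose": (0.8, 0.3),
                            "proline": (0.6, 0.2), "glycine": (0.3, 0.1),
                            "leucine": (0.2, 0.08)},
    "Asclepias tuberosa":  {"glucose": (5.0, 0.8), "fructose": (5.5, 0.9),
                            "sucrose": (7.0, 1.5), "maltose": (0.9, 0.4),
                            "proline": (0.8, 0.3), "glycine": (0.4, 0.15),
                            "leucine": (0.25, 0.1)},
    "Centaurea stoebe":    {"glucose": (9.0, 2.5), "fructose": (9.5, 2.8),
                            "sucrose": (8.0, 3.0), "maltose": (0.9, 0.5),
                            "proline": (3.5, 1.2), "glycine": (1.2, 0.5),
                            "leucine": (0.8, 0.3)},
    "Cirsium discolor":    {"glucose": (10.0, 1.8), "fructose": (10.5, 2.0),
                            "sucrose": (9.0, 2.2), "maltose": (0.85, 0.35),
                            "proline": (4.0, 0.9), "glycine": (1.5, 0.4),
                            "leucine": (1.0, 0.25)},
    "Cirsium pumilum":     {"glucose": (8.5, 3.0), "fructose": (9.0, 3.2),
                            "sucrose": (7.5, 2.8), "maltose": (0.8, 0.4),
                            "proline": (3.0, 1.5), "glycine": (1.1, 0.6),
                            "leucine": (0.7, 0.35)},
    "Monarda fistulosa":   {"glucose": (7.5, 1.2), "fructose": (8.0, 1.4),
                            "sucrose": (8.5, 1.8), "maltose": (0.75, 0.3),
                            "proline": (2.5, 0.7), "glycine": (0.9, 0.3),
                            "leucine": (0.6, 0.2)},
}

DEFAULT_FEMALE_SPECIES = (
    "Centaurea stoebe", "Cirsium discolor", "Cirsium pumilum",
    "Monarda fistulosa",
)

#: 13 biological replicates per species, 8 for C. discolor (field design).
DEFAULT_N_REPS: dict[str, int] = {"Cirsium discolor": 8}
DEFAULT_REPLICATES = 13


def profiles_frame(
    profiles: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Long-format view of a profiles mapping: species, compound, mean, sd."""
    src = DEFAULT_NECTAR_PROFILES if profiles is None else profiles
    rows = [
        (sp, comp, m, s)
        for sp, comps in src.items()
        for comp, (m, s) in comps.items()
    ]
    return pd.DataFrame(rows, columns=["species", "compound", "mean", "sd"])


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given natural-scale mean/SD."""
    if mean <= 0:
        raise ValueError("log-normal mean must be > 0")
    if sd == 0:
        return float(np.log(mean)), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def simulate_nectar_panel(
    profiles: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    n_reps: Mapping[str, int] | int | None = None,
    seed: int = 0,
    group_shift: float = 0.0,
    shifted_species: Sequence[str] = DEFAULT_FEMALE_SPECIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a long-format nectar panel plus its truth table of means.

    ``group_shift`` adds a constant to the natural-scale mean of every
    compound of the ``shifted_species`` (female-associated by default),
    giving contrast-recovery tests a known effect size.  Returns
    ``(samples, truth)`` where truth holds the effective mean/sd per
    species x compound.
    """
    prof = profiles_frame(profiles)
    if n_reps is None:
        reps = {sp: DEFAULT_N_REPS.get(sp, DEFAULT_REPLICATES)
                for sp in prof["species"].unique()}
    elif isinstance(n_reps, int):
        reps = {sp: n_reps for sp in prof["species"].unique()}
    else:
        reps = {sp: int(n_reps.get(sp, DEFAULT_REPLICATES))
                for sp in prof["species"].unique()}

    rows = []
    truth_rows = []
    for _, row in prof.sort_values(["species", "compound"]).iterrows():
        sp, comp = row["species"], row["compound"]
        mean, sd = float(row["mean"]), float(row["sd"])
        if sp in set(shifted_species):
            mean = mean + group_shift
        truth_rows.append((sp, comp, mean, sd))
        mu, sigma = _lognormal_params(mean, sd)
        # crc32 gives a process-independent per-(species, compound) stream.
        tag = zlib.crc32(f"{sp}|{comp}".encode()) % (2**31)
        rng = np.random.default_rng([int(seed), 17, tag])
        n = reps[sp]
        draws = (np.full(n, mean) if sigma == 0
                 else rng.lognormal(mu, sigma, size=n))
        for i, v in enumerate(draws, start=1):
            rows.append((sp, f"{sp.split()[0][:3]}{sp.split()[-1][:3]}_{i:02d}",
                         comp, float(v)))
    samples = pd.DataFrame(
        rows, columns=["species", "sample_id", "compound", "concentration"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["species", "compound", "true_mean", "true_sd"]
    )
    return samples, truth
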