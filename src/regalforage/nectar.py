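"""Nectar-chemistry contrasts between female- and male-associated plants.

Concentrations are screened for outliers per species x compound (values more
than ``k`` sample standard deviations from the group mean are removed, k = 4
by default).  Each compound is then modeled with species-specific means and
species-specific residual variances -- nectar traits are strongly
heteroscedastic across species -- and the planned contrast

    L = mean(female-associated species means) - mean(male-associated species means)

is tested with F = (L / SE)^2 on 1 and Satterthwaite-approximated
denominator degrees of freedom (the pooled-residual df is reported alongside
for comparison).  Families of compounds (carbohydrates, amino acids) get a
Bonferroni-adjusted alpha of ``family_alpha / family size``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import FEMALE_ASSOCIATED, MALE_ASSOCIATED

#: A-priori compound families (totals are computed, not measured, columns).
CARBOHYDRATE_FAMILY = (
    "glucose", "fructose", "sucrose", "maltose", "total carbohydrates",
)
AMINO_ACID_FAMILY = ("proline", "glycine", "leucine", "total amino acids")

#: Default class membership used when deriving the totals.
DEFAULT_COMPOUND_CLASSES: dict[str, str] = {
    "glucose": "carbohydrate",
    "fructose": "carbohydrate",
    "sucrose": "carbohydrate",
    "maltose": "carbohydrate",
    "proline": "amino acid",
    "glycine": "amino acid",
    "leucine": "amino acid",
    "phenylalanine": "amino acid",
}

TOTAL_BY_CLASS = {
    "carbohydrate": "total carbohydrates",
    "amino acid": "total amino acids",
}


@dataclass(frozen=True)
class OutlierReport:
    removed: pd.DataFrame  # species, sample_id, compound, concentration, z
    k: float

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def remove_outliers(
    samples: pd.DataFrame, k: float = 4.0
) -> tuple[pd.DataFrame, OutlierReport]:
    """Drop values more than ``k`` sample SDs from their group mean.

    The screening group is species x compound; the candidate value is
    included in its own mean/SD.  Groups with fewer than 3 values, or zero
    SD, are never screened.
    """
    df = samples.reset_index(drop=True)
    grp = df.groupby(["species", "compound"])["concentration"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    n = grp.transform("size")
    dev = (df["concentration"] - mean).abs()
    screenable = (n >= 3) & (sd > 0)
    mask = screenable & (dev > k * sd)
    removed = df[mask].copy()
    removed["z_score"] = (dev / sd)[mask]
    return df[~mask].reset_index(drop=True), OutlierReport(
        removed=removed.reset_index(drop=True), k=float(k)
    )


def add_totals(
    samples: pd.DataFrame,
    compound_classes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Append per-sample total rows (one per compound class).

    Totals sum every detected compound of a class within a (species,
    sample_id); compounds absent from ``compound_classes`` contribute to no
    total.  Existing total rows are replaced.
    """
    classes = dict(DEFAULT_COMPOUND_CLASSES if compound_classes is None
                   else compound_classes)
    total_names = set(TOTAL_BY_CLASS.values())
    base = samples[~samples["compound"].isin(total_names)].copy()
    work = base[base["compound"].str.lower().isin(classes)].copy()
    work["_class"] = work["compound"].str.lower().map(classes)
    totals = (
        work.groupby(["species", "sample_id", "_class"], as_index=False)
        ["concentration"].sum()
    )
    totals["compound"] = totals["_class"].map(TOTAL_BY_CLASS)
    totals = totals.drop(columns="_class")
    return pd.concat([base, totals[base.columns.intersection(
        ["species", "sample_id", "compound", "concentration"])]],
        ignore_index=True)


def exclude_sparse_compounds(
    samples: pd.DataFrame, max_missing: float = 0.5
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Drop compounds undetected in more than ``max_missing`` of samples.

    A "sample" is a (species, sample_id) pair present anywhere in the panel;
    a compound is undetected in a sample when it has no row for it.  Mirrors
    the a-priori exclusion of compounds unquantifiable in most replicates.
    """
    universe = samples[["species", "sample_id"]].drop_duplicates()
    n_samples = len(universe)
    detected = samples.groupby("compound")["sample_id"].size()
    sparse = tuple(
        sorted(c for c, n in detected.items() if 1 - n / n_samples > max_missing)
    )
    return samples[~samples["compound"].isin(sparse)].reset_index(drop=True), sparse


@dataclass(frozen=True)
class ContrastResult:
    """Planned female-minus-male group contrast for one compound."""

    compound: str
    estimate: float  # concentration units
    se: float
    f_stat: float
    num_df: int
    den_df: float  # Satterthwaite approximation
    den_df_pooled: float  # sum of (n_i - 1), for comparison
    p_value: float
    group_means: dict[str, float]
    excluded_species: tuple[str, ...] = ()
    alpha_adjusted: float | None = None
    significant: bool | None = None


def group_contrast(
    samples: pd.DataFrame,
    compound: str,
    labels: Mapping[str, str],
    min_replicates: int = 2,
) -> ContrastResult:
    """Heterogeneous-variance contrast of female- vs male-associated species.

    Weights are +1/n_F on each female-associated species mean and -1/n_M on
    each male-associated one, so the estimate is the difference of the two
    group averages of species means.  SE uses species-specific variances
    (Welch-Satterthwaite), matching a model with species as fixed effect and
    a separate residual variance per species.
    """
    sub = samples[samples["compound"].str.casefold() == compound.casefold()]
    if sub.empty:
        raise ValueError(f"no samples for compound {compound!r}")
    stats_df = (
        sub.groupby("species")["concentration"]
        .agg(n="size", mean="mean", var=lambda v: v.var(ddof=1))
    )
    excluded = tuple(sorted(stats_df.index[stats_df["n"] < min_replicates]))
    if excluded:
        warnings.warn(
            f"{compound}: species with < {min_replicates} replicates excluded "
            f"from the contrast: {excluded}",
            UserWarning,
            stacklevel=2,
        )
        stats_df = stats_df[stats_df["n"] >= min_replicates]

    fem = sorted(s for s in stats_df.index if labels.get(s) == FEMALE_ASSOCIATED)
    mal = sorted(s for s in stats_df.index if labels.get(s) == MALE_ASSOCIATED)
    if len(fem) < 1 or len(mal) < 1:
        raise ValueError(
            f"{compound}: need >=1 species per group "
            f"(female={fem}, male={mal})"
        )
    weights = {s: 1.0 / len(fem) for s in fem}
    weights.update({s: -1.0 / len(mal) for s in mal})

    est = sum(w * stats_df.loc[s, "mean"] for s, w in weights.items())
    comps = np.array([
        weights[s] ** 2 * stats_df.loc[s, "var"] / stats_df.loc[s, "n"]
        for s in weights
    ])
    var = float(comps.sum())
    dfs = np.array([stats_df.loc[s, "n"] - 1 for s in weights], dtype=float)
    den_df_pooled = float(dfs.sum())
    if var > 0:
        den_df = float(var**2 / np.sum(comps**2 / dfs))
        f_stat = float(est**2 / var)
        p = float(stats.f.sf(f_stat, 1, den_df))
    else:  # all within-species variances zero
        den_df = den_df_pooled
        f_stat = float("inf") if est != 0 else 0.0
        p = 0.0 if est != 0 else 1.0
    group_means = {
        FEMALE_ASSOCIATED: float(np.mean([stats_df.loc[s, "mean"] for s in fem])),
        MALE_ASSOCIATED: float(np.mean([stats_df.loc[s, "mean"] for s in mal])),
    }
    return ContrastResult(
        compound=compound, estimate=float(est), se=float(np.sqrt(var)),
        f_stat=f_stat, num_df=1, den_df=den_df, den_df_pooled=den_df_pooled,
        p_value=p, group_means=group_means, excluded_species=excluded,
    )


def bonferroni_family(
    results: Sequence[ContrastResult], family_alpha: float = 0.05
) -> list[ContrastResult]:
    """Set ``alpha_adjusted = family_alpha / len(family)`` on every result."""
    if not results:
        raise ValueError("empty contrast family")
    alpha = family_alpha / len(results)
    return [
        dataclasses.replace(r, alpha_adjusted=alpha,
                            significant=bool(r.p_value < alpha))
        for r in results
    ]
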