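"""Pooled chi-squared test of sex x plant visitation and species labeling.

Dissimilarity says *that* the sexes forage differently; the chi-squared
analysis of the pooled sex x plant table says *which* plants drive the
difference.  Pearson residuals (O - E) / sqrt(E) give each cell's signed
deviation from independence; a plant whose female-row residual exceeds +2
is labeled female-associated, below -2 male-associated, otherwise neutral
(2 approximates a standard-normal criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import VisitationDataset
from .dissimilarity import SexPlantTable

FEMALE_ASSOCIATED = "female_associated"
MALE_ASSOCIATED = "male_associated"
NEUTRAL = "neutral"


def most_visited(ds: VisitationDataset, n: int) -> tuple[str, ...]:
    """The ``n`` species with the greatest pooled visit totals."""
    totals = ds.records.groupby("plant_species")["count"].sum()
    return tuple(totals.sort_values(ascending=False, kind="stable").index[:n])


def pooled_table(
    ds: VisitationDataset,
    years: Iterable[int] | None = None,
    species: Iterable[str] | None = None,
) -> SexPlantTable:
    """Sex x plant table pooled over ``years`` (default: all years).

    ``species`` optionally restricts the columns (e.g. the six most visited
    plants) before margins are formed.
    """
    df = ds.records
    if years is not None:
        df = df[df["year"].isin(list(years))]
    if species is not None:
        df = df[df["plant_species"].isin(list(species))]
    table = (
        df.pivot_table(index="sex", columns="plant_species", values="count",
                       aggfunc="sum", fill_value=0)
        .reindex(index=["F", "M"], fill_value=0)
    )
    table.index.name = None
    table.columns.name = None
    table = table.loc[:, table.sum(axis=0) > 0]
    return SexPlantTable(table.astype(np.int64))


@dataclass
class AssociationResult:
    table: SexPlantTable
    chi2: float
    df: int
    p_value: float
    expected: pd.DataFrame = field(repr=False)
    pearson_residuals: pd.DataFrame = field(repr=False)
    species_labels: dict[str, str]
    low_expected_cells: tuple[tuple[str, str], ...] = ()


def chi_squared_association(
    table: SexPlantTable,
    min_expected: float = 5.0,
    residual_threshold: float = 2.0,
) -> AssociationResult:
    """Pearson chi-squared test of independence on a sex x plant table.

    No continuity correction (the table is 2 x S with large counts).
    Expected cells below ``min_expected`` are listed in a warning but the
    test is still computed.
    """
    obs = table.data.to_numpy(dtype=float)
    if obs.sum() <= 0 or (obs.sum(axis=1) <= 0).any():
        raise ValueError("both sex rows must have positive totals")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    resid = (obs - expected) / np.sqrt(expected)
    resid_df = pd.DataFrame(resid, index=["F", "M"], columns=table.species)
    expected_df = pd.DataFrame(expected, index=["F", "M"], columns=table.species)

    low = tuple(
        (row, col)
        for i, row in enumerate(["F", "M"])
        for j, col in enumerate(table.species)
        if expected[i, j] < min_expected
    )
    if low:
        warnings.warn(
            f"{len(low)} expected cell(s) below {min_expected}: {low}",
            UserWarning,
            stacklevel=2,
        )

    labels = {}
    for sp in table.species:
        r = resid_df.loc["F", sp]
        if r > residual_threshold:
            labels[sp] = FEMALE_ASSOCIATED
        elif r < -residual_threshold:
            labels[sp] = MALE_ASSOCIATED
        else:
            labels[sp] = NEUTRAL
    return AssociationResult(
        table=table, chi2=float(chi2), df=int(df), p_value=float(p),
        expected=expected_df, pearson_residuals=resid_df,
        species_labels=labels, low_expected_cells=low,
    )
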