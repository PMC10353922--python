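"""Morisita-Horn dissimilarity between sexes and its Patefield null model.

For each year the visits form a 2 x S contingency table (rows F/M, columns
plant species).  The observed dissimilarity between the two row assemblages

    d_mh(x, y) = 1 - 2 sum_i x_i y_i / [(sum x_i^2/X^2 + sum y_i^2/Y^2) X Y]

is compared with the permutation null induced by randomly re-pairing visit
sex labels with plant labels while keeping every row and column total fixed
(Patefield's algorithm for random two-way tables with given margins).  The
observed value is classified against the percentile 95% interval of the
null replicates: *above* (more dissimilar than random re-pairing), *within*,
or *below* (sexes more similar than expected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import VisitationDataset


class OneSexAbsentError(ValueError):
    """A year lacks records of one sex; dissimilarity is not computable."""


@dataclass(frozen=True)
class SexPlantTable:
    """2 x S visit-count table, rows ``F`` and ``M``, columns plant species."""

    data: pd.DataFrame

    def __post_init__(self):
        if list(self.data.index) != ["F", "M"]:
            raise ValueError("rows must be exactly ['F', 'M']")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative cell counts")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def row_margins(self) -> np.ndarray:
        return self.data.to_numpy().sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.data.to_numpy().sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.data.to_numpy().sum())


def year_table(ds: VisitationDataset, year: int) -> SexPlantTable:
    """Sex x plant visit-count table for one year.

    Species unvisited by both sexes that year are omitted.  Raises
    :class:`OneSexAbsentError` when either sex has no records (the year is
    non-computable for dissimilarity).
    """
    df = ds.year_records(year)
    table = (
        df.pivot_table(index="sex", columns="plant_species", values="count",
                       aggfunc="sum", fill_value=0)
        .reindex(index=["F", "M"], fill_value=0)
    )
    table.index.name = None
    table.columns.name = None
    if table.to_numpy().sum(axis=1).min() == 0 or table.shape[1] == 0:
        raise OneSexAbsentError(f"year {year} lacks records of one sex")
    table = table.loc[:, table.sum(axis=0) > 0]
    return SexPlantTable(table.astype(np.int64))


def morisita_horn(x, y) -> float:
    """Abundance-based Morisita-Horn dissimilarity in [0, 1].

    0 means identical relative composition, 1 means no shared species.  The
    index is symmetric and invariant to proportional rescaling of either
    count vector.  The result is clamped to [0, 1] against rounding.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("assemblages must share species indexing")
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("morisita_horn undefined for an empty assemblage")
    num = 2.0 * float(x @ y)
    den = ((x @ x) / X**2 + (y @ y) / Y**2) * X * Y
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def _morisita_horn_rows(F: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Vectorized d_mh over paired rows of two (n, S) count matrices."""
    F = np.asarray(F, dtype=float)
    M = np.asarray(M, dtype=float)
    X = F.sum(axis=1)
    Y = M.sum(axis=1)
    num = 2.0 * np.einsum("ij,ij->i", F, M)
    den = ((F * F).sum(axis=1) / X**2 + (M * M).sum(axis=1) / Y**2) * X * Y
    return np.clip(1.0 - num / den, 0.0, 1.0)


def patefield_sample(row_margins, col_margins, rng=None) -> np.ndarray:
    """One random R x C table with the given margins (permutation null).

    Rows are filled sequentially by conditional multivariate-hypergeometric
    draws from the remaining column totals, which yields the generalized
    hypergeometric distribution over tables -- the distribution induced by
    randomly re-pairing individual visit sex labels with plant labels.
    """
    rng = np.random.default_rng(rng)
    rows = np.asarray(row_margins, dtype=np.int64)
    cols = np.asarray(col_margins, dtype=np.int64)
    if rows.sum() != cols.sum():
        raise ValueError("row and column margin sums differ")
    out = np.empty((len(rows), len(cols)), dtype=np.int64)
    remaining = cols.copy()
    for i, r in enumerate(rows[:-1]):
        out[i] = rng.multivariate_hypergeometric(remaining, int(r))
        remaining = remaining - out[i]
    out[-1] = remaining
    return out


def _patefield_first_rows(col_margins, n_first: int, n_reps: int, rng) -> np.ndarray:
    """(n_reps, S) first rows of random 2-row tables with fixed margins."""
    cols = np.asarray(col_margins, dtype=np.int64)
    return rng.multivariate_hypergeometric(cols, int(n_first), size=n_reps)


@dataclass(frozen=True)
class NullTestResult:
    observed_dmh: float
    null_values: np.ndarray = field(repr=False)
    ci_lower: float
    ci_upper: float
    classification: str  # above | within | below
    n_reps: int
    seed: int | None


def null_test(
    table: SexPlantTable,
    n_reps: int = 1000,
    ci_level: float = 0.95,
    rng=None,
    ci_method: str = "percentile",
) -> NullTestResult:
    """Observed d_mh against ``n_reps`` Patefield null tables.

    The interval is the percentile interval of the null replicates by
    default (linear-interpolation quantiles at (1-level)/2 and
    (1+level)/2); ``ci_method='sd'`` uses a normal approximation around the
    null mean instead.  A degenerate single-species table yields CI [0, 0]
    and classification ``within``.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    if ci_method not in ("percentile", "sd"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    obs_F, obs_M = table.data.to_numpy()
    if table.row_margins.min() <= 0:
        raise OneSexAbsentError("both row margins must be positive")
    observed = morisita_horn(obs_F, obs_M)
    S = table.data.shape[1]
    if S == 1:
        null_values = np.zeros(n_reps)
        return NullTestResult(observed, null_values, 0.0, 0.0, "within",
                              n_reps, seed)
    n_F = int(table.row_margins[0])
    cols = table.col_margins
    F = _patefield_first_rows(cols, n_F, n_reps, rng)
    M = cols[None, :] - F
    null_values = _morisita_horn_rows(F, M)
    if ci_method == "percentile":
        lo, hi = np.quantile(
            null_values, [(1 - ci_level) / 2, (1 + ci_level) / 2]
        )
    else:
        from scipy import stats as _stats

        z = _stats.norm.ppf((1 + ci_level) / 2)
        mu, sd = null_values.mean(), null_values.std(ddof=1)
        lo, hi = mu - z * sd, mu + z * sd
    if observed > hi:
        cls = "above"
    elif observed < lo:
        cls = "below"
    else:
        cls = "within"
    return NullTestResult(observed, null_values, float(lo), float(hi), cls,
                          n_reps, seed)


def yearly_null_tests(
    ds: VisitationDataset,
    n_reps: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    ci_method: str = "percentile",
) -> dict[int, NullTestResult | None]:
    """Null test per year; ``None`` marks years with one sex absent.

    Each year draws from its own seeded stream (derived from the master seed
    and the year), so per-year results do not depend on year ordering.
    """
    out: dict[int, NullTestResult | None] = {}
    for year in ds.years:
        try:
            table = year_table(ds, year)
        except OneSexAbsentError:
            out[year] = None
            continue
        rng = np.random.default_rng([seed, 101, year])
        out[year] = null_test(table, n_reps=n_reps, ci_level=ci_level,
                              rng=rng, ci_method=ci_method)
    return out
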