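"""Per sex-year diversity of visited plants and the paired sex comparison.

Richness counts the plant species a sex visited in a year; the effective
species number (ESN, Hill number of order 1) is exp of the Shannon entropy
of the visit proportions and reads as "the number of equally visited species
that would give the same entropy".  ESN is comparable across groups where
the raw entropy is not, which is why the sex contrast is run on it.

The sex contrast is a linear mixed model ``metric ~ sex + (1 | year)``:
sex as fixed effect, year as random intercept to absorb the within-year
pairing of the male and female values.  Residual autocorrelation across
years is screened with the sample ACF and a Durbin-Watson statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson
from statsmodels.tsa.stattools import acf as _acf

from .io import VisitationDataset

log = logging.getLogger(__name__)

METRICS = ("richness", "effective_species_number")


def build_assemblage(ds: VisitationDataset, year: int, sex: str) -> pd.Series:
    """Visit counts per plant species for one sex-year (may be empty)."""
    df = ds.year_records(year)
    df = df[df["sex"] == sex]
    counts = df.groupby("plant_species")["count"].sum().sort_index()
    counts.name = f"{year}-{sex}"
    return counts


def diversity_metrics(counts) -> dict[str, float]:
    """Richness, Shannon entropy (natural log) and ESN of an assemblage.

    H = -sum p_i ln p_i with p_i = x_i / X and 0 ln 0 = 0; ESN = exp(H).
    """
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    total = x.sum()
    if total <= 0:
        raise ValueError("diversity metrics undefined for an empty assemblage")
    h = float(stats.entropy(x / total))  # natural log
    return {
        "richness": int(len(x)),
        "shannon_H": h,
        "effective_species_number": float(np.exp(h)),
    }


def diversity_table(ds: VisitationDataset) -> pd.DataFrame:
    """Metrics for every sex-year with at least one record."""
    rows = []
    for year in ds.years:
        for sex in ("F", "M"):
            counts = build_assemblage(ds, year, sex)
            if counts.sum() == 0:
                continue
            rows.append({"year": year, "sex": sex, **diversity_metrics(counts)})
    return pd.DataFrame(rows)


@dataclass
class MixedModelResult:
    """Female-minus-male effect on a diversity metric across paired years."""

    metric: str
    sex_effect: float
    se: float
    t_stat: float
    p_value: float
    n_years: int
    df_residual: float
    method: str  # "mixed_reml" or "paired_t" (singular-fit fallback)
    n_years_female_greater: int
    residuals: pd.DataFrame = field(repr=False)  # year, sex, resid


def paired_sex_comparison(
    metrics: pd.DataFrame, metric: str
) -> MixedModelResult:
    """REML mixed model ``metric ~ sex + (1|year)`` on years with both sexes.

    Falls back to a paired t-test (with a logged notice) when the
    between-year variance estimate collapses to zero, where the mixed model
    is singular and the paired test is the identical inference.
    """
    if metric not in metrics.columns:
        raise KeyError(metric)
    wide = metrics.pivot(index="year", columns="sex", values=metric)
    wide = wide.dropna(subset=["F", "M"]) if {"F", "M"} <= set(wide.columns) else wide.iloc[0:0]
    if len(wide) < 3:
        raise ValueError(
            f"need >=3 years with both sexes for {metric}, got {len(wide)}"
        )
    long = (
        wide.reset_index()
        .melt(id_vars="year", value_vars=["F", "M"], value_name="value")
        .sort_values(["year", "sex"], ignore_index=True)
    )
    long["is_female"] = (long["sex"] == "F").astype(float)
    n_greater = int((wide["F"] > wide["M"]).sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            long["value"].to_numpy(),
            sm.add_constant(long["is_female"].to_numpy()),
            groups=long["year"].to_numpy(),
        )
        try:
            fit = model.fit(reml=True)
            singular = (not fit.converged) or float(np.asarray(fit.cov_re)[0, 0]) < 1e-8
        except Exception:  # pragma: no cover - numerical failure path
            fit, singular = None, True

    if not singular:
        effect = float(fit.params[1])
        se = float(fit.bse[1])
        resid = long.assign(resid=np.asarray(fit.resid))[["year", "sex", "resid"]]
        return MixedModelResult(
            metric=metric, sex_effect=effect, se=se,
            t_stat=effect / se, p_value=float(fit.pvalues[1]),
            n_years=len(wide), df_residual=float(len(long) - 2 - len(wide) + 1),
            method="mixed_reml", n_years_female_greater=n_greater,
            residuals=resid,
        )

    log.info("singular mixed fit for %s; falling back to paired t-test", metric)
    diff = (wide["F"] - wide["M"]).to_numpy(dtype=float)
    n = len(diff)
    effect = float(diff.mean())
    se = float(diff.std(ddof=1) / np.sqrt(n))
    if se == 0.0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = effect / se
        p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
    resid_vals = np.concatenate([diff - effect, np.zeros(0)])
    resid = pd.DataFrame({
        "year": wide.index.to_numpy(), "sex": "F-M", "resid": resid_vals,
    })
    return MixedModelResult(
        metric=metric, sex_effect=effect, se=se, t_stat=t_stat, p_value=p,
        n_years=n, df_residual=float(n - 1), method="paired_t",
        n_years_female_greater=n_greater, residuals=resid,
    )


@dataclass(frozen=True)
class TimeDiagnostics:
    acf: np.ndarray  # lags 1..nlags
    durbin_watson: float
    nlags: int


def residual_time_diagnostics(
    residuals, nlags: int | None = None
) -> TimeDiagnostics:
    """Sample ACF (lags 1..min(15, n-2)) and Durbin-Watson statistic.

    Accepts a raw residual sequence or a :class:`MixedModelResult`, in which
    case the per-year mean residuals (ordered by year) are used so the series
    has one value per time step.
    """
    if isinstance(residuals, MixedModelResult):
        series = (
            residuals.residuals.groupby("year")["resid"].mean().sort_index()
        ).to_numpy()
    else:
        series = np.asarray(residuals, dtype=float)
    n = len(series)
    if n < 2:
        raise ValueError("need >=2 residuals")
    if nlags is None:
        nlags = min(15, n - 2)
    nlags = max(nlags, 0)
    dw = float(durbin_watson(series))
    if nlags == 0 or np.allclose(series, series[0]):
        rho = np.full(nlags, np.nan)
    else:
        rho = _acf(series, nlags=nlags, fft=False)[1:]
    return TimeDiagnostics(acf=rho, durbin_watson=dw, nlags=nlags)
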