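"""Domain types, CSV readers/writers and validation for visitation and nectar tables.

The universal input of the pipeline is a long-format table of nectaring
observations: one row per feeding event (or per pre-aggregated group of
events), with the calendar year, the ordinal day (January 1 = day 1), the
butterfly's sex (``F``/``M``) and the nectar plant species.  Congeneric
thistles may carry the ambiguous label ``"Cirsium spp."`` until the
phenology classifier assigns them (see :mod:`regalforage.taxon`).

Nectar metabolite panels are long-format as well: one row per
(species, biological replicate, compound) with a normalized concentration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEXES = ("F", "M")

#: Ambiguous congeneric label allowed prior to phenology-based assignment.
AMBIGUOUS_CIRSIUM = "Cirsium spp."

VISIT_COLUMNS = ("year", "ordinal_day", "sex", "plant_species")
NECTAR_COLUMNS = ("species", "sample_id", "compound", "concentration")


class ConfigurationError(ValueError):
    """Input file or dialect does not match the expected schema."""


class ValidationError(ValueError):
    """Rows violate the data model's invariants; message names the rows."""


def normalize_label(label: object) -> str:
    """Whitespace-normalize a species label (strip + collapse internal runs).

    Labels are *compared* case-insensitively downstream; the canonical
    spelling is the first form encountered.  Two decades of hand-entered
    field data motivate the tolerance.
    """
    return " ".join(str(label).split())


def is_ambiguous_label(label: str) -> bool:
    return normalize_label(label).casefold() == AMBIGUOUS_CIRSIUM.casefold()


def _canonicalize_species(series: pd.Series) -> tuple[pd.Series, tuple[str, ...]]:
    """Map labels to canonical spellings (first-seen per casefolded key)."""
    canonical: dict[str, str] = {}
    out = []
    for raw in series:
        norm = normalize_label(raw)
        key = norm.casefold()
        canonical.setdefault(key, norm)
        out.append(canonical[key])
    return pd.Series(out, index=series.index, dtype="object"), tuple(
        sorted(canonical.values())
    )


@dataclass(frozen=True)
class VisitationDataset:
    """Long-format feeding observations plus the species catalog.

    ``records`` columns: ``year``, ``ordinal_day``, ``sex``, ``plant_species``,
    ``count`` (positive integer weight; defaults to 1 per observed event) and
    optionally ``assigned`` (True where an ambiguous label was relabeled by
    the phenology classifier).
    """

    records: pd.DataFrame
    species_catalog: tuple[str, ...]
    year_range: tuple[int, int]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VisitationDataset":
        df = frame.copy()
        missing = [c for c in VISIT_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing required columns: {missing}")
        if "count" not in df.columns:
            df["count"] = 1
        df["count"] = df["count"].fillna(1)

        problems: list[str] = []

        def _flag(mask: pd.Series, what: str) -> None:
            if mask.any():
                rows = list(df.index[mask][:10])
                problems.append(f"{what} (rows {rows}{'...' if mask.sum() > 10 else ''})")

        for col in ("year", "ordinal_day", "count"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            _flag(coerced.isna() | (coerced != coerced.round()), f"non-integer {col}")
            df[col] = coerced

        sex = df["sex"].astype(str).str.strip().str.upper().str[:1]
        _flag(~sex.isin(SEXES), "sex not in {F, M}")
        if not problems:
            _flag((df["ordinal_day"] < 1) | (df["ordinal_day"] > 366),
                  "ordinal_day outside 1..366")
            _flag(df["count"] < 1, "count < 1")
        if problems:
            raise ValidationError("; ".join(problems))

        df["sex"] = sex
        for col in ("year", "ordinal_day", "count"):
            df[col] = df[col].astype(np.int64)
        df["plant_species"], catalog = _canonicalize_species(df["plant_species"])
        if "assigned" not in df.columns:
            df["assigned"] = False
        df = df.reset_index(drop=True)
        if len(df):
            year_range = (int(df["year"].min()), int(df["year"].max()))
        else:
            year_range = (0, 0)
        return cls(records=df, species_catalog=catalog, year_range=year_range)

    # -- conveniences -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_visits(self) -> int:
        return int(self.records["count"].sum()) if len(self.records) else 0

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.records["year"].unique()))

    @property
    def n_ambiguous(self) -> int:
        if not len(self.records):
            return 0
        return int(
            self.records["plant_species"].map(is_ambiguous_label).sum()
        )

    def year_records(self, year: int) -> pd.DataFrame:
        return self.records[self.records["year"] == year]

    def replace_records(self, frame: pd.DataFrame) -> "VisitationDataset":
        return VisitationDataset.from_frame(frame)


@dataclass
class ValidationReport:
    """Report-only summary: totals, flagged oddities; never raises."""

    n_records: int
    total_visits: int
    counts_by_sex_year: pd.DataFrame  # columns: year, sex, n_records, visits
    n_ambiguous: int
    n_duplicate_rows: int
    unknown_species: tuple[str, ...]

    def summary(self) -> str:
        lines = [
            f"records: {self.n_records} (total visit weight {self.total_visits})",
            f"ambiguous '{AMBIGUOUS_CIRSIUM}' records awaiting assignment: {self.n_ambiguous}",
            f"duplicate rows (legal, flagged only): {self.n_duplicate_rows}",
        ]
        if self.unknown_species:
            lines.append(f"species outside catalog: {list(self.unknown_species)}")
        return "\n".join(lines)


def read_visitation(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> VisitationDataset:
    """Read a visitation CSV.

    ``dialect`` maps standard column names (``year``, ``ordinal_day``, ``sex``,
    ``plant_species``, ``count``) to the file's actual headers, absorbing
    whatever schema a deposited dataset uses.
    """
    raw = pd.read_csv(path)
    if dialect:
        rename = {src: std for std, src in dialect.items() if src in raw.columns}
        missing = [std for std, src in dialect.items()
                   if src not in raw.columns and std in VISIT_COLUMNS]
        if missing:
            raise ConfigurationError(
                f"dialect names columns absent from {path}: {missing}"
            )
        raw = raw.rename(columns=rename)
    return VisitationDataset.from_frame(raw)


def write_visitation(ds: VisitationDataset, path: str | Path) -> None:
    cols = ["year", "ordinal_day", "sex", "plant_species", "count"]
    if ds.records["assigned"].any():
        cols.append("assigned")
    ds.records[cols].to_csv(path, index=False)


def validate_dataset(ds: VisitationDataset) -> ValidationReport:
    """Summarize a dataset; duplicates are flagged, never removed."""
    df = ds.records
    if len(df):
        by = (
            df.groupby(["year", "sex"], as_index=False)
            .agg(n_records=("count", "size"), visits=("count", "sum"))
        )
        dupes = int(df.duplicated(subset=list(VISIT_COLUMNS) + ["count"]).sum())
        unknown = tuple(
            sorted(
                set(df["plant_species"]) - set(ds.species_catalog)
            )
        )
    else:
        by = pd.DataFrame(columns=["year", "sex", "n_records", "visits"])
        dupes = 0
        unknown = ()
    return ValidationReport(
        n_records=len(df),
        total_visits=ds.total_visits,
        counts_by_sex_year=by,
        n_ambiguous=ds.n_ambiguous,
        n_duplicate_rows=dupes,
        unknown_species=unknown,
    )


# -- nectar tables ---------------------------------------------------------

def read_nectar(path: str | Path) -> pd.DataFrame:
    """Read a long-format nectar panel and validate its invariants."""
    df = pd.read_csv(path)
    missing = [c for c in NECTAR_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")
    return validate_nectar(df)


def validate_nectar(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["species"], _ = _canonicalize_species(df["species"])
    df["compound"] = df["compound"].map(normalize_label)
    df["concentration"] = pd.to_numeric(df["concentration"])
    if (df["concentration"] < 0).any():
        bad = list(df.index[df["concentration"] < 0][:10])
        raise ValidationError(f"negative concentrations (rows {bad})")
    key = ["species", "sample_id", "compound"]
    if df.duplicated(subset=key).any():
        bad = df[df.duplicated(subset=key, keep=False)].sort_values(key)
        raise ValidationError(
            f"duplicate (species, sample_id, compound) keys:\n{bad.head(10)}"
        )
    return df.reset_index(drop=True)


def write_nectar(df: pd.DataFrame, path: str | Path) -> None:
    df[list(NECTAR_COLUMNS)].to_csv(path, index=False)
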