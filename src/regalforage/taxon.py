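"""Phenology-based assignment of ambiguous congeneric records.

Field observers sometimes record a thistle visit only as ``"Cirsium spp."``
even though two species with well-separated flowering phenologies occur on
the landscape (*Cirsium pumilum* blooms early, *C. discolor* late).  With a
single feature (ordinal day) any maximum-margin linear classifier reduces to
a day threshold, so the assignment stage fits a 1-D hard-margin rule on the
unambiguous records and relabels the ambiguous ones deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import VisitationDataset, is_ambiguous_label, normalize_label

DEFAULT_SPECIES_PAIR = ("Cirsium pumilum", "Cirsium discolor")

#: Half-width (days) of the neighbourhood used to break exact boundary ties.
TIE_WINDOW_DAYS = 7


class FittingError(ValueError):
    """Training data cannot support a two-class rule."""


@dataclass(frozen=True)
class PhenoClassifier:
    """Day-threshold classifier between an early- and a late-blooming species.

    ``boundary`` is the decision threshold in ordinal days: days strictly
    below go to ``early_species``, strictly above to ``late_species``, and a
    day exactly on the boundary goes to ``tie_label`` (the class with the
    greater training weight within +-7 days of the boundary).
    """

    boundary: float
    early_species: str
    late_species: str
    tie_label: str
    separable: bool
    training_summary: dict = field(default_factory=dict)

    def predict_day(self, day: float) -> str:
        if day < self.boundary:
            return self.early_species
        if day > self.boundary:
            return self.late_species
        return self.tie_label

    def predict(self, days) -> np.ndarray:
        days = np.asarray(days, dtype=float)
        out = np.where(days < self.boundary, self.early_species, self.late_species)
        out = np.where(days == self.boundary, self.tie_label, out)
        return out.astype(object)


def _class_days(ds: VisitationDataset, species: str) -> np.ndarray:
    key = normalize_label(species).casefold()
    df = ds.records
    mask = df["plant_species"].str.casefold() == key
    return np.repeat(df.loc[mask, "ordinal_day"].to_numpy(),
                     df.loc[mask, "count"].to_numpy())


def fit_phenology_classifier(
    ds: VisitationDataset,
    species_pair: tuple[str, str] = DEFAULT_SPECIES_PAIR,
) -> PhenoClassifier:
    """Fit the day-threshold rule on unambiguous records of the two species.

    Separable classes get the exact hard-margin boundary (midpoint of the
    closest pair of training days).  Overlapping classes get the threshold
    minimizing weighted training error, ties broken by proximity to the
    midpoint of the class means.  Identical day distributions trigger a
    degenerate-margin warning and the midpoint boundary with the tie rule.
    """
    a_days = _class_days(ds, species_pair[0])
    b_days = _class_days(ds, species_pair[1])
    if len(a_days) == 0 or len(b_days) == 0:
        raise FittingError(
            f"need >=1 unambiguous record of each of {species_pair}; "
            f"got {len(a_days)} and {len(b_days)}"
        )
    # Order classes by mean day: the earlier-flowering one is "early".
    if a_days.mean() <= b_days.mean():
        early_name, late_name = species_pair
        early, late = a_days, b_days
    else:
        early_name, late_name = species_pair[1], species_pair[0]
        early, late = b_days, a_days

    summary = {
        "early_species": early_name,
        "early_mean": float(early.mean()),
        "early_sd": float(early.std(ddof=0)),
        "early_n": int(len(early)),
        "late_species": late_name,
        "late_mean": float(late.mean()),
        "late_sd": float(late.std(ddof=0)),
        "late_n": int(len(late)),
    }

    if early.max() < late.min():
        boundary = (early.max() + late.min()) / 2.0
        separable = True
    elif early.min() == early.max() == late.min() == late.max():
        warnings.warn(
            "degenerate margin: both classes concentrate on day "
            f"{int(early.min())}; using that day as the boundary with the "
            "local-frequency tie rule",
            UserWarning,
            stacklevel=2,
        )
        boundary = float(early.min())
        separable = False
    else:
        boundary, separable = _best_overlapping_threshold(early, late), False

    tie_label = _tie_label(early_name, late_name, early, late, boundary)
    return PhenoClassifier(
        boundary=float(boundary),
        early_species=early_name,
        late_species=late_name,
        tie_label=tie_label,
        separable=separable,
        training_summary=summary,
    )


def _best_overlapping_threshold(early: np.ndarray, late: np.ndarray) -> float:
    """Threshold minimizing 0-1 training error; deterministic tie-break."""
    days = np.unique(np.concatenate([early, late]))
    candidates = np.concatenate(
        [[days[0] - 0.5], (days[:-1] + days[1:]) / 2.0, [days[-1] + 0.5]]
    )
    errors = np.array(
        [np.sum(early >= t) + np.sum(late < t) for t in candidates], dtype=float
    )
    best = errors == errors.min()
    target = (early.mean() + late.mean()) / 2.0
    # Among minimal-error thresholds prefer the one nearest the mean midpoint.
    idx = np.argmin(np.abs(candidates - target) + np.where(best, 0, np.inf))
    return float(candidates[idx])


def _tie_label(
    early_name: str, late_name: str,
    early: np.ndarray, late: np.ndarray, boundary: float,
) -> str:
    lo, hi = boundary - TIE_WINDOW_DAYS, boundary + TIE_WINDOW_DAYS
    n_early = int(np.sum((early >= lo) & (early <= hi)))
    n_late = int(np.sum((late >= lo) & (late <= hi)))
    return early_name if n_early >= n_late else late_name


def assign_ambiguous(
    ds: VisitationDataset, clf: PhenoClassifier
) -> VisitationDataset:
    """Relabel every ambiguous record via the classifier.

    Record count is conserved; only the species field of ambiguous records
    changes, and those records carry ``assigned=True`` as provenance.
    """
    df = ds.records.copy()
    mask = df["plant_species"].map(is_ambiguous_label)
    if not mask.any():
        return ds
    df.loc[mask, "plant_species"] = clf.predict(df.loc[mask, "ordinal_day"])
    df.loc[mask, "assigned"] = True
    return VisitationDataset.from_frame(df)
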