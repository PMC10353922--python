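"""End-to-end orchestration: assignment, full-season and overlap analyses.

``run_pipeline`` executes the stages in order -- ambiguous-record
assignment, full-season dissimilarity/diversity/association, overlap-window
detection and the same analyses on the restricted dataset, the
dissimilarity-vs-median-gap regression, and (when a nectar panel is given)
outlier screening, heterogeneous-variance contrasts and Bonferroni
families -- and returns a :class:`ReportBundle` that can be written as
diffable TSV files plus a JSON bundle.  Reports contain no wall-clock
content, so identical inputs and seed produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (VisitationDataset, read_nectar, read_visitation,
                 validate_dataset)
from .taxon import fit_phenology_classifier, assign_ambiguous
from .phenology import (OverlapWindow, median_gap_regression, overlap_windows,
                        restrict_to_overlap)
from .diversity import (METRICS, diversity_table, paired_sex_comparison,
                        residual_time_diagnostics)
from .dissimilarity import yearly_null_tests
from .association import (chi_squared_association, most_visited, pooled_table)
from .nectar import (AMINO_ACID_FAMILY, CARBOHYDRATE_FAMILY, add_totals,
                     bonferroni_family, exclude_sparse_compounds,
                     group_contrast, remove_outliers)

log = logging.getLogger(__name__)

DEFAULT_FAMILIES: dict[str, tuple[str, ...]] = {
    "carbohydrates": CARBOHYDRATE_FAMILY,
    "amino_acids": AMINO_ACID_FAMILY,
}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    visits_csv: str | None = None
    nectar_csv: str | None = None
    out_dir: str | None = None
    seed: int = 0
    n_reps: int = 1000
    ci_level: float = 0.95
    overlap_lower: float = 0.25
    overlap_upper: float = 0.75
    min_overlap_days: int = 4
    overlap_rule: str = "caption"
    residual_threshold: float = 2.0
    n_focal_species: int = 6
    outlier_k: float = 4.0
    nectar_families: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FAMILIES)
    )
    dialect: Mapping[str, str] | None = None

    def __post_init__(self):
        if not (0 < self.overlap_lower < self.overlap_upper < 1):
            raise ValueError("need 0 < overlap_lower < overlap_upper < 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "nectar_families" in raw:
            raw["nectar_families"] = {
                k: tuple(v) for k, v in raw["nectar_families"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nectar_families"] = {k: list(v)
                                for k, v in self.nectar_families.items()}
        # the output location is environment, not analysis: identical inputs
        # and seed must yield byte-identical reports wherever they land
        d.pop("out_dir")
        return d


@dataclass
class ReportBundle:
    config: dict
    validation: dict
    dissimilarity_full: pd.DataFrame
    dissimilarity_overlap: pd.DataFrame
    overlap_windows: pd.DataFrame
    diversity_metrics: pd.DataFrame
    diversity_models: pd.DataFrame
    association: dict[str, Any]
    median_gap: dict[str, Any] | None
    nectar: pd.DataFrame | None
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "dissimilarity_full": self.dissimilarity_full,
            "dissimilarity_overlap": self.dissimilarity_overlap,
            "overlap_windows": self.overlap_windows,
            "diversity_metrics": self.diversity_metrics,
            "diversity_models": self.diversity_models,
        }
        for key, res in self.association.items():
            if res is not None:
                out[f"association_{key}_residuals"] = res["residuals"]
        if self.nectar is not None:
            out["nectar_contrasts"] = self.nectar
        return out

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables().items():
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        with open(out / "bundle.json", "w") as fh:
            json.dump(_jsonify(self.as_dict()), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def as_dict(self) -> dict:
        assoc = {}
        for key, res in self.association.items():
            if res is None:
                assoc[key] = None
                continue
            assoc[key] = {k: v for k, v in res.items() if k != "residuals"}
            assoc[key]["residuals"] = res["residuals"].to_dict("records")
        return {
            "config": self.config,
            "validation": self.validation,
            "dissimilarity_full": self.dissimilarity_full.to_dict("records"),
            "dissimilarity_overlap":
                self.dissimilarity_overlap.to_dict("records"),
            "overlap_windows": self.overlap_windows.to_dict("records"),
            "diversity_metrics": self.diversity_metrics.to_dict("records"),
            "diversity_models": self.diversity_models.to_dict("records"),
            "association": assoc,
            "median_gap": self.median_gap,
            "nectar": (None if self.nectar is None
                       else self.nectar.to_dict("records")),
            "provenance": self.provenance,
        }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        log.info("stage %s: %.2fs", name, time.perf_counter() - t0)
        return result
    return wrap


def _dissimilarity_frame(results: Mapping[int, Any]) -> pd.DataFrame:
    rows = []
    for year, res in sorted(results.items()):
        if res is None:
            rows.append({"year": year, "observed_dmh": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan,
                         "classification": "not_computable",
                         "n_reps": 0})
        else:
            rows.append({"year": year, "observed_dmh": res.observed_dmh,
                         "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
                         "classification": res.classification,
                         "n_reps": res.n_reps})
    return pd.DataFrame(rows)


def _association_report(table, cfg: PipelineConfig) -> dict:
    res = chi_squared_association(
        table, residual_threshold=cfg.residual_threshold
    )
    resid = res.pearson_residuals.reset_index(names="sex").melt(
        id_vars="sex", var_name="plant_species", value_name="pearson_residual"
    )
    return {
        "chi2": res.chi2, "df": res.df, "p_value": res.p_value,
        "species_labels": res.species_labels,
        "low_expected_cells": list(res.low_expected_cells),
        "residuals": resid,
    }


def _diversity_section(ds, dataset_name, rows_models, rows_metrics):
    metrics = diversity_table(ds)
    metrics.insert(0, "dataset", dataset_name)
    rows_metrics.append(metrics)
    for metric in METRICS:
        try:
            res = paired_sex_comparison(metrics, metric)
        except ValueError as exc:
            log.info("diversity %s/%s skipped: %s", dataset_name, metric, exc)
            continue
        diag = residual_time_diagnostics(res)
        rows_models.append({
            "dataset": dataset_name, "metric": metric,
            "sex_effect": res.sex_effect, "se": res.se,
            "t_stat": res.t_stat, "p_value": res.p_value,
            "n_years": res.n_years, "df_residual": res.df_residual,
            "method": res.method,
            "n_years_female_greater": res.n_years_female_greater,
            "durbin_watson": diag.durbin_watson,
            "acf_lag1": float(diag.acf[0]) if diag.nlags >= 1 else np.nan,
        })


def run_pipeline(
    cfg: PipelineConfig,
    dataset: VisitationDataset | None = None,
    nectar_samples: pd.DataFrame | None = None,
) -> ReportBundle:
    """Run every stage and return the report bundle.

    ``dataset`` / ``nectar_samples`` may be passed in-memory; otherwise they
    are read from the paths in ``cfg``.
    """
    if dataset is None:
        if cfg.visits_csv is None:
            raise ValueError("no visitation input: set visits_csv or pass dataset")
        dataset = _stage("read")(read_visitation, cfg.visits_csv, cfg.dialect)
    if nectar_samples is None and cfg.nectar_csv is not None:
        nectar_samples = _stage("read_nectar")(read_nectar, cfg.nectar_csv)

    report = validate_dataset(dataset)
    validation = {
        "n_records": report.n_records,
        "total_visits": report.total_visits,
        "n_ambiguous": report.n_ambiguous,
        "n_duplicate_rows": report.n_duplicate_rows,
    }

    if dataset.n_ambiguous:
        def _assign(ds):
            clf = fit_phenology_classifier(ds)
            validation["assignment_boundary_day"] = clf.boundary
            return assign_ambiguous(ds, clf)
        dataset = _stage("assign")(_assign, dataset)

    # Full-season analyses.
    null_full = _stage("dissimilarity_full")(
        yearly_null_tests, dataset, cfg.n_reps, cfg.ci_level, cfg.seed
    )
    diss_full = _dissimilarity_frame(null_full)

    rows_models: list[dict] = []
    rows_metrics: list[pd.DataFrame] = []
    _stage("diversity_full")(
        _diversity_section, dataset, "full", rows_models, rows_metrics
    )

    association: dict[str, Any] = {}
    focal = most_visited(dataset, cfg.n_focal_species)
    association["full"] = _stage("association_full")(
        _association_report, pooled_table(dataset), cfg
    )
    association["full_focal"] = _stage("association_full_focal")(
        _association_report, pooled_table(dataset, species=focal), cfg
    )

    # Overlap restriction and repeated analyses.
    windows = _stage("overlap_windows")(
        overlap_windows, dataset,
        lower=cfg.overlap_lower, upper=cfg.overlap_upper,
        min_days=cfg.min_overlap_days, rule=cfg.overlap_rule,
    )
    win_frame = pd.DataFrame([dataclasses.asdict(w) for w in windows.values()])
    overlap_ds = _stage("overlap_restrict")(restrict_to_overlap, dataset, windows)

    if len(overlap_ds):
        null_overlap = _stage("dissimilarity_overlap")(
            yearly_null_tests, overlap_ds, cfg.n_reps, cfg.ci_level,
            cfg.seed + 1,
        )
        diss_overlap = _dissimilarity_frame(null_overlap)
        _stage("diversity_overlap")(
            _diversity_section, overlap_ds, "overlap", rows_models, rows_metrics
        )
        association["overlap"] = _stage("association_overlap")(
            _association_report, pooled_table(overlap_ds), cfg
        )
        sig_years = [y for y, r in null_overlap.items()
                     if r is not None and r.classification == "above"]
        if sig_years:
            association["overlap_significant_years"] = _stage(
                "association_overlap_sig")(
                _association_report,
                pooled_table(overlap_ds, years=sig_years), cfg,
            )
        else:
            association["overlap_significant_years"] = None
    else:
        diss_overlap = _dissimilarity_frame({})
        association["overlap"] = None
        association["overlap_significant_years"] = None

    # Dissimilarity vs median-date gap (full dataset).
    per_year_dmh = {y: (r.observed_dmh if r is not None else None)
                    for y, r in null_full.items()}
    try:
        reg = median_gap_regression(
            {y: d for y, d in per_year_dmh.items() if d is not None}, dataset
        )
        median_gap = dataclasses.asdict(reg)
    except ValueError as exc:
        log.info("median-gap regression skipped: %s", exc)
        median_gap = None

    # Nectar contrasts.
    nectar_frame = None
    if nectar_samples is not None:
        def _nectar():
            labels = association["full_focal"]["species_labels"]
            work = add_totals(nectar_samples)
            work, sparse = exclude_sparse_compounds(work)
            work, outliers = remove_outliers(work, k=cfg.outlier_k)
            rows = []
            for family, compounds in cfg.nectar_families.items():
                present = [c for c in compounds
                           if (work["compound"].str.casefold()
                               == c.casefold()).any()]
                results = []
                for comp in present:
                    try:
                        results.append(group_contrast(work, comp, labels))
                    except ValueError as exc:
                        log.info("contrast %s skipped: %s", comp, exc)
                if not results:
                    continue
                for res in bonferroni_family(results):
                    d = dataclasses.asdict(res)
                    d.pop("group_means")
                    d["family"] = family
                    d["excluded_species"] = ",".join(res.excluded_species)
                    rows.append(d)
            frame = pd.DataFrame(rows)
            validation["nectar_outliers_removed"] = outliers.n_removed
            validation["nectar_sparse_compounds_excluded"] = list(sparse)
            return frame
        nectar_frame = _stage("nectar")(_nectar)

    bundle = ReportBundle(
        config=cfg.to_dict(),
        validation=validation,
        dissimilarity_full=diss_full,
        dissimilarity_overlap=diss_overlap,
        overlap_windows=win_frame,
        diversity_metrics=(pd.concat(rows_metrics, ignore_index=True)
                           if rows_metrics else pd.DataFrame()),
        diversity_models=pd.DataFrame(rows_models),
        association=association,
        median_gap=median_gap,
        nectar=nectar_frame,
        provenance={
            "package": "regalforage",
            "version": __version__,
            "seed": cfg.seed,
        },
    )
    if cfg.out_dir:
        bundle.write(cfg.out_dir)
    return bundle
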