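"""Cohort-level orchestration: quantification, eligibility, survival report.

Order of operations per patient: segmentation -> classification -> per-lesion
metrics -> whole-body aggregation.  Cohort level: eligibility filtering
(>= 2 segmented lesions, complete outcomes), univariate Cox screening over
the standard variable roster, forward-stepwise multivariate selection, ROC
cutoffs for retained markers, Kaplan-Meier / log-rank on the dichotomized
markers, and the three-group dissemination x tumor-burden stratification.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import PatientFeatures, aggregate_patient
from .io import ExclusionMask, SUVVolume
from .segmentation import SegmentationConfig, classify_lesions, segment_lesions
from .survival import (CoxResult, SeparationError, cox_fit, cox_stepwise,
                       km_logrank, outcome_columns, roc_best_cutoff,
                       stratify_dmax_mtv)

__all__ = [
    "PipelineConfig",
    "UNIVARIATE_VARIABLES",
    "run_patient",
    "patient_features_row",
    "filter_eligible",
    "run_survival_workflow",
    "summarize_dmax_pairs",
    "summarize_lesion_sites",
    "write_report_json",
    "write_km_curves_csv",
]

logger = logging.getLogger(__name__)

#: The 13-variable univariate screening roster: clinical covariates plus the
#: primary-tumor, targeted-lesion and whole-body imaging parameters.
UNIVARIATE_VARIABLES = (
    "age", "gender", "histology", "stage",
    "suv_max_primary", "suv_mean_primary", "mtv_primary_ml", "tlg_primary_g",
    "suv_max_targeted", "suv_mean_targeted",
    "dmax_cm", "mtv_tot_ml", "tlg_wb_g",
)


@dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    dmax_mode: str = "centroid"
    candidate_p: float = 0.10          # univariate bar for multivariate entry
    p_enter: float = 0.05
    p_remove: float = 0.10
    ties: str = "efron"
    stage_coding: str = "ordinal"      # or "binary" (III vs IV)
    histology_coding: str = "adeno_vs_rest"
    outcomes: tuple[str, ...] = ("OS", "PFS")
    seed: int = 0


def run_patient(volume: SUVVolume, masks: Sequence[ExclusionMask] = (),
                class_map: Mapping[int, str] | None = None,
                config: PipelineConfig | None = None
                ) -> tuple[PatientFeatures | None, dict]:
    """Quantify a single patient.

    Returns (features, log).  ``features`` is None when segmentation finds
    no lesion; a single-lesion patient gets features with the Dmax fields
    absent and is excluded later by the eligibility filter.
    """
    if config is None:
        config = PipelineConfig()
    pid = volume.patient_id
    log: dict = {"patient_id": pid, "n_masks": len(list(masks))}
    try:
        lesion_set = segment_lesions(volume, config.segmentation, masks)
        log["n_lesions"] = len(lesion_set)
        if class_map:
            lesion_set = classify_lesions(lesion_set, class_map)
        if len(lesion_set) == 0:
            log["eligible"] = False
            log["reason"] = "no lesion above threshold"
            return None, log
        features = aggregate_patient(volume, lesion_set, config.dmax_mode)
        log["eligible"] = len(lesion_set) >= 2
        if not log["eligible"]:
            log["reason"] = "fewer than 2 segmented lesions"
        return features, log
    except Exception as exc:
        raise type(exc)(f"patient {pid!r}: {exc}") from exc


def patient_features_row(features: PatientFeatures | None,
                         patient_id: str = "") -> dict:
    """Flatten PatientFeatures into a cohort-table row."""
    if features is None:
        return {"patient_id": patient_id, "n_lesions": 0}
    pm, tm = features.primary_metrics, features.targeted_metrics
    return {
        "patient_id": features.patient_id,
        "n_lesions": features.n_lesions,
        "suv_max_primary": pm.suv_max if pm else np.nan,
        "suv_mean_primary": pm.suv_mean if pm else np.nan,
        "mtv_primary_ml": pm.mtv_ml if pm else np.nan,
        "tlg_primary_g": pm.tlg_g if pm else np.nan,
        "suv_max_targeted": tm.suv_max,
        "suv_mean_targeted": tm.suv_mean,
        "mtv_tot_ml": features.mtv_tot_ml,
        "tlg_wb_g": features.tlg_wb_g,
        "dmax_cm": features.dmax_cm if features.dmax_cm is not None else np.nan,
        "dmax_pair_type": features.dmax_pair_type or "",
    }


def filter_eligible(cohort: pd.DataFrame,
                    outcomes: Sequence[str] = ("OS", "PFS")) -> pd.DataFrame:
    """Keep patients with >= 2 segmented lesions and complete outcome data.

    Per-patient exclusion reasons are logged and attached to the result as
    ``df.attrs["exclusions"]``.  Raises if no patient survives the filter.
    """
    exclusions: dict[str, str] = {}
    keep = pd.Series(True, index=cohort.index)
    n_lesions = pd.to_numeric(cohort.get("n_lesions"), errors="coerce")
    too_few = n_lesions < 2
    outcome_cols = [c for o in outcomes for c in outcome_columns(o)]
    missing = cohort[outcome_cols].isna().any(axis=1) if outcome_cols else \
        pd.Series(False, index=cohort.index)
    for idx in cohort.index:
        pid = str(cohort.at[idx, "patient_id"])
        if too_few.loc[idx]:
            exclusions[pid] = "fewer than 2 FDG-positive lesions"
            keep.loc[idx] = False
        elif missing.loc[idx]:
            exclusions[pid] = "missing outcome"
            keep.loc[idx] = False
    for pid, reason in exclusions.items():
        logger.info("excluding patient %s: %s", pid, reason)
    out = cohort[keep].copy()
    if out.empty:
        raise ValueError("no eligible patients after filtering")
    out.attrs["exclusions"] = exclusions
    return out


def _coded_column(cohort: pd.DataFrame, variable: str,
                  config: PipelineConfig) -> tuple[str, pd.Series]:
    """Resolve a roster variable to a numeric column, coding categoricals."""
    if variable == "histology":
        if "histology_adeno" in cohort.columns:
            return "histology", pd.to_numeric(cohort["histology_adeno"])
        return "histology", (cohort["histology"] == "adenocarcinoma").astype(int)
    if variable == "stage":
        if config.stage_coding == "binary":
            src = cohort["stage"].astype(str)
            return "stage", src.str.startswith("IV").astype(int)
        if "stage_ordinal" in cohort.columns:
            return "stage", pd.to_numeric(cohort["stage_ordinal"])
        order = {"IIIA": 1, "IIIB": 2, "IIIC": 3, "IVA": 4, "IVB": 5}
        return "stage", cohort["stage"].map(order)
    return variable, pd.to_numeric(cohort[variable], errors="coerce")


def run_survival_workflow(cohort: pd.DataFrame,
                          config: PipelineConfig | None = None) -> dict:
    """Run the full prognostic workflow and return a JSON-ready report.

    For each outcome: univariate Cox over the 13-variable roster; variables
    with univariate p below ``candidate_p``, plus age, are forwarded to
    forward-stepwise multivariate selection; a ROC Youden cutoff and a
    dichotomized Kaplan-Meier / log-rank comparison are produced for each
    retained variable; and when cutoffs for both Dmax and MTV_TOT are
    available, the three-group combined stratification is added.
    """
    if config is None:
        config = PipelineConfig()
    work = cohort.copy()
    coded_cols: dict[str, str] = {}
    for var in UNIVARIATE_VARIABLES:
        name, series = _coded_column(work, var, config)
        col = f"__coded_{name}"
        work[col] = series
        coded_cols[var] = col

    report: dict = {"config": {
        "suv_threshold": config.segmentation.suv_threshold,
        "connectivity": config.segmentation.connectivity,
        "dmax_mode": config.dmax_mode,
        "candidate_p": config.candidate_p,
        "p_enter": config.p_enter, "p_remove": config.p_remove,
        "ties": config.ties, "stage_coding": config.stage_coding,
        "seed": config.seed,
    }, "n_patients": int(len(work)), "outcomes": {}}

    for outcome in config.outcomes:
        entry: dict = {"univariate": [], "multivariate": None,
                       "cutoffs": {}, "km_logrank": {}}
        univ_p: dict[str, float] = {}
        for var in UNIVARIATE_VARIABLES:
            try:
                fit = cox_fit(work, outcome, [coded_cols[var]], config.ties)
            except (SeparationError, ValueError) as exc:
                entry["univariate"].append({"variable": var, "error": str(exc)})
                continue
            univ_p[var] = float(fit.model_p)
            entry["univariate"].append({
                "variable": var,
                "coef": float(fit.coef[0]),
                "hazard_ratio": float(fit.hazard_ratio[0]),
                "chi2": float(fit.model_chi2),
                "p": float(fit.model_p),
            })
        candidates = [v for v, p in univ_p.items() if p < config.candidate_p]
        if "age" not in candidates and "age" in univ_p:
            candidates.append("age")
        entry["multivariate_candidates"] = candidates
        retained: list[str] = []
        if candidates:
            step = cox_stepwise(work, outcome, [coded_cols[v] for v in candidates],
                                config.p_enter, config.p_remove, config.ties)
            inv = {coded_cols[v]: v for v in candidates}
            retained = [inv[c] for c in step.variables]
            entry["multivariate"] = {
                "retained": retained,
                "coef": {inv[c]: float(b) for c, b in zip(step.variables, step.coef)},
                "hazard_ratio": {inv[c]: float(h)
                                 for c, h in zip(step.variables, step.hazard_ratio)},
                "model_chi2": float(step.model_chi2),
                "model_p": float(step.model_p),
                "inclusion_log": list(step.inclusion_log),
            }
        # ROC cutoffs + dichotomized KM for retained continuous markers
        for var in retained:
            col = coded_cols[var]
            if work[col].nunique() < 3:  # already dichotomous / categorical
                continue
            try:
                cut = roc_best_cutoff(work.assign(**{var: work[col]}), var, outcome)
            except ValueError as exc:
                entry["cutoffs"][var] = {"error": str(exc)}
                continue
            entry["cutoffs"][var] = {
                "cutoff": cut.cutoff, "sensitivity": cut.sensitivity,
                "specificity": cut.specificity, "youden_j": cut.youden_j,
            }
            groups = np.where(work[col] > cut.cutoff, "above", "below_or_equal")
            try:
                lr = km_logrank(work, outcome, groups)
                entry["km_logrank"][var] = _logrank_entry(lr)
            except ValueError as exc:
                entry["km_logrank"][var] = {"error": str(exc)}
        # combined Dmax x MTV_TOT three-group stratification
        try:
            dmax_cut = roc_best_cutoff(work.assign(dmax=work[coded_cols["dmax_cm"]]),
                                       "dmax", outcome)
            mtv_cut = roc_best_cutoff(work.assign(mtv=work[coded_cols["mtv_tot_ml"]]),
                                      "mtv", outcome)
            strata = stratify_dmax_mtv(work, dmax_cut.cutoff, mtv_cut.cutoff,
                                       dmax_col=coded_cols["dmax_cm"],
                                       mtv_col=coded_cols["mtv_tot_ml"])
            lr3 = km_logrank(work, outcome, strata)
            entry["three_group"] = {
                "dmax_cutoff_cm": dmax_cut.cutoff,
                "mtv_cutoff_ml": mtv_cut.cutoff,
                **_logrank_entry(lr3),
            }
        except ValueError as exc:
            entry["three_group"] = {"error": str(exc)}
        report["outcomes"][outcome] = entry
    return report


def _logrank_entry(lr) -> dict:
    return {
        "groups": [str(g) for g in lr.group_labels],
        "chi_square": lr.chi_square,
        "df": lr.df,
        "p": lr.p,
        "group_n": {str(k): v for k, v in lr.group_n.items()},
        "group_events": {str(k): v for k, v in lr.group_events.items()},
        "curves": {str(k): {"times": list(map(float, t)),
                            "survival": list(map(float, s))}
                   for k, (t, s) in lr.curves.items()},
    }


def summarize_lesion_sites(class_counts: Mapping[str, int]) -> dict:
    """Tally lesions by anatomical site and the grand total.

    ``class_counts`` maps lesion class (primary / node / distant) to a
    count; the total is their exact sum.
    """
    total = int(sum(class_counts.values()))
    return {"by_class": {k: int(v) for k, v in class_counts.items()},
            "total_lesions": total}


def summarize_dmax_pairs(cohort: pd.DataFrame) -> pd.DataFrame:
    """Tally the dissemination pair types across patients with percentages.

    Returns one row per pair type with columns ``n`` and ``percent``
    (exact, unrounded percentage of the cohort).
    """
    counts = cohort["dmax_pair_type"].value_counts()
    n_total = int(counts.sum())
    out = pd.DataFrame({"n": counts.astype(int)})
    out["percent"] = 100.0 * out["n"] / n_total
    out.index.name = "pair_type"
    return out


def write_report_json(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def write_km_curves_csv(report: dict, path: str) -> None:
    """Flatten every KM curve in a report to step coordinates (CSV)."""
    rows = []
    for outcome, entry in report.get("outcomes", {}).items():
        sources = dict(entry.get("km_logrank", {}))
        if "three_group" in entry and "curves" in entry.get("three_group", {}):
            sources["three_group"] = entry["three_group"]
        for name, block in sources.items():
            for group, curve in block.get("curves", {}).items():
                for t, s in zip(curve["times"], curve["survival"]):
                    rows.append({"outcome": outcome, "analysis": name,
                                 "group": group, "time_months": t,
                                 "survival": s})
    pd.DataFrame(rows).to_csv(path, index=False)
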