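"""End-to-end cohort analysis: RF frames -> maps -> texture -> biomarkers -> stats.

``analyze_cohort`` takes a list of patients (simulated or loaded from disk),
computes phantom-normalised parametric maps per scan plane, extracts mean and
GLCM texture features over the central-tumour ROI, aggregates them into
per-visit volumetric biomarkers and baseline-relative deltas, and runs the
group comparisons, LDA response classification and recurrence-free survival
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import (
    FEATURES,
    PARAMETERS,
    biomarker_name,
    build_biomarker_table,
    feature_matrix,
    roi_from_tumor_mask,
)
from .config import RunConfig
from .spectral import SpectralMapper
from .stats import (
    POSITIVE_CLASS,
    SurvivalResult,
    classify_and_score,
    compare_groups,
    logrank,
)
from .texture import GLCMTexturizer

logger = logging.getLogger(__name__)

#: combination feature sets mirroring the study's combined classifiers
COMBINATIONS = {
    "mbf+intercept0_mean": ["mbf_mean", "intercept0_mean"],
    "mbf+intercept0_contrast": ["mbf_contrast", "intercept0_contrast"],
    "mbf+intercept0_correlation": ["mbf_correlation", "intercept0_correlation"],
    "mbf+intercept0_homogeneity": ["mbf_homogeneity", "intercept0_homogeneity"],
    "mbf+intercept0_combined8": [
        biomarker_name(p, f) for p in ("mbf", "intercept0") for f in FEATURES
    ],
}

MEAN_BIOMARKERS = [biomarker_name(p, "mean") for p in ("mbf", "intercept0")]
TEXTURE_BIOMARKERS = [
    biomarker_name(p, f)
    for p in ("mbf", "intercept0")
    for f in ("contrast", "correlation", "homogeneity")
]


@dataclass
class CohortResult:
    feature_rows: pd.DataFrame
    visit_table: pd.DataFrame
    delta_table: pd.DataFrame
    comparisons: pd.DataFrame
    classification: pd.DataFrame
    classification_results: dict = field(repr=False, default_factory=dict)
    survival_true: SurvivalResult | None = None
    survival_predicted: SurvivalResult | None = None
    config: RunConfig = field(default_factory=RunConfig)


def analyze_patient(patient, config: RunConfig) -> list:
    """Per-plane spectral mean + texture features for every visit of a patient."""
    mapper = SpectralMapper(
        window_wavelengths=config.window_length_wavelengths, overlap=config.window_overlap
    ).fit(patient.phantom_frame)
    texturizer = GLCMTexturizer(
        n_levels=config.n_levels,
        distances=config.distances,
        range_policy=config.range_policy,
    ).fit()
    rows = []
    label = getattr(patient, "true_label", "")
    for visit, frames in patient.frames_by_visit.items():
        masks = patient.tumor_masks_by_visit[visit]
        for plane, (frame, tmask) in enumerate(zip(frames, masks)):
            maps = mapper.transform(frame)
            map_tumor = maps.map_roi(tmask.mask)
            if map_tumor.sum() < 4:
                logger.warning(
                    "patient %s %s plane %d: tumour covers <4 map pixels; skipped",
                    patient.patient_id,
                    visit,
                    plane,
                )
                continue
            roi = roi_from_tumor_mask(map_tumor, maps.focal_row(), config.roi_fraction)
            roi &= maps.valid_mask
            if roi.sum() < 4:
                logger.warning(
                    "patient %s %s plane %d: <4 valid ROI pixels; skipped",
                    patient.patient_id,
                    visit,
                    plane,
                )
                continue
            for param in PARAMETERS:
                values = maps.parameter(param)
                feats = texturizer.features(values, roi)
                for feature, value in (
                    ("mean", float(values[roi].mean())),
                    ("contrast", feats.contrast),
                    ("correlation", feats.correlation),
                    ("homogeneity", feats.homogeneity),
                ):
                    rows.append(
                        {
                            "patient_id": patient.patient_id,
                            "label": label,
                            "visit": visit,
                            "plane": plane,
                            "parameter": param,
                            "feature": feature,
                            "value": value,
                        }
                    )
    return rows


def compare_all(delta: pd.DataFrame) -> pd.DataFrame:
    """Responder vs non-responder comparison per biomarker and visit."""
    rows = []
    for (visit, bm), _sub in delta.groupby(["visit", "biomarker"], sort=True):
        try:
            X, labels, _, forms = feature_matrix(delta, bm, visit=visit)
        except ValueError:
            continue
        x = X[:, 0]
        resp = x[labels != POSITIVE_CLASS]
        nonr = x[labels == POSITIVE_CLASS]
        if len(resp) < 2 or len(nonr) < 2:
            continue
        c = compare_groups(resp, nonr, biomarker=bm, visit=visit)
        rows.append(
            {
                "visit": visit,
                "biomarker": bm,
                "form": forms[bm],
                "test": c.test_used,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "mean_responder": c.mean_responder,
                "se_responder": c.se_responder,
                "mean_nonresponder": c.mean_nonresponder,
                "se_nonresponder": c.se_nonresponder,
            }
        )
    return pd.DataFrame(rows)


def classify_all(delta: pd.DataFrame, config: RunConfig, visit: str = "wk1"):
    """LDA sensitivity/specificity/AUC for single biomarkers and combinations."""
    singles = [biomarker_name(p, f) for p in PARAMETERS for f in FEATURES]
    sets = {bm: [bm] for bm in singles}
    sets.update(COMBINATIONS)
    rows, results = [], {}
    for name, bms in sets.items():
        try:
            X, labels, patients, forms = feature_matrix(delta, bms, visit=visit)
        except ValueError:
            continue
        if len(np.unique(labels)) < 2:
            continue
        res = classify_and_score(
            X,
            labels,
            biomarkers=bms,
            visit=visit,
            eval_mode=config.lda_eval_mode,
            ridge=config.lda_ridge,
        )
        results[name] = (res, patients)
        rows.append(
            {
                "visit": visit,
                "feature_set": name,
                "n_features": len(bms),
                "eval_mode": res.eval_mode,
                "sensitivity_pct": res.sensitivity,
                "specificity_pct": res.specificity,
                "p_value": res.p_value,
                "auc": res.auc,
            }
        )
    return pd.DataFrame(rows), results


def analyze_cohort(patients, config: RunConfig | None = None, classify_visit: str = "wk1"):
    """Full analysis of a cohort of patients; returns :class:`CohortResult`."""
    config = config or RunConfig()
    rows = []
    for p in patients:
        rows.extend(analyze_patient(p, config))
    feature_rows = pd.DataFrame(rows)
    if feature_rows.empty:
        raise ValueError("no analysable frames in the cohort")
    visit_table, delta = build_biomarker_table(
        feature_rows,
        guard_mean=config.guard_epsilon_mean,
        guard_texture=config.guard_epsilon_texture,
    )
    comparisons = compare_all(delta)
    classification, results = classify_all(delta, config, visit=classify_visit)

    survival_true = survival_predicted = None
    times = np.array([p.recurrence_time for p in patients], dtype=float)
    events = np.array([p.recurrence_event for p in patients], dtype=bool)
    labels = np.array([p.true_label for p in patients])
    ids = [p.patient_id for p in patients]
    if len(np.unique(labels)) == 2 and events.any():
        survival_true = logrank(times, events, labels)
        key = "mbf_contrast"
        if key in results:
            res, pat = results[key]
            pred = dict(zip(pat, res.predicted))
            keep = [i for i, pid in enumerate(ids) if pid in pred]
            plabels = np.array([pred[ids[i]] for i in keep])
            if len(np.unique(plabels)) == 2 and events[keep].any():
                survival_predicted = logrank(times[keep], events[keep], plabels)

    return CohortResult(
        feature_rows=feature_rows,
        visit_table=visit_table,
        delta_table=delta,
        comparisons=comparisons,
        classification=classification,
        classification_results={k: v[0] for k, v in results.items()},
        survival_true=survival_true,
        survival_predicted=survival_predicted,
        config=config,
    )


def group_mean_shifts(visit_table: pd.DataFrame, parameter: str = "mbf") -> pd.DataFrame:
    """Group-mean absolute dBr shift of a parameter's ROI mean vs baseline.

    The dBr shifts quoted for calibration are absolute changes of the
    volumetric mean-value biomarker relative to week 0.
    """
    sub = visit_table[(visit_table.parameter == parameter) & (visit_table.feature == "mean")]
    base = sub[sub.visit == "wk0"].set_index("patient_id")["value"]
    rows = []
    for (visit, label), g in sub[sub.visit != "wk0"].groupby(["visit", "label"]):
        shifts = g.set_index("patient_id")["value"] - base.reindex(g.patient_id).values
        shifts = shifts.dropna()
        if len(shifts) == 0:
            continue
        rows.append(
            {
                "visit": visit,
                "label": label,
                "parameter": parameter,
                "mean_shift_dbr": float(shifts.mean()),
                "se_shift_dbr": float(shifts.std(ddof=1) / np.sqrt(len(shifts)))
                if len(shifts) > 1
                else float("nan"),
                "n": int(len(shifts)),
            }
        )
    return pd.DataFrame(rows)
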