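"""Tumour-volumetric biomarkers and baseline-relative percent changes.

Per scan plane the pipeline produces a mean value and three texture features
for each of the three spectral parameters (MBF, spectral slope, 0-MHz
intercept).  This module aggregates plane values into per-visit tumour
volumetric averages and forms the longitudinal biomarkers: the change of
each visit's value relative to the pre-treatment baseline (week 0), both as
a percent of the baseline magnitude and as an absolute difference.

The percent form matches how the biomarkers are named downstream
("%MeanDelta", "%ContrastDelta", ...); the absolute form is carried
alongside because percent change is ill-conditioned when the baseline sits
near zero (a stability guard flags those cases, and biomarkers where any
patient trips the guard fall back to the absolute form for the whole
cohort so every patient is on one scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARAMETERS = ("mbf", "intercept0", "slope")
FEATURES = ("mean", "contrast", "correlation", "homogeneity")
BASELINE_VISIT = "wk0"

#: stability guards for percent change, per feature family. dBr-valued means
#: use 0.5 dBr; dimensionless texture features use 0.05.
GUARD_MEAN = 0.5
GUARD_TEXTURE = 0.05


@dataclass(frozen=True)
class PercentChange:
    percent: float  # NaN when the baseline is unstable
    absolute: float
    stable: bool


def roi_from_tumor_mask(
    tumor_mask: np.ndarray, focal_row: int, fraction: float = 2.0 / 3.0
) -> np.ndarray:
    """Central tumour subregion covering ``fraction`` of the tumour area.

    The ROI is centred laterally on the tumour centroid and axially on the
    transducer focal depth (clamped into the tumour's row range), and grows
    outward by pixel distance until it covers the requested fraction —
    for a circular tumour this is the concentric disc of radius
    ``sqrt(fraction) * R``.  Deterministic: ties are broken by (row, col).
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    rows, cols = np.nonzero(tumor_mask)
    if rows.size == 0:
        raise ValueError("tumour mask is empty")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return tumor_mask.copy()
    r0 = float(np.clip(focal_row, rows.min(), rows.max()))
    c0 = float(cols.mean())
    dist = (rows - r0) ** 2 + (cols - c0) ** 2
    order = np.lexsort((cols, rows, dist))
    k = max(2, int(round(fraction * rows.size)))
    roi = np.zeros_like(tumor_mask)
    roi[rows[order[:k]], cols[order[:k]]] = True
    return roi


def volumetric_average(per_plane_values) -> float:
    """Unweighted mean across scan planes, dropping undefined (NaN) planes."""
    vals = np.asarray(list(per_plane_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no plane values to average")
    defined = np.isfinite(vals)
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("volumetric average: dropped %d undefined plane value(s)", n_dropped)
    if not defined.any():
        raise ValueError("all plane values are undefined")
    return float(vals[defined].mean())


def percent_change(value_t: float, value_baseline: float, guard_epsilon: float) -> PercentChange:
    """100 * (v_t - v_0) / |v_0| with a small-baseline stability guard."""
    if not np.isfinite(value_baseline):
        raise ValueError("baseline value is missing or undefined")
    absolute = float(value_t - value_baseline)
    if abs(value_baseline) < guard_epsilon:
        return PercentChange(percent=float("nan"), absolute=absolute, stable=False)
    return PercentChange(
        percent=float(100.0 * absolute / abs(value_baseline)), absolute=absolute, stable=True
    )


def biomarker_name(parameter: str, feature: str) -> str:
    return f"{parameter}_{feature}"


def build_visit_table(feature_rows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-plane feature rows into per-visit volumetric values.

    ``feature_rows`` columns: patient_id, label, visit, plane, parameter,
    feature, value.  Returns one row per (patient, visit, parameter,
    feature) with the volumetric average.
    """
    required = {"patient_id", "label", "visit", "plane", "parameter", "feature", "value"}
    missing = required - set(feature_rows.columns)
    if missing:
        raise ValueError(f"feature rows lack columns: {sorted(missing)}")
    dup = feature_rows.duplicated(["patient_id", "visit", "plane", "parameter", "feature"])
    if dup.any():
        raise ValueError("duplicate (patient, visit, plane, parameter, feature) rows")
    grouped = (
        feature_rows.groupby(
            ["patient_id", "label", "visit", "parameter", "feature"], sort=True
        )["value"]
        .apply(lambda v: volumetric_average(v.to_numpy()))
        .reset_index()
    )
    return grouped


def build_biomarker_table(
    feature_rows: pd.DataFrame,
    guard_mean: float = GUARD_MEAN,
    guard_texture: float = GUARD_TEXTURE,
) -> tuple:
    """Visit-value table plus the baseline-relative delta-biomarker table.

    Patients without a baseline visit are excluded (with a warning).  The
    delta table has one row per (patient, post-baseline visit, biomarker)
    with percent and absolute changes and the per-row stability flag.
    """
    visits = build_visit_table(feature_rows)
    have_baseline = set(visits.loc[visits.visit == BASELINE_VISIT, "patient_id"])
    excluded = sorted(set(visits.patient_id) - have_baseline)
    if excluded:
        logger.warning("excluding patients without baseline visit: %s", excluded)
        visits = visits[visits.patient_id.isin(have_baseline)]

    base = visits[visits.visit == BASELINE_VISIT].set_index(
        ["patient_id", "parameter", "feature"]
    )["value"]
    rows = []
    post = visits[visits.visit != BASELINE_VISIT]
    for rec in post.itertuples(index=False):
        b = base.get((rec.patient_id, rec.parameter, rec.feature), float("nan"))
        guard = guard_mean if rec.feature == "mean" else guard_texture
        if not np.isfinite(b):
            continue
        pc = percent_change(rec.value, b, guard)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "label": rec.label,
                "visit": rec.visit,
                "parameter": rec.parameter,
                "feature": rec.feature,
                "biomarker": biomarker_name(rec.parameter, rec.feature),
                "value": rec.value,
                "baseline": b,
                "pct_change": pc.percent,
                "abs_change": pc.absolute,
                "baseline_stable": pc.stable,
            }
        )
    delta = pd.DataFrame(rows)
    if not delta.empty:
        n_unstable = int((~delta["baseline_stable"]).sum())
        if n_unstable:
            logger.info("%d delta rows carry an unstable baseline (percent is NaN)", n_unstable)
    return visits, delta


def feature_matrix(
    delta: pd.DataFrame, biomarkers, visit: str = "wk1"
) -> tuple:
    """Patient x biomarker matrix of delta values for classification.

    Uses percent change when every patient's baseline is stable for the
    biomarker; otherwise falls back to absolute change for that biomarker
    (one consistent scale per column).  Returns ``(X, labels, patient_ids,
    column_forms)``; patients with any missing value are dropped.
    """
    if isinstance(biomarkers, str):
        biomarkers = [biomarkers]
    sub = delta[delta.visit == visit]
    if sub.empty:
        raise ValueError(f"no delta rows at visit {visit!r}")
    cols, forms = [], {}
    wide_parts = []
    for bm in biomarkers:
        rows = sub[sub.biomarker == bm]
        if rows.empty:
            raise ValueError(f"biomarker {bm!r} absent at visit {visit!r}")
        use_pct = bool(rows["baseline_stable"].all()) and rows["pct_change"].notna().all()
        col = rows.set_index("patient_id")["pct_change" if use_pct else "abs_change"]
        forms[bm] = "percent" if use_pct else "absolute"
        wide_parts.append(col.rename(bm))
        cols.append(bm)
    wide = pd.concat(wide_parts, axis=1).dropna()
    labels = (
        sub.drop_duplicates("patient_id").set_index("patient_id")["label"].loc[wide.index]
    )
    return wide.to_numpy(float), labels.to_numpy(), list(wide.index), forms
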