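"""File formats and the file-driven pipeline runner.

RF container layout (HDF5, one file per patient visit):

* ``/rf``          float array, axial x lateral x plane
* ``/phantom_rf``  matched phantom acquisition, axial x lateral (x 1)
* root attributes: ``container_version``, ``sampling_frequency_MHz``,
  ``centre_frequency_MHz``, ``fractional_bandwidth``, ``focal_depth_mm``,
  ``gain_id``, ``axial_pitch_mm``, ``lateral_pitch_mm``, ``patient_id``,
  ``visit``.

ROIs are 8-bit PNGs (nonzero = in-ROI) or polygon JSON rasterised with the
even-odd rule.  Cohort manifests are CSV with one row per (patient, visit,
plane).  An import shim for flat binary RF with a JSON sidecar is provided;
vendor formats are out of scope.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import RunConfig
from .pipeline import analyze_cohort, group_mean_shifts
from .simulate import RasterMask, SimulatedPatient
from .spectral import RFFrame

logger = logging.getLogger(__name__)

CONTAINER_VERSION = "1"
REQUIRED_ATTRS = (
    "container_version",
    "sampling_frequency_MHz",
    "centre_frequency_MHz",
    "fractional_bandwidth",
    "focal_depth_mm",
    "gain_id",
    "lateral_pitch_mm",
    "patient_id",
    "visit",
)

MANIFEST_COLUMNS = (
    "patient_id",
    "label",
    "visit",
    "plane",
    "frame_path",
    "roi_path",
    "recurrence_time",
    "event",
)


class PipelineStageError(RuntimeError):
    """Failure attributed to a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# RF container
# ---------------------------------------------------------------------------


def write_rf_container(path, frames, phantom_frame: RFFrame) -> None:
    """Write one patient-visit's plane stack and its matched phantom."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    ref = frames[0]
    rf = np.stack([f.samples for f in frames], axis=2)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rf", data=rf)
        fh.create_dataset("phantom_rf", data=phantom_frame.samples)
        fh.attrs["container_version"] = CONTAINER_VERSION
        fh.attrs["sampling_frequency_MHz"] = ref.sampling_frequency
        fh.attrs["centre_frequency_MHz"] = ref.centre_frequency
        fh.attrs["fractional_bandwidth"] = ref.fractional_bandwidth
        fh.attrs["focal_depth_mm"] = ref.focal_depth
        fh.attrs["gain_id"] = ref.gain_id
        fh.attrs["axial_pitch_mm"] = ref.axial_pitch
        fh.attrs["lateral_pitch_mm"] = ref.lateral_pitch
        fh.attrs["patient_id"] = ref.patient_id
        fh.attrs["visit"] = ref.visit


def read_rf_container(path):
    """Read a container back into ``(frames, phantom_frame)``."""
    with h5py.File(path, "r") as fh:
        for attr in REQUIRED_ATTRS:
            if attr not in fh.attrs:
                raise ValueError(f"RF container {path} lacks required attribute {attr!r}")
        version = str(fh.attrs["container_version"])
        if version != CONTAINER_VERSION:
            raise ValueError(
                f"unsupported RF container version {version!r} (supported: {CONTAINER_VERSION})"
            )
        rf = np.asarray(fh["rf"])
        phantom = np.asarray(fh["phantom_rf"])
        meta = {k: fh.attrs[k] for k in fh.attrs}
    if rf.ndim == 2:
        rf = rf[:, :, None]
    if phantom.ndim == 3:
        phantom = phantom[:, :, 0]

    def _frame(samples, plane, visit):
        return RFFrame(
            samples=samples,
            sampling_frequency=float(meta["sampling_frequency_MHz"]),
            centre_frequency=float(meta["centre_frequency_MHz"]),
            fractional_bandwidth=float(meta["fractional_bandwidth"]),
            focal_depth=float(meta["focal_depth_mm"]),
            lateral_pitch=float(meta["lateral_pitch_mm"]),
            gain_id=str(meta["gain_id"]),
            patient_id=str(meta["patient_id"]),
            visit=visit,
            plane=plane,
        )

    frames = [_frame(rf[:, :, k], k, str(meta["visit"])) for k in range(rf.shape[2])]
    phantom_frame = _frame(phantom, 0, "phantom")
    return frames, phantom_frame


def read_flat_rf(bin_path, sidecar_path) -> RFFrame:
    """Import shim: flat binary RF (float32, axial-major) + JSON sidecar."""
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    shape = (int(meta["n_axial"]), int(meta["n_lines"]))
    samples = np.fromfile(bin_path, dtype=np.float32).reshape(shape)
    return RFFrame(
        samples=samples.astype(float),
        sampling_frequency=float(meta["sampling_frequency_MHz"]),
        centre_frequency=float(meta["centre_frequency_MHz"]),
        fractional_bandwidth=float(meta.get("fractional_bandwidth", 0.6)),
        focal_depth=float(meta.get("focal_depth_mm", 0.0)),
        lateral_pitch=float(meta["lateral_pitch_mm"]),
        gain_id=str(meta.get("gain_id", "g0")),
    )


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------


def write_roi_png(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def _rasterize_polygon(vertices: np.ndarray, shape: tuple) -> np.ndarray:
    """Even-odd (ray-crossing) polygon rasterisation at pixel centres."""
    vz, vx = vertices[:, 0], vertices[:, 1]
    rows = np.arange(shape[0]) + 0.5
    cols = np.arange(shape[1]) + 0.5
    mask = np.zeros(shape, dtype=bool)
    n = len(vertices)
    for k in range(n):
        z1, x1 = vz[k], vx[k]
        z2, x2 = vz[(k + 1) % n], vx[(k + 1) % n]
        if z1 == z2:
            continue
        # rows whose horizontal ray crosses this edge (half-open in z)
        lo, hi = min(z1, z2), max(z1, z2)
        r_sel = (rows >= lo) & (rows < hi)
        if not r_sel.any():
            continue
        x_cross = x1 + (rows[r_sel] - z1) * (x2 - x1) / (z2 - z1)
        mask[r_sel] ^= cols[None, :] < x_cross[:, None]
    return mask


def read_roi(path, expected_shape: tuple | None = None) -> np.ndarray:
    """Read an ROI mask: PNG (nonzero = in-ROI) or polygon JSON.

    Polygon JSON: ``{"shape": [n_axial, n_lines],
    "vertices": [[z, x], ...]}`` in pixel units, even-odd fill.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            spec = json.load(fh)
        shape = tuple(int(v) for v in spec["shape"])
        mask = _rasterize_polygon(np.asarray(spec["vertices"], float), shape)
    else:
        mask = np.asarray(iio.imread(path)) != 0
        if mask.ndim == 3:
            mask = mask.any(axis=2)
    if expected_shape is not None and tuple(mask.shape) != tuple(expected_shape):
        raise ValueError(
            f"ROI shape {mask.shape} does not match the frame shape {tuple(expected_shape)}"
        )
    return mask


# ---------------------------------------------------------------------------
# cohort manifest + export
# ---------------------------------------------------------------------------


def export_cohort(patients, out_dir, write_rois: bool = True) -> Path:
    """Write a simulated cohort to disk (containers, ROI PNGs, manifest).

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        for visit, frames in p.frames_by_visit.items():
            cpath = out / f"{p.patient_id}_{visit}.h5"
            write_rf_container(cpath, frames, p.phantom_frame)
            for plane, tmask in enumerate(p.tumor_masks_by_visit[visit]):
                rpath = out / f"{p.patient_id}_{visit}_p{plane}_roi.png"
                if write_rois:
                    write_roi_png(rpath, tmask.mask)
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "label": p.true_label,
                        "visit": visit,
                        "plane": plane,
                        "frame_path": cpath.name,
                        "roi_path": rpath.name,
                        "recurrence_time": p.recurrence_time,
                        "event": int(p.recurrence_event),
                    }
                )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest, index=False, float_format="%.10g"
    )
    return manifest


def load_cohort(manifest_path):
    """Rebuild patient records from a manifest for analysis.

    Patients lacking a baseline (wk0) container are skipped with a warning.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    patients = []
    for pid, g in df.groupby("patient_id", sort=True):
        if "wk0" not in set(g.visit):
            logger.warning("patient %s has no baseline visit; skipped", pid)
            continue
        frames_by_visit, masks_by_visit = {}, {}
        phantom = None
        for visit, gv in g.groupby("visit", sort=True):
            fpath = root / gv.frame_path.iloc[0]
            frames, phantom = read_rf_container(fpath)
            masks = []
            for rec in gv.sort_values("plane").itertuples(index=False):
                mask = read_roi(root / rec.roi_path, expected_shape=frames[0].samples.shape)
                masks.append(
                    RasterMask(mask, frames[0].axial_pitch, frames[0].lateral_pitch)
                )
            frames_by_visit[visit] = frames
            masks_by_visit[visit] = masks
        rec0 = g.iloc[0]
        patients.append(
            SimulatedPatient(
                patient_id=str(pid),
                true_label=str(rec0.label),
                frames_by_visit=frames_by_visit,
                tumor_masks_by_visit=masks_by_visit,
                phantom_frame=phantom,
                recurrence_time=float(rec0.recurrence_time),
                recurrence_event=bool(rec0.event),
                focal_depth=phantom.focal_depth,
                true_shifts={},
            )
        )
    return patients


# ---------------------------------------------------------------------------
# maps container
# ---------------------------------------------------------------------------


def write_maps(path, maps) -> None:
    """Write a ParametricMaps triple to HDF5."""
    with h5py.File(path, "w") as fh:
        for name in ("mbf", "slope", "intercept0"):
            fh.create_dataset(name, data=getattr(maps, name))
        fh.create_dataset("valid_mask", data=maps.valid_mask)
        fh.create_dataset("axial_centers", data=maps.axial_centers)
        fh.create_dataset("lateral_centers", data=maps.lateral_centers)
        fh.attrs["axial_pitch_mm"] = maps.axial_pitch
        fh.attrs["lateral_pitch_mm"] = maps.lateral_pitch
        fh.attrs["focal_depth_mm"] = maps.focal_depth
        fh.attrs["band_MHz"] = [maps.band.f_low, maps.band.f_centre, maps.band.f_high]
        fh.attrs["window_length_samples"] = maps.window_length
        fh.attrs["window_lines"] = maps.window_lines
        for k, v in maps.config.items():
            fh.attrs[f"config_{k}"] = v


# ---------------------------------------------------------------------------
# end-to-end runner
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _survival_frame(result) -> pd.DataFrame:
    rows = []
    for g, c in result.curves.items():
        for t, s, r in zip(c.times, c.survival, c.at_risk):
            rows.append({"group": g, "time_months": t, "survival": s, "at_risk": r})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, cohort_manifest, out_dir=None):
    """Execute maps -> texture -> biomarkers -> stats on a cohort manifest.

    Writes biomarker, comparison (classification-table) and survival CSVs
    plus a run-metadata YAML into ``out_dir``; any stage failure aborts with
    a :class:`PipelineStageError` naming the stage.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        patients = load_cohort(cohort_manifest)
        if not patients:
            raise ValueError("manifest yields no analysable patients")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("load", str(e)) from e
    try:
        result = analyze_cohort(patients, config)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("analysis", str(e)) from e
    try:
        _write_csv(result.visit_table, out / "biomarkers_visit.csv")
        _write_csv(result.delta_table, out / "biomarkers_delta.csv")
        _write_csv(result.comparisons, out / "group_comparisons.csv")
        _write_csv(result.classification, out / "classification.csv")
        _write_csv(group_mean_shifts(result.visit_table, "mbf"), out / "mbf_shifts.csv")
        if result.survival_true is not None:
            _write_csv(_survival_frame(result.survival_true), out / "survival_true.csv")
            pd.DataFrame(
                [
                    {
                        "grouping": "true_label",
                        "statistic": result.survival_true.statistic,
                        "p_value": result.survival_true.p_value,
                    }
                ]
                + (
                    [
                        {
                            "grouping": "predicted_mbf_contrast",
                            "statistic": result.survival_predicted.statistic,
                            "p_value": result.survival_predicted.p_value,
                        }
                    ]
                    if result.survival_predicted is not None
                    else []
                )
            ).pipe(_write_csv, out / "logrank.csv")
            if result.survival_predicted is not None:
                _write_csv(
                    _survival_frame(result.survival_predicted), out / "survival_predicted.csv"
                )
        import yaml

        with open(out / "run_metadata.yaml", "w") as fh:
            yaml.safe_dump(
                {"config": config.as_metadata(), "n_patients": len(patients)},
                fh,
                sort_keys=True,
            )
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("export", str(e)) from e
    return result
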