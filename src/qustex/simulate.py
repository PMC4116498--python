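"""Synthetic RF cohort simulator.

Generates point-scatterer fields, beamformed RF frames, matched reference
phantom frames, and full longitudinal responder / non-responder cohorts with
the statistical structure the downstream analysis assumes:

* backscatter is a linear convolution of a Gaussian-envelope tone burst with
  a random point-scatterer reflectivity field (fully developed speckle at the
  default density of ~5 scatterers per wavelength-squared resolution cell);
* chemotherapy response shifts tumour backscatter by a per-patient dBr
  amount, delivered as a flat in-tumour gain; *heterogeneous* response adds
  zero-mean patch-to-patch dB contrast on circular patches with
  Poisson-placed centres and diffuse (Gaussian-smoothed) margins, calibrated
  so the tumour-averaged dBr map shift recovers the programmed target;
* the 0-MHz-intercept shift is decoupled from the MBF shift by a flat
  linear spectral tilt (dB/MHz) over the tumour scatterers;
* recurrence-free survival times are exponential with a longer median for
  responders, administratively censored at 50 months.

Everything is driven by :class:`numpy.random.Generator` seeds; identical
seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve, firwin2
from scipy.spatial import cKDTree

from .spectral import (
    SPEED_OF_SOUND_MM_US,
    RFFrame,
    gaussian_pulse_taps,
    pulse_power_spectrum,
)

#: default scatterer density: 5 per resolution cell, one cell ~= lambda^2 at 7 MHz
RESOLUTION_CELL_MM2 = (SPEED_OF_SOUND_MM_US / 7.0) ** 2
DEFAULT_DENSITY_PER_MM2 = 5.0 / RESOLUTION_CELL_MM2

#: region labels
BACKGROUND, TUMOR, RESPONDING = 0, 1, 2


# ---------------------------------------------------------------------------
# pulse
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseModel:
    """Gaussian-envelope tone burst used for both transmit and receive."""

    centre_frequency: float  # MHz
    fractional_bandwidth: float
    sampling_frequency: float  # MHz
    taps: np.ndarray

    @property
    def pulse_length(self) -> int:
        return len(self.taps)

    def power_spectrum(self, nfft: int = 4096):
        return pulse_power_spectrum(self.taps, self.sampling_frequency, nfft=nfft)


def make_pulse(
    centre_frequency: float = 7.0,
    fractional_bandwidth: float = 0.6,
    sampling_frequency: float = 40.0,
) -> PulseModel:
    """Build the calibration/simulation pulse.

    Raises
    ------
    ValueError
        If the centre frequency is at or above Nyquist (aliasing) or the
        bandwidth is outside (0, 1].
    """
    taps = gaussian_pulse_taps(centre_frequency, fractional_bandwidth, sampling_frequency)
    energy = float(np.sum(taps**2))
    if not np.isfinite(energy) or energy <= 0:
        raise ValueError("pulse energy must be finite and nonzero")
    return PulseModel(
        centre_frequency=centre_frequency,
        fractional_bandwidth=fractional_bandwidth,
        sampling_frequency=sampling_frequency,
        taps=taps,
    )


# ---------------------------------------------------------------------------
# scatterer fields
# ---------------------------------------------------------------------------


@dataclass
class ScattererField:
    """Point scatterers in a 2-D (axial x lateral) frame, positions in mm.

    ``tilt_db_per_mhz`` carries an optional per-scatterer linear spectral
    tilt (relative to the centre frequency) used to decouple MBF and 0-MHz
    intercept shifts in response patches.
    """

    extent: tuple  # (axial_mm, lateral_mm)
    positions: np.ndarray  # (n, 2): axial z, lateral x
    amplitudes: np.ndarray
    region_labels: np.ndarray
    density: float  # scatterers per mm^2
    tilt_db_per_mhz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 2)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        if self.tilt_db_per_mhz is None:
            self.tilt_db_per_mhz = np.zeros(len(self.amplitudes))
        if self.density <= 0:
            raise ValueError("scatterer density must be positive")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("scatterer amplitudes must be finite")
        z, x = self.positions[:, 0], self.positions[:, 1]
        if self.positions.shape[0] and (
            z.min() < 0 or x.min() < 0 or z.max() > self.extent[0] or x.max() > self.extent[1]
        ):
            raise ValueError("scatterer positions fall outside the frame extent")

    def copy(self) -> "ScattererField":
        return ScattererField(
            extent=self.extent,
            positions=self.positions.copy(),
            amplitudes=self.amplitudes.copy(),
            region_labels=self.region_labels.copy(),
            density=self.density,
            tilt_db_per_mhz=self.tilt_db_per_mhz.copy(),
        )


def make_scatterer_field(
    extent: tuple,
    density: float = DEFAULT_DENSITY_PER_MM2,
    amplitude_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> ScattererField:
    """Poisson-distributed uniform scatterers with zero-mean normal amplitudes.

    ``density`` is in scatterers per mm^2 (the default corresponds to ~5 per
    wavelength-squared resolution cell at 7 MHz, i.e. fully developed
    speckle).  The expected count is ``density * area``.
    """
    if extent[0] <= 0 or extent[1] <= 0:
        raise ValueError("frame extent must be positive in both directions")
    if density <= 0:
        raise ValueError("scatterer density must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    area = extent[0] * extent[1]
    n = int(rng.poisson(density * area))
    positions = np.column_stack(
        [rng.uniform(0, extent[0], n), rng.uniform(0, extent[1], n)]
    )
    amplitudes = rng.normal(0.0, amplitude_sd, n)
    return ScattererField(
        extent=tuple(extent),
        positions=positions,
        amplitudes=amplitudes,
        region_labels=np.full(n, BACKGROUND),
        density=density,
    )


@dataclass
class RasterMask:
    """Boolean mask on the frame pixel grid with its physical pitches."""

    mask: np.ndarray
    axial_pitch: float  # mm per row
    lateral_pitch: float  # mm per column

    def extent(self) -> tuple:
        return (self.mask.shape[0] * self.axial_pitch, self.mask.shape[1] * self.lateral_pitch)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        if positions.size == 0:
            return np.zeros(0, dtype=bool)
        rows = np.clip(
            (positions[:, 0] / self.axial_pitch).astype(int), 0, self.mask.shape[0] - 1
        )
        cols = np.clip(
            (positions[:, 1] / self.lateral_pitch).astype(int), 0, self.mask.shape[1] - 1
        )
        return self.mask[rows, cols]


def circular_mask(
    shape: tuple, axial_pitch: float, lateral_pitch: float, center_mm: tuple, radius_mm: float
) -> RasterMask:
    """Rasterised circular region (tumour cross-section) on the frame grid."""
    zz = (np.arange(shape[0]) + 0.5) * axial_pitch
    xx = (np.arange(shape[1]) + 0.5) * lateral_pitch
    dist2 = (zz[:, None] - center_mm[0]) ** 2 + (xx[None, :] - center_mm[1]) ** 2
    return RasterMask(dist2 <= radius_mm**2, axial_pitch, lateral_pitch)


def mark_tumor(field: ScattererField, tumor: RasterMask, echogenicity_db: float = -3.0) -> None:
    """Label scatterers inside the tumour and apply its baseline echogenicity.

    Breast tumours are typically hypoechoic; the default is -3 dB relative to
    the surrounding tissue, which also keeps the baseline MBF biomarker away
    from the percent-change stability guard.
    """
    inside = tumor.contains(field.positions)
    field.region_labels[inside] = TUMOR
    field.amplitudes[inside] *= 10.0 ** (echogenicity_db / 20.0)


# ---------------------------------------------------------------------------
# treatment-response effect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseEffect:
    """Programmed backscatter change for one visit.

    ``mbf_shift_mean``/``intercept_shift_mean`` are the target
    *tumour-averaged* dBr shifts; the per-patient draw is
    ``N(mean, sd)``.  ``heterogeneity_fraction`` is the expected fraction of
    tumour area covered by response patches; patch amplitudes are scaled so
    the tumour average still recovers the drawn target.
    ``patch_contrast_db`` is the patch-to-patch dB scatter producing the
    texture signal (zero-mean, so it leaves the tumour average unchanged in
    expectation).
    """

    week: str
    mbf_shift_mean: float
    mbf_shift_sd: float
    intercept_shift_mean: float
    intercept_shift_sd: float
    heterogeneity_fraction: float = 0.75
    patch_scale: float = 2.0  # characteristic patch radius, mm
    patch_contrast_db: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heterogeneity_fraction <= 1.0:
            raise ValueError("heterogeneity_fraction must lie in [0, 1]")
        if min(self.mbf_shift_sd, self.intercept_shift_sd) < 0:
            raise ValueError("shift standard deviations must be non-negative")
        if self.patch_scale <= 0:
            raise ValueError("patch_scale must be positive")


@dataclass
class PatchSet:
    """Poisson-placed circular response patches, persisted across visits."""

    centers: np.ndarray  # (m, 2) mm
    radius: float
    contrasts: np.ndarray  # (m,) standard-normal patch factors


def sample_patches(
    tumor: RasterMask, fraction: float, patch_scale: float, rng: np.random.Generator
) -> PatchSet:
    """Poisson patch centres with intensity chosen so the expected patch-union
    coverage of the tumour equals ``fraction`` (Boolean-model formula)."""
    rows, cols = np.nonzero(tumor.mask)
    if rows.size == 0:
        raise ValueError("tumour mask is empty")
    if fraction <= 0:
        return PatchSet(np.zeros((0, 2)), patch_scale, np.zeros(0))
    area = rows.size * tumor.axial_pitch * tumor.lateral_pitch
    lam = -np.log(max(1.0 - fraction, 1e-12)) / (np.pi * patch_scale**2)
    n = int(rng.poisson(lam * area))
    n = max(n, 1)
    # draw centres uniformly over tumour pixels (jittered within a pixel)
    idx = rng.integers(0, rows.size, n)
    centers = np.column_stack(
        [
            (rows[idx] + rng.uniform(0, 1, n)) * tumor.axial_pitch,
            (cols[idx] + rng.uniform(0, 1, n)) * tumor.lateral_pitch,
        ]
    )
    return PatchSet(centers, patch_scale, rng.standard_normal(n))


def _smoothed_shift_field(
    tumor: RasterMask,
    patches: PatchSet,
    patch_shifts_db: np.ndarray,
    base_db: float = 0.0,
    smooth_mm: float = 1.0,
    grid_mm: float = 0.25,
):
    """Rasterise per-patch dB shifts and smooth them inside the tumour.

    Normalised (mask-aware) Gaussian smoothing gives the response diffuse
    ~1 mm margins; a constant field stays exactly constant, so the
    tumour-averaged shift is preserved.
    Returns ``(grid, pitches)`` with NaN outside the tumour.
    """
    nz = max(2, int(np.ceil(tumor.mask.shape[0] * tumor.axial_pitch / grid_mm)))
    nx = max(2, int(np.ceil(tumor.mask.shape[1] * tumor.lateral_pitch / grid_mm)))
    zz = (np.arange(nz) + 0.5) * grid_mm
    xx = (np.arange(nx) + 0.5) * grid_mm
    # tumour membership on the coarse grid
    rows = np.clip((zz / tumor.axial_pitch).astype(int), 0, tumor.mask.shape[0] - 1)
    cols = np.clip((xx / tumor.lateral_pitch).astype(int), 0, tumor.mask.shape[1] - 1)
    tmask = tumor.mask[np.ix_(rows, cols)]

    shift = np.full((nz, nx), base_db)
    if len(patches.centers):
        tree = cKDTree(patches.centers)
        pts = np.column_stack(
            [np.repeat(zz, nx), np.tile(xx, nz)]
        )
        dist, nearest = tree.query(pts, k=1)
        covered = (dist <= patches.radius).reshape(nz, nx)
        shift[covered] += patch_shifts_db[nearest.reshape(nz, nx)[covered]]
    sigma = smooth_mm / grid_mm
    w = tmask.astype(float)
    num = gaussian_filter(shift * w, sigma, mode="constant")
    den = gaussian_filter(w, sigma, mode="constant")
    out = np.full((nz, nx), np.nan)
    ok = den > 1e-9
    out[ok] = num[ok] / den[ok]
    out[~tmask] = np.nan
    return out, grid_mm


def apply_response_effect(
    field: ScattererField,
    effect: ResponseEffect,
    tumor_mask: RasterMask,
    seed: int | np.random.Generator = 0,
    patches: PatchSet | None = None,
    drawn_shifts: tuple | None = None,
    centre_frequency: float = 7.0,
) -> ScattererField:
    """Apply one visit's response effect to a baseline scatterer field.

    The per-patient tumour-mean targets ``(delta_mbf, delta_int)`` are drawn
    from the effect's normal distributions (or supplied via ``drawn_shifts``
    by the cohort simulator, which persists patches across visits).  The
    drawn mean shift is delivered across the whole tumour; patches covering
    ``heterogeneity_fraction`` of its area add zero-mean patch-to-patch
    contrast (``patch_contrast_db``), the texture signature of heterogeneous
    response.  Scatterer amplitudes are scaled by ``10**(shift/20)`` of the
    smoothed dB shift field, calibrated so the measured tumour-averaged map
    shift recovers ``delta_mbf``; a flat spectral tilt encodes the
    intercept/MBF difference.  ``heterogeneity_fraction = 0`` returns the
    field unchanged.
    """
    tol = max(tumor_mask.axial_pitch, tumor_mask.lateral_pitch)
    if not np.allclose(tumor_mask.extent(), field.extent, atol=tol):
        raise ValueError("tumour mask extent does not match the scatterer field extent")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = effect.heterogeneity_fraction
    if f == 0:
        return field.copy()
    if patches is None:
        patches = sample_patches(tumor_mask, f, effect.patch_scale, rng)
    if drawn_shifts is None:
        delta_mbf = rng.normal(effect.mbf_shift_mean, effect.mbf_shift_sd)
        delta_int = rng.normal(effect.intercept_shift_mean, effect.intercept_shift_sd)
    else:
        delta_mbf, delta_int = drawn_shifts

    patch_shifts = effect.patch_contrast_db * patches.contrasts
    shift_grid, grid_mm = _smoothed_shift_field(
        tumor_mask, patches, patch_shifts, base_db=delta_mbf
    )

    # Calibrate the field so the *measured* tumour-mean dBr shift recovers the
    # drawn target: the sliding-window estimator averages power within each
    # window before taking the log, which inflates the dB-domain ROI mean of a
    # heterogeneous field (Jensen bias).  Predict that window-averaged dB mean
    # on the shift grid (masked box filter at the 10-wavelength window scale)
    # and absorb the difference into a flat in-tumour offset.  For a spatially
    # constant shift the prediction is exact and the offset is zero.
    from scipy.ndimage import uniform_filter

    wavelength_mm = SPEED_OF_SOUND_MM_US / centre_frequency
    # lateral: full 10-wavelength window (unweighted line averaging); axial:
    # the Hann taper halves the effective power-averaging length
    k_lat = max(1, int(round(10.0 * wavelength_mm / grid_mm)))
    k_ax = max(1, int(round(5.0 * wavelength_mm / grid_mm)))
    tmask_grid = np.isfinite(shift_grid)
    lin = np.where(tmask_grid, 10.0 ** (np.nan_to_num(shift_grid) / 10.0), 0.0)
    num = uniform_filter(lin, size=(k_ax, k_lat), mode="constant")
    den = uniform_filter(tmask_grid.astype(float), size=(k_ax, k_lat), mode="constant")
    ok = den > 0.5
    pred = np.full(shift_grid.shape, np.nan)
    pred[ok] = 10.0 * np.log10(num[ok] / den[ok])
    inner = ok & tmask_grid
    if inner.any():
        shift_grid = shift_grid + (delta_mbf - float(np.nanmean(pred[inner])))

    out = field.copy()
    inside = tumor_mask.contains(out.positions)
    if not np.any(inside):
        return out
    # fill grid cells outside the (coarser) tumour raster from their nearest
    # in-tumour neighbour so boundary scatterers see a consistent shift
    from scipy.ndimage import distance_transform_edt

    invalid = ~np.isfinite(shift_grid)
    if invalid.any() and not invalid.all():
        _, (iz, ix) = distance_transform_edt(invalid, return_indices=True)
        shift_filled = shift_grid[iz, ix]
    else:
        shift_filled = np.nan_to_num(shift_grid)
    pos = out.positions[inside]
    gz = np.clip((pos[:, 0] / grid_mm).astype(int), 0, shift_grid.shape[0] - 1)
    gx = np.clip((pos[:, 1] / grid_mm).astype(int), 0, shift_grid.shape[1] - 1)
    s_db = shift_filled[gz, gx]
    out.amplitudes[inside] *= 10.0 ** (s_db / 20.0)

    # flat spectral tilt over the tumour decouples the 0-MHz intercept mean
    tilt = (delta_mbf - delta_int) / centre_frequency
    if abs(tilt) > 1e-12:
        out.tilt_db_per_mhz[inside] = tilt
    if len(patches.centers):
        tree = cKDTree(patches.centers)
        dist, _ = tree.query(pos, k=1)
        idx = np.nonzero(inside)[0][dist <= patches.radius]
        out.region_labels[idx] = RESPONDING
    return out


# ---------------------------------------------------------------------------
# RF frame synthesis
# ---------------------------------------------------------------------------


def _tilt_kernel(pulse: PulseModel, tilt_db_per_mhz: float, numtaps: int = 31) -> np.ndarray:
    """FIR whose amplitude response is 10**(b (f - fc) / 20), unity at fc."""
    nyq = pulse.sampling_frequency / 2.0
    f = np.linspace(0.0, nyq, 256)
    gain = 10.0 ** (tilt_db_per_mhz * (f - pulse.centre_frequency) / 20.0)
    gain = np.clip(gain, 0.0, 1e3)
    return firwin2(numtaps, f / nyq, gain)


def simulate_rf_frame(
    field: ScattererField,
    pulse: PulseModel,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
    lateral_pitch: float = 0.2,
    focal_depth: float = 10.0,
    gain: float = 1.0,
    gain_id: str = "g0",
    patient_id: str = "",
    visit: str = "",
    plane: int = 0,
) -> RFFrame:
    """Linear convolution backscatter model.

    Each scatterer contributes a pulse echo at fast-time delay ``2 z / c``
    (linear interpolation between samples) on its nearest scan line; white
    Gaussian noise is added and the whole frame is scaled by the acquisition
    gain.  The model is exactly linear in the scatterer amplitudes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axial_pitch = SPEED_OF_SOUND_MM_US / (2.0 * pulse.sampling_frequency)
    n_axial = int(round(field.extent[0] / axial_pitch))
    n_lines = int(round(field.extent[1] / lateral_pitch))
    if n_axial < 2 or n_lines < 1:
        raise ValueError("frame extent too small for the sampling geometry")

    rf = np.zeros((n_axial, n_lines))
    tilts = field.tilt_db_per_mhz
    for tilt in np.unique(tilts):
        sel = tilts == tilt
        if not np.any(sel):
            continue
        grid = np.zeros((n_axial, n_lines))
        z = field.positions[sel, 0] / axial_pitch
        x = np.clip((field.positions[sel, 1] / lateral_pitch).astype(int), 0, n_lines - 1)
        amp = field.amplitudes[sel]
        i0 = np.floor(z).astype(int)
        w = z - i0
        ok = (i0 >= 0) & (i0 < n_axial)
        np.add.at(grid, (i0[ok], x[ok]), amp[ok] * (1.0 - w[ok]))
        ok1 = (i0 + 1 >= 0) & (i0 + 1 < n_axial)
        np.add.at(grid, (i0[ok1] + 1, x[ok1]), amp[ok1] * w[ok1])
        kernel = pulse.taps
        if abs(tilt) > 1e-12:
            kernel = np.convolve(pulse.taps, _tilt_kernel(pulse, tilt))
        rf += fftconvolve(grid, kernel[:, None], mode="same")

    if noise_sd > 0:
        rf += rng.normal(0.0, noise_sd, rf.shape)
    rf *= gain
    return RFFrame(
        samples=rf,
        sampling_frequency=pulse.sampling_frequency,
        centre_frequency=pulse.centre_frequency,
        fractional_bandwidth=pulse.fractional_bandwidth,
        focal_depth=focal_depth,
        lateral_pitch=lateral_pitch,
        gain_id=gain_id,
        patient_id=patient_id,
        visit=visit,
        plane=plane,
    )


@dataclass(frozen=True)
class AcquisitionSettings:
    """Scanner settings shared between a patient frame and its phantom."""

    extent: tuple = (20.0, 20.0)  # (axial, lateral) mm
    lateral_pitch: float = 0.2
    focal_depth: float = 10.0
    gain: float = 1.0
    gain_id: str = "g0"
    density: float = DEFAULT_DENSITY_PER_MM2
    noise_sd: float = 0.01


def simulate_phantom_frame(
    pulse: PulseModel, settings: AcquisitionSettings, seed: int | np.random.Generator = 0
) -> RFFrame:
    """Homogeneous tissue-mimicking reference phantom frame for one setting."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phantom = make_scatterer_field(settings.extent, settings.density, 1.0, rng)
    return simulate_rf_frame(
        phantom,
        pulse,
        noise_sd=settings.noise_sd,
        seed=rng,
        lateral_pitch=settings.lateral_pitch,
        focal_depth=settings.focal_depth,
        gain=settings.gain,
        gain_id=settings.gain_id,
        visit="phantom",
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

VISITS = ("wk0", "wk1", "wk4", "wk8", "preop")

#: default per-visit effects. Means are the tumour-averaged dBr shifts the
#: paper reports at weeks 1 and 4; patient-level SDs are the reported standard
#: errors scaled by sqrt(group n) (15 responders, 5 non-responders).  The
#: patch contrast (texture effect size) is a simulator choice: responders
#: develop ~4-5 dB patch-to-patch heterogeneity, non-responders ~1 dB.
DEFAULT_EFFECTS = {
    "responder": {
        "wk1": ResponseEffect("wk1", 3.7, 1.5 * np.sqrt(15), 1.9, 0.9 * np.sqrt(15), 0.75, 2.0, 4.0),
        "wk4": ResponseEffect("wk4", 6.8, 1.7 * np.sqrt(15), 2.3, 0.5 * np.sqrt(15), 0.75, 2.0, 5.0),
    },
    "non-responder": {
        "wk1": ResponseEffect("wk1", -2.1, 1.8 * np.sqrt(5), -1.8, 1.4 * np.sqrt(5), 0.75, 2.0, 1.0),
        "wk4": ResponseEffect("wk4", -4.9, 6.0 * np.sqrt(5), -0.4, 1.6 * np.sqrt(5), 0.75, 2.0, 1.0),
    },
}

#: exponential recurrence-time medians (months) and administrative censoring
DEFAULT_SURVIVAL = {"responder": 48.0, "non-responder": 12.0, "censor_months": 50.0}


@dataclass
class CohortDesign:
    """Desk-scale acquisition geometry for simulated cohorts."""

    extent: tuple = (20.0, 20.0)
    lateral_pitch: float = 0.2
    density: float = DEFAULT_DENSITY_PER_MM2
    noise_sd: float = 0.01
    focal_depth: float = 10.0
    n_planes: int = 3
    plane_spacing: float = 5.0  # mm between parallel scan planes
    tumor_radius_range: tuple = (6.5, 9.0)  # 3-D radius, mm
    tumor_echogenicity_db: float = -3.0
    gain_range: tuple = (0.7, 1.4)
    visits: tuple = ("wk0", "wk1", "wk4")
    min_plane_radius: float = 2.5  # skip planes whose cross-section is tiny
    pulse_centre_frequency: float = 7.0
    pulse_bandwidth: float = 0.6
    pulse_sampling_frequency: float = 40.0


@dataclass
class SimulatedPatient:
    """One simulated patient: longitudinal multi-plane frames + ground truth."""

    patient_id: str
    true_label: str  # "responder" | "non-responder"
    frames_by_visit: dict  # visit -> list[RFFrame] (one per plane)
    tumor_masks_by_visit: dict  # visit -> list[RasterMask]
    phantom_frame: RFFrame
    recurrence_time: float  # months
    recurrence_event: bool
    focal_depth: float
    true_shifts: dict  # visit -> (delta_mbf, delta_intercept) programmed targets


def simulate_cohort(
    n_responders: int = 15,
    n_nonresponders: int = 5,
    effects_by_group: dict | None = None,
    survival_model: dict | None = None,
    seed: int = 0,
    design: CohortDesign | None = None,
) -> list:
    """Simulate a longitudinal responder / non-responder cohort.

    Per patient: one fixed scatterer field per scan plane (the tissue), one
    matched phantom frame, baseline plus follow-up visits where the group's
    visit effect is applied to the *baseline* field (shifts are programmed
    relative to baseline, as the biomarkers are), and an exponential
    recurrence time.  Patch geometry persists across visits within a patient.
    """
    if n_responders + n_nonresponders < 2:
        raise ValueError("cohort needs at least two patients")
    effects = DEFAULT_EFFECTS if effects_by_group is None else effects_by_group
    for g in effects:
        if g not in ("responder", "non-responder"):
            raise KeyError(f"unknown group key {g!r} in effects_by_group")
    surv = dict(DEFAULT_SURVIVAL)
    if survival_model:
        surv.update(survival_model)
    design = design or CohortDesign()
    pulse = make_pulse(
        design.pulse_centre_frequency, design.pulse_bandwidth, design.pulse_sampling_frequency
    )
    axial_pitch = SPEED_OF_SOUND_MM_US / (2.0 * pulse.sampling_frequency)
    frame_shape = (
        int(round(design.extent[0] / axial_pitch)),
        int(round(design.extent[1] / design.lateral_pitch)),
    )

    labels = ["responder"] * n_responders + ["non-responder"] * n_nonresponders
    seeds = np.random.SeedSequence(seed).spawn(len(labels))
    patients = []
    for k, (label, ss) in enumerate(zip(labels, seeds)):
        rng = np.random.default_rng(ss)
        pid = f"P{k + 1:03d}"
        gain = float(rng.uniform(*design.gain_range))
        radius3d = float(rng.uniform(*design.tumor_radius_range))
        center = (design.focal_depth, design.extent[1] / 2.0)

        offsets = (np.arange(design.n_planes) - (design.n_planes - 1) / 2.0) * design.plane_spacing
        plane_radii = np.sqrt(np.maximum(radius3d**2 - offsets**2, 0.0))
        keep = plane_radii >= design.min_plane_radius
        plane_radii = plane_radii[keep]
        if plane_radii.size == 0:
            plane_radii = np.array([radius3d])

        base_fields, masks, patch_sets = [], [], []
        for r in plane_radii:
            fld = make_scatterer_field(design.extent, design.density, 1.0, rng)
            tmask = circular_mask(frame_shape, axial_pitch, design.lateral_pitch, center, r)
            mark_tumor(fld, tmask, design.tumor_echogenicity_db)
            base_fields.append(fld)
            masks.append(tmask)
            # patches drawn once per patient-plane; fraction/scale taken from
            # the first follow-up effect (identical across visits by default)
            first_eff = next(iter(effects[label].values()))
            patch_sets.append(
                sample_patches(tmask, first_eff.heterogeneity_fraction, first_eff.patch_scale, rng)
            )

        phantom = simulate_phantom_frame(
            pulse,
            AcquisitionSettings(
                extent=design.extent,
                lateral_pitch=design.lateral_pitch,
                focal_depth=design.focal_depth,
                gain=gain,
                gain_id="g0",
                density=design.density,
                noise_sd=design.noise_sd,
            ),
            rng,
        )
        phantom.patient_id = pid

        frames_by_visit, masks_by_visit, true_shifts = {}, {}, {}
        for visit in design.visits:
            frames, vmasks = [], []
            if visit == "wk0":
                drawn = (0.0, 0.0)
                vis_fields = base_fields
            else:
                eff = effects[label].get(visit)
                if eff is None:
                    continue
                drawn = (
                    float(rng.normal(eff.mbf_shift_mean, eff.mbf_shift_sd)),
                    float(rng.normal(eff.intercept_shift_mean, eff.intercept_shift_sd)),
                )
                vis_fields = [
                    apply_response_effect(
                        f,
                        eff,
                        m,
                        rng,
                        patches=p,
                        drawn_shifts=drawn,
                        centre_frequency=design.pulse_centre_frequency,
                    )
                    for f, m, p in zip(base_fields, masks, patch_sets)
                ]
            true_shifts[visit] = drawn
            for ip, (fld, m) in enumerate(zip(vis_fields, masks)):
                frames.append(
                    simulate_rf_frame(
                        fld,
                        pulse,
                        noise_sd=design.noise_sd,
                        seed=rng,
                        lateral_pitch=design.lateral_pitch,
                        focal_depth=design.focal_depth,
                        gain=gain,
                        gain_id="g0",
                        patient_id=pid,
                        visit=visit,
                        plane=ip,
                    )
                )
                vmasks.append(m)
            frames_by_visit[visit] = frames
            masks_by_visit[visit] = vmasks

        median = surv[label]
        t = float(rng.exponential(median / np.log(2.0)))
        censor = surv["censor_months"]
        patients.append(
            SimulatedPatient(
                patient_id=pid,
                true_label=label,
                frames_by_visit=frames_by_visit,
                tumor_masks_by_visit=masks_by_visit,
                phantom_frame=phantom,
                recurrence_time=min(t, censor),
                recurrence_event=bool(t <= censor),
                focal_depth=design.focal_depth,
                true_shifts=true_shifts,
            )
        )
    return patients
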