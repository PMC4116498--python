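"""Phantom-normalised power spectra and sliding-window spectral parameter maps.

Quantitative ultrasound spectroscopy estimates tissue backscatter properties
from the power spectrum of beamformed radiofrequency (RF) echo data.  Each
analysis window (~10 wavelengths long) is Fourier transformed line by line,
averaged, and divided by the spectrum of the *same* window location in a
reference-phantom acquisition made with identical scanner settings.  The
normalisation cancels the system transfer function, beam diffraction and (to
first order) depth-dependent attenuation, leaving a relative spectrum in dBr
(dB relative to the phantom).  A straight line fitted over the transducer's
-6 dB band summarises each window by three parameters:

* mid-band fit (MBF): fitted value at the centre frequency, dBr — tracks
  backscatter power from sub-resolution scatterers;
* spectral slope: gradient in dBr/MHz — sensitive to effective scatterer size;
* 0-MHz intercept: extrapolated fit at 0 MHz, dBr — sensitive to scatterer
  concentration and theoretically attenuation-free.

Sliding the window over the frame on a regular grid yields parametric maps,
one value per window centre, which downstream modules quantise for texture
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: speed of sound used for all delay/pitch computations, mm/us
SPEED_OF_SOUND_MM_US = 1.54


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RFFrame:
    """One beamformed RF echo frame (axial fast-time x lateral line index).

    Parameters
    ----------
    samples
        2-D float array, shape ``(n_axial, n_lines)``.
    sampling_frequency, centre_frequency
        MHz.  The axial sample pitch follows as ``c / (2 * fs)``.
    fractional_bandwidth
        -6 dB fractional bandwidth of the calibration pulse (dimensionless).
    focal_depth
        Transducer focal depth in mm.
    gain_id
        Identifier of the gain/acquisition setting; phantom normalisation
        refuses to mix settings.
    lateral_pitch
        mm between adjacent scan lines.
    """

    samples: np.ndarray
    sampling_frequency: float
    centre_frequency: float
    focal_depth: float
    lateral_pitch: float
    gain_id: str = "g0"
    fractional_bandwidth: float = 0.6
    patient_id: str = ""
    visit: str = ""
    plane: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("RF samples must be a 2-D (axial x lateral) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")
        if not 0 < self.centre_frequency < self.sampling_frequency / 2:
            raise ValueError(
                f"centre frequency {self.centre_frequency} MHz must lie below the "
                f"Nyquist frequency {self.sampling_frequency / 2} MHz"
            )

    @property
    def axial_pitch(self) -> float:
        """Axial mm per sample: c / (2 fs)."""
        return SPEED_OF_SOUND_MM_US / (2.0 * self.sampling_frequency)

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    def settings_key(self) -> tuple:
        """Acquisition-setting key used to match a phantom reference."""
        return (
            self.samples.shape,
            round(self.sampling_frequency, 9),
            round(self.centre_frequency, 9),
            round(self.lateral_pitch, 9),
            round(self.focal_depth, 9),
            self.gain_id,
        )


@dataclass(frozen=True)
class AnalysisBand:
    """The -6 dB analysis band of the calibration pulse, MHz."""

    f_low: float
    f_centre: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_centre < self.f_high:
            raise ValueError("band must satisfy 0 < f_low < f_centre < f_high")


@dataclass(frozen=True)
class SpectralFit:
    """Straight-line summary of one normalised window spectrum."""

    mbf: float  # dBr at f_centre
    slope: float  # dBr/MHz
    intercept0: float  # dBr at 0 MHz

    def __post_init__(self) -> None:
        # mbf = slope * f_centre + intercept0 holds by construction; nothing to
        # enforce here beyond finiteness.
        if not all(np.isfinite([self.mbf, self.slope, self.intercept0])):
            raise ValueError("spectral fit parameters must be finite")


@dataclass
class ParametricMaps:
    """MBF / slope / 0-MHz-intercept maps on the sliding-window grid.

    Invalid pixels (empty windows, masked bands) carry NaN in the value arrays
    and ``False`` in ``valid_mask`` — never a silent zero.
    """

    mbf: np.ndarray
    slope: np.ndarray
    intercept0: np.ndarray
    valid_mask: np.ndarray
    axial_centers: np.ndarray  # sample index of each map row's window centre
    lateral_centers: np.ndarray  # line index of each map column's window centre
    axial_pitch: float
    lateral_pitch: float
    focal_depth: float
    band: AnalysisBand
    window_length: int  # axial samples
    window_lines: int
    config: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.mbf.shape

    def map_roi(self, frame_mask: np.ndarray) -> np.ndarray:
        """Project a frame-space boolean mask onto the map grid.

        A map pixel is inside the ROI when the frame pixel at its window
        centre is inside.
        """
        frame_mask = np.asarray(frame_mask, dtype=bool)
        return frame_mask[np.ix_(self.axial_centers, self.lateral_centers)]

    def focal_row(self) -> int:
        """Map row whose window centre is closest to the focal depth."""
        depths = self.axial_centers * self.axial_pitch
        return int(np.argmin(np.abs(depths - self.focal_depth)))

    def parameter(self, name: str) -> np.ndarray:
        try:
            return {"mbf": self.mbf, "slope": self.slope, "intercept0": self.intercept0}[name]
        except KeyError:
            raise KeyError(f"unknown spectral parameter {name!r}") from None


# ---------------------------------------------------------------------------
# calibration pulse helpers (shared with the simulator)
# ---------------------------------------------------------------------------

# -6 dB in power is a factor 10**0.6; for a Gaussian power spectrum
# exp(-(f-fc)^2 / (2 s^2)) the -6 dB half-width is s*sqrt(1.2 ln 10).
_HALFWIDTH_SIGMAS = float(np.sqrt(1.2 * np.log(10.0)))


def gaussian_pulse_taps(
    centre_frequency: float, fractional_bandwidth: float, sampling_frequency: float
) -> np.ndarray:
    """Sampled Gaussian-envelope tone burst with the given -6 dB bandwidth."""
    if centre_frequency >= sampling_frequency / 2:
        raise ValueError(
            f"centre frequency {centre_frequency} MHz is at or above the Nyquist "
            f"frequency {sampling_frequency / 2} MHz (aliasing)"
        )
    if not 0 < fractional_bandwidth <= 1:
        raise ValueError("fractional bandwidth must lie in (0, 1]")
    # sigma of the *power* spectrum; the amplitude-spectrum sigma is sqrt(2)
    # larger, hence the extra sqrt(2) in the envelope width
    sigma_f = fractional_bandwidth * centre_frequency / (2.0 * _HALFWIDTH_SIGMAS)
    sigma_t = 1.0 / (2.0 * np.pi * np.sqrt(2.0) * sigma_f)  # us
    half = int(np.ceil(4.0 * sigma_t * sampling_frequency))
    half = max(half, 2)
    t = np.arange(-half, half + 1) / sampling_frequency
    taps = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.cos(2.0 * np.pi * centre_frequency * t)
    return taps


def pulse_power_spectrum(taps: np.ndarray, sampling_frequency: float, nfft: int = 4096):
    """Densely sampled one-sided power spectrum of a pulse."""
    spec = np.abs(np.fft.rfft(taps, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sampling_frequency)
    return freqs, spec


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_window_spectrum(
    frame: RFFrame, ax_start: int, ax_len: int, lat_start: int, n_lines: int
):
    """Average per-line Hann-tapered periodograms of one analysis window.

    Returns ``(freqs_MHz, power_linear)``.  An all-zero window returns an
    all-zero spectrum (the caller masks it; no -inf is produced here).
    """
    if ax_len < 2 or n_lines < 1:
        raise ValueError("window must span at least 2 samples and 1 line")
    if ax_start < 0 or lat_start < 0 or ax_start + ax_len > frame.n_axial or (
        lat_start + n_lines > frame.n_lines
    ):
        raise ValueError("analysis window exceeds the frame bounds")
    segment = frame.samples[ax_start : ax_start + ax_len, lat_start : lat_start + n_lines]
    taper = hann(ax_len, sym=False)
    spec = np.fft.rfft(segment * taper[:, None], axis=0)
    # scale is arbitrary (it cancels in phantom normalisation) but kept
    # periodogram-like for standalone use
    power = (np.abs(spec) ** 2).mean(axis=1) / (ax_len * np.sum(taper**2))
    freqs = np.fft.rfftfreq(ax_len, d=1.0 / frame.sampling_frequency)
    return freqs, power


def normalize_spectrum(
    sample_spectrum: np.ndarray,
    reference_spectrum: np.ndarray,
    freqs: np.ndarray | None = None,
    reference_freqs: np.ndarray | None = None,
    floor_rel: float = 1e-12,
):
    """Per-bin log ratio of a tissue spectrum to the phantom reference, in dBr.

    Returns ``(db, mask)`` where ``mask`` flags bins with a usable ratio.
    Bins where the reference falls below ``floor_rel`` times its maximum, or
    where the sample power is non-positive, are masked (NaN) instead of
    producing huge or infinite dBr values.
    """
    sample_spectrum = np.asarray(sample_spectrum, dtype=float)
    reference_spectrum = np.asarray(reference_spectrum, dtype=float)
    if sample_spectrum.shape != reference_spectrum.shape:
        raise ValueError("sample and reference spectra have mismatched shapes")
    if freqs is not None and reference_freqs is not None:
        if not np.allclose(freqs, reference_freqs):
            raise ValueError("sample and reference frequency axes differ")
    ref_max = reference_spectrum.max() if reference_spectrum.size else 0.0
    mask = (reference_spectrum > floor_rel * ref_max) & (sample_spectrum > 0) & (ref_max > 0)
    db = np.full_like(sample_spectrum, np.nan)
    db[mask] = 10.0 * np.log10(sample_spectrum[mask] / reference_spectrum[mask])
    return db, mask


def determine_band(freqs: np.ndarray, power: np.ndarray) -> AnalysisBand:
    """Locate the -6 dB band around the spectral peak of a calibration pulse.

    The centre is the peak frequency; the edges are where the power first
    falls 6 dB below the peak on either side, located by linear interpolation
    of the dB spectrum between bins.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.shape != power.shape or freqs.ndim != 1:
        raise ValueError("freqs and power must be matching 1-D arrays")
    k = int(np.argmax(power))
    if k == 0 or k == len(power) - 1:
        raise ValueError("spectral peak sits at the edge of the frequency axis; no -6 dB band")
    pmax = power[k]
    if pmax <= 0:
        raise ValueError("calibration spectrum has no positive peak")
    thr = pmax * 10.0 ** (-0.6)  # -6 dB in power

    def _edge(indices) -> float:
        prev = k
        for i in indices:
            if power[i] < thr:
                # dB-linear interpolation between bins i and prev
                p_lo, p_hi = power[i], power[prev]
                d_lo = 10 * np.log10(max(p_lo, 1e-300) / pmax)
                d_hi = 10 * np.log10(p_hi / pmax)
                w = (-6.0 - d_hi) / (d_lo - d_hi)
                return float(freqs[prev] + w * (freqs[i] - freqs[prev]))
            prev = i
        raise ValueError("-6 dB band edge not found inside the frequency axis")

    f_low = _edge(range(k - 1, -1, -1))
    f_high = _edge(range(k + 1, len(power)))
    return AnalysisBand(f_low=f_low, f_centre=float(freqs[k]), f_high=f_high)


def fit_spectrum(
    freqs: np.ndarray,
    db: np.ndarray,
    band: AnalysisBand,
    mask: np.ndarray | None = None,
    min_bins: int = 3,
) -> SpectralFit:
    """Ordinary least squares of the dBr spectrum vs frequency over the band."""
    freqs = np.asarray(freqs, dtype=float)
    db = np.asarray(db, dtype=float)
    sel = (freqs >= band.f_low) & (freqs <= band.f_high) & np.isfinite(db)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if sel.sum() < min_bins:
        raise ValueError(
            f"only {int(sel.sum())} usable bins inside the analysis band "
            f"(need >= {min_bins})"
        )
    slope, intercept0 = np.polyfit(freqs[sel], db[sel], 1)
    return SpectralFit(
        mbf=float(slope * band.f_centre + intercept0),
        slope=float(slope),
        intercept0=float(intercept0),
    )


# ---------------------------------------------------------------------------
# sliding-window mapper
# ---------------------------------------------------------------------------


def _window_grid(frame: RFFrame, window_wavelengths: float, overlap: float):
    """Axial/lateral window length, step and start indices for a frame."""
    # a window of N wavelengths in depth spans 2*N*fs/fc fast-time samples
    ax_len = int(round(window_wavelengths * 2.0 * frame.sampling_frequency / frame.centre_frequency))
    ax_len = max(ax_len, 4)
    lat_len = max(1, int(round(ax_len * frame.axial_pitch / frame.lateral_pitch)))
    ax_step = max(1, int(round(ax_len * (1.0 - overlap))))
    lat_step = max(1, int(round(lat_len * (1.0 - overlap))))
    if ax_len > frame.n_axial or lat_len > frame.n_lines:
        raise ValueError("frame is smaller than one analysis window")
    ax_starts = np.arange(0, frame.n_axial - ax_len + 1, ax_step)
    lat_starts = np.arange(0, frame.n_lines - lat_len + 1, lat_step)
    return ax_len, lat_len, ax_starts, lat_starts


def _window_powers(frame: RFFrame, ax_len: int, lat_len: int, ax_starts, lat_starts):
    """Periodogram power for every window on the grid.

    Returns an array of shape ``(n_ax, n_lat, n_freq)``; vectorised over
    lateral position via a cumulative sum across lines.
    """
    taper = hann(ax_len, sym=False)[:, None]
    n_freq = ax_len // 2 + 1
    out = np.empty((len(ax_starts), len(lat_starts), n_freq))
    for i, a0 in enumerate(ax_starts):
        seg = frame.samples[a0 : a0 + ax_len, :] * taper
        per_line = np.abs(np.fft.rfft(seg, axis=0)) ** 2  # (n_freq, n_lines)
        csum = np.concatenate(
            [np.zeros((n_freq, 1)), np.cumsum(per_line, axis=1)], axis=1
        )
        for j, l0 in enumerate(lat_starts):
            out[i, j] = (csum[:, l0 + lat_len] - csum[:, l0]) / lat_len
    return out


class SpectralMapper(BaseEstimator, TransformerMixin):
    """Sliding-window spectral parameter mapper, fitted on a reference phantom.

    ``fit`` takes the matched phantom :class:`RFFrame` and caches its window
    spectra; ``transform`` maps a patient frame acquired with the *same*
    settings into :class:`ParametricMaps`.  Window-by-window normalisation
    against the same phantom location cancels system and depth effects.

    Parameters
    ----------
    window_wavelengths : float, default 10
        Axial window length in wavelengths at the centre frequency.
    overlap : float, default 0.5
        Fractional overlap between neighbouring windows, both directions.
    band : AnalysisBand or None
        Analysis band; derived from a calibration pulse built from the
        phantom's metadata when None.
    floor_rel : float
        Relative reference floor below which bins are masked.
    """

    def __init__(
        self,
        window_wavelengths: float = 10.0,
        overlap: float = 0.5,
        band: AnalysisBand | None = None,
        floor_rel: float = 1e-12,
        min_band_bins: int = 3,
    ):
        self.window_wavelengths = window_wavelengths
        self.overlap = overlap
        self.band = band
        self.floor_rel = floor_rel
        self.min_band_bins = min_band_bins

    def fit(self, X: RFFrame, y=None) -> "SpectralMapper":
        if not isinstance(X, RFFrame):
            raise TypeError("SpectralMapper.fit expects a phantom RFFrame")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        self.phantom_frame_ = X
        ax_len, lat_len, ax_starts, lat_starts = _window_grid(
            X, self.window_wavelengths, self.overlap
        )
        self.window_length_ = ax_len
        self.window_lines_ = lat_len
        self.ax_starts_ = ax_starts
        self.lat_starts_ = lat_starts
        self.freqs_ = np.fft.rfftfreq(ax_len, d=1.0 / X.sampling_frequency)
        self.phantom_power_ = _window_powers(X, ax_len, lat_len, ax_starts, lat_starts)
        if self.band is not None:
            self.band_ = self.band
        else:
            taps = gaussian_pulse_taps(
                X.centre_frequency, X.fractional_bandwidth, X.sampling_frequency
            )
            self.band_ = determine_band(*pulse_power_spectrum(taps, X.sampling_frequency))
        self.band_sel_ = (self.freqs_ >= self.band_.f_low) & (self.freqs_ <= self.band_.f_high)
        if self.band_sel_.sum() < self.min_band_bins:
            raise ValueError("analysis band covers fewer bins than min_band_bins")
        return self

    def transform(self, X: RFFrame) -> ParametricMaps:
        if not hasattr(self, "phantom_frame_"):
            raise RuntimeError("SpectralMapper must be fitted on a phantom frame first")
        if X.settings_key() != self.phantom_frame_.settings_key():
            raise ValueError(
                "frame acquisition settings do not match the fitted phantom; "
                "normalisation would be invalid"
            )
        ax_len, lat_len = self.window_length_, self.window_lines_
        power = _window_powers(X, ax_len, lat_len, self.ax_starts_, self.lat_starts_)
        ref = self.phantom_power_
        sel = self.band_sel_
        fb = self.freqs_[sel]
        n_ax, n_lat, _ = power.shape

        ref_band = ref[:, :, sel]
        sam_band = power[:, :, sel]
        ref_max = ref_band.max(axis=2, keepdims=True)
        usable = (ref_band > self.floor_rel * np.maximum(ref_max, 1e-300)) & (sam_band > 0)
        n_usable = usable.sum(axis=2)

        mbf = np.full((n_ax, n_lat), np.nan)
        slope = np.full((n_ax, n_lat), np.nan)
        intercept = np.full((n_ax, n_lat), np.nan)
        valid = n_usable >= self.min_band_bins

        full = valid & (n_usable == sel.sum())
        if np.any(full):
            db = 10.0 * np.log10(sam_band[full] / ref_band[full])  # (n_full, nb)
            A = np.column_stack([fb, np.ones_like(fb)])
            coef, *_ = np.linalg.lstsq(A, db.T, rcond=None)
            slope[full] = coef[0]
            intercept[full] = coef[1]
        partial = valid & ~full
        for i, j in zip(*np.nonzero(partial)):
            u = usable[i, j]
            db_ij = 10.0 * np.log10(sam_band[i, j, u] / ref_band[i, j, u])
            s, b0 = np.polyfit(fb[u], db_ij, 1)
            slope[i, j], intercept[i, j] = s, b0
        mbf[valid] = slope[valid] * self.band_.f_centre + intercept[valid]

        return ParametricMaps(
            mbf=mbf,
            slope=slope,
            intercept0=intercept,
            valid_mask=valid,
            axial_centers=self.ax_starts_ + ax_len // 2,
            lateral_centers=self.lat_starts_ + lat_len // 2,
            axial_pitch=X.axial_pitch,
            lateral_pitch=X.lateral_pitch,
            focal_depth=X.focal_depth,
            band=self.band_,
            window_length=ax_len,
            window_lines=lat_len,
            config={
                "window_wavelengths": self.window_wavelengths,
                "overlap": self.overlap,
                "taper": "hann",
                "averaging": "linear-power, per-line periodograms",
                "floor_rel": self.floor_rel,
            },
        )


def compute_parametric_maps(
    frame: RFFrame,
    phantom_frame: RFFrame,
    window_length_wavelengths: float = 10.0,
    window_overlap: float = 0.5,
    band: AnalysisBand | None = None,
) -> ParametricMaps:
    """Functional wrapper around :class:`SpectralMapper` for one frame."""
    mapper = SpectralMapper(
        window_wavelengths=window_length_wavelengths, overlap=window_overlap, band=band
    )
    return mapper.fit(phantom_frame).transform(frame)
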