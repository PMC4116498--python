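"""RF simulator: pulse spectra, scatterer statistics, linearity, response."""

import numpy as np
import pytest
from scipy.signal import hilbert

import qustex as qx
from qustex.simulate import (
    AcquisitionSettings,
    RasterMask,
    ScattererField,
    apply_response_effect,
    circular_mask,
    make_pulse,
    make_scatterer_field,
    mark_tumor,
    simulate_phantom_frame,
    simulate_rf_frame,
)
from qustex.spectral import SPEED_OF_SOUND_MM_US, compute_parametric_maps, determine_band


class TestPulse:
    def test_spectral_peak_at_centre_frequency(self):
        p = make_pulse(7.0, 0.6, 40.0)
        freqs, spec = p.power_spectrum(nfft=4096)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - 7.0) <= 40.0 / 4096

    def test_minus6db_band_straddles_centre(self):
        p = make_pulse(7.0, 0.6, 40.0)
        band = determine_band(*p.power_spectrum())
        assert band.f_low < 7.0 < band.f_high

    def test_bandwidth_scales_with_fractional_bandwidth(self):
        # -6 dB width of the bw=0.6 pulse is ~2x that of the bw=0.3 pulse,
        # measured on the DFT of the generated taps
        widths = {}
        for bw in (0.3, 0.6):
            band = determine_band(*make_pulse(7.0, bw, 40.0).power_spectrum(nfft=8192))
            widths[bw] = band.f_high - band.f_low
        assert widths[0.6] / widths[0.3] == pytest.approx(2.0, abs=0.1)
        assert widths[0.6] == pytest.approx(0.6 * 7.0, abs=0.1)

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="[Nn]yquist|alias"):
            make_pulse(25.0, 0.6, 40.0)

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            make_pulse(7.0, 0.0, 40.0)


class TestScattererField:
    def test_seed_determinism(self):
        a = make_scatterer_field((10.0, 10.0), density=50.0, seed=1)
        b = make_scatterer_field((10.0, 10.0), density=50.0, seed=1)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_expected_count_and_moments(self):
        f = make_scatterer_field((20.0, 20.0), density=100.0, amplitude_sd=2.0, seed=3)
        n = len(f.amplitudes)
        assert abs(n - 100.0 * 400.0) < 5 * np.sqrt(100.0 * 400.0)
        assert abs(f.amplitudes.mean()) < 5 * 2.0 / np.sqrt(n)
        assert f.amplitudes.std() == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("bad", [dict(density=0.0), dict(extent=(0.0, 10.0))])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(extent=(10.0, 10.0), density=10.0, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            make_scatterer_field(**kwargs)

    def test_density_doubling_doubles_mean_power(self, pulse):
        # incoherent regime: mean backscattered power proportional to density,
        # averaged over >= 50 field realizations
        powers = {d: [] for d in (60.0, 120.0)}
        for seed in range(50):
            for d in powers:
                f = make_scatterer_field((6.0, 4.0), density=d, seed=seed * 2 + int(d))
                fr = simulate_rf_frame(f, pulse, noise_sd=0.0, seed=0, lateral_pitch=0.2)
                powers[d].append(np.mean(fr.samples**2))
        ratio = np.mean(powers[120.0]) / np.mean(powers[60.0])
        assert ratio == pytest.approx(2.0, abs=0.2)


class TestFrameSynthesis:
    def test_empty_field_gives_zero_frame(self, pulse):
        f = ScattererField(
            extent=(5.0, 5.0),
            positions=np.zeros((0, 2)),
            amplitudes=np.zeros(0),
            region_labels=np.zeros(0, dtype=int),
            density=1.0,
        )
        fr = simulate_rf_frame(f, pulse, noise_sd=0.0, seed=0)
        assert np.all(fr.samples == 0.0)

    def test_linearity_in_amplitudes(self, pulse):
        f = make_scatterer_field((8.0, 6.0), density=30.0, seed=5)
        f2 = f.copy()
        f2.amplitudes *= 2.0
        a = simulate_rf_frame(f, pulse, noise_sd=0.0, seed=0).samples
        b = simulate_rf_frame(f2, pulse, noise_sd=0.0, seed=0).samples
        assert np.allclose(b, 2.0 * a, atol=1e-12)

    def test_superposition(self, pulse):
        f1 = make_scatterer_field((8.0, 6.0), density=20.0, seed=6)
        f2 = make_scatterer_field((8.0, 6.0), density=20.0, seed=7)
        both = ScattererField(
            extent=(8.0, 6.0),
            positions=np.vstack([f1.positions, f2.positions]),
            amplitudes=np.concatenate([f1.amplitudes, f2.amplitudes]),
            region_labels=np.concatenate([f1.region_labels, f2.region_labels]),
            density=40.0,
        )
        a = simulate_rf_frame(f1, pulse, noise_sd=0.0, seed=0).samples
        b = simulate_rf_frame(f2, pulse, noise_sd=0.0, seed=0).samples
        ab = simulate_rf_frame(both, pulse, noise_sd=0.0, seed=0).samples
        assert np.allclose(ab, a + b, atol=1e-10)

    def test_single_scatterer_echo_delay(self, pulse):
        # envelope peak at fast-time delay 2*depth/c, within one sample
        depth = 10.0
        f = ScattererField(
            extent=(20.0, 4.0),
            positions=np.array([[depth, 2.0]]),
            amplitudes=np.array([1.0]),
            region_labels=np.array([0]),
            density=1.0,
        )
        fr = simulate_rf_frame(f, pulse, noise_sd=0.0, seed=0, lateral_pitch=0.2)
        line = fr.samples[:, 10]
        envelope = np.abs(hilbert(line))
        expected = 2.0 * depth / (SPEED_OF_SOUND_MM_US * 1e-3) * 1e-3 / 40.0  # us * MHz
        expected_sample = 2.0 * depth / SPEED_OF_SOUND_MM_US * 40.0 / 2.0
        # axial pitch is c/(2 fs): sample index = depth / pitch
        expected_sample = depth / fr.axial_pitch
        assert abs(int(np.argmax(envelope)) - expected_sample) <= 1.0


class TestPhantom:
    def test_same_seed_same_settings_identical(self, pulse):
        s = AcquisitionSettings(extent=(10.0, 8.0))
        a = simulate_phantom_frame(pulse, s, seed=3)
        b = simulate_phantom_frame(pulse, s, seed=3)
        assert np.array_equal(a.samples, b.samples)

    def test_phantom_library_keyed_by_settings(self, pulse):
        lib = {}
        for gid, gain in (("g_lo", 0.8), ("g_hi", 1.6)):
            s = AcquisitionSettings(extent=(10.0, 8.0), gain=gain, gain_id=gid)
            ph = simulate_phantom_frame(pulse, s, seed=1)
            lib[ph.settings_key()] = ph
        assert len(lib) == 2
        probe = simulate_phantom_frame(
            pulse, AcquisitionSettings(extent=(10.0, 8.0), gain=1.6, gain_id="g_hi"), seed=9
        )
        assert probe.settings_key() in lib


def _tumor_setup(seed, extent=(12.0, 12.0), radius=4.0):
    rng = np.random.default_rng(seed)
    fld = make_scatterer_field(extent, seed=rng)
    ap = SPEED_OF_SOUND_MM_US / 80.0
    shape = (int(round(extent[0] / ap)), int(round(extent[1] / 0.2)))
    tmask = circular_mask(shape, ap, 0.2, (extent[0] / 2, extent[1] / 2), radius)
    mark_tumor(fld, tmask, -3.0)
    return fld, tmask, rng


class TestResponseEffect:
    def test_zero_fraction_returns_field_unchanged(self):
        fld, tmask, rng = _tumor_setup(0)
        eff = qx.ResponseEffect("wk1", 5.0, 0.0, 5.0, 0.0, heterogeneity_fraction=0.0)
        out = apply_response_effect(fld, eff, tmask, rng)
        assert np.array_equal(out.amplitudes, fld.amplitudes)

    def test_full_fraction_fixed_shift_doubles_tumor_amplitudes(self):
        # 20*log10(2) dBr applied homogeneously doubles every tumour amplitude
        fld, tmask, rng = _tumor_setup(1)
        delta = 20.0 * np.log10(2.0)
        eff = qx.ResponseEffect("wk1", delta, 0.0, delta, 0.0, 1.0, 2.0, 0.0)
        out = apply_response_effect(fld, eff, tmask, rng)
        inside = tmask.contains(fld.positions)
        assert np.allclose(out.amplitudes[inside], 2.0 * fld.amplitudes[inside], rtol=1e-9)
        assert np.array_equal(out.amplitudes[~inside], fld.amplitudes[~inside])

    def test_mask_extent_mismatch_rejected(self):
        fld, _, rng = _tumor_setup(2)
        wrong = circular_mask((100, 50), 0.05, 0.2, (2.0, 2.0), 1.0)
        eff = qx.ResponseEffect("wk1", 3.0, 0.0, 3.0, 0.0)
        with pytest.raises(ValueError, match="extent"):
            apply_response_effect(fld, eff, wrong, rng)

    def test_invalid_effect_parameters_rejected(self):
        with pytest.raises(ValueError):
            qx.ResponseEffect("wk1", 1.0, 0.0, 1.0, 0.0, heterogeneity_fraction=1.5)
        with pytest.raises(ValueError):
            qx.ResponseEffect("wk1", 1.0, -1.0, 1.0, 0.0)


class TestCohort:
    def test_structure_and_determinism(self):
        from .conftest import SMALL_DESIGN

        a = qx.simulate_cohort(2, 2, seed=5, design=SMALL_DESIGN)
        b = qx.simulate_cohort(2, 2, seed=5, design=SMALL_DESIGN)
        assert [p.true_label for p in a] == ["responder"] * 2 + ["non-responder"] * 2
        for pa, pb in zip(a, b):
            assert pa.recurrence_time == pb.recurrence_time
            for visit in pa.frames_by_visit:
                for fa, fb in zip(pa.frames_by_visit[visit], pb.frames_by_visit[visit]):
                    assert np.array_equal(fa.samples, fb.samples)
        for p in a:
            assert "wk0" in p.frames_by_visit  # baseline always present
            assert p.recurrence_time <= 50.0
            for frames in p.frames_by_visit.values():
                for fr in frames:
                    assert fr.settings_key() == p.phantom_frame.settings_key()

    def test_unknown_group_key_rejected(self):
        with pytest.raises(KeyError):
            qx.simulate_cohort(2, 2, effects_by_group={"responders": {}}, seed=0)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            qx.simulate_cohort(1, 0, seed=0)

    def test_null_effects_give_indistinguishable_groups(self, small_phantom):
        # with all effect sizes zero, responder and non-responder week-1 MBF
        # shifts are statistically indistinguishable in >= 90% of cohorts
        from scipy.stats import ks_2samp

        from .conftest import SMALL_DESIGN

        null = qx.ResponseEffect("wk1", 0.0, 0.0, 0.0, 0.0, 0.75, 2.0, 0.0)
        effects = {"responder": {"wk1": null}, "non-responder": {"wk1": null}}
        design = SMALL_DESIGN
        import dataclasses

        design = dataclasses.replace(design, visits=("wk0", "wk1"))
        n_reject = 0
        for seed in range(20):
            patients = qx.simulate_cohort(
                8, 8, effects_by_group=effects, seed=1000 + seed, design=design
            )
            shifts = {"responder": [], "non-responder": []}
            for p in patients:
                mapper = qx.SpectralMapper().fit(p.phantom_frame)
                vals = {}
                for visit in ("wk0", "wk1"):
                    m = mapper.transform(p.frames_by_visit[visit][0])
                    roi = qx.roi_from_tumor_mask(
                        m.map_roi(p.tumor_masks_by_visit[visit][0].mask), m.focal_row()
                    )
                    vals[visit] = float(np.mean(m.mbf[roi & m.valid_mask]))
                shifts[p.true_label].append(vals["wk1"] - vals["wk0"])
            p_val = ks_2samp(shifts["responder"], shifts["non-responder"]).pvalue
            n_reject += p_val <= 0.05
        assert n_reject <= 2  # >= 90% of 20 cohorts indistinguishable

    def test_patch_scale_monotonicity_of_map_contrast(self, phantom, pulse):
        # at matched mean shift, smaller patches do not decrease mean GLCM
        # contrast of the MBF map (more patch boundaries per unit area).
        # A fixed quantization range puts all maps on one gray-level mapping;
        # under per-map min-max the comparison would instead be confounded by
        # the larger dynamic range of coarse-patch maps.
        contrasts = {2.0: [], 4.0: []}
        for seed in range(20):
            for scale in contrasts:
                fld, tmask, _ = _tumor_setup(seed, extent=(20.0, 20.0), radius=7.5)
                eff = qx.ResponseEffect("wk1", 3.7, 0.0, 3.7, 0.0, 0.5, scale, 4.0)
                out = apply_response_effect(fld, eff, tmask, np.random.default_rng(seed))
                fr = simulate_rf_frame(
                    out, pulse, noise_sd=0.01, seed=seed, lateral_pitch=0.2, focal_depth=10.0
                )
                m = compute_parametric_maps(fr, phantom)
                roi = qx.roi_from_tumor_mask(m.map_roi(tmask.mask), m.focal_row())
                feats = qx.texture_of_map(
                    m.mbf, roi & m.valid_mask, range_policy="fixed", fixed_range=(-12.0, 10.0)
                )
                contrasts[scale].append(feats.contrast)
        assert np.mean(contrasts[2.0]) >= np.mean(contrasts[4.0])
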