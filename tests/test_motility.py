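"""Peristalsis quantification: spectra, occlusion, propagation, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sinusoid_series
from gastroflow.exceptions import (
    BandResolutionError,
    DegenerateReferenceError,
    InsufficientDataError,
    UnsupportedGeometryError,
)
from gastroflow.motility import (
    AreaTimeSeries,
    FrequencyBand,
    SliceGeometry,
    amplitude_spectrum,
    analyze_timepoint,
    apparent_speed,
    bandpass,
    crosscorr_speed,
    cpm_to_hz,
    dominant_frequency,
    hz_to_cpm,
    occlusion,
    propagation_distance,
    smooth_for_display,
)
from gastroflow.phantom import PhantomSpec, generate_area_signals


class TestSmoothing:
    def test_constant_series_unchanged(self):
        s = AreaTimeSeries(np.full(200, 42.0), 6.24)
        np.testing.assert_allclose(smooth_for_display(s), 42.0)

    def test_linear_ramp_unchanged_in_interior(self):
        areas = np.linspace(10.0, 110.0, 200)
        s = AreaTimeSeries(areas, 6.24)
        smoothed = smooth_for_display(s, window=59, order=1)
        np.testing.assert_allclose(smoothed[29:-29], areas[29:-29], rtol=1e-10)

    def test_nyquist_alternation_attenuated(self):
        areas = 100.0 + np.where(np.arange(300) % 2 == 0, 1.0, -1.0)
        s = AreaTimeSeries(areas, 6.24)
        smoothed = smooth_for_display(s)
        assert np.max(np.abs(smoothed - 100.0)) < 1.0

    def test_short_series_window_reduced(self, caplog):
        s = AreaTimeSeries(np.linspace(1, 2, 20), 6.24)
        with caplog.at_level("WARNING"):
            smoothed = smooth_for_display(s, window=59)
        assert smoothed.shape == (20,)
        assert any("reducing window" in r.message for r in caplog.records)

    def test_even_window_rejected(self):
        s = AreaTimeSeries(np.ones(100), 6.24)
        with pytest.raises(ValueError):
            smooth_for_display(s, window=58)


class TestSpectrum:
    def test_grid_sinusoid_occupies_single_bin(self):
        s = make_sinusoid_series(0.05, amplitude=10.0)
        freqs, amps = amplitude_spectrum(s)
        peak = np.argmax(amps)
        others = np.delete(amps, peak)
        assert amps[peak] == pytest.approx(10.0, rel=1e-9)
        assert np.all(others <= 1e-9 * amps[peak])

    def test_constant_signal_zero_spectrum(self):
        s = AreaTimeSeries(np.full(128, 7.0), 6.24)
        _, amps = amplitude_spectrum(s)
        np.testing.assert_allclose(amps, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n", [128, 129])
    def test_parseval_identity(self, n):
        rng = np.random.default_rng(0)
        x = rng.normal(100.0, 5.0, n)
        s = AreaTimeSeries(np.abs(x), 6.24)
        _, amps = amplitude_spectrum(s)
        if n % 2 == 0:
            power = np.sum(amps[1:-1] ** 2) / 2.0 + amps[-1] ** 2
        else:
            power = np.sum(amps[1:] ** 2) / 2.0
        assert power == pytest.approx(np.var(s.areas), rel=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            amplitude_spectrum(AreaTimeSeries(np.ones(8), 6.24))


class TestDominantFrequency:
    def test_synthetic_3cpm_recovered_within_one_bin(self):
        s = make_sinusoid_series(0.05, on_grid=False)
        freqs, amps = amplitude_spectrum(s)
        result = dominant_frequency(freqs, amps)
        bin_cpm = hz_to_cpm(s.frame_rate / len(s))
        assert result.valid
        assert result.dominant_frequency_cpm == pytest.approx(3.0, abs=bin_cpm)

    def test_flat_inband_spectrum_invalid(self):
        freqs = np.linspace(0.0, 0.5, 200)
        amps = np.ones_like(freqs)
        result = dominant_frequency(freqs, amps)
        assert result.dominance_factor == pytest.approx(1.0)
        assert not result.valid
        assert result.dominant_frequency_cpm is None

    def test_tie_breaks_to_lowest_frequency(self):
        freqs = np.linspace(0.0, 0.5, 1000)
        amps = np.zeros_like(freqs)
        in_band = (freqs >= 0.03) & (freqs <= 0.07)
        idx = np.flatnonzero(in_band)
        amps[idx[10]] = 5.0
        amps[idx[30]] = 5.0
        result = dominant_frequency(freqs, amps)
        assert result.peak_frequency_cpm == pytest.approx(hz_to_cpm(freqs[idx[10]]))

    def test_band_coarser_than_resolution_raises(self):
        s = AreaTimeSeries(np.arange(16, dtype=float), 6.24)
        freqs, amps = amplitude_spectrum(s)
        with pytest.raises(BandResolutionError):
            dominant_frequency(freqs, amps)

    def test_band_conversion_endpoints(self):
        band = FrequencyBand(0.03, 0.07)
        assert band.low_cpm == pytest.approx(1.8)
        assert band.high_cpm == pytest.approx(4.2)
        assert cpm_to_hz(4.2) == pytest.approx(0.07)


class TestBandpass:
    def test_inband_grid_sinusoid_reconstructed(self):
        s = make_sinusoid_series(0.05, amplitude=10.0, offset=100.0)
        filtered = bandpass(s)
        expected = s.areas - s.areas.mean()
        np.testing.assert_allclose(filtered, expected, atol=1e-9 * 10.0)

    def test_breathing_component_rejected(self):
        s = make_sinusoid_series(0.2, amplitude=10.0)
        filtered = bandpass(s)
        assert np.sum(filtered**2) <= 1e-9 * np.sum((s.areas - s.areas.mean()) ** 2)

    def test_idempotent(self):
        spec = PhantomSpec(noise_sd=0.05, seed=3)
        s = generate_area_signals(spec)[0]
        once = bandpass(s)
        twice = bandpass(AreaTimeSeries(np.clip(once + s.areas.mean(), 0, None), s.frame_rate))
        np.testing.assert_allclose(twice, once, atol=1e-9)


class TestOcclusion:
    def test_constant_areas_zero_occlusion(self):
        result = occlusion(AreaTimeSeries(np.full(50, 123.0), 6.24))
        np.testing.assert_allclose(result.occlusion_pct, 0.0)
        assert result.mean_occlusion_pct == 0.0

    def test_hand_example_ten_frames(self):
        areas = np.array([100.0] * 9 + [50.0])
        result = occlusion(AreaTimeSeries(areas, 6.24))
        assert result.reference_area == pytest.approx(100.0)
        np.testing.assert_allclose(result.occlusion_pct[:9], 0.0)
        assert result.occlusion_pct[9] == pytest.approx(50.0)
        assert result.mean_occlusion_pct == pytest.approx(5.0)

    def test_areas_above_reference_clip_to_zero(self):
        rng = np.random.default_rng(1)
        areas = rng.uniform(50.0, 150.0, 200)
        result = occlusion(AreaTimeSeries(areas, 6.24))
        assert np.all(result.occlusion_pct >= 0.0)
        assert np.all(result.occlusion_pct <= 100.0)

    def test_all_zero_areas_degenerate(self):
        with pytest.raises(DegenerateReferenceError):
            occlusion(AreaTimeSeries(np.zeros(20), 6.24))

    def test_noiseless_phantom_max_occlusion_matches_depth(self):
        for depth in (0.2, 0.5, 0.8):
            spec = PhantomSpec(occlusion_depth=depth, breathing_amplitude=0, noise_sd=0)
            series = generate_area_signals(spec)[0]
            result = occlusion(series)
            assert result.max_occlusion_pct == pytest.approx(100 * depth, abs=5.0)

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(5)
        areas = rng.uniform(10.0, 100.0, 64)
        base = occlusion(AreaTimeSeries(areas, 6.24))
        scaled = occlusion(AreaTimeSeries(areas * scale, 6.24))
        np.testing.assert_allclose(scaled.occlusion_pct, base.occlusion_pct, rtol=1e-9)


class TestPropagation:
    @pytest.mark.parametrize("df,expected", [(1.5, 30.0), (3.5, 50.0)])
    def test_distance_from_distance_factor(self, df, expected):
        geom = SliceGeometry(slice_thickness=5.0, distance_factor=df)
        assert propagation_distance(geom) == pytest.approx(expected)

    def test_distance_vanishes_with_geometry(self):
        geom = SliceGeometry(slice_thickness=1e-9, distance_factor=0.0)
        assert propagation_distance(geom) == pytest.approx(0.0, abs=1e-8)

    def test_non_three_slice_unsupported(self):
        with pytest.raises(UnsupportedGeometryError):
            propagation_distance(SliceGeometry(n_slices=2))

    def test_apparent_speed_worked_example(self):
        assert apparent_speed(3.0, 34.0) == pytest.approx(1.70)

    def test_apparent_speed_zero_frequency(self):
        assert apparent_speed(0.0, 50.0) == 0.0

    def test_apparent_speed_bilinear(self):
        assert apparent_speed(6.0, 34.0) == pytest.approx(2 * apparent_speed(3.0, 34.0))
        assert apparent_speed(3.0, 68.0) == pytest.approx(2 * apparent_speed(3.0, 34.0))


class TestCrossCorrSpeed:
    def test_noiseless_phantom_speed_within_15_percent(self):
        geom = SliceGeometry(distance_factor=3.0)
        spec = PhantomSpec(
            true_frequency=2.0, wave_speed=1.7, breathing_amplitude=0,
            noise_sd=0, geometry=geom,
        )
        result = crosscorr_speed(generate_area_signals(spec), geom)
        assert result.speed_mm_s == pytest.approx(1.7, rel=0.15)

    def test_identical_signals_absent(self):
        s = make_sinusoid_series(0.05, amplitude=30.0)
        result = crosscorr_speed([s, s, s], SliceGeometry())
        assert result.speed_mm_s is None
        assert abs(result.optimal_lag_s) <= 1.0 / s.frame_rate

    def test_reversed_slice_order_negates_optimal_lag(self):
        geom = SliceGeometry(distance_factor=3.0)
        spec = PhantomSpec(
            true_frequency=2.0, wave_speed=1.7, breathing_amplitude=0,
            noise_sd=0, geometry=geom,
        )
        sigs = generate_area_signals(spec)
        forward = crosscorr_speed(sigs, geom)
        backward = crosscorr_speed(sigs[::-1], geom)
        assert backward.optimal_lag_s == pytest.approx(-forward.optimal_lag_s)

    def test_short_record_rejected(self):
        s = make_sinusoid_series(0.05, n=100)  # 16 s record
        with pytest.raises(InsufficientDataError):
            crosscorr_speed([s, s, s], SliceGeometry())


class TestAnalyzeTimepoint:
    def test_two_valid_slices_aggregate(self, geometry):
        n, fr = 1123, 6.24
        f_a = round(0.05 * n / fr) * fr / n
        f_b = round(0.048 * n / fr) * fr / n
        slices = [
            make_sinusoid_series(f_a, n=n),
            make_sinusoid_series(f_b, n=n),
            AreaTimeSeries(np.full(n, 100.0), fr, slice_index=2),
        ]
        report = analyze_timepoint(slices, geometry)
        assert report.n_valid_slices == 2
        expected = hz_to_cpm((f_a + f_b) / 2)
        assert report.mean_frequency_cpm == pytest.approx(expected)
        assert report.apparent_speed_mm_s == pytest.approx(
            expected / 60.0 * 30.0
        )

    def test_single_valid_slice_suppresses_frequency_not_occlusion(self, geometry):
        n = 1123
        slices = [
            make_sinusoid_series(0.05, n=n),
            AreaTimeSeries(np.full(n, 100.0), 6.24, slice_index=1),
            AreaTimeSeries(np.full(n, 100.0), 6.24, slice_index=2),
        ]
        report = analyze_timepoint(slices, geometry)
        assert report.mean_frequency_cpm is None
        assert report.apparent_speed_mm_s is None
        assert len(report.occlusion) == 3

    def test_all_constant_slices(self, geometry):
        slices = [AreaTimeSeries(np.full(600, 50.0), 6.24, slice_index=i) for i in range(3)]
        report = analyze_timepoint(slices, geometry)
        assert report.n_valid_slices == 0
        assert report.mean_frequency_cpm is None
        for occ in report.occlusion:
            assert occ.mean_occlusion_pct == 0.0

    def test_empty_input_rejected(self, geometry):
        with pytest.raises(InsufficientDataError):
            analyze_timepoint([], geometry)

    def test_scale_invariance_of_frequency_and_dominance(self, geometry):
        spec = PhantomSpec(noise_sd=0.05, seed=11)
        sigs = generate_area_signals(spec)
        scaled = [
            AreaTimeSeries(s.areas * 37.5, s.frame_rate, s.slice_index) for s in sigs
        ]
        r1 = analyze_timepoint(sigs, geometry)
        r2 = analyze_timepoint(scaled, geometry)
        for f1, f2 in zip(r1.frequency, r2.frequency):
            assert f2.peak_frequency_cpm == pytest.approx(f1.peak_frequency_cpm)
            assert f2.dominance_factor == pytest.approx(f1.dominance_factor, rel=1e-9)

    def test_reported_frequencies_inside_band(self, geometry):
        band = FrequencyBand()
        for seed in range(5):
            spec = PhantomSpec(noise_sd=0.1, seed=seed)
            report = analyze_timepoint(generate_area_signals(spec), geometry, band)
            for f in report.frequency:
                if f.valid:
                    assert band.low_cpm <= f.dominant_frequency_cpm <= band.high_cpm
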