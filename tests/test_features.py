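"""Feature extraction: cycle segmentation, rhythm ratios, windowed band
power with its Parseval oracle, relative statistics, and vector assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasotone import (
    GenConfig,
    WaveformCycle,
    band_power,
    build_feature_vector,
    detect_cycles,
    generate_vasomotor,
    relative_amplitude,
    relative_power,
    rhythm_ratio,
)
from tests.conftest import sine


class TestDetectCycles:
    def test_unit_sine_cycle_count_and_symmetry(self):
        cycles = detect_cycles(sine(1, 500, 10.0), 500)
        # interior valley->peak->valley triplets of a 10-s, 1-Hz sine
        # (boundary extrema have reduced prominence and may drop out)
        assert 8 <= len(cycles) <= 10
        assert np.mean([c.t_r for c in cycles]) == pytest.approx(0.5, rel=0.01)
        assert np.mean([c.t_f for c in cycles]) == pytest.approx(0.5, rel=0.01)

    def test_constant_signal_yields_no_cycles(self):
        assert detect_cycles(np.full(1000, 2.0), 500) == []

    def test_constriction_preset_ratio_recovered(self, constriction_signal):
        x, fs = constriction_signal
        rr = rhythm_ratio(detect_cycles(x, fs))
        assert rr["mean"] == pytest.approx(0.6, rel=0.01)

    def test_cycle_amplitude_is_peak_minus_valley_mean(self):
        cycles = detect_cycles(sine(1, 500, 10.0, amp=4.0), 500)
        assert np.mean([c.amplitude for c in cycles]) == pytest.approx(8.0, rel=0.01)


class TestRhythmRatio:
    def test_symmetric_cycles(self):
        cycles = [WaveformCycle(i, i + 0.5, i + 1.0, 1.0) for i in range(5)]
        rr = rhythm_ratio(cycles)
        assert rr["mean"] == 1.0 and rr["sd"] == 0.0

    def test_arithmetic(self):
        rr = rhythm_ratio([WaveformCycle(0.0, 0.3, 0.4, 1.0)])
        assert rr["per_cycle"][0] == pytest.approx(3.0)

    def test_time_reversal_gives_reciprocal(self, constriction_signal):
        x, fs = constriction_signal
        fwd = rhythm_ratio(detect_cycles(x, fs))["mean"]
        rev = rhythm_ratio(detect_cycles(x[::-1], fs))["mean"]
        assert fwd * rev == pytest.approx(1.0, rel=0.02)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            rhythm_ratio([])


class TestBandPower:
    def test_on_bin_tone_recovers_half_squared_amplitude(self):
        # 20 Hz lies two bins from DC at the 100-ms window, where the Hann
        # taper's spread stays clear of the excluded DC bin: estimate is exact
        ps = band_power(sine(20, 1000, 5.0), 1000)
        assert ps.mean_power == pytest.approx(0.5, rel=0.01)

    def test_long_window_resolves_low_tone(self):
        ps = band_power(sine(10, 1000, 10.0), 1000, window=1.0)
        assert ps.mean_power == pytest.approx(0.5, rel=0.01)

    def test_zero_signal(self):
        assert band_power(np.zeros(1000), 1000).mean_power == 0.0

    def test_quadratic_amplitude_scaling(self):
        p1 = band_power(sine(20, 1000, 5.0), 1000).mean_power
        p2 = band_power(sine(20, 1000, 5.0, amp=2.0), 1000).mean_power
        assert p2 / p1 == pytest.approx(4.0, rel=1e-6)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(500), 80.0)

    def test_windowed_matches_single_periodogram_oracle(self):
        # oracle equivalence on a stationary tone: the windowed mean must
        # agree with one full-segment periodogram within leakage tolerance
        x = sine(20, 1000, 8.0) + 0.3 * sine(33, 1000, 8.0)
        windowed = band_power(x, 1000, window=0.1).mean_power
        brute = band_power(x, 1000, window=8.0, overlap=0.0).mean_power
        assert windowed == pytest.approx(brute, rel=0.10)


class TestRelativeStatistics:
    def test_identical_segments_unity(self):
        x = sine(20, 1000, 4.0)
        assert relative_power(x, x, 1000) == pytest.approx(1.0)
        assert relative_amplitude(x, x, 1000) == pytest.approx(1.0)

    def test_doubled_waveform_quadruples_power(self):
        x = sine(20, 1000, 4.0)
        assert relative_power(x, 2 * x, 1000) == pytest.approx(4.0, rel=1e-6)

    def test_tripled_waveform_triples_amplitude(self):
        x = sine(1, 500, 10.0)
        assert relative_amplitude(x, 3 * x, 500) == pytest.approx(3.0, rel=0.01)

    def test_zero_pre_segment_rejected(self):
        x = sine(20, 1000, 2.0)
        with pytest.raises(ValueError):
            relative_power(np.zeros_like(x), x, 1000)
        with pytest.raises(ValueError):
            relative_amplitude(np.zeros_like(x), x, 1000)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_consistency(self, c):
        x = sine(20, 1000, 2.0) + 0.2 * sine(7, 1000, 2.0)
        y = sine(20, 1000, 2.0, amp=1.5)
        base = relative_power(x, y, 1000)
        assert relative_power(c * x, c * y, 1000) == pytest.approx(base, rel=1e-9)

    def test_dose_ratio_matches_full_segment_oracle(self, clean_cfg):
        pre = generate_vasomotor(clean_cfg(dose_scale=0.0, seed=5), "constriction")
        post = generate_vasomotor(clean_cfg(dose_scale=2.0, seed=5), "constriction")
        windowed = relative_power(pre.data[0], post.data[0], pre.fs)
        brute = (
            band_power(post.data[0], post.fs, window=post.duration, overlap=0).mean_power
            / band_power(pre.data[0], pre.fs, window=pre.duration, overlap=0).mean_power
        )
        assert windowed > 1.0
        assert windowed == pytest.approx(brute, rel=0.05)

    def test_dose_series_strictly_increasing(self, clean_cfg):
        # mirrors graded drug administration: 0.1 / 0.2 / 0.4 dose units
        pre = generate_vasomotor(clean_cfg(dose_scale=0.0, seed=8), "dilation")
        ratios = []
        for dose in (0.1, 0.2, 0.4):
            post = generate_vasomotor(clean_cfg(dose_scale=dose, seed=8), "dilation")
            ratios.append(relative_amplitude(pre.data[0], post.data[0], pre.fs))
        assert ratios[0] < ratios[1] < ratios[2]


class TestFeatureVector:
    def test_zero_segment(self):
        fv = build_feature_vector(np.zeros(2000), 1000)
        assert fv.rms == 0 and fv.peak_to_peak == 0 and fv.band_power == 0
        assert np.isnan(fv.rhythm_ratio_mean)

    def test_single_tone_centroid(self):
        fv = build_feature_vector(sine(10, 1000, 10.0), 1000)
        assert fv.spectral_centroid == pytest.approx(10.0, abs=0.5)

    def test_states_differ_in_configured_direction(self, clean_cfg):
        con = generate_vasomotor(clean_cfg(seed=3), "constriction")
        dil = generate_vasomotor(clean_cfg(seed=3), "dilation")
        fv_c = build_feature_vector(con.data[0], con.fs)
        fv_d = build_feature_vector(dil.data[0], dil.fs)
        assert fv_c.rhythm_ratio_mean < 1.0 < fv_d.rhythm_ratio_mean

    def test_relative_fields_only_with_pre_segment(self):
        x = sine(20, 1000, 2.0)
        assert build_feature_vector(x, 1000).relative_power is None
        fv = build_feature_vector(x, 1000, pre=x)
        assert fv.relative_power == pytest.approx(1.0)

    def test_segment_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            build_feature_vector(np.ones(50), 1000)
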