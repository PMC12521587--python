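"""Preprocessing chain: masking criteria, notch/band-pass responses,
common average reference algebra, sliding RMS, and filter properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasotone import (
    MultichannelRecording,
    bandpass,
    car,
    notch,
    remove_bad_channels,
    sliding_rms,
)
from tests.conftest import sine


def rec_of(data, fs=1000.0, **kw):
    return MultichannelRecording(data=np.atleast_2d(np.asarray(data, float)),
                                 fs=fs, **kw)


class TestRemoveBadChannels:
    def test_flat_channel_masked(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 5, (4, 1000))
        data[2] = 0.0
        out = remove_bad_channels(rec_of(data), flat_tol=0.1)
        assert not out.mask[2] and out.mask[[0, 1, 3]].all()

    def test_no_bad_channels_identity(self):
        rng = np.random.default_rng(1)
        out = remove_bad_channels(rec_of(rng.normal(0, 5, (4, 1000))))
        assert out.mask.all()

    def test_three_injected_corruptions_all_caught(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 5, (8, 2000))
        data[1] = 0.02  # flat (constant)
        data[4] = 6000.0 * np.sign(rng.normal(size=2000))  # saturated
        data[6] = np.linspace(0, 0.05, 2000)  # flat drift below tolerance
        out = remove_bad_channels(rec_of(data), flat_tol=0.1, sat_frac=0.01)
        assert (~out.mask).sum() == 3
        assert not out.mask[[1, 4, 6]].any()

    def test_all_masked_is_error(self):
        with pytest.raises(ValueError, match="all channels"):
            remove_bad_channels(rec_of(np.zeros((3, 100))))


class TestNotch:
    def test_mains_tone_suppressed(self):
        x = sine(50, 4000, 5.0)
        out = notch(rec_of(x, fs=4000), mains_freq=50)
        assert np.sqrt(np.mean(out.data**2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_passband_tone_untouched(self):
        x = sine(10, 4000, 5.0)
        out = notch(rec_of(x, fs=4000), mains_freq=50)
        assert np.abs(out.data[0] - x).max() < 0.01

    def test_zero_in_zero_out(self):
        out = notch(rec_of(np.zeros(4000), fs=4000))
        assert np.all(out.data == 0)

    def test_mains_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            notch(rec_of(np.zeros(100), fs=100), mains_freq=50)

    def test_masked_channel_untouched(self):
        data = np.vstack([sine(50, 1000, 2.0), sine(50, 1000, 2.0)])
        rec = rec_of(data, mask=[True, False])
        out = notch(rec)
        assert np.array_equal(out.data[1], data[1])
        assert not np.array_equal(out.data[0], data[0])


class TestCar:
    def test_hand_computed_example(self):
        out = car(rec_of([[1, 2], [3, 4]]))
        assert np.array_equal(out.data, [[-1, -1], [1, 1]])

    def test_identical_channels_cancel(self):
        out = car(rec_of(np.tile(sine(5, 500, 1.0), (4, 1))))
        assert np.allclose(out.data, 0)

    def test_masked_channels_excluded_from_reference(self):
        data = np.array([[1.0, 1.0], [3.0, 3.0], [100.0, 100.0]])
        out = car(rec_of(data, mask=[True, True, False]))
        assert np.allclose(out.data[:2], [[-1, -1], [1, 1]])
        assert np.array_equal(out.data[2], data[2])

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            car(rec_of(np.ones((1, 10))))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_zero_cross_channel_mean(self, seed):
        data = np.random.default_rng(seed).normal(size=(6, 50))
        out = car(rec_of(data))
        assert np.allclose(out.data.mean(axis=0), 0, atol=1e-12)


class TestBandpass:
    def test_passband_gain_near_unity(self):
        x = sine(10, 4000, 10.0)
        out = bandpass(rec_of(x, fs=4000))
        mid = out.data[0, 8000:-8000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.02)

    def test_stopband_attenuation(self):
        # a 500 Hz tone is 10x above the band edge: a 4th-order design
        # applied twice leaves essentially nothing in steady state (the
        # interior; boundary ringing of the 0.5 Hz edge is excluded)
        x = sine(500, 4000, 10.0)
        out = bandpass(rec_of(x, fs=4000))
        mid = out.data[0, 16000:-16000]
        assert np.sqrt(np.mean(mid**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_zero_in_zero_out(self):
        out = bandpass(rec_of(np.zeros(2000), fs=1000))
        assert np.all(out.data == 0)

    @pytest.mark.parametrize("kw", [{"hi": 600}, {"lo": 0}, {"lo": 60, "hi": 50}])
    def test_invalid_band_rejected(self, kw):
        with pytest.raises(ValueError):
            bandpass(rec_of(np.zeros(1000), fs=1000), **kw)

    def test_zero_phase_no_peak_shift(self):
        # a band-limited tone must come through with unshifted peaks
        fs, f0 = 1000.0, 8.0
        x = sine(f0, fs, 10.0)
        out = bandpass(rec_of(x, fs=fs))
        sl = slice(2000, 8000)
        raw_peaks = np.flatnonzero(
            (x[sl][1:-1] > x[sl][:-2]) & (x[sl][1:-1] > x[sl][2:])
        )
        filt = out.data[0, sl]
        filt_peaks = np.flatnonzero(
            (filt[1:-1] > filt[:-2]) & (filt[1:-1] > filt[2:])
        )
        assert np.abs(raw_peaks - filt_peaks).max() <= 1

    def test_idempotent_on_compliant_signal(self):
        # a signal whose spectrum already sits inside the analysis band
        # (2-40 Hz noise) passes the band-pass essentially unchanged
        from scipy import signal as sps

        rng = np.random.default_rng(4)
        sos = sps.butter(4, (2, 40), btype="bandpass", fs=1000, output="sos")
        x = sps.sosfiltfilt(sos, rng.normal(size=(2, 30000)), axis=-1)
        once = bandpass(rec_of(x, fs=1000))
        twice = bandpass(once)
        g = 6000
        rms0 = np.sqrt(np.mean(x[:, g:-g] ** 2))
        rms2 = np.sqrt(np.mean(twice.data[:, g:-g] ** 2))
        assert abs(rms2 - rms0) / rms0 < 0.03

    def test_linearity(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 2000))
        a, b = 2.5, -1.25
        for op in (bandpass, notch):
            lhs = op(rec_of(a * x + b * y, fs=500)).data
            rhs = a * op(rec_of(x, fs=500)).data + b * op(rec_of(y, fs=500)).data
            assert np.allclose(lhs, rhs, atol=1e-9)


class TestSlidingRms:
    def test_constant_signal(self):
        env = sliding_rms(rec_of(np.full(1000, -3.0), fs=1000))
        assert np.allclose(env.values, 3.0)

    def test_unit_sine_integer_cycles(self):
        # 10 Hz with a 100-ms window: exactly one cycle per window
        env = sliding_rms(rec_of(sine(10, 1000, 2.0), fs=1000), window=0.1)
        assert np.allclose(env.values, 1 / np.sqrt(2), rtol=0.01)

    def test_zero_signal(self):
        env = sliding_rms(rec_of(np.zeros(500), fs=500))
        assert np.all(env.values == 0)

    def test_trailing_partial_window_dropped(self):
        env = sliding_rms(rec_of(np.ones(1050), fs=1000), window=0.1, hop=0.05)
        assert env.n_windows == 20  # 1050 samples: last start at 950

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError):
            sliding_rms(rec_of(np.ones(50), fs=1000), window=0.1)
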