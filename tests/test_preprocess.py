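"""Filtering, Beer-Lambert conversion, standardization, resampling."""

import numpy as np
import pytest

from msvdfuse.preprocess import (FilterSpec, MbllParams, baseline_standardize,
                                 butterworth_filter, downsample, mbll,
                                 moving_average_downsize, power_envelope,
                                 synchronize)
from msvdfuse.signal_io import Modality, Recording


def tone(freq, fs, dur, n_channels=1, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return Recording(np.tile(amp * np.sin(2 * np.pi * freq * t), (n_channels, 1)),
                     fs=fs, channel_names=[f"c{i}" for i in range(n_channels)])


class TestButterworth:
    def test_midband_tone_passes_unattenuated(self):
        rec = tone(10.0, 250.0, 8.0)
        out = butterworth_filter(rec, FilterSpec("bandpass", 1.0, 50.0, 4,
                                                 zero_phase=True))
        steady = out.data[0, 500:-500]
        assert np.abs(steady).max() == pytest.approx(1.0, rel=0.01)

    def test_dc_rejected_by_bandpass(self):
        rec = Recording(np.ones((1, 2000)), fs=250.0, channel_names=["c"])
        out = butterworth_filter(rec, FilterSpec("bandpass", 1.0, 50.0, 4,
                                                 zero_phase=True))
        assert np.abs(out.data[0, 500:-500]).max() < 1e-3

    def test_zero_phase_no_lag_on_pulse(self):
        n = 1000
        x = np.exp(-0.5 * ((np.arange(n) - 500) / 30.0) ** 2)
        rec = Recording(x[None, :], fs=250.0, channel_names=["c"])
        out = butterworth_filter(rec, FilterSpec("lowpass", None, 20.0, 4,
                                                 zero_phase=True))
        assert np.argmax(out.data[0]) == np.argmax(x)

    def test_causal_filter_lags(self):
        n = 1000
        x = np.exp(-0.5 * ((np.arange(n) - 500) / 30.0) ** 2)
        rec = Recording(x[None, :], fs=250.0, channel_names=["c"])
        out = butterworth_filter(rec, FilterSpec("lowpass", None, 5.0, 4,
                                                 zero_phase=False))
        assert np.argmax(out.data[0]) > np.argmax(x)

    def test_edge_at_nyquist_rejected(self):
        rec = tone(10.0, 100.0, 2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_filter(rec, FilterSpec("lowpass", None, 50.0, 4))

    def test_channel_names_preserved(self):
        rec = tone(10.0, 250.0, 2.0, n_channels=3)
        out = butterworth_filter(rec, FilterSpec("bandpass", 1.0, 50.0, 4))
        assert out.channel_names == rec.channel_names


class TestMbll:
    def _intensity_from_conc(self, dhbo, dhbr, params):
        """Forward model: concentrations -> optical densities -> intensities."""
        M = params.extinction * (params.distance_cm * np.asarray(params.dpf)[:, None])
        dod = M @ np.stack([dhbo, dhbr])
        return 10.0 ** (-dod)   # baseline intensity 1

    def test_round_trip_recovers_concentrations(self, rng):
        params = MbllParams()
        dhbo = 0.01 * np.sin(np.linspace(0, 6, 200))
        dhbr = -0.005 * np.cos(np.linspace(0, 6, 200))
        I = self._intensity_from_conc(dhbo, dhbr, params)
        rec = Recording(I, fs=10.0, channel_names=["w1", "w2"],
                        modality=Modality.NIRS_INTENSITY)
        hbo, hbr = mbll(rec, params, baseline_window=(0, 1))
        np.testing.assert_allclose(hbo.data[0], dhbo - dhbo[0], atol=1e-10)
        np.testing.assert_allclose(hbr.data[0], dhbr - dhbr[0], atol=1e-10)

    def test_identity_system(self):
        params = MbllParams(extinction=np.eye(2), dpf=(1.0, 1.0), distance_cm=1.0)
        I = np.vstack([np.full(10, 2.0), np.full(10, 3.0)])
        I[0, 5:] = 4.0
        rec = Recording(I, fs=1.0, channel_names=["w1", "w2"],
                        modality=Modality.NIRS_INTENSITY)
        hbo, hbr = mbll(rec, params, baseline_window=(0, 5))
        dod1 = -np.log10(I[0] / 2.0)
        np.testing.assert_allclose(hbo.data[0], dod1, atol=1e-12)
        np.testing.assert_allclose(hbr.data[0], 0.0, atol=1e-12)

    def test_baseline_intensity_gives_zero(self):
        rec = Recording(np.full((2, 8), 5.0), fs=1.0, channel_names=["a", "b"],
                        modality=Modality.NIRS_INTENSITY)
        hbo, hbr = mbll(rec)
        np.testing.assert_allclose(hbo.data, 0.0, atol=1e-14)
        np.testing.assert_allclose(hbr.data, 0.0, atol=1e-14)

    def test_linearity_of_od_stage(self, rng):
        params = MbllParams()
        a1 = 0.01 * rng.standard_normal(50)
        a2 = 0.01 * rng.standard_normal(50)
        out = {}
        for tag, (x, y) in {"1": (a1, np.zeros(50)), "2": (a2, np.zeros(50)),
                            "s": (2 * a1 + 3 * a2, np.zeros(50))}.items():
            I = self._intensity_from_conc(x, y, params)
            rec = Recording(I, fs=1.0, channel_names=["w1", "w2"],
                            modality=Modality.NIRS_INTENSITY)
            hbo, _ = mbll(rec, params, baseline_window=(0, 50))
            out[tag] = hbo.data[0] - hbo.data[0].mean()
        np.testing.assert_allclose(out["s"], 2 * out["1"] + 3 * out["2"], atol=1e-6)

    def test_guards(self):
        wrong = Recording(np.ones((2, 4)), fs=1.0, channel_names=["a", "b"],
                          modality=Modality.HBO)
        with pytest.raises(ValueError, match="NIRS_INTENSITY"):
            mbll(wrong)
        with pytest.raises(ValueError, match="singular"):
            MbllParams(extinction=np.ones((2, 2)))
        neg = Recording(np.ones((2, 4)), fs=1.0, channel_names=["a", "b"],
                        modality=Modality.NIRS_INTENSITY)
        neg.data[1, 2] = -0.5
        with pytest.raises(ValueError, match="positive"):
            mbll(neg)


class TestBaselineStandardize:
    def test_two_point_channel(self):
        rec = Recording(np.array([[1.0, 3.0]]), fs=1.0, channel_names=["a"])
        np.testing.assert_allclose(baseline_standardize(rec).data, [[-1.0, 1.0]])

    def test_idempotent(self, rng):
        rec = Recording(rng.standard_normal((3, 100)), fs=1.0,
                        channel_names=["a", "b", "c"])
        once = baseline_standardize(rec)
        twice = baseline_standardize(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_constant_channel_named_in_error(self):
        rec = Recording(np.vstack([np.arange(5.0), np.full(5, 2.0)]), fs=1.0,
                        channel_names=["good", "flat"])
        with pytest.raises(ValueError, match="flat"):
            baseline_standardize(rec)


class TestResampling:
    def test_tone_amplitude_preserved(self):
        rec = tone(1.0, 1000.0, 10.0)
        out = downsample(rec, 200.0)
        assert out.fs == 200.0
        steady = out.data[0, 200:-200]
        assert np.abs(steady).max() == pytest.approx(1.0, rel=0.01)

    def test_length_arithmetic(self):
        rec = Recording(np.zeros((1, 1000)), fs=1000.0, channel_names=["c"])
        assert downsample(rec, 200.0).n_samples == 200

    def test_dc_preserved(self):
        rec = Recording(np.full((1, 1000), 3.3), fs=1000.0, channel_names=["c"])
        out = downsample(rec, 100.0)
        steady = out.data[0, 10:-10]
        np.testing.assert_allclose(steady, 3.3, atol=1e-6)

    def test_upward_target_rejected(self):
        rec = Recording(np.zeros((1, 100)), fs=10.0, channel_names=["c"])
        with pytest.raises(ValueError, match="below"):
            downsample(rec, 20.0)


class TestMovingAverageDownsize:
    def test_single_full_window(self):
        rec = Recording(np.array([[1.0, 2.0, 3.0, 4.0]]), fs=4.0,
                        channel_names=["c"])
        out = moving_average_downsize(rec, window_s=1.0, target_fs=1.0)
        np.testing.assert_allclose(out.data, [[2.5]])
        assert out.fs == 1.0

    def test_constant_invariance(self):
        rec = Recording(np.full((2, 100), 7.0), fs=10.0, channel_names=["a", "b"])
        out = moving_average_downsize(rec, window_s=1.0, target_fs=5.0)
        np.testing.assert_allclose(out.data, 7.0)

    def test_degenerate_window_identity(self):
        rec = Recording(np.arange(10.0)[None, :], fs=10.0, channel_names=["c"])
        out = moving_average_downsize(rec, window_s=0.1, target_fs=10.0)
        np.testing.assert_allclose(out.data, rec.data)

    def test_window_longer_than_signal(self):
        rec = Recording(np.ones((1, 5)), fs=10.0, channel_names=["c"])
        with pytest.raises(ValueError, match="longer"):
            moving_average_downsize(rec, window_s=1.0, target_fs=1.0)

    def test_non_overlapping_blocks(self):
        rec = Recording(np.arange(8.0)[None, :], fs=4.0, channel_names=["c"])
        out = moving_average_downsize(rec, window_s=1.0, target_fs=1.0,
                                      non_overlapping=True)
        np.testing.assert_allclose(out.data, [[1.5, 5.5]])


class TestEnvelopeAndSync:
    def test_envelope_tracks_amplitude_steps(self):
        fs = 250.0
        t = np.arange(int(10 * fs)) / fs
        amp = np.where((t >= 4) & (t < 6), 2.0, 0.5)
        rec = Recording((amp * np.sin(2 * np.pi * 10 * t))[None, :], fs=fs,
                        channel_names=["c"])
        env = power_envelope(rec)
        assert env.n_samples == rec.n_samples
        # forward-looking 1-s RMS window: [4.0, 4.9] s windows lie fully
        # inside the high-amplitude segment [4, 6) s
        mid = env.data[0, int(4.0 * fs):int(4.9 * fs)].mean()
        base = env.data[0, int(1 * fs):int(3 * fs)].mean()
        # RMS of a sinusoid is amp/sqrt(2)
        assert mid == pytest.approx(2.0 / np.sqrt(2), rel=0.05)
        assert base == pytest.approx(0.5 / np.sqrt(2), rel=0.05)

    def test_synchronize_equalizes_grid(self):
        a = Recording(np.random.default_rng(0).standard_normal((2, 2500)),
                      fs=250.0, channel_names=["a", "b"])
        b = Recording(np.random.default_rng(1).standard_normal((3, 105)),
                      fs=10.42, channel_names=["x", "y", "z"])
        sa, sb = synchronize(a, b, target_fs=10.0)
        assert sa.fs == sb.fs == 10.0
        assert sa.n_samples == sb.n_samples
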