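import numpy as np
import pytest

from ambitopo.spectral import (ERSPArray, WaveletParams, average_ersp,
                               bandpass_and_notch, compute_ersp,
                               cycles_equal_frequency, morlet_sigma,
                               wavelet_power)
from ambitopo.synthetic import EpochSet

FS = 250.0


def make_epochs(signals, labels=None, fs=FS, channels=None):
    signals = np.asarray(signals, dtype=float)
    if signals.ndim == 1:
        signals = signals[None, None, :]
    n_trials, n_ch = signals.shape[:2]
    channels = channels or tuple(f"ch{i}" for i in range(n_ch))
    labels = labels if labels is not None else np.array(["LA"] * n_trials)
    return EpochSet(0, channels, fs, (-2.0, 2.0), signals, labels)


def spectrum_power_at(x, fs, f, core=slice(250, 750)):
    """Windowed spectral power on the central segment (edge-transient free)."""
    seg = x[core] * np.hanning(core.stop - core.start)
    spec = np.abs(np.fft.rfft(seg)) ** 2
    freqs = np.fft.rfftfreq(core.stop - core.start, 1 / fs)
    return spec[np.argmin(np.abs(freqs - f))]


t_epoch = np.arange(-2.0, 2.0, 1 / FS)


class TestFiltering:
    def test_notch_attenuates_50hz_by_40db(self):
        x = np.sin(2 * np.pi * 50.0 * t_epoch)
        out = bandpass_and_notch(make_epochs(x)).data[0, 0]
        before = spectrum_power_at(x, FS, 50.0)
        after = spectrum_power_at(out, FS, 50.0)
        assert 10 * np.log10(before / after) >= 40.0

    def test_in_band_tone_preserved_within_5pct(self):
        x = np.sin(2 * np.pi * 10.0 * t_epoch)
        out = bandpass_and_notch(make_epochs(x)).data[0, 0]
        core = slice(200, 800)  # away from filter edge transients
        ratio = np.sqrt(np.mean(out[core] ** 2) / np.mean(x[core] ** 2))
        assert abs(ratio - 1.0) < 0.05

    def test_dc_offset_removed(self):
        x = np.full_like(t_epoch, 3.0)
        out = bandpass_and_notch(make_epochs(x)).data[0, 0]
        assert np.abs(out[300:700]).max() < 0.05

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_and_notch(make_epochs(np.zeros_like(t_epoch)), hi=130.0)


class TestMorletSigma:
    def test_n_equals_f_gives_constant_sigma(self):
        f = np.arange(4.0, 40.5, 1.0)
        sig = morlet_sigma(f, cycles_equal_frequency)
        np.testing.assert_allclose(sig, 1.0 / (2 * np.pi))
        assert morlet_sigma(10.0) == pytest.approx(0.15915, abs=1e-5)
        assert morlet_sigma(40.0) == pytest.approx(0.15915, abs=1e-5)

    def test_alternative_cycles_rule(self):
        assert morlet_sigma(10.0, lambda f: 7.0) == pytest.approx(7 / (20 * np.pi))

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            morlet_sigma(0.0)


class TestWaveletPower:
    def test_tone_peaks_at_its_frequency_and_is_time_constant(self):
        wp = wavelet_power(make_epochs(np.sin(2 * np.pi * 10.0 * t_epoch)))
        prof = wp.data[0, 0].mean(axis=1)
        assert wp.freqs[np.argmax(prof)] == 10.0
        row = wp.data[0, 0, np.argmax(prof)]
        assert row.std() / row.mean() < 1e-6

    def test_quadratic_amplitude_scaling_and_zero_signal(self):
        x = np.sin(2 * np.pi * 10.0 * t_epoch)
        w1 = wavelet_power(make_epochs(x)).data
        w2 = wavelet_power(make_epochs(2 * x)).data
        np.testing.assert_allclose(w2, 4 * w1, rtol=1e-10)
        assert np.all(wavelet_power(make_epochs(np.zeros_like(x))).data == 0)

    def test_separated_tones_superpose_within_10pct(self):
        a = np.sin(2 * np.pi * 8.0 * t_epoch)
        b = np.sin(2 * np.pi * 30.0 * t_epoch)
        w_sum = wavelet_power(make_epochs(a + b)).data[0, 0]
        wa = wavelet_power(make_epochs(a)).data[0, 0]
        wb = wavelet_power(make_epochs(b)).data[0, 0]
        freqs = np.arange(4.0, 40.5, 1.0)
        for f, single in ((8.0, wa), (30.0, wb)):
            i = np.argmin(np.abs(freqs - f))
            assert np.abs(w_sum[i] / (wa + wb)[i] - 1.0).max() < 0.10
            assert np.abs(single[i].mean() / w_sum[i].mean() - 1.0) < 0.10

    def test_edge_artifact_guard(self):
        short = EpochSet(0, ("ch0",), FS, (-0.6, 0.6),
                         np.zeros((1, 1, 300)), np.array(["LA"]))
        with pytest.raises(ValueError, match="sigma"):
            wavelet_power(short)

    def test_matches_mne_up_to_per_frequency_normalization(self):
        """Independent oracle: mne's Morlet TFR with the same n=f rule."""
        from mne.time_frequency import tfr_array_morlet

        rng = np.random.default_rng(11)
        y = rng.standard_normal((3, 2, len(t_epoch)))
        params = WaveletParams(freqs=np.arange(5.0, 40.0, 7.0))
        wp = wavelet_power(make_epochs(y, labels=np.array(["LA", "HA", "LA"])), params)
        ref = tfr_array_morlet(y, FS, freqs=params.freqs, n_cycles=params.freqs,
                               output="power", zero_mean=False)
        idx = np.clip(np.round((params.times + 2.0) * FS).astype(int), 0, y.shape[-1] - 1)
        ref = ref[..., idx]
        ratio = wp.data / ref
        spread = ratio.std(axis=(0, 1, 3)) / ratio.mean(axis=(0, 1, 3))
        assert np.max(spread) < 1e-4


class TestERSP:
    def test_hand_example(self):
        """Post power 0.6 against a 0.4 baseline -> ERSP 0.5."""
        from ambitopo.spectral import PowerArray

        times = np.linspace(-0.5, 0.5, 10)
        data = np.where(times >= 0, 0.6, 0.4) * np.ones((1, 1, 1, 10))
        pw = PowerArray(data=data, channels=("ch0",), freqs=np.array([10.0]),
                        times=times)
        ersp = compute_ersp(pw)
        post = ersp.data[0, 0, 0, times >= 0]
        np.testing.assert_allclose(post, 0.5, rtol=1e-12)

    def test_constant_power_gives_zero_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 2, len(t_epoch)))
        labels = np.array(["LA", "HA", "LA", "HA"])
        e1 = compute_ersp(wavelet_power(make_epochs(x, labels)), labels=labels)
        e2 = compute_ersp(wavelet_power(make_epochs(5.0 * x, labels)), labels=labels)
        np.testing.assert_allclose(e1.data, e2.data, rtol=1e-9)
        # stationary tone + weak noise floor: pre == post in distribution,
        # so ERSP stays near zero at the tone frequency
        tone = np.sin(2 * np.pi * 10 * t_epoch)
        ez = compute_ersp(wavelet_power(make_epochs(tone)), baseline_floor=0.0)
        i10 = np.argmin(np.abs(ez.freqs - 10.0))
        assert np.abs(ez.data[0, 0, i10]).max() < 1e-6

    def test_zero_baseline_guard(self):
        from ambitopo.spectral import PowerArray

        times = np.linspace(-0.5, 0.5, 10)
        data = np.where(times >= 0, 1.0, 0.0) * np.ones((1, 1, 1, 10))
        pw = PowerArray(data=data, channels=("ch0",), freqs=np.array([10.0]),
                        times=times)
        with pytest.raises(FloatingPointError, match="ch0"):
            compute_ersp(pw)

    def test_average_over_condition(self):
        times = np.linspace(-0.5, 0.5, 5)
        base = np.ones((2, 1, 1, 5))
        base[0] *= 0.2
        base[1] *= 0.4
        ersp = ERSPArray(data=base, channels=("c",), freqs=np.array([8.0]),
                         times=times, labels=np.array(["HA", "HA"]))
        mean = average_ersp(ersp, condition="HA")
        np.testing.assert_allclose(mean.data, 0.3)
        assert mean.level == "subject_mean"
        with pytest.raises(ValueError, match="no trials"):
            average_ersp(ersp, condition="LA")

    def test_poststim_restriction(self):
        times = np.linspace(-0.5, 0.5, 11)
        e = ERSPArray(data=np.zeros((1, 1, 1, 11)), channels=("c",),
                      freqs=np.array([8.0]), times=times,
                      labels=np.array(["LA"]))
        assert np.all(e.poststim().times >= 0)
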