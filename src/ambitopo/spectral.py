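"""Filtering, Morlet wavelet power, and event-related spectral perturbation.

The time-frequency representation is the complex Morlet wavelet

    W(f, t) = exp(2 i pi f t) * exp(-t^2 / (2 sigma^2)),   sigma = n / (2 pi f),

with the cycles rule n = f by default: sigma is then the constant
1/(2 pi) ~ 0.159 s at every frequency, i.e. fixed temporal resolution and
frequency-proportional spectral bandwidth.  Wavelet power WP is the squared
magnitude of the signal's convolution with the unit-energy wavelet, and the
event-related spectral perturbation normalizes post-stimulus power by the
prestimulus baseline:

    ERSP(ch, f, t) = (WP(ch, f, t) - B(ch, f)) / B(ch, f),

where B is the time-mean of prestimulus WP per channel and frequency.  The
ratio makes ERSP dimensionless and invariant to global amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import signal as sps

from .synthetic import EpochSet


def bandpass_and_notch(
    epochs: EpochSet,
    lo: float = 1.0,
    hi: float = 100.0,
    notch: float | None = 50.0,
    numtaps: int | None = None,
    notch_width: float = 2.0,
) -> EpochSet:
    """Zero-phase FIR band-pass plus an optional notch.

    Both filters are linear-phase FIRs applied forward-backward
    (``filtfilt``), so cluster time bounds downstream suffer no group
    delay.  ``numtaps`` defaults to ~3 cycles of the low cut-off.
    """
    fs = epochs.fs
    nyq = fs / 2.0
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper cut-off {hi} Hz >= Nyquist {nyq} Hz")
    if numtaps is None:
        numtaps = int(3 * fs / lo) | 1  # odd
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    data = sps.filtfilt(taps, [1.0], epochs.data, axis=-1, padtype="odd",
                        padlen=min(3 * numtaps, epochs.data.shape[-1] - 1))
    if notch is not None:
        if notch >= nyq:
            raise ValueError(f"notch {notch} Hz >= Nyquist {nyq} Hz")
        ntaps = int(6 * fs / notch_width) | 1
        band = [notch - notch_width / 2.0, notch + notch_width / 2.0]
        ntap = sps.firwin(ntaps, band, fs=fs)  # band-stop (pass_zero=True)
        data = sps.filtfilt(ntap, [1.0], data, axis=-1, padtype="odd",
                            padlen=min(3 * ntaps, data.shape[-1] - 1))
    return EpochSet(epochs.subject_id, epochs.channels, fs, epochs.window,
                    data, epochs.labels.copy())


def cycles_equal_frequency(f: np.ndarray) -> np.ndarray:
    """The n = f cycles rule (constant sigma = 1/(2 pi) s)."""
    return np.asarray(f, dtype=float)


def morlet_sigma(f, cycles_rule: Callable = cycles_equal_frequency):
    """Gaussian width sigma = n(f) / (2 pi f) in seconds."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    n = np.asarray(cycles_rule(f), dtype=float)
    if np.any(n <= 0):
        raise ValueError("cycles rule must return positive n")
    out = n / (2.0 * np.pi * f)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class WaveletParams:
    """Analysis grid for wavelet power / ERSP.

    Defaults: 4-40 Hz in 1-Hz steps, 50 output time points over
    [-0.5, +0.5] s around stimulus onset.
    """

    freqs: np.ndarray = field(default_factory=lambda: np.arange(4.0, 40.0 + 0.5, 1.0))
    cycles_rule: Callable = cycles_equal_frequency
    t_start: float = -0.5
    t_stop: float = 0.5
    n_times: int = 50
    edge_sigmas: float = 3.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or len(f) < 1 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if f[0] < 4.0 - 1e-9 or f[-1] > 40.0 + 1e-9:
            raise ValueError("freqs must lie within [4, 40] Hz")
        object.__setattr__(self, "freqs", f)
        if not self.t_start < 0 < self.t_stop:
            raise ValueError("time grid must straddle stimulus onset")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_stop, self.n_times)

    @property
    def sigmas(self) -> np.ndarray:
        return np.atleast_1d(morlet_sigma(self.freqs, self.cycles_rule))


def morlet_kernel(f: float, sigma: float, fs: float) -> np.ndarray:
    """Unit-energy complex Morlet wavelet sampled at fs, support +-5 sigma."""
    half = int(np.ceil(5.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * sigma**2))
    w /= np.sqrt(np.sum(np.abs(w) ** 2))
    return w


def wavelet_power(epochs: EpochSet, params: WaveletParams | None = None) -> "PowerArray":
    """Per-trial wavelet power on the analysis grid.

    FFT convolution of every (trial, channel) signal with the complex
    wavelet at each grid frequency; power = |conv|^2 sampled at the output
    time points.  Raises if the output window comes within
    ``params.edge_sigmas`` Gaussian widths of the epoch edges, where
    convolution edge artifacts would leak in (the 4-s epoch around a
    [-0.5, 0.5] s window is safe by a wide margin).
    """
    if params is None:
        params = WaveletParams()
    fs = epochs.fs
    times = epochs.times
    out_times = params.times
    sigmas = params.sigmas
    guard = params.edge_sigmas * sigmas.max()
    if out_times[0] - guard < times[0] or out_times[-1] + guard > times[-1]:
        raise ValueError(
            f"output window [{out_times[0]}, {out_times[-1]}] s within "
            f"{params.edge_sigmas} sigma ({guard:.3f} s) of epoch edges")
    if params.freqs[-1] >= fs / 2.0:
        raise ValueError("top analysis frequency at or above Nyquist")

    n_trials, n_ch, n_samp = epochs.data.shape
    kernels = [morlet_kernel(f, s, fs) for f, s in zip(params.freqs, sigmas)]
    max_half = max((len(k) - 1) // 2 for k in kernels)

    # crop the epoch to the output window plus full kernel support; samples
    # farther out cannot influence the requested output points
    lo_idx = max(0, int(np.floor((out_times[0] - times[0]) * fs)) - max_half)
    hi_idx = min(n_samp, int(np.ceil((out_times[-1] - times[0]) * fs)) + max_half + 2)
    crop = epochs.data[..., lo_idx:hi_idx]
    crop_t0 = times[0] + lo_idx / fs
    n_crop = crop.shape[-1]
    flat = crop.reshape(n_trials * n_ch, n_crop)
    # nearest cropped sample of each output time point
    t_idx = np.clip(np.round((out_times - crop_t0) * fs).astype(int), 0, n_crop - 1)

    from scipy.fft import fft, ifft, next_fast_len

    max_len = max(len(k) for k in kernels)
    nfft = next_fast_len(n_crop + max_len - 1)
    X = fft(flat, n=nfft, axis=-1)

    wp = np.empty((n_trials, n_ch, len(params.freqs), len(out_times)))
    for j, k in enumerate(kernels):
        K = fft(k, n=nfft)
        conv = ifft(X * K, axis=-1)
        # 'same' alignment: convolution center lag = (len(k)-1)//2
        start = (len(k) - 1) // 2
        seg = conv[:, start + t_idx[0]: start + t_idx[-1] + 1]
        p = np.abs(seg[:, t_idx - t_idx[0]]) ** 2
        wp[:, :, j, :] = p.reshape(n_trials, n_ch, len(out_times))
    return PowerArray(data=wp, channels=epochs.channels, freqs=params.freqs.copy(),
                      times=out_times.copy())


def measure_box_power(data: np.ndarray, fs: float, t0: float,
                      f_lo: float, f_hi: float, t_lo: float, t_hi: float,
                      cycles_rule: Callable = cycles_equal_frequency,
                      n_probe_freqs: int = 3) -> float:
    """Mean wavelet power of ``data`` inside a frequency-band x time-window box.

    ``data`` is (n_signals, n_samples) with the first sample at time ``t0``
    seconds.  Used by the synthetic generator to calibrate injected burst
    amplitudes against the background power the analysis wavelet actually
    measures.
    """
    from scipy.fft import fft, ifft, next_fast_len

    data = np.atleast_2d(data)
    n_samp = data.shape[-1]
    freqs = np.linspace(f_lo, f_hi, n_probe_freqs)
    sigmas = np.atleast_1d(morlet_sigma(freqs, cycles_rule))
    times = t0 + np.arange(n_samp) / fs
    sel = (times >= t_lo) & (times <= t_hi)
    if not np.any(sel):
        raise ValueError("time window contains no samples")
    kernels = [morlet_kernel(f, s, fs) for f, s in zip(freqs, sigmas)]
    nfft = next_fast_len(n_samp + max(len(k) for k in kernels) - 1)
    X = fft(data, n=nfft, axis=-1)
    total = 0.0
    for k in kernels:
        conv = ifft(X * fft(k, n=nfft), axis=-1)
        start = (len(k) - 1) // 2
        same = conv[:, start:start + n_samp]
        total += float(np.mean(np.abs(same[:, sel]) ** 2))
    return total / len(kernels)


def sinusoid_wavelet_gain(fc: float, fs: float,
                          cycles_rule: Callable = cycles_equal_frequency) -> float:
    """Measured wavelet power of a unit-amplitude sinusoid at its own frequency.

    For the unit-energy kernel this is |w_hat(fc)|^2 / 4 (the wavelet picks
    up the positive-frequency half of the sinusoid); used to convert a
    target power increase into a burst amplitude.
    """
    k = morlet_kernel(fc, float(morlet_sigma(fc, cycles_rule)), fs)
    t = np.arange(len(k)) / fs
    resp = np.abs(np.sum(np.conj(k) * np.exp(2j * np.pi * fc * t))) ** 2
    return float(resp) / 4.0


@dataclass
class PowerArray:
    """(trial, channel, frequency, time) wavelet power with axis metadata."""

    data: np.ndarray
    channels: tuple[str, ...]
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.data.shape[1:] != (len(self.channels), len(self.freqs), len(self.times)):
            raise ValueError("power shape does not match axes")
        if np.any(self.data < 0):
            raise ValueError("wavelet power must be nonnegative")


@dataclass
class ERSPArray:
    """Relative spectral perturbation over (channel, frequency, time).

    ``level`` is "trial" (leading trial axis present) or "subject_mean";
    ``condition`` tags averaged arrays with their class.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    freqs: np.ndarray
    times: np.ndarray
    level: str = "trial"
    condition: str = "none"
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        expect = (len(self.channels), len(self.freqs), len(self.times))
        core = self.data.shape[1:] if self.level == "trial" else self.data.shape
        if core != expect:
            raise ValueError(f"ERSP shape {self.data.shape} does not match axes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite ERSP values")

    def poststim(self) -> "ERSPArray":
        """Restrict the time axis to [0, +inf) for the statistics stage."""
        sel = self.times >= 0
        return replace(self, data=self.data[..., sel], times=self.times[sel])


def compute_ersp(power: PowerArray, baseline_window: tuple[float, float] = (-0.5, 0.0),
                 labels: np.ndarray | None = None,
                 baseline_floor: float = 1e-12) -> ERSPArray:
    """ERSP = (WP - B) / B with B the prestimulus time-mean per (ch, f).

    The baseline is computed per trial, so single-trial ERSP is
    self-normalized; ``baseline_window`` must end at or before onset.
    """
    b0, b1 = baseline_window
    if b1 > 0 or b0 >= b1:
        raise ValueError("baseline window must lie within the prestimulus segment")
    sel = (power.times >= b0) & (power.times < b1)
    if not np.any(sel):
        raise ValueError("baseline window contains no time samples")
    B = power.data[..., sel].mean(axis=-1, keepdims=True)
    bad = B.squeeze(-1) <= baseline_floor
    if np.any(bad):
        tr, ch, fr = np.unravel_index(np.argmax(bad), bad.shape)
        raise FloatingPointError(
            f"baseline power below floor {baseline_floor} at trial {tr}, "
            f"channel {power.channels[ch]}, {power.freqs[fr]:g} Hz")
    ersp = (power.data - B) / B
    return ERSPArray(data=ersp, channels=power.channels, freqs=power.freqs.copy(),
                     times=power.times.copy(), level="trial", labels=labels)


def average_ersp(ersp: ERSPArray, labels: np.ndarray | None = None,
                 condition: str = "HA") -> ERSPArray:
    """Subject-mean ERSP over all trials of one condition."""
    if ersp.level != "trial":
        raise ValueError("average_ersp expects trial-level ERSP")
    if labels is None:
        labels = ersp.labels
    if labels is None:
        raise ValueError("labels required")
    labels = np.asarray(labels)
    sel = labels == condition
    if not np.any(sel):
        raise ValueError(f"no trials of condition {condition!r}")
    return ERSPArray(data=ersp.data[sel].mean(axis=0), channels=ersp.channels,
                     freqs=ersp.freqs.copy(), times=ersp.times.copy(),
                     level="subject_mean", condition=condition)


def subject_condition_ersp(epochs: EpochSet, params: WaveletParams | None = None,
                           baseline_window: tuple[float, float] = (-0.5, 0.0),
                           ) -> tuple[ERSPArray, ERSPArray, ERSPArray]:
    """Convenience: per-trial ERSP plus HA and LA subject means."""
    wp = wavelet_power(epochs, params)
    trial = compute_ersp(wp, baseline_window, labels=epochs.labels)
    return trial, average_ersp(trial, condition="HA"), average_ersp(trial, condition="LA")
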